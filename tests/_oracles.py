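"""Independent numerical oracles used by the tests.

Deliberately brute-force and independent of the package's closed forms:
Biot-Savart line quadrature for loop fields, and direct spherical-grid
integration of the Kelvin point kernel for the uniformly loaded ball.
"""

import numpy as np

MU0 = 4e-7 * np.pi


def biot_savart_loop(loop_radius, loop_z, ampere_turns, points, segments=10_000):
    """Midpoint-rule Biot-Savart line integral around one circular loop."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    phi = (np.arange(segments) + 0.5) * (2.0 * np.pi / segments)
    a = loop_radius
    wire = np.column_stack([a * np.cos(phi), a * np.sin(phi), np.full_like(phi, loop_z)])
    dl = np.column_stack([-a * np.sin(phi), a * np.cos(phi), np.zeros_like(phi)]) * (
        2.0 * np.pi / segments
    )
    out = np.empty_like(pts)
    for k, p in enumerate(pts):
        r = p - wire
        rn = np.linalg.norm(r, axis=1)
        out[k] = MU0 * ampere_turns / (4.0 * np.pi) * np.sum(
            np.cross(dl, r) / rn[:, None] ** 3, axis=0
        )
    return out if np.asarray(points).ndim == 2 else out[0]


def kelvin_ball_quadrature(point, R, force_density, G, nu, n_r=60, n_t=60, n_p=60):
    """Numerically integrate the Kelvin point kernel over the loaded ball.

    Spherical midpoint grid; the evaluation point must lie outside the
    ball or the integrand is singular.
    """
    x = np.asarray(point, dtype=float)
    r = (np.arange(n_r) + 0.5) * (R / n_r)
    t = (np.arange(n_t) + 0.5) * (np.pi / n_t)
    p = (np.arange(n_p) + 0.5) * (2.0 * np.pi / n_p)
    rr, tt, pp = np.meshgrid(r, t, p, indexing="ij")
    y = np.stack(
        [rr * np.sin(tt) * np.cos(pp), rr * np.sin(tt) * np.sin(pp), rr * np.cos(tt)], axis=-1
    ).reshape(-1, 3)
    w = (rr**2 * np.sin(tt)).reshape(-1) * (R / n_r) * (np.pi / n_t) * (2.0 * np.pi / n_p)
    d = x[None, :] - y
    dist = np.linalg.norm(d, axis=1)
    C = force_density / (16.0 * np.pi * G * (1.0 - nu))
    u = C * (d * (d[:, 2] / dist**3)[:, None])
    u[:, 2] += C * (3.0 - 4.0 * nu) / dist
    return (u * w[:, None]).sum(axis=0)
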