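"""Kelvin fundamental solution and the uniformly loaded ball benchmark.

The Kelvin solution is the displacement of an infinite, linear isotropic
elastic solid under a point force.  Superposing it over a ball carrying a
uniform axial body force density gives a closed-form displacement field
everywhere (inside and outside the ball), which serves as an independent
analytic benchmark for the finite-element forward solver: a spherical
inclusion deep inside a large domain should reproduce it.

For a point force P e_z at the origin::

    u_i(x) = P / (16 pi G (1 - nu)) * [ (3 - 4 nu) delta_iz / r
                                        + x_i x_z / r^3 ]

Writing x_i x_z / r^3 = delta_iz / r - d2r/dx_i dx_z, the ball superposition
reduces to derivatives of the Newtonian potential Phi = int 1/|x-y| dy and
the biharmonic potential Psi = int |x-y| dy of the ball, both of which are
classical closed forms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kelvin_point_displacement", "kelvin_ball_displacement", "kelvin_ball_center_uz"]


def kelvin_point_displacement(points, force_z: float, G: float, nu: float) -> np.ndarray:
    """Displacement [m] at ``points`` due to a point force ``force_z`` [N]
    along +z at the origin, in an infinite medium."""
    x = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(x, axis=1)
    if np.any(r == 0):
        raise ValueError("Kelvin point solution is singular at the origin")
    C = force_z / (16.0 * np.pi * G * (1.0 - nu))
    u = C * (x * (x[:, 2] / r**3)[:, None])
    u[:, 2] += C * (3.0 - 4.0 * nu) / r
    return u if np.asarray(points).ndim == 2 else u[0]


def _phi_psi_derivs(s: np.ndarray, R: float):
    """phi(s), psi'(s)/s and psi''(s) for the ball potentials.

    phi(s)  = int_ball 1/|x-y| dy
    psi(s)  = int_ball |x-y| dy
    Returns (phi, dpsi_over_s, d2psi); the Hessian of psi(|x|) is
    d2psi * xx^T/s^2 + (dpsi/s) (I - xx^T/s^2).
    """
    V = 4.0 * np.pi * R**3 / 3.0
    inside = s <= R
    s_out = np.where(inside, R, s)  # safe divisor; interior branch ignores it
    phi = np.where(inside, 2.0 * np.pi * (R**2 - s**2 / 3.0), V / s_out)
    # psi interior: pi R^4 + (2 pi/3) R^2 s^2 - (pi/15) s^4
    dpsi_over_s = np.where(
        inside,
        (4.0 * np.pi / 3.0) * R**2 - (4.0 * np.pi / 15.0) * s**2,
        V * (1.0 - R**2 / (5.0 * s_out**2)) / s_out,
    )
    d2psi = np.where(
        inside,
        (4.0 * np.pi / 3.0) * R**2 - (4.0 * np.pi / 5.0) * s**2,
        V * (2.0 * R**2 / (5.0 * s_out**3)),
    )
    return phi, dpsi_over_s, d2psi


def kelvin_ball_displacement(points, R: float, force_density: float, G: float, nu: float) -> np.ndarray:
    """Displacement [m] of an infinite medium under a uniform axial body
    force ``force_density`` [N/m^3] inside the ball of radius ``R`` centered
    at the origin.  Valid at interior and exterior points; smooth across the
    ball surface."""
    x = np.atleast_2d(np.asarray(points, dtype=float))
    s = np.linalg.norm(x, axis=1)
    C = force_density / (16.0 * np.pi * G * (1.0 - nu))
    phi, dpsi_over_s, d2psi = _phi_psi_derivs(s, R)

    # Hessian of psi: H_ij = d2psi * n_i n_j + dpsi_over_s * (delta_ij - n_i n_j)
    safe = np.maximum(s, 1e-300)
    n = x / safe[:, None]
    Hz = (d2psi - dpsi_over_s)[:, None] * n * n[:, 2:3] # column i of H at j=z, minus diag part
    u = -C * Hz
    u[:, 2] -= C * dpsi_over_s
    u[:, 2] += C * (4.0 - 4.0 * nu) * phi
    # s -> 0 limit: n is ill-defined but (d2psi - dpsi_over_s) -> 0, so Hz -> 0.
    u[s == 0.0, :2] = 0.0
    if np.any(s == 0.0):
        u[s == 0.0, 2] = C * ((4.0 - 4.0 * nu) * 2.0 * np.pi * R**2 - (4.0 * np.pi / 3.0) * R**2)
    return u if np.asarray(points).ndim == 2 else u[0]


def kelvin_ball_center_uz(R: float, force_density: float, G: float, nu: float) -> float:
    """Closed-form axial displacement at the ball center::

        u_z(0) = f R^2 (20/3 - 8 nu) / (16 G (1 - nu))
    """
    return force_density * R**2 * (20.0 / 3.0 - 8.0 * nu) / (16.0 * G * (1.0 - nu))
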