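"""Magnetostatics of a coaxial Helmholtz/Maxwell coil pair.

A Helmholtz pair (two coaxial loops, co-directed currents, spacing ``d``)
magnetizes nanoparticles with a nearly uniform axial field; a Maxwell pair
(opposed currents, spacing ``d = sqrt(3)*a``) superposes a nearly uniform
axial gradient that exerts force on the magnetized particles.  This module
provides the closed-form axial field and gradient of both pairs, the full
off-axis field of a circular loop via complete elliptic integrals, force on
a nanoparticle load, and the inverse "design" calculators that size the
ampere-turns for a target center field or center force.

All quantities are SI: meters, Tesla, Tesla/m, Newtons, ampere-turns (the
product n*I of turns and current).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ellipe, ellipk

from .constants import MU0

__all__ = [
    "CoilSpec",
    "NanoparticleLoad",
    "FieldSample",
    "CoilRoleError",
    "helmholtz_axial_field",
    "maxwell_axial_field",
    "maxwell_axial_gradient",
    "loop_field",
    "pair_field",
    "pair_force_vectors",
    "force_on_load",
    "required_helmholtz_ampere_turns",
    "required_maxwell_ampere_turns",
    "imaging_volume_uniformity",
    "UniformityReport",
]


class CoilRoleError(ValueError):
    """Raised when an operation receives a coil with the wrong role."""


@dataclass(frozen=True)
class CoilSpec:
    """Geometry and excitation of one coaxial coil pair.

    Parameters
    ----------
    radius_a : float
        Loop radius ``a`` [m].
    spacing_d : float
        Axial interspacing ``d`` between the two loops [m].  The loops sit
        at ``z = +/- d/2`` on a common axis through the origin.
    ampere_turns : float
        Excitation ``n*I`` [A] of each loop.
    role : str
        ``"helmholtz"`` (co-directed currents) or ``"maxwell"`` (opposed
        currents; the loop at ``+d/2`` carries the positive current).
    """

    radius_a: float
    spacing_d: float
    ampere_turns: float
    role: str

    def __post_init__(self) -> None:
        if not self.radius_a > 0:
            raise ValueError(f"radius_a must be positive, got {self.radius_a}")
        if not self.spacing_d > 0:
            raise ValueError(f"spacing_d must be positive, got {self.spacing_d}")
        if not math.isfinite(self.ampere_turns):
            raise ValueError("ampere_turns must be finite")
        if self.role not in ("helmholtz", "maxwell"):
            raise ValueError(f"role must be 'helmholtz' or 'maxwell', got {self.role!r}")

    @classmethod
    def helmholtz(cls, radius_a: float, ampere_turns: float, spacing_d: float | None = None) -> "CoilSpec":
        """Helmholtz pair; default spacing is the optimal ``d = a``."""
        return cls(radius_a, radius_a if spacing_d is None else spacing_d, ampere_turns, "helmholtz")

    @classmethod
    def maxwell(cls, radius_a: float, ampere_turns: float, spacing_d: float | None = None) -> "CoilSpec":
        """Maxwell pair; default spacing is the optimal ``d = sqrt(3)*a``."""
        d = math.sqrt(3.0) * radius_a if spacing_d is None else spacing_d
        return cls(radius_a, d, ampere_turns, "maxwell")

    def with_ampere_turns(self, ampere_turns: float) -> "CoilSpec":
        return dataclasses.replace(self, ampere_turns=ampere_turns)


@dataclass(frozen=True)
class NanoparticleLoad:
    """Magnetic nanoparticle deposit at a region of interest.

    ``saturation_magnetization`` is the specific (per-mass) saturated
    moment [A*m^2/kg]; superparamagnetic iron-oxide particles saturate
    around 20-40 A*m^2/kg at fields of 0.2-0.5 T.  Below saturation the
    per-particle moment follows the susceptibility law ``m = chi*H``;
    ``susceptibility_chi`` is the corresponding mass susceptibility
    [m^3/kg].  ``weight_w`` is the total deposited particle mass [kg].
    """

    saturation_magnetization: float
    susceptibility_chi: float
    weight_w: float
    saturation_field_T: float = 0.4

    def __post_init__(self) -> None:
        if self.saturation_magnetization < 0:
            raise ValueError("saturation_magnetization must be >= 0")
        if self.weight_w < 0:
            raise ValueError("weight_w must be >= 0")
        if self.saturation_field_T <= 0:
            raise ValueError("saturation_field_T must be > 0")

    def moment_per_kg(self, field_magnitude_T: float, regime: str = "auto") -> float:
        """Specific moment [A*m^2/kg] at the given field magnitude.

        ``regime`` is ``"auto"`` (saturated iff |B| >= saturation_field_T),
        ``"saturated"`` or ``"linear"``.  The linear regime uses
        ``m = chi*H = chi*|B|/mu0`` clipped at saturation; no interpolation
        between regimes is attempted.
        """
        if regime == "saturated":
            return self.saturation_magnetization
        linear = self.susceptibility_chi * field_magnitude_T / MU0
        if regime == "linear":
            return min(linear, self.saturation_magnetization)
        if regime == "auto":
            if field_magnitude_T >= self.saturation_field_T:
                return self.saturation_magnetization
            return min(linear, self.saturation_magnetization)
        raise ValueError(f"unknown regime {regime!r}")


@dataclass(frozen=True)
class FieldSample:
    """Field quantities at one point: B vector [T] and axial gradient [T/m]."""

    position: np.ndarray
    B: np.ndarray
    dBz_dz: float

    @property
    def B_magnitude(self) -> float:
        return float(np.linalg.norm(self.B))


def _require_role(coil: CoilSpec, role: str) -> None:
    if coil.role != role:
        raise CoilRoleError(f"operation requires a {role} coil, got role={coil.role!r}")


def helmholtz_axial_field(coil: CoilSpec, z) -> np.ndarray | float:
    """Axial field B_z(z) [T] of a Helmholtz pair on its axis.

    Sum of the two single-loop on-axis fields with co-directed currents::

        B_z(z) = mu0*n*I*a^2/2 * ( [(d/2 - z)^2 + a^2]^(-3/2)
                                 + [(d/2 + z)^2 + a^2]^(-3/2) )

    an even function of z.  At the optimal spacing ``d = a`` the center
    value is ``(4/5)^(3/2) * mu0*n*I/a ~= 0.716 mu0*n*I/a``.
    """
    _require_role(coil, "helmholtz")
    a, d, ni = coil.radius_a, coil.spacing_d, coil.ampere_turns
    z = np.asarray(z, dtype=float)
    term = lambda s: ((d / 2 + s * z) ** 2 + a**2) ** -1.5  # noqa: E731
    out = 0.5 * MU0 * ni * a**2 * (term(-1.0) + term(+1.0))
    return out if out.ndim else float(out)


def maxwell_axial_field(coil: CoilSpec, z) -> np.ndarray | float:
    """Axial field B_z(z) [T] of a Maxwell pair (odd in z, zero at center)."""
    _require_role(coil, "maxwell")
    a, d, ni = coil.radius_a, coil.spacing_d, coil.ampere_turns
    z = np.asarray(z, dtype=float)
    out = 0.5 * MU0 * ni * a**2 * (
        ((z - d / 2) ** 2 + a**2) ** -1.5 - ((z + d / 2) ** 2 + a**2) ** -1.5
    )
    return out if out.ndim else float(out)


def maxwell_axial_gradient(coil: CoilSpec, z) -> np.ndarray | float:
    """Axial gradient GR_z(z) = dB_z/dz [T/m] of a Maxwell pair on its axis.

    ::

        GR_z(z) = 3*mu0*n*I*a^2/2 * ( (d/2 - z) / [(d/2 - z)^2 + a^2]^(5/2)
                                    + (d/2 + z) / [(d/2 + z)^2 + a^2]^(5/2) )

    an even function of z, maximally flat at the center for
    ``d = sqrt(3)*a`` where ``GR_z(0) = 0.641 mu0*n*I/a^2``.
    """
    _require_role(coil, "maxwell")
    a, d, ni = coil.radius_a, coil.spacing_d, coil.ampere_turns
    z = np.asarray(z, dtype=float)

    def term(s):
        q = d / 2 + s * z
        return q * (q**2 + a**2) ** -2.5

    out = 1.5 * MU0 * ni * a**2 * (term(-1.0) + term(+1.0))
    return out if out.ndim else float(out)


def loop_field(loop_radius: float, loop_z: float, ampere_turns: float, point) -> np.ndarray:
    """Full off-axis field [T] of a single circular current loop.

    The loop of radius ``loop_radius`` lies in the plane ``z = loop_z``,
    centered on the z-axis, carrying ``ampere_turns`` amps (positive
    current = counter-clockwise seen from +z, giving B_z > 0 on axis).
    Uses the standard complete-elliptic-integral closed form; points are
    accepted as shape ``(3,)`` or ``(n, 3)``.

    Raises
    ------
    ValueError
        If a point lies (numerically) on the wire circle itself.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    if pts.shape[-1] != 3:
        raise ValueError("point must have 3 components")
    a = float(loop_radius)
    x, y = pts[:, 0], pts[:, 1]
    zeta = pts[:, 2] - float(loop_z)
    rho = np.hypot(x, y)

    wire_dist2 = (rho - a) ** 2 + zeta**2
    if np.any(wire_dist2 < (1e-9 * a) ** 2):
        raise ValueError("field evaluation on the wire circle is singular")

    B = np.zeros_like(pts)
    pref = MU0 * ampere_turns / (2.0 * np.pi)

    on_axis = rho < 1e-12 * a
    off = ~on_axis
    # On-axis limit: purely axial.
    B[on_axis, 2] = MU0 * ampere_turns * a**2 / (2.0 * (a**2 + zeta[on_axis] ** 2) ** 1.5)

    if np.any(off):
        r, zz = rho[off], zeta[off]
        denom = (a + r) ** 2 + zz**2
        m = 4.0 * a * r / denom
        K, E = ellipk(m), ellipe(m)
        near = (a - r) ** 2 + zz**2
        Bz = pref / np.sqrt(denom) * (K + E * (a**2 - r**2 - zz**2) / near)
        Brho = pref * zz / (r * np.sqrt(denom)) * (-K + E * (a**2 + r**2 + zz**2) / near)
        B[off, 2] = Bz
        B[off, 0] = Brho * x[off] / r
        B[off, 1] = Brho * y[off] / r

    return B if np.asarray(point).ndim == 2 else B[0]


def _pair_loops(coil: CoilSpec) -> list[tuple[float, float, float]]:
    """(radius, z, signed ampere-turns) for the two loops of a pair."""
    sign_lower = 1.0 if coil.role == "helmholtz" else -1.0
    return [
        (coil.radius_a, +coil.spacing_d / 2.0, coil.ampere_turns),
        (coil.radius_a, -coil.spacing_d / 2.0, sign_lower * coil.ampere_turns),
    ]


def _total_B(helmholtz: CoilSpec, maxwell: CoilSpec, pts: np.ndarray) -> np.ndarray:
    B = np.zeros_like(pts)
    for a, z0, ni in _pair_loops(helmholtz) + _pair_loops(maxwell):
        B += loop_field(a, z0, ni, pts)
    return B


def pair_field(helmholtz: CoilSpec, maxwell: CoilSpec, point) -> FieldSample:
    """Superposed field of the coaxial, concentric Helmholtz/Maxwell pair.

    The axial gradient dB_z/dz is evaluated by central differences of the
    elliptic-integral field with step ``1e-5 * a`` (the closed-form
    derivative is only available on the axis).
    """
    _require_role(helmholtz, "helmholtz")
    _require_role(maxwell, "maxwell")
    p = np.asarray(point, dtype=float)
    B = _total_B(helmholtz, maxwell, np.atleast_2d(p))[0]
    h = 1e-5 * helmholtz.radius_a
    step = np.array([0.0, 0.0, h])
    pts = np.vstack([p + step, p - step])
    Bpm = _total_B(helmholtz, maxwell, pts)
    dBz = float((Bpm[0, 2] - Bpm[1, 2]) / (2.0 * h))
    return FieldSample(position=p.copy(), B=B, dBz_dz=dBz)


def pair_force_vectors(
    helmholtz: CoilSpec, maxwell: CoilSpec, load: NanoparticleLoad, points, regime: str = "auto"
) -> np.ndarray:
    """Force vectors F = (m . grad) B [N] at many points, m = m_z(B) z_hat.

    With the moment pinned along +z (the Helmholtz field direction), the
    force reduces to ``m_z * dB/dz``, all three components, evaluated by
    central differences in z of the loop fields.  Used for the
    vector-map view of the imaging region.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h = 1e-5 * helmholtz.radius_a
    step = np.array([0.0, 0.0, h])
    B0 = _total_B(helmholtz, maxwell, pts)
    dB = (_total_B(helmholtz, maxwell, pts + step) - _total_B(helmholtz, maxwell, pts - step)) / (2 * h)
    Bmag = np.linalg.norm(B0, axis=1)
    m = np.array([load.moment_per_kg(b, regime) for b in Bmag]) * load.weight_w
    return m[:, None] * dB


def force_on_load(load: NanoparticleLoad, sample: FieldSample, regime: str = "auto") -> np.ndarray:
    """Axial magnetic force vector [N] on a nanoparticle load at a sample.

    In the saturated regime ``F_z = saturation_magnetization * w * dB_z/dz``;
    zero load gives zero force.
    """
    m = load.moment_per_kg(sample.B_magnitude, regime) * load.weight_w
    return np.array([0.0, 0.0, m * sample.dBz_dz])


def required_helmholtz_ampere_turns(target_B: float, radius_a: float) -> float:
    """Ampere-turns for a Helmholtz pair (d = a) to reach B at its center.

    Inverts the center-field formula ``B_z(0) = (4/5)^(3/2) mu0 nI / a``;
    e.g. 0.4 T at a = 0.075 m needs about 3.34e4 A.
    """
    if not target_B >= 0:
        raise ValueError("target_B must be >= 0")
    if not radius_a > 0:
        raise ValueError("radius_a must be positive")
    unit = CoilSpec.helmholtz(radius_a, 1.0)
    return float(target_B / helmholtz_axial_field(unit, 0.0))


def required_maxwell_ampere_turns(target_force: float, load: NanoparticleLoad, radius_a: float) -> float:
    """Ampere-turns for a Maxwell pair (d = sqrt(3) a) to exert a target
    axial force on a saturated load at the center.

    Inverts ``F_z = M_sat * w * 0.641 mu0 nI / a^2``.
    """
    if load.weight_w <= 0:
        raise ZeroDivisionError("load.weight_w must be positive to size the gradient coil")
    if load.saturation_magnetization <= 0:
        raise ZeroDivisionError("load.saturation_magnetization must be positive")
    if not radius_a > 0:
        raise ValueError("radius_a must be positive")
    unit = CoilSpec.maxwell(radius_a, 1.0)
    gr = maxwell_axial_gradient(unit, 0.0)
    return float(target_force / (load.saturation_magnetization * load.weight_w * gr))


@dataclass(frozen=True)
class UniformityReport:
    """Force uniformity over the cubic imaging volume of side 2a/3."""

    cube_side: float
    grid_n: int
    center_force: float
    max_relative_deviation: float
    max_axial_relative_deviation: float
    axial_z: np.ndarray
    axial_force: np.ndarray


def imaging_volume_uniformity(
    helmholtz: CoilSpec, maxwell: CoilSpec, grid_n: int = 11, load: NanoparticleLoad | None = None
) -> UniformityReport:
    """Sample the axial force over the cube of side 2a/3 at the center.

    The force on a saturated load is proportional to dB_z/dz, so the
    report is computed for a unit saturated moment unless a load is given.
    Reports the maximum relative deviation of F_z from its center value
    over the full cube and along the axis, plus the axial profile.
    """
    if grid_n < 3:
        raise ValueError("grid_n must be >= 3")
    if load is None:
        load = NanoparticleLoad(saturation_magnetization=1.0, susceptibility_chi=0.0, weight_w=1.0)
    a = helmholtz.radius_a
    side = 2.0 * a / 3.0
    c = np.linspace(-side / 2.0, side / 2.0, grid_n)
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    Fz = pair_force_vectors(helmholtz, maxwell, load, pts, regime="saturated")[:, 2]
    Fz = Fz.reshape(grid_n, grid_n, grid_n)
    ic = grid_n // 2
    f0 = Fz[ic, ic, ic]
    dev = np.abs(Fz - f0) / abs(f0)
    axial = Fz[ic, ic, :]
    return UniformityReport(
        cube_side=side,
        grid_n=grid_n,
        center_force=float(f0),
        max_relative_deviation=float(dev.max()),
        max_axial_relative_deviation=float(np.abs(axial - f0).max() / abs(f0)),
        axial_z=c.copy(),
        axial_force=axial.copy(),
    )
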