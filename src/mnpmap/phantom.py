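"""Tissue-mimicking phantoms: gridded elastic media with force-loaded inclusions.

The phantoms emulate soft tissue (breast-like, E = 5-30 kPa, nu = 0.495)
containing compact regions of deposited magnetic nanoparticles.  Under a
uniform external field gradient the particle-laden regions experience a
uniform axial body force; the background carries none.  A 2D phantom
(10 cm x 10 cm, long cylindrical inclusions, plane strain) feeds the force
-map inversion; a 3D phantom (10 cm x 10 cm x 6 cm, spherical inclusion)
feeds the total-force estimates.

Grids are voxel-centered: an axis with n voxels of size h spans [0, n*h],
with voxel centers at (i + 1/2) h.  Axis order is (y, z) in 2D and
(x, y, z) in 3D; z is the axial (force/ultrasound beam) direction, the
last array axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElasticMedium",
    "Inclusion",
    "Phantom",
    "DisplacementField",
    "build_phantom_2d",
    "build_phantom_3d",
    "phantom_from_dict",
    "add_measurement_noise",
]


@dataclass(frozen=True)
class ElasticMedium:
    """Linear isotropic elastic medium.

    Parameters are Young's modulus E [Pa], Poisson ratio nu (strictly below
    the incompressible limit 0.5), and density rho [kg/m^3].  Density is
    carried for completeness but unused by the static solver.
    """

    youngs_modulus_E: float
    poisson_nu: float
    density_rho: float = 1000.0

    def __post_init__(self) -> None:
        if not self.youngs_modulus_E > 0:
            raise ValueError("youngs_modulus_E must be positive")
        if not 0.0 < self.poisson_nu < 0.5:
            raise ValueError(
                f"poisson_nu must lie strictly in (0, 0.5); nu = 0.5 is singular "
                f"(got {self.poisson_nu})"
            )
        if not self.density_rho > 0:
            raise ValueError("density_rho must be positive")

    @property
    def shear_modulus_G(self) -> float:
        """G = E / (2 (1 + nu)) [Pa]."""
        return self.youngs_modulus_E / (2.0 * (1.0 + self.poisson_nu))

    @property
    def lame_lambda(self) -> float:
        """First Lame parameter lambda = 2 G nu / (1 - 2 nu) [Pa]."""
        nu = self.poisson_nu
        return 2.0 * self.shear_modulus_G * nu / (1.0 - 2.0 * nu)


@dataclass(frozen=True)
class Inclusion:
    """Circular (2D) or spherical (3D) nanoparticle-laden region."""

    center: tuple  # physical coordinates [m]
    diameter: float  # [m]
    force_density: float  # applied axial body force [N/m^3]


@dataclass
class Phantom:
    """Gridded elastic medium with inclusion masks and an axial force map."""

    grid_shape: tuple
    voxel_size: tuple  # [m] per axis
    medium: ElasticMedium
    inclusion_mask: np.ndarray  # bool, union of all inclusions
    force_density_Fz: np.ndarray  # [N/m^3], uniform per inclusion, 0 outside
    inclusions: list = field(default_factory=list)
    inclusion_masks: list = field(default_factory=list)  # one bool array per inclusion

    @property
    def ndim(self) -> int:
        return len(self.grid_shape)

    @property
    def domain_size(self) -> tuple:
        return tuple(n * h for n, h in zip(self.grid_shape, self.voxel_size))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n, h = self.grid_shape[axis], self.voxel_size[axis]
        return (np.arange(n) + 0.5) * h

    @property
    def total_force(self) -> float:
        """Total applied force [N] (or N/m in 2D plane strain, per unit depth
        of the cylindrical inclusion): force density times mask measure."""
        return float(self.force_density_Fz.sum() * self.voxel_volume)

    def with_force_density(self, force_density: float) -> "Phantom":
        """Copy of the phantom with a single uniform force density applied
        to every inclusion voxel."""
        fz = np.where(self.inclusion_mask, float(force_density), 0.0)
        incl = [Inclusion(i.center, i.diameter, float(force_density)) for i in self.inclusions]
        return Phantom(
            self.grid_shape, self.voxel_size, self.medium, self.inclusion_mask.copy(),
            fz, incl, [m.copy() for m in self.inclusion_masks],
        )


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors [m] on the phantom grid.

    ``u`` has shape ``grid_shape + (ndim,)``; the axial (z) component is the
    last vector component.  ``boundary_condition_tag`` records the forward
    solve's constraint for provenance.
    """

    u: np.ndarray
    voxel_size: tuple
    boundary_condition_tag: str = "unknown"

    @property
    def ndim(self) -> int:
        return self.u.shape[-1]

    @property
    def grid_shape(self) -> tuple:
        return self.u.shape[:-1]

    @property
    def axial(self) -> np.ndarray:
        """The z (axial) displacement component."""
        return self.u[..., -1]


def _rasterize(grid_shape, voxel_size, center, radius) -> np.ndarray:
    """Voxel-center-in-shape mask for a circle/sphere."""
    axes = [(np.arange(n) + 0.5) * h - c for n, h, c in zip(grid_shape, voxel_size, center)]
    grids = np.meshgrid(*axes, indexing="ij")
    d2 = sum(g**2 for g in grids)
    return d2 <= radius**2


def _check_interior(center, radius, domain) -> None:
    for c, L in zip(center, domain):
        if c - radius <= 0.0 or c + radius >= L:
            raise ValueError(
                f"inclusion (center {center}, radius {radius}) touches or crosses "
                f"the domain boundary {domain}"
            )


def build_phantom_2d(
    side_cm: float = 10.0,
    inclusions=None,
    E: float = 10e3,
    nu: float = 0.495,
    grid_n: int = 201,
    rho: float = 1000.0,
) -> Phantom:
    """Square 2D phantom (plane strain) with circular inclusions.

    Parameters
    ----------
    side_cm : float
        Domain side [cm]; default 10 cm.
    inclusions : list of (center_cm, diameter_mm, force_density) or None
        ``center_cm`` is an (y, z) pair in cm; ``diameter_mm`` in mm;
        ``force_density`` in N/m^3.  ``None`` gives the single-inclusion
        default: D = 10 mm at the domain center with unit force density.
    grid_n : int
        Voxels per axis; at least 50 so the 10 mm inclusion spans several
        voxels.
    """
    if grid_n < 50:
        raise ValueError("grid_n must be >= 50 (resolution floor for a 10 mm inclusion)")
    side = side_cm * 1e-2
    if inclusions is None:
        inclusions = [((side_cm / 2.0, side_cm / 2.0), 10.0, 1.0)]
    grid_shape = (grid_n, grid_n)
    h = (side / grid_n, side / grid_n)
    return _build(grid_shape, h, inclusions, E, nu, rho)


def build_phantom_3d(
    size_cm=(10.0, 10.0, 6.0),
    inclusion_D_mm: float = 10.0,
    E: float = 10e3,
    nu: float = 0.495,
    grid_n=(51, 51, 31),
    force_density: float = 1.0,
    rho: float = 1000.0,
) -> Phantom:
    """Box 3D phantom with one spherical inclusion at the domain center.

    The default 10 x 10 x 6 cm box admits sphere diameters of 5-40 mm
    (a 40 mm sphere leaves 1 cm clearance along the thin axis).
    """
    if not 5.0 <= inclusion_D_mm <= 40.0:
        raise ValueError("inclusion_D_mm must lie in [5, 40] mm")
    size = tuple(s * 1e-2 for s in size_cm)
    center_cm = tuple(s / 2.0 for s in size_cm)
    grid_shape = tuple(int(n) for n in grid_n)
    h = tuple(s / n for s, n in zip(size, grid_shape))
    incl = [(center_cm, inclusion_D_mm, force_density)]
    return _build(grid_shape, h, incl, E, nu, rho)


def _build(grid_shape, voxel_size, inclusions, E, nu, rho) -> Phantom:
    medium = ElasticMedium(E, nu, rho)
    domain = tuple(n * h for n, h in zip(grid_shape, voxel_size))
    fz = np.zeros(grid_shape)
    union = np.zeros(grid_shape, dtype=bool)
    incl_objs, masks = [], []
    for center_cm, D_mm, f in inclusions:
        center = tuple(c * 1e-2 for c in center_cm)
        radius = D_mm * 1e-3 / 2.0
        _check_interior(center, radius, domain)
        mask = _rasterize(grid_shape, voxel_size, center, radius)
        if np.any(mask & union):
            raise ValueError("inclusions overlap")
        fz[mask] = f
        union |= mask
        incl_objs.append(Inclusion(center, 2.0 * radius, f))
        masks.append(mask)
    return Phantom(grid_shape, voxel_size, medium, union, fz, incl_objs, masks)


def phantom_from_dict(cfg: dict) -> Phantom:
    """Build a phantom from a flat config mapping (as read from YAML).

    Expected keys: ``dim`` (2 or 3), ``E_Pa``, ``nu``, ``grid_n`` (int or
    list), and either ``inclusions`` (list of ``{center_cm, diameter_mm,
    force_density}``) with ``side_cm`` for 2D, or ``inclusion_D_mm`` with
    ``size_cm`` and ``force_density`` for 3D.
    """
    dim = int(cfg.get("dim", 2))
    E = float(cfg.get("E_Pa", 10e3))
    nu = float(cfg.get("nu", 0.495))
    if dim == 2:
        inclusions = None
        if "inclusions" in cfg:
            inclusions = [
                (tuple(i["center_cm"]), float(i["diameter_mm"]), float(i.get("force_density", 1.0)))
                for i in cfg["inclusions"]
            ]
        return build_phantom_2d(
            side_cm=float(cfg.get("side_cm", 10.0)), inclusions=inclusions,
            E=E, nu=nu, grid_n=int(cfg.get("grid_n", 201)),
        )
    if dim == 3:
        grid_n = cfg.get("grid_n", (51, 51, 31))
        if isinstance(grid_n, int):
            grid_n = (grid_n, grid_n, max(3, int(grid_n * 0.6)))
        return build_phantom_3d(
            size_cm=tuple(cfg.get("size_cm", (10.0, 10.0, 6.0))),
            inclusion_D_mm=float(cfg.get("inclusion_D_mm", 10.0)),
            E=E, nu=nu, grid_n=tuple(grid_n),
            force_density=float(cfg.get("force_density", 1.0)),
        )
    raise ValueError("dim must be 2 or 3")


def add_measurement_noise(
    field: DisplacementField, axial_precision: float, seed: int
) -> DisplacementField:
    """Add zero-mean Gaussian noise of SD ``axial_precision`` [m] to the
    axial displacement component only (emulating the finite displacement
    precision of ultrasound speckle tracking).  Deterministic per seed."""
    if axial_precision < 0:
        raise ValueError("axial_precision must be >= 0")
    u = field.u.copy()
    if axial_precision > 0:
        rng = np.random.default_rng(seed)
        u[..., -1] += rng.normal(0.0, axial_precision, size=u.shape[:-1])
    return DisplacementField(u, field.voxel_size, field.boundary_condition_tag)
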