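"""Static Navier forward solver on the phantom's structured grid.

Solves the static limit of Navier's equation for linear isotropic
elasticity,

    G lap(u) + G/(1 - 2 nu) grad(div u) + F = 0,

for the displacement induced by the phantom's axial body-force map.  The
discretization is displacement-based finite elements on the regular voxel
grid: bilinear quadrilaterals (2D plane strain) or trilinear hexahedra
(3D), one element per voxel.  Near-incompressibility (nu = 0.495) is
handled by selective reduced integration: the volumetric (lambda) term is
integrated at the element centroid while the shear (mu) term uses full
Gauss quadrature.  On these uniform box meshes this is algebraically
identical to the mixed Q1/P0 displacement-pressure element with the
element pressure condensed out, so both ``incompressibility_treatment``
options share one code path.

Boundary conditions: the phantom rests on its bottom face (z = 0, fully
fixed) with all other faces traction-free ("bottom_fixed", the default),
or all faces fixed ("all_fixed"), or all faces set to prescribed
displacements ("prescribed", used to impose analytic far-field values in
verification studies).

Linear systems are solved directly (sparse LU) in 2D and by Jacobi-
preconditioned conjugate gradients in 3D.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .kelvin import kelvin_ball_displacement
from .phantom import DisplacementField, Phantom, build_phantom_3d

__all__ = [
    "SolverConfig",
    "SolverError",
    "solve_static",
    "axial_strain",
    "calibrate_force_for_peak_strain",
    "total_force_for_peak_displacement",
    "kelvin_boundary_values",
]


class SolverError(RuntimeError):
    """Raised on singular systems or non-convergence of the linear solve."""


@dataclass(frozen=True)
class SolverConfig:
    formulation: str = "auto"  # plane_strain_2d | full_3d | auto (from phantom)
    boundary_condition: str = "bottom_fixed"  # bottom_fixed | all_fixed | prescribed
    linear_solver_tolerance: float = 1e-8
    incompressibility_treatment: str = "selective_reduced_integration"
    max_iterations: int = 20000

    def __post_init__(self) -> None:
        if not 0.0 < self.linear_solver_tolerance <= 1e-4:
            raise ValueError("linear_solver_tolerance must lie in (0, 1e-4]")
        if self.formulation not in ("auto", "plane_strain_2d", "full_3d"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.boundary_condition not in ("bottom_fixed", "all_fixed", "prescribed"):
            raise ValueError(f"unknown boundary_condition {self.boundary_condition!r}")
        if self.incompressibility_treatment not in ("selective_reduced_integration", "mixed_u_p"):
            raise ValueError(
                f"unknown incompressibility_treatment {self.incompressibility_treatment!r}"
            )


def _shape_gradients(nd: int, h, xi) -> np.ndarray:
    """Physical gradients of the 2^nd Q1 shape functions at point xi in [0,1]^nd.

    Corner order matches itertools.product([0,1], repeat=nd): first axis
    slowest, consistent with C-order node indexing.
    """
    corners = list(itertools.product((0, 1), repeat=nd))
    g = np.empty((len(corners), nd))
    for a, c in enumerate(corners):
        for i in range(nd):
            val = 1.0
            for j in range(nd):
                lj = xi[j] if c[j] else 1.0 - xi[j]
                dj = 1.0 if c[j] else -1.0
                val *= dj / h[j] if j == i else lj
            g[a, i] = val
    return g


def _element_stiffness(h, mu: float, lam: float) -> np.ndarray:
    """SRI element stiffness for a box element with spacings h.

    Shear part 2*mu*eps:eps at full (2-point per axis) Gauss quadrature;
    volumetric part lam*(div u)(div v) at the centroid only.
    """
    nd = len(h)
    ncorner = 2**nd
    vol = float(np.prod(h))
    gp = 0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)
    K = np.zeros((ncorner * nd, ncorner * nd))
    for xi in itertools.product(gp, repeat=nd):
        g = _shape_gradients(nd, h, xi)
        gg = g @ g.T  # grad N_a . grad N_b
        w = vol / ncorner
        for i in range(nd):
            for j in range(nd):
                blk = mu * np.outer(g[:, j], g[:, i])  # d_i N_b d_j N_a, rows a cols b
                if i == j:
                    blk = blk + mu * gg
                K[i::nd, j::nd] += w * blk
    g0 = _shape_gradients(nd, h, [0.5] * nd)
    for i in range(nd):
        for j in range(nd):
            K[i::nd, j::nd] += vol * lam * np.outer(g0[:, i], g0[:, j])
    return K


def _element_dofs(grid_shape) -> np.ndarray:
    """Global dof indices (nelem, 2^nd * nd) for every voxel element."""
    nd = len(grid_shape)
    node_shape = tuple(n + 1 for n in grid_shape)
    origins = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    origin_idx = np.stack([o.ravel() for o in origins], axis=1)  # (nelem, nd)
    corners = np.array(list(itertools.product((0, 1), repeat=nd)))  # (2^nd, nd)
    node_idx = origin_idx[:, None, :] + corners[None, :, :]  # (nelem, 2^nd, nd)
    strides = np.array([int(np.prod(node_shape[i + 1:])) for i in range(nd)])
    nids = (node_idx * strides).sum(axis=2)  # (nelem, 2^nd)
    dofs = (nids[:, :, None] * nd + np.arange(nd)).reshape(nids.shape[0], -1)
    return dofs.astype(np.int64)


def _assemble(phantom: Phantom) -> tuple[sp.csr_matrix, np.ndarray]:
    """Global stiffness matrix and consistent load vector (nodal dofs)."""
    nd = phantom.ndim
    med = phantom.medium
    Ke = _element_stiffness(phantom.voxel_size, med.shear_modulus_G, med.lame_lambda)
    dofs = _element_dofs(phantom.grid_shape)
    node_shape = tuple(n + 1 for n in phantom.grid_shape)
    ndof = int(np.prod(node_shape)) * nd

    nloc = Ke.shape[0]
    K = sp.csr_matrix((ndof, ndof))
    chunk = max(1, int(2e7) // (nloc * nloc))
    ke_flat = Ke.ravel()
    for start in range(0, dofs.shape[0], chunk):
        d = dofs[start:start + chunk]
        rows = np.repeat(d, nloc, axis=1).ravel()
        cols = np.tile(d, (1, nloc)).ravel()
        data = np.tile(ke_flat, d.shape[0])
        K = K + sp.coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()

    # Consistent load: uniform f_z per element spreads vol/2^nd to each corner.
    f = np.zeros(ndof)
    fz_elem = phantom.force_density_Fz.ravel()
    share = phantom.voxel_volume / (2**nd)
    zdofs = dofs[:, nd - 1::nd]  # z-component dof of each corner
    np.add.at(f, zdofs.ravel(), np.repeat(fz_elem * share, 2**nd))
    return K, f


def _fixed_dofs(phantom: Phantom, bc: str) -> np.ndarray:
    nd = phantom.ndim
    node_shape = tuple(n + 1 for n in phantom.grid_shape)
    fixed = np.zeros(node_shape, dtype=bool)
    if bc == "bottom_fixed":
        fixed[..., 0] = True
    else:  # all_fixed / prescribed constrain every boundary node
        for ax in range(nd):
            sl = [slice(None)] * nd
            sl[ax] = 0
            fixed[tuple(sl)] = True
            sl[ax] = -1
            fixed[tuple(sl)] = True
    return np.repeat(fixed.ravel(), nd)


def solve_static(
    phantom: Phantom,
    config: SolverConfig | None = None,
    boundary_values: np.ndarray | None = None,
) -> DisplacementField:
    """Solve the static Navier equation for the phantom's displacement field.

    Parameters
    ----------
    phantom : Phantom
        Elastic medium, grid, and axial body-force map.
    config : SolverConfig, optional
        Formulation, boundary condition and solver tolerances.
    boundary_values : ndarray, optional
        Nodal displacements on the node grid, shape
        ``(n+1, ...) + (ndim,)``; required when
        ``config.boundary_condition == "prescribed"`` (only boundary
        entries are used).

    Returns
    -------
    DisplacementField
        Displacement vectors at the voxel centers (corner-node averages of
        the nodal finite-element solution).
    """
    config = config or SolverConfig()
    nd = phantom.ndim
    if config.formulation == "plane_strain_2d" and nd != 2:
        raise ValueError("plane_strain_2d formulation requires a 2D phantom")
    if config.formulation == "full_3d" and nd != 3:
        raise ValueError("full_3d formulation requires a 3D phantom")
    if config.boundary_condition == "prescribed" and boundary_values is None:
        raise ValueError("prescribed boundary condition requires boundary_values")

    node_shape = tuple(n + 1 for n in phantom.grid_shape)
    K, f = _assemble(phantom)
    fixed = _fixed_dofs(phantom, config.boundary_condition)
    if not fixed.any():
        raise SolverError("no constrained boundary: the static system is singular")
    free = ~fixed

    u = np.zeros(K.shape[0])
    if config.boundary_condition == "prescribed":
        bv = np.asarray(boundary_values, dtype=float)
        if bv.shape != node_shape + (nd,):
            raise ValueError(f"boundary_values must have shape {node_shape + (nd,)}")
        u[fixed] = bv.reshape(-1)[fixed]

    rhs = f[free] - K[free] @ u
    Kff = K[free][:, free].tocsr()
    tol = config.linear_solver_tolerance
    if nd == 2:
        u[free] = spla.spsolve(Kff.tocsc(), rhs)
    else:
        diag = Kff.diagonal()
        if np.any(diag <= 0):
            raise SolverError("non-positive diagonal in stiffness matrix")
        M = spla.LinearOperator(Kff.shape, matvec=lambda x: x / diag)
        sol, info = spla.cg(Kff, rhs, rtol=tol, atol=0.0, M=M, maxiter=config.max_iterations)
        if info != 0:
            res = np.linalg.norm(Kff @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
            raise SolverError(
                f"conjugate-gradient solve did not converge (info={info}, "
                f"relative residual {res:.3e}, tolerance {tol:.1e})"
            )
        u[free] = sol

    rnorm = np.linalg.norm(rhs)
    if rnorm > 0:
        res = np.linalg.norm(Kff @ u[free] - rhs) / rnorm
        if not np.isfinite(res) or res > 100.0 * tol:
            raise SolverError(f"post-solve relative residual {res:.3e} exceeds tolerance")

    u_nodes = u.reshape(node_shape + (nd,))
    u_cells = u_nodes
    for ax in range(nd):
        sl_lo = [slice(None)] * (nd + 1)
        sl_hi = [slice(None)] * (nd + 1)
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        u_cells = 0.5 * (u_cells[tuple(sl_lo)] + u_cells[tuple(sl_hi)])
    return DisplacementField(u_cells, phantom.voxel_size, config.boundary_condition)


def axial_strain(field: DisplacementField) -> np.ndarray:
    """Axial strain eps_zz = d u_z / d z by central differences (one-sided
    at the two z-boundary layers)."""
    hz = field.voxel_size[-1]
    return np.gradient(field.axial, hz, axis=-1)


def calibrate_force_for_peak_strain(
    phantom: Phantom, target_peak_strain: float, config: SolverConfig | None = None
) -> float:
    """Force density [N/m^3] giving the target peak axial strain in the
    inclusions.

    Exploits linearity: one unit-force solve, then exact rescaling by
    target/achieved peak strain (no iteration).
    """
    if target_peak_strain < 0:
        raise ValueError("target_peak_strain must be >= 0")
    if target_peak_strain == 0:
        return 0.0
    if not phantom.inclusion_mask.any():
        raise SolverError("degenerate phantom: no inclusion to calibrate against")
    unit = phantom.with_force_density(1.0)
    field = solve_static(unit, config)
    eps = axial_strain(field)
    peak = float(np.abs(eps[phantom.inclusion_mask]).max())
    if peak == 0.0:
        raise SolverError("degenerate phantom: unit force produced zero strain")
    return target_peak_strain / peak


def total_force_for_peak_displacement(
    D_mm: float,
    E_kPa: float,
    target_u_peak: float,
    config: SolverConfig | None = None,
    nu: float = 0.495,
    grid_n=(51, 51, 31),
) -> float:
    """Total force [N] on a spherical inclusion of diameter ``D_mm`` in the
    3D phantom needed to reach ``target_u_peak`` [m] peak axial displacement.

    One unit-force 3D solve, linear rescale to the target peak, then
    multiplication by the inclusion volume.
    """
    if target_u_peak < 0:
        raise ValueError("target_u_peak must be >= 0")
    if target_u_peak == 0:
        return 0.0
    phantom = build_phantom_3d(inclusion_D_mm=D_mm, E=E_kPa * 1e3, nu=nu, grid_n=grid_n)
    field = solve_static(phantom, config)
    peak = float(np.abs(field.axial).max())
    if peak == 0.0:
        raise SolverError("unit force produced zero displacement")
    f_density = target_u_peak / peak
    volume = float(phantom.inclusion_mask.sum()) * phantom.voxel_volume
    return f_density * volume


def kelvin_boundary_values(phantom: Phantom) -> np.ndarray:
    """Nodal boundary displacements from the analytic uniformly-loaded-ball
    solution, for verification solves with ``boundary_condition="prescribed"``.

    The phantom must hold exactly one (spherical) inclusion; the analytic
    infinite-medium field is evaluated at every node of the grid (only
    boundary nodes are consumed by the solver).
    """
    if len(phantom.inclusions) != 1:
        raise ValueError("kelvin_boundary_values requires a single-inclusion phantom")
    incl = phantom.inclusions[0]
    nd = phantom.ndim
    if nd != 3:
        raise ValueError("the Kelvin ball benchmark is three-dimensional")
    node_axes = [np.arange(n + 1) * h - c for n, h, c in
                 zip(phantom.grid_shape, phantom.voxel_size, incl.center)]
    grids = np.meshgrid(*node_axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    u = kelvin_ball_displacement(
        pts, incl.diameter / 2.0, incl.force_density,
        phantom.medium.shear_modulus_G, phantom.medium.poisson_nu,
    )
    return u.reshape(tuple(n + 1 for n in phantom.grid_shape) + (nd,))
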