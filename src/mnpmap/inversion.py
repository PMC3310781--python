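"""Inverse mapping: displacement fields back to magnetic force/density maps.

The static Navier equation inverts by direct differentiation:

    F = -G lap(u) - G/(1 - 2 nu) grad(div u)            (full form)

Ultrasound elastography measures only the axial (z) displacement, so the
practical estimator drops the divergence term and the elevational (x)
second derivative, keeping the lateral/axial Laplacian of u_z:

    F_z = -G (d2 u_z / dy2 + d2 u_z / dz2)              (axial-only form)

Since soft tissue is nearly incompressible the divergence term is small in
the interior, but omitting it produces a characteristic halo of overshoot
around the inclusion boundary.  This module implements both estimators
(3-point central second differences; the boundary ring where the stencils
do not fit is flagged invalid), plus the map metrics used to quantify the
halo artifact and the linearity of mean recovered intensity versus applied
force, and the conversion from force density to nanoparticle density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats

from .phantom import DisplacementField

__all__ = [
    "ForceMap",
    "DensityMap",
    "LinearityReport",
    "laplacian_force_map",
    "full_force_map",
    "normalize_map",
    "mean_intensity_in_mask",
    "linearity_report",
    "halo_metric",
    "density_from_force",
]


@dataclass(frozen=True)
class ForceMap:
    """Recovered axial force-density map [N/m^3] with provenance.

    ``method`` is ``"laplacian_only"`` (axial-only estimator) or
    ``"full_navier"``; ``valid_mask`` excludes the boundary ring where the
    finite-difference stencils do not fit.  Normalized maps have
    max |F_z| = 1 over the valid region.
    """

    Fz: np.ndarray
    method: str
    voxel_size: tuple
    valid_mask: np.ndarray
    normalization: str = "raw"


@dataclass(frozen=True)
class DensityMap:
    """Effective magnetization [A/m] and optional mass density [kg/m^3]."""

    magnetization_Apm: np.ndarray
    mass_density_kgm3: np.ndarray | None
    valid_mask: np.ndarray


def _second_diff(arr: np.ndarray, h: float, axis: int) -> np.ndarray:
    """3-point central second difference; zero on the boundary layers."""
    out = np.zeros_like(arr)
    lo = [slice(None)] * arr.ndim
    hi = [slice(None)] * arr.ndim
    mid = [slice(None)] * arr.ndim
    lo[axis], mid[axis], hi[axis] = slice(0, -2), slice(1, -1), slice(2, None)
    out[tuple(mid)] = (arr[tuple(lo)] - 2.0 * arr[tuple(mid)] + arr[tuple(hi)]) / h**2
    return out


def _mixed_diff(arr: np.ndarray, hi_: float, hj: float, ax_i: int, ax_j: int) -> np.ndarray:
    """Central mixed second difference d2/dxi dxj; zero on boundary layers."""
    def shift(sign_i, sign_j):
        sl = [slice(1, -1)] * arr.ndim
        sl[ax_i] = slice(1 + sign_i, arr.shape[ax_i] - 1 + sign_i)
        sl[ax_j] = slice(1 + sign_j, arr.shape[ax_j] - 1 + sign_j)
        return arr[tuple(sl)]

    out = np.zeros_like(arr)
    core = [slice(1, -1)] * arr.ndim
    out[tuple(core)] = (
        shift(1, 1) - shift(1, -1) - shift(-1, 1) + shift(-1, -1)
    ) / (4.0 * hi_ * hj)
    return out


def _interior_mask(shape, margins) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(m, n - m if m else None) for n, m in zip(shape, margins))
    mask[sl] = True
    return mask


def laplacian_force_map(
    field: DisplacementField, G: float, presmooth_sigma: float = 0.0
) -> ForceMap:
    """Axial-only force estimator F_z = -G (d2u_z/dy2 + d2u_z/dz2).

    Only the lateral (y) and axial (z) second derivatives enter; the
    elevational (x) derivative is deliberately omitted, matching what a
    single-plane ultrasound acquisition can measure.  In 2D the y-z
    Laplacian is the full in-plane Laplacian by construction.

    ``presmooth_sigma`` (in voxels, default off) applies a Gaussian
    filter to u_z before differentiation — useful when measurement noise
    was injected, since second differences amplify voxel-scale noise.
    """
    uz = field.axial
    if presmooth_sigma > 0:
        uz = ndimage.gaussian_filter(uz, presmooth_sigma)
    if uz.shape[-1] < 3 or uz.shape[-2] < 3:
        raise ValueError("grid must span at least 3 voxels in y and z")
    hy, hz = field.voxel_size[-2], field.voxel_size[-1]
    nd = uz.ndim
    lap = _second_diff(uz, hy, nd - 2) + _second_diff(uz, hz, nd - 1)
    margins = [0] * nd
    margins[nd - 2] = margins[nd - 1] = 1
    valid = _interior_mask(uz.shape, margins)
    return ForceMap(np.where(valid, -G * lap, 0.0), "laplacian_only", field.voxel_size, valid)


def full_force_map(
    field: DisplacementField, G: float, nu: float, presmooth_sigma: float = 0.0
) -> ForceMap:
    """Full static inverse F = -G lap(u) - G/(1-2 nu) grad(div u), axial
    component, using all displacement components.

    ``presmooth_sigma`` (voxels) optionally smooths all components before
    differentiation, as in :func:`laplacian_force_map`."""
    if nu >= 0.5:
        raise ZeroDivisionError("nu = 0.5 makes the 1/(1-2*nu) factor singular")
    u = field.u
    if presmooth_sigma > 0:
        u = np.stack(
            [ndimage.gaussian_filter(u[..., c], presmooth_sigma) for c in range(u.shape[-1])],
            axis=-1,
        )
    nd = field.ndim
    if any(s < 3 for s in u.shape[:-1]):
        raise ValueError("grid must span at least 3 voxels per axis")
    h = field.voxel_size
    uz = u[..., -1]
    zax = nd - 1

    lap_uz = sum(_second_diff(uz, h[ax], ax) for ax in range(nd))
    # d/dz (div u) = sum_i d2 u_i / (dz dx_i)
    dz_div = _second_diff(uz, h[zax], zax)
    for ax in range(nd - 1):
        dz_div = dz_div + _mixed_diff(u[..., ax], h[ax], h[zax], ax, zax)

    Fz = -G * lap_uz - G / (1.0 - 2.0 * nu) * dz_div
    valid = _interior_mask(uz.shape, [1] * nd)
    return ForceMap(np.where(valid, Fz, 0.0), "full_navier", field.voxel_size, valid)


def normalize_map(fmap: ForceMap) -> ForceMap:
    """Divide by max |F_z| over the valid region; idempotent."""
    peak = float(np.abs(fmap.Fz[fmap.valid_mask]).max()) if fmap.valid_mask.any() else 0.0
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero force map")
    return replace(fmap, Fz=fmap.Fz / peak, normalization="max_abs")


def mean_intensity_in_mask(fmap: ForceMap, mask: np.ndarray, erosion: int = 2) -> float:
    """Mean F_z over the mask, eroded by ``erosion`` voxels to keep the
    boundary overshoot out of the average, and restricted to the valid
    region.

    The default erosion of two voxels covers the support of the central
    second-difference stencils (radius one voxel) plus the half-voxel
    jitter of the rasterized inclusion boundary, so the reported mean is
    the plateau value of the recovered force, uncontaminated by the
    boundary smear."""
    if mask.shape != fmap.Fz.shape:
        raise ValueError("mask shape must match the map")
    m = ndimage.binary_erosion(mask, iterations=erosion) if erosion else mask
    m = m & fmap.valid_mask
    if not m.any():
        raise ValueError("mask is empty after erosion/validity restriction")
    return float(fmap.Fz[m].mean())


@dataclass(frozen=True)
class LinearityReport:
    slope: float
    intercept: float
    r_squared: float
    relative_intercept: float  # |intercept| / |slope * max input|


def linearity_report(input_forces, output_means) -> LinearityReport:
    """Ordinary least squares of mean recovered intensity on applied force."""
    x = np.asarray(input_forces, dtype=float)
    y = np.asarray(output_means, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need at least 3 matched (input, output) points")
    fit = stats.linregress(x, y)
    rel = abs(fit.intercept) / abs(fit.slope * np.abs(x).max())
    return LinearityReport(float(fit.slope), float(fit.intercept), float(fit.rvalue**2), float(rel))


def halo_metric(
    fmap: ForceMap, inclusion_mask: np.ndarray, shell_radii: float = 2.0, guard: int = 2
) -> float:
    """Overshoot metric: max |F_z| over the background shell around the
    inclusion (outside the mask, within ``shell_radii`` equivalent radii of
    its centroid) divided by mean |F_z| inside the eroded mask.

    A guard band of ``guard`` voxels just outside the mask is excluded
    from the shell: the central-difference stencils smear the force
    discontinuity over that band for *any* estimator, whereas the halo
    artifact of the axial-only estimator extends over a fraction of the
    inclusion radius.  Excluding the band makes the metric measure the
    halo rather than the stencil smear.

    Zero for perfect recovery (uniform inside, zero outside); invariant
    under map normalization.
    """
    if inclusion_mask.shape != fmap.Fz.shape:
        raise ValueError("mask shape must match the map")
    if not inclusion_mask.any():
        raise ValueError("empty inclusion mask")
    nd = fmap.Fz.ndim
    h = np.asarray(fmap.voxel_size, dtype=float)
    idx = np.argwhere(inclusion_mask)
    centroid = (idx.mean(axis=0) + 0.5) * h
    measure = inclusion_mask.sum() * float(np.prod(h))
    if nd == 2:
        r_eq = np.sqrt(measure / np.pi)
    else:
        r_eq = (measure * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    axes = [(np.arange(n) + 0.5) * h[ax] - centroid[ax] for ax, n in enumerate(fmap.Fz.shape)]
    grids = np.meshgrid(*axes, indexing="ij")
    dist = np.sqrt(sum(g**2 for g in grids))
    excluded = ndimage.binary_dilation(inclusion_mask, iterations=guard) if guard else inclusion_mask
    shell = (~excluded) & (dist <= shell_radii * r_eq) & fmap.valid_mask
    if not shell.any():
        raise ValueError("degenerate background shell around the inclusion")
    interior = ndimage.binary_erosion(inclusion_mask, iterations=max(guard, 1)) & fmap.valid_mask
    if not interior.any():
        raise ValueError("inclusion too small for an eroded interior")
    denom = float(np.abs(fmap.Fz[interior]).mean())
    if denom == 0.0:
        return float(np.inf) if np.abs(fmap.Fz[shell]).max() > 0 else 0.0
    return float(np.abs(fmap.Fz[shell]).max() / denom)


def density_from_force(fmap: ForceMap, gradient: float, moment_per_kg: float | None = None) -> DensityMap:
    """Convert a force-density map to a nanoparticle density map.

    Under a uniform axial field gradient the per-voxel force is
    ``F_z = M_z dB_z/dz``, so the effective magnetization is
    ``M_z = F_z / gradient`` [A/m]; dividing further by the specific
    saturated moment [A*m^2/kg] yields the deposited particle mass per
    volume [kg/m^3].  This is the sense in which the force map *is* the
    nanoparticle density map.
    """
    if gradient == 0.0:
        raise ZeroDivisionError("field gradient must be nonzero")
    M = fmap.Fz / gradient
    rho = M / moment_per_kg if moment_per_kg else None
    return DensityMap(M, rho, fmap.valid_mask.copy())
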