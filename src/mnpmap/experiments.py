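"""Scripted end-to-end experiments: the package's reproduction surface.

Each experiment runs one pipeline (coil calculations, or phantom ->
forward solve -> inversion -> metrics), writes its maps, tables and a
flat key:value metrics report, and serializes its fully resolved
parameter set so any run can be repeated exactly.

Experiment ids
--------------
``coefficients``      center-field/gradient/force coefficients of the coil pair
``fig5_single``       2D single-inclusion phantom: displacement/strain/force maps
``fig5_double``       2D double-inclusion phantom (10 mm + 5 mm)
``fig6_7_divergence`` full vs axial-only force maps, cut views, halo metrics
``fig8_linearity``    mean recovered intensity vs applied force (OLS)
``fig9_total_force``  total force for 10 um peak displacement, D and E sweeps
``fig10_currents``    ampere-turn requirements of both coils
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import coils, inversion, solver
from .io import write_csv_map, write_displacement, write_mhd, write_yaml
from .phantom import build_phantom_2d

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "render_maps", "EXPERIMENT_IDS"]

EXPERIMENT_IDS = (
    "coefficients",
    "fig5_single",
    "fig5_double",
    "fig6_7_divergence",
    "fig8_linearity",
    "fig9_total_force",
    "fig10_currents",
)

#: Canonical study parameters shared by the experiments.
DEFAULTS = {
    "coil_radius_m": 0.075,          # 15 cm diameter coil, breast-scale
    "helmholtz_target_B_T": 0.4,     # saturating field
    "saturation_magnetization": 20.0,  # A m^2 / kg
    "E_Pa": 10e3,
    "nu": 0.495,
    "target_peak_strain": 1e-3,      # 0.1 % optimum elastography strain
    "target_peak_displacement_m": 10e-6,
    "grid_n_2d": 201,
    "grid_n_2d_fine": 401,           # resolves the 5 mm inclusion (>= 20 voxels/diameter)
    "grid_n_3d": (41, 41, 25),       # desk-scale sweep grid
    "double_centers_cm": ((5.0, 3.75), (5.0, 6.25)),  # 2.5 cm apart, symmetric about center
}


@dataclass(frozen=True)
class ExperimentConfig:
    experiment_id: str
    overrides: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment_id not in EXPERIMENT_IDS:
            raise ValueError(
                f"unknown experiment {self.experiment_id!r}; choose from {EXPERIMENT_IDS}"
            )

    def param(self, key: str):
        return self.overrides.get(key, DEFAULTS[key])


@dataclass
class ExperimentReport:
    experiment_id: str
    metrics: dict
    tables: dict
    artifacts: list

    def metric(self, key: str) -> float:
        return self.metrics[key]


def run_experiment(config: ExperimentConfig, out_dir=None, render: bool = False) -> ExperimentReport:
    """Execute one experiment; optionally write artifacts under ``out_dir``."""
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    runner = {
        "coefficients": _run_coefficients,
        "fig5_single": _run_fig5_single,
        "fig5_double": _run_fig5_double,
        "fig6_7_divergence": _run_fig6_7,
        "fig8_linearity": _run_fig8,
        "fig9_total_force": _run_fig9,
        "fig10_currents": _run_fig10,
    }[config.experiment_id]
    report = runner(config, out_dir, render)
    if out_dir is not None:
        resolved = {**DEFAULTS, **config.overrides,
                    "experiment_id": config.experiment_id, "seed": config.seed}
        write_yaml(out_dir / "params.yaml", resolved)
        write_yaml(out_dir / "metrics.yaml", report.metrics)
    return report


# --------------------------------------------------------------------------
# individual experiments

def _run_coefficients(config, out_dir, render):
    a = config.param("coil_radius_m")
    helm = coils.CoilSpec.helmholtz(a, 1.0)
    maxw = coils.CoilSpec.maxwell(a, 1.0)
    from .constants import MU0

    c_h = coils.helmholtz_axial_field(helm, 0.0) * a / MU0
    c_m = coils.maxwell_axial_gradient(maxw, 0.0) * a**2 / MU0
    msat = config.param("saturation_magnetization")
    load = coils.NanoparticleLoad(msat, 0.0, 1.0)
    sample = coils.pair_field(helm, maxw, [0.0, 0.0, 0.0])
    fz = coils.force_on_load(load, sample, regime="saturated")[2]
    c_f = fz * a**2 / MU0  # coefficient of w * mu0 * nI / a^2
    metrics = {
        "helmholtz_center_coefficient": float(c_h),
        "maxwell_center_gradient_coefficient": float(c_m),
        "saturated_force_coefficient": float(c_f),
    }
    rows = [
        ("B_z(0) * a / (mu0 n1 I1), d=a", c_h),
        ("GR_z(0) * a^2 / (mu0 n2 I2), d=sqrt(3) a", c_m),
        (f"F_z(0) * a^2 / (w mu0 n2 I2), M_sat={msat:g} Am^2/kg", c_f),
    ]
    artifacts = []
    if out_dir is not None:
        artifacts.append(_write_table(out_dir / "coefficients.csv", ["quantity", "value"], rows))
    return ExperimentReport("coefficients", metrics, {"coefficients": rows}, artifacts)


def _solve_2d(config, inclusions, grid_n):
    ph = build_phantom_2d(
        grid_n=grid_n, inclusions=inclusions,
        E=config.param("E_Pa"), nu=config.param("nu"),
    )
    f_cal = solver.calibrate_force_for_peak_strain(ph, config.param("target_peak_strain"))
    ph = ph.with_force_density(f_cal)
    field = solver.solve_static(ph)
    return ph, field, f_cal


def _map_metrics(ph, field, metrics, out_dir, render, artifacts):
    G, nu = ph.medium.shear_modulus_G, ph.medium.poisson_nu
    eps = solver.axial_strain(field)
    lap = inversion.laplacian_force_map(field, G)
    full = inversion.full_force_map(field, G, nu)
    metrics["peak_displacement_um"] = float(np.abs(field.axial).max() * 1e6)
    metrics["peak_strain_percent"] = float(np.abs(eps).max() * 100.0)
    metrics["peak_inclusion_strain_percent"] = float(
        np.abs(eps[ph.inclusion_mask]).max() * 100.0
    )
    applied = float(ph.force_density_Fz.max())
    for i, mask in enumerate(ph.inclusion_masks):
        tag = f"inclusion{i}"
        metrics[f"{tag}_mean_full_over_applied"] = inversion.mean_intensity_in_mask(full, mask) / applied
        metrics[f"{tag}_mean_laplacian_over_applied"] = inversion.mean_intensity_in_mask(lap, mask) / applied
        metrics[f"{tag}_halo_full"] = inversion.halo_metric(full, mask)
        metrics[f"{tag}_halo_laplacian"] = inversion.halo_metric(lap, mask)
    if out_dir is not None:
        artifacts += write_displacement(out_dir, field)
        artifacts.append(write_mhd(out_dir / "force_laplacian.mhd", lap.Fz, field.voxel_size))
        artifacts.append(write_mhd(out_dir / "force_full.mhd", full.Fz, field.voxel_size))
        artifacts.append(write_csv_map(out_dir / "uz.csv", field.axial, field.voxel_size, "axial displacement [m]"))
        if render:
            side = ph.domain_size[0] * 100
            artifacts.append(render_maps(field.axial * 1e6, "heatmap", out_dir / "uz_um.png",
                                         extent_cm=side, title="axial displacement [um]"))
            artifacts.append(render_maps(eps * 100, "heatmap", out_dir / "strain_pct.png",
                                         extent_cm=side, title="axial strain [%]"))
            artifacts.append(render_maps(inversion.normalize_map(lap).Fz, "heatmap",
                                         out_dir / "force_laplacian.png", extent_cm=side,
                                         title="normalized force map (axial-only)"))
    return lap, full


def _run_fig5_single(config, out_dir, render):
    ph, field, f_cal = _solve_2d(config, None, config.param("grid_n_2d"))
    metrics = {"calibrated_force_density_N_per_m3": f_cal}
    artifacts: list = []
    _map_metrics(ph, field, metrics, out_dir, render, artifacts)
    return ExperimentReport("fig5_single", metrics, {}, artifacts)


def _double_inclusions(config):
    c1, c2 = config.param("double_centers_cm")
    return [(tuple(c1), 10.0, 1.0), (tuple(c2), 5.0, 1.0)]


def _run_fig5_double(config, out_dir, render):
    ph, field, f_cal = _solve_2d(config, _double_inclusions(config), config.param("grid_n_2d_fine"))
    metrics = {"calibrated_force_density_N_per_m3": f_cal}
    artifacts: list = []
    _map_metrics(ph, field, metrics, out_dir, render, artifacts)
    return ExperimentReport("fig5_double", metrics, {}, artifacts)


def _run_fig6_7(config, out_dir, render):
    """Full vs axial-only inversion on the single-inclusion phantom."""
    ph, field, f_cal = _solve_2d(config, None, config.param("grid_n_2d"))
    G, nu = ph.medium.shear_modulus_G, ph.medium.poisson_nu
    lap = inversion.normalize_map(inversion.laplacian_force_map(field, G))
    full = inversion.normalize_map(inversion.full_force_map(field, G, nu))
    mask = ph.inclusion_mask
    metrics = {
        "halo_full": inversion.halo_metric(full, mask),
        "halo_laplacian": inversion.halo_metric(lap, mask),
        "halo_reduced_by_divergence_term": bool(
            inversion.halo_metric(full, mask) < inversion.halo_metric(lap, mask)
        ),
    }
    artifacts: list = []
    # cut views through the inclusion center, along z
    iy = ph.grid_shape[0] // 2
    z_cm = ph.voxel_centers(1) * 100
    rows = list(zip(z_cm, full.Fz[iy, :], lap.Fz[iy, :]))
    if out_dir is not None:
        artifacts.append(_write_table(out_dir / "cut_views.csv",
                                      ["z_cm", "F_full_normalized", "F_laplacian_normalized"], rows))
        if render:
            side = ph.domain_size[0] * 100
            artifacts.append(render_maps(full.Fz, "heatmap", out_dir / "force_full.png",
                                         extent_cm=side, title="normalized force map (full)"))
            artifacts.append(render_maps(lap.Fz, "heatmap", out_dir / "force_laplacian.png",
                                         extent_cm=side, title="normalized force map (axial-only)"))
    return ExperimentReport("fig6_7_divergence", metrics, {"cut_views": rows}, artifacts)


def _run_fig8(config, out_dir, render):
    """Linearity of mean recovered intensity vs applied force (5 levels)."""
    grid_n = config.param("grid_n_2d")
    ph = build_phantom_2d(grid_n=grid_n, E=config.param("E_Pa"), nu=config.param("nu"))
    f_cal = solver.calibrate_force_for_peak_strain(ph, config.param("target_peak_strain"))
    levels = f_cal * np.linspace(0.2, 1.0, 5)
    G = ph.medium.shear_modulus_G
    means = []
    for f in levels:
        fld = solver.solve_static(ph.with_force_density(f))
        fmap = inversion.laplacian_force_map(fld, G)
        means.append(inversion.mean_intensity_in_mask(fmap, ph.inclusion_mask))
    rep = inversion.linearity_report(levels, means)
    metrics = {
        "slope": rep.slope, "intercept": rep.intercept,
        "r_squared": rep.r_squared, "relative_intercept": rep.relative_intercept,
    }
    rows = list(zip(levels, means))
    artifacts: list = []
    if out_dir is not None:
        artifacts.append(_write_table(out_dir / "linearity.csv",
                                      ["applied_force_N_per_m3", "mean_recovered_N_per_m3"], rows))
    return ExperimentReport("fig8_linearity", metrics, {"linearity": rows}, artifacts)


def _run_fig9(config, out_dir, render):
    """Total force for 10 um peak displacement: D sweep x E sweep (3D)."""
    grid_n = tuple(config.param("grid_n_3d"))
    target = config.param("target_peak_displacement_m")
    nu = config.param("nu")
    D_list = config.overrides.get("D_list_mm", (10.0, 20.0, 30.0, 40.0))
    E_list = config.overrides.get("E_list_kPa", (5.0, 10.0, 20.0, 30.0))
    rows = []
    for E in E_list:
        for D in D_list:
            F = solver.total_force_for_peak_displacement(D, E, target, nu=nu, grid_n=grid_n)
            rows.append((E, D, F))
    forces = np.array([r[2] for r in rows])
    byD = {D: [r[2] for r in rows if r[1] == D] for D in D_list}
    atE10 = [r[2] for r in rows if r[0] == 10.0] or forces.tolist()
    metrics = {
        "total_force_mN_min": float(forces.min() * 1e3),
        "total_force_mN_max": float(forces.max() * 1e3),
        "size_dependence_max_over_min_at_E10": float(max(atE10) / min(atE10)),
        "stiffness_scaling_max_deviation": float(max(
            np.ptp([f / E for (E, D, f) in rows if D == Dk]) / np.mean([f / E for (E, D, f) in rows if D == Dk])
            for Dk in D_list
        )),
    }
    artifacts: list = []
    if out_dir is not None:
        artifacts.append(_write_table(out_dir / "total_force.csv",
                                      ["E_kPa", "D_mm", "total_force_N"], rows))
    return ExperimentReport("fig9_total_force", metrics, {"total_force": rows}, artifacts)


def _run_fig10(config, out_dir, render):
    """Coil current requirements for saturation field and target forces."""
    a = config.param("coil_radius_m")
    msat = config.param("saturation_magnetization")
    nI_h = coils.required_helmholtz_ampere_turns(config.param("helmholtz_target_B_T"), a)
    weights_g = config.overrides.get("weights_g", (0.25, 0.5, 0.75, 1.0))
    forces_mN = np.asarray(config.overrides.get("forces_mN", np.arange(10.0, 41.0, 2.0)))
    rows = []
    for w_g in weights_g:
        load = coils.NanoparticleLoad(msat, 0.0, w_g * 1e-3)
        for F_mN in forces_mN:
            nI = coils.required_maxwell_ampere_turns(F_mN * 1e-3, load, a)
            rows.append((w_g, F_mN, nI))
    metrics = {
        "helmholtz_ampere_turns_for_0p4T": float(nI_h),
        "maxwell_ampere_turns_min": float(min(r[2] for r in rows)),
        "maxwell_ampere_turns_max": float(max(r[2] for r in rows)),
    }
    artifacts: list = []
    if out_dir is not None:
        artifacts.append(_write_table(out_dir / "maxwell_currents.csv",
                                      ["weight_g", "force_mN", "ampere_turns_A"], rows))
    return ExperimentReport("fig10_currents", metrics, {"maxwell_currents": rows}, artifacts)


# --------------------------------------------------------------------------
# rendering and small helpers

def render_maps(data, style: str, path, extent_cm: float = 10.0, title: str = "",
                vectors=None) -> Path:
    """Render a 2D map (``style="heatmap"``) or a vector field
    (``style="vector"``, with ``vectors=(Y, Z, Vy, Vz)``) to PNG with
    physical axes in cm.  Deterministic: identical data and style produce
    identical bytes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4), dpi=110)
    if style == "heatmap":
        im = ax.imshow(np.asarray(data).T, origin="lower", cmap="viridis",
                       extent=[0, extent_cm, 0, extent_cm], aspect="auto")
        fig.colorbar(im, ax=ax)
    elif style == "vector":
        Y, Z, Vy, Vz = vectors
        ax.quiver(Y, Z, Vy, Vz)
    else:
        raise ValueError(f"unknown style {style!r}")
    ax.set_xlabel("y [cm]")
    ax.set_ylabel("z [cm]")
    if title:
        ax.set_title(title)
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", metadata={"Software": "mnpmap"})
    plt.close(fig)
    path.write_bytes(buf.getvalue())
    return path


def _write_table(path, header, rows) -> Path:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for r in rows:
            w.writerow([f"{v:.10g}" if isinstance(v, float) else v for v in r])
    return path
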