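"""Volume, table and config I/O.

Scalar volumes travel as MetaImage (MHD/RAW) via SimpleITK with the grid
spacing recorded in the header; 2D maps are additionally exportable as
CSV.  Configs and metrics reports are flat YAML key:value files so every
run can be reproduced from its serialized parameter set.

Array axis convention is (y, z) in 2D and (x, y, z) in 3D with z last;
SimpleITK stores (z, y, x), so writers reverse the axes and readers
reverse them back.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml


def write_mhd(path, array: np.ndarray, spacing) -> Path:
    """Write a scalar volume as MetaImage; spacing per axis in meters."""
    path = Path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, str(path))
    return path


def read_mhd(path) -> tuple[np.ndarray, tuple]:
    """Read a MetaImage volume; returns (array, spacing) in package axis order."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).T
    return arr, tuple(img.GetSpacing())


def write_displacement(out_dir, field, prefix: str = "u") -> list[Path]:
    """Write each displacement component as a separate MHD volume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = ["x", "y", "z"][3 - field.ndim:]
    paths = []
    for c, name in enumerate(names):
        paths.append(write_mhd(out_dir / f"{prefix}_{name}.mhd", field.u[..., c], field.voxel_size))
    return paths


def read_displacement(out_dir, prefix: str = "u"):
    """Read a displacement field written by :func:`write_displacement`."""
    from .phantom import DisplacementField

    out_dir = Path(out_dir)
    comps, spacing = [], None
    for name in ["x", "y", "z"]:
        p = out_dir / f"{prefix}_{name}.mhd"
        if p.exists():
            arr, spacing = read_mhd(p)
            comps.append(arr)
    if not comps:
        raise FileNotFoundError(f"no {prefix}_*.mhd components in {out_dir}")
    return DisplacementField(np.stack(comps, axis=-1), spacing)


def write_csv_map(path, array2d: np.ndarray, spacing, comment: str = "") -> Path:
    """Write a 2D map as CSV (rows = y, columns = z), spacing noted in header."""
    path = Path(path)
    header = f"{comment}\nrows: y, cols: z; spacing [m]: {tuple(spacing)}"
    np.savetxt(path, array2d, delimiter=",", header=header)
    return path


def write_yaml(path, data: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(data), fh, sort_keys=False)
    return path


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
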