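"""File formats for every stage.

Voxel grids travel as TIFF stacks or headered CSV text; curves and cohort
tables as CSV with a header row; spectra as two-column tab-separated text;
ground truth as a JSON sidecar named ``<basename>.truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import VoxelGrid

__all__ = [
    "write_voxel_tiff",
    "read_voxel_tiff",
    "write_voxel_csv",
    "read_voxel_csv",
    "write_curve_csv",
    "read_curve_csv",
    "write_indent_csv",
    "read_indent_csv",
    "write_spectrum_txt",
    "read_spectrum_txt",
    "write_truth_json",
    "read_truth_json",
    "truth_sidecar_path",
]


def truth_sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.name.rsplit(".", 1)[0] + ".truth.json")


def write_truth_json(path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ------------------------------------------------------------- voxel grids

def write_voxel_tiff(path, grid: VoxelGrid) -> None:
    tifffile.imwrite(
        path,
        grid.values.astype(np.float32),
        photometric="minisblack",
        metadata={"voxel_size_mm": grid.voxel_size},
    )


def read_voxel_tiff(path, voxel_size: float | None = None) -> VoxelGrid:
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        if voxel_size is None:
            meta = tif.shaped_metadata or tif.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            voxel_size = float(meta.get("voxel_size_mm", 0.006))
    return VoxelGrid(values=values, voxel_size=voxel_size)


def write_voxel_csv(path, grid: VoxelGrid) -> None:
    """Plain-text voxel grid: comment header with shape/voxel size, then one
    row per voxel-row, slices concatenated along axis 0."""
    nz, ny, nx = grid.values.shape
    with open(path, "w") as fh:
        fh.write(f"# shape: {nz} {ny} {nx}\n")
        fh.write(f"# voxel_size_mm: {grid.voxel_size}\n")
        np.savetxt(fh, grid.values.reshape(nz * ny, nx), fmt="%.6g", delimiter=",")


def read_voxel_csv(path) -> VoxelGrid:
    shape = None
    voxel_size = 0.006
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# shape:"):
                shape = tuple(int(v) for v in line.split(":")[1].split())
            elif line.startswith("# voxel_size_mm:"):
                voxel_size = float(line.split(":")[1])
    data = np.loadtxt(path, delimiter=",", comments="#")
    if shape is None:
        raise ValueError(f"{path}: missing '# shape:' header")
    return VoxelGrid(values=data.reshape(shape), voxel_size=voxel_size)


# ------------------------------------------------------------------ curves

def write_curve_csv(path, displacement, force, time=None) -> None:
    cols = {"displacement_mm": displacement, "force_N": force}
    if time is not None:
        cols = {"time_s": time, **cols}
    pd.DataFrame(cols).to_csv(path, index=False)


def read_curve_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("displacement_mm", "force_N"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def write_indent_csv(path, time, depth, load) -> None:
    pd.DataFrame({"time_s": time, "depth_nm": depth, "load_uN": load}).to_csv(
        path, index=False
    )


def read_indent_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time_s", "depth_nm", "load_uN"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


# ----------------------------------------------------------------- spectra

def write_spectrum_txt(path, wavenumber, intensity) -> None:
    np.savetxt(path, np.column_stack([wavenumber, intensity]), fmt="%.6g", delimiter="\t")


def read_spectrum_txt(path):
    data = np.loadtxt(path, delimiter=None)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, intensity)")
    return data[:, 0], data[:, 1]
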