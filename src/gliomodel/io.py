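"""Readers and writers: HDF5 fields and paths, legacy VTK, NIfTI, TOML config."""

from __future__ import annotations

import sys
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .macro_pde import MacroSolution
from .pdifmp import MicroPath
from .tensor_fields import DiffusionTensorField

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "save_field_h5",
    "load_field_h5",
    "save_solution_h5",
    "save_paths_h5",
    "write_vtk_scalar",
    "read_nifti_tensor_slice",
    "load_config",
    "paths_summary",
]


def save_field_h5(path, field: DiffusionTensorField, A: Optional[np.ndarray] = None) -> None:
    """Write a tensor field (and optionally the tissue fraction A) to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("tensors", data=field.tensors)
        fh.create_dataset("mask", data=field.mask)
        fh.create_dataset("spacing", data=field.spacing)
        fh.create_dataset("origin", data=field.origin)
        if A is not None:
            fh.create_dataset("A", data=np.asarray(A))


def load_field_h5(path) -> DiffusionTensorField:
    import h5py

    with h5py.File(path, "r") as fh:
        return DiffusionTensorField(
            origin=fh["origin"][()],
            spacing=fh["spacing"][()],
            tensors=fh["tensors"][()],
            mask=fh["mask"][()],
        )


def save_solution_h5(path, solution: MacroSolution) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times_s", data=solution.times)
        fh.create_dataset("M", data=solution.M)
        fh.create_dataset("step_times_s", data=solution.step_times)
        fh.create_dataset("mass_series", data=solution.mass_series)
        fh.create_dataset("max_series", data=solution.max_series)
        fh.create_dataset("mask", data=solution.mask)
        fh.attrs["clip_total"] = solution.clip_total


def save_paths_h5(path, paths: Sequence[MicroPath]) -> None:
    """One HDF5 group per trajectory (jump times plus saved states)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for i, p in enumerate(paths):
            g = fh.create_group(f"path_{i:06d}")
            g.create_dataset("jump_times", data=p.jump_times)
            g.create_dataset("times", data=p.times)
            g.create_dataset("x", data=p.x)
            g.create_dataset("z", data=p.z)
            g.create_dataset("v", data=p.v)
            if p.seed is not None:
                g.attrs["seed"] = p.seed


def paths_summary(paths: Sequence[MicroPath]):
    """Per-path summary table: jump count, final position, displacement^2."""
    import pandas as pd

    rows = []
    for i, p in enumerate(paths):
        rows.append(
            {
                "path": i,
                "n_jumps": p.n_jumps,
                "x_final": p.x[-1, 0],
                "y_final": p.x[-1, 1],
                "disp2": float(((p.x[-1] - p.x[0]) ** 2).sum()),
            }
        )
    return pd.DataFrame(rows)


def write_vtk_scalar(path, name: str, data: np.ndarray, spacing, origin) -> None:
    """Legacy VTK structured-points writer (ASCII) for quick visualisation."""
    data = np.asarray(data)
    ny, nx = data.shape
    spacing = np.broadcast_to(np.asarray(spacing, float), (2,))
    origin = np.asarray(origin, float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {origin[0]:g} {origin[1]:g} 0\n")
        fh.write(f"SPACING {spacing[0]:g} {spacing[1]:g} 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        for row in data:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_nifti_tensor_slice(
    tensor_path, mask_path, z_index: int, spacing=None
) -> DiffusionTensorField:
    """Read one axial slice of a NIfTI tensor volume plus mask.

    Expects a 5D tensor image (x, y, z, 1, 6) or 4D (x, y, z, 6) in the
    lower-triangular component order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz), which
    is the common tensor-fit output layout.  This is an interface for real
    acquisitions; the shipped studies run entirely on synthetic fields.
    """
    import nibabel as nib

    img = nib.load(str(tensor_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5:
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError("expected a NIfTI tensor image with 6 components")
    sl = data[:, :, z_index, :]  # (nx, ny, 6)
    sl = np.transpose(sl, (1, 0, 2))  # row-major (ny, nx, 6)
    xx, xy, yy, xz, yz, zz = (sl[..., i] for i in range(6))
    tensors = np.zeros(sl.shape[:2] + (3, 3))
    tensors[..., 0, 0] = xx
    tensors[..., 1, 1] = yy
    tensors[..., 2, 2] = zz
    tensors[..., 0, 1] = tensors[..., 1, 0] = xy
    tensors[..., 0, 2] = tensors[..., 2, 0] = xz
    tensors[..., 1, 2] = tensors[..., 2, 1] = yz
    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj)[:, :, z_index].T.astype(bool)
    if spacing is None:
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]), float(zooms[1]))
    return DiffusionTensorField(
        origin=np.zeros(2),
        spacing=np.asarray(spacing, float),
        tensors=tensors,
        mask=mask,
    )


_CONFIG_DEFAULTS = {
    "field": {
        "kind": "brain_slice",
        "shape": [96, 96],
        "spacing_mm": 0.5,
        "anisotropy_ratio": 9.0,
        "seed": 0,
    },
    "micro": {"n_paths": 100, "T_days": 0.001, "save_dt": 0.0, "seed": 0, "z0": 0.0},
    "macro": {
        "dt_days": 1.0,
        "t_end_days": 600.0,
        "save_every": 100,
        "scheme": "fv_upwind",
    },
}


def load_config(path=None) -> dict:
    """Load a TOML run configuration, filling unset keys with defaults."""
    cfg = {k: dict(v) for k, v in _CONFIG_DEFAULTS.items()}
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values)
    return cfg
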