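"""NIfTI + JSON-sidecar interchange for simulated series and thermal maps.

Image series travel as two 4D NIfTI stacks per orientation (magnitude
and phase, shape rows x cols x 1 x frames, mm units in the affine) plus
one JSON sidecar holding acquisition parameters, frame times and seeds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigError
from .geometry import ScanGrid
from .thermometry import AcquisitionParams, ImageSeries, ThermalMapSeries

__all__ = [
    "write_image_series",
    "read_image_series",
    "write_thermal_maps",
    "read_thermal_maps",
]


def _affine(grid: ScanGrid) -> np.ndarray:
    return np.diag(
        [grid.in_plane_voxel_mm, grid.in_plane_voxel_mm, grid.slice_thickness_mm, 1.0]
    )


def _save_stack(frames: np.ndarray, grid: ScanGrid, path: Path) -> None:
    # (t, rows, cols) -> (rows, cols, 1, t)
    data = np.moveaxis(frames, 0, -1)[:, :, None, :]
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(grid)), str(path))


def _load_stack(path: Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return np.moveaxis(data[:, :, 0, :], -1, 0)


def write_image_series(
    outdir: str | Path, series: dict[str, ImageSeries], sidecar_extra: dict | None = None
) -> None:
    """Write coronal/sagittal magnitude+phase stacks plus a sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    first = next(iter(series.values()))
    sidecar = {
        "acq": dataclasses.asdict(first.acq),
        "grid": dataclasses.asdict(first.grid),
        "times_s": first.times_s.tolist(),
        "orientations": sorted(series),
    }
    sidecar.update(sidecar_extra or {})
    for plane, s in series.items():
        _save_stack(s.magnitudes, s.grid, outdir / f"{plane}_magnitude.nii")
        _save_stack(s.phases, s.grid, outdir / f"{plane}_phase.nii")
    (outdir / "series.json").write_text(json.dumps(sidecar, indent=2))


def read_image_series(indir: str | Path) -> dict[str, ImageSeries]:
    indir = Path(indir)
    sidecar_path = indir / "series.json"
    if not sidecar_path.exists():
        raise ConfigError(f"no series.json sidecar in {indir}")
    sidecar = json.loads(sidecar_path.read_text())
    acq = AcquisitionParams(**sidecar["acq"])
    out = {}
    for plane in sidecar["orientations"]:
        grid = ScanGrid(**{**sidecar["grid"], "orientation": plane})
        out[plane] = ImageSeries(
            magnitudes=_load_stack(indir / f"{plane}_magnitude.nii"),
            phases=_load_stack(indir / f"{plane}_phase.nii"),
            times_s=np.asarray(sidecar["times_s"]),
            orientation=plane,
            grid=grid,
            acq=acq,
        )
    return out


def write_thermal_maps(outdir: str | Path, series: dict[str, ThermalMapSeries]) -> None:
    """Write dT (°C) and validity-mask stacks plus a sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    first = next(iter(series.values()))
    sidecar = {
        "grid": dataclasses.asdict(first.grid),
        "times_s": first.times_s.tolist(),
        "orientations": sorted(series),
        "effective_prf_coeff": first.effective_prf_coeff,
    }
    for plane, s in series.items():
        _save_stack(s.dT, s.grid, outdir / f"{plane}_dT.nii")
        _save_stack(s.valid.astype(np.float32), s.grid, outdir / f"{plane}_valid.nii")
    (outdir / "thermal.json").write_text(json.dumps(sidecar, indent=2))


def read_thermal_maps(indir: str | Path) -> dict[str, ThermalMapSeries]:
    indir = Path(indir)
    sidecar = json.loads((indir / "thermal.json").read_text())
    out = {}
    for plane in sidecar["orientations"]:
        grid = ScanGrid(**{**sidecar["grid"], "orientation": plane})
        out[plane] = ThermalMapSeries(
            dT=_load_stack(indir / f"{plane}_dT.nii"),
            times_s=np.asarray(sidecar["times_s"]),
            valid=_load_stack(indir / f"{plane}_valid.nii") > 0.5,
            orientation=plane,
            grid=grid,
            effective_prf_coeff=sidecar["effective_prf_coeff"],
        )
    return out
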