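"""CEM43 thermal dose, two-plane 3D reconstruction and summary metrics.

Thermal dose is expressed as cumulative equivalent minutes at 43 °C
(Sapareto–Dewey):

    CEM43 = sum_i R^(43 - T_i) * dt_i,   R = 0.5 for T >= 43 °C,
                                         R = 0.25 below,

with absolute temperature formed as baseline (37 °C, patient-like
conditions) plus the measured temperature change, and the accumulation
covering the sonication plus the observed cooling minute.  The ablation
criterion of the study is the volume above 240 EM.

The two orthogonal thermal maps (coronal and sagittal, sharing the
vertical line through the focus) are combined into a 3D temperature
distribution with a normalized-product scheme, exact for separable
fields; it is a documented deterministic stand-in for the unnamed
proprietary reconstruction of the original processing chain and is
flagged as such in output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .errors import DegenerateInputError, InvalidSpecError
from .geometry import RegionSpec, ScanGrid, voxel_centers_in_region
from .thermometry import ThermalMapSeries

__all__ = [
    "DoseConfig",
    "DoseMap",
    "SonicationMetrics",
    "cem43",
    "reconstruct_3d",
    "dose_volume",
    "max_unmasked_temperature",
    "edge_mean_temperature",
    "apparent_marker_size",
    "compare_groups",
    "significance_stars",
]

RECONSTRUCTION_METHOD = "normalized-product two-plane reconstruction"


@dataclass(frozen=True)
class DoseConfig:
    """Thermal-dose model constants and reconstruction grid."""

    baseline_temp_C: float = 37.0
    threshold_EM: float = 240.0
    breakpoint_C: float = 43.0
    R_above: float = 0.5
    R_below: float = 0.25
    reconstruction_grid_mm: float = 1.56
    reconstruction_extent_mm: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.R_below <= self.R_above < 1:
            raise InvalidSpecError("require 0 < R_below <= R_above < 1")
        if self.threshold_EM <= 0:
            raise InvalidSpecError("dose threshold must be positive")
        if self.reconstruction_grid_mm <= 0 or self.reconstruction_extent_mm <= 0:
            raise InvalidSpecError("reconstruction grid parameters must be positive")


@dataclass
class DoseMap:
    """Accumulated CEM43 equivalent minutes per voxel."""

    values: np.ndarray  # EM, any spatial shape
    voxel_volume_mm3: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.voxel_volume_mm3 <= 0:
            raise InvalidSpecError("voxel volume must be positive")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidSpecError("dose values must be finite and non-negative")


@dataclass
class SonicationMetrics:
    """Per-sonication summary used for the per-marker comparisons."""

    phantom_id: str
    marker_name: str | None
    sonication_index: int
    max_unmasked_dT_C: float
    edge_mean_dT_C: float
    dose_volume_ml: float
    masked_count: int
    masked_volume_mm3: float
    ratio_to_marker_volume: float | None
    growth_factor: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def cem43(
    dT: np.ndarray,
    times_s: np.ndarray,
    config: DoseConfig | None = None,
) -> np.ndarray:
    """Accumulate CEM43 over a temperature-change time series.

    ``dT`` has shape (n_frames, ...); absolute temperature is baseline
    plus dT.  Each frame after the first contributes its preceding
    inter-frame interval (in minutes) at rate R^(43 - T).
    """
    config = config or DoseConfig()
    dT = np.asarray(dT, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if dT.shape[0] != times_s.shape[0]:
        raise InvalidSpecError("one timestamp per frame required")
    if times_s.size > 1 and np.any(np.diff(times_s) < 0):
        raise InvalidSpecError("negative frame interval")
    dose = np.zeros(dT.shape[1:], dtype=float)
    for i in range(1, dT.shape[0]):
        dt_min = (times_s[i] - times_s[i - 1]) / 60.0
        T = config.baseline_temp_C + dT[i]
        R = np.where(T >= config.breakpoint_C, config.R_above, config.R_below)
        dose += R ** (config.breakpoint_C - T) * dt_min
    return dose


def _center_line(plane: np.ndarray, col_coords: np.ndarray) -> np.ndarray:
    """Profile along the shared vertical axis at the in-plane origin
    (mean of the columns nearest x = 0 / z = 0)."""
    order = np.argsort(np.abs(col_coords))
    if abs(col_coords[order[0]]) < 1e-9:
        return plane[:, order[0]].astype(float)
    return 0.5 * (plane[:, order[0]] + plane[:, order[1]])


def reconstruct_3d(
    coronal: np.ndarray,
    sagittal: np.ndarray,
    grid: ScanGrid,
    config: DoseConfig | None = None,
    eps_fraction: float = 0.05,
) -> tuple[np.ndarray, dict]:
    """Normalized-product 3D temperature reconstruction.

    ``T(x, y, z) = Tc(x, y) * Ts(y, z) / max(Tline(y), eps)`` on an
    isotropic grid cropped to the reconstruction cube, where Tline is
    the mean of the two planes' profiles along their shared vertical
    line and eps guards small denominators.  Output is clamped to
    [0, max(Tc, Ts)].  Exact for separable fields.  A relative mismatch
    above 20% between the two line profiles raises a consistency
    warning, not a failure.

    Returns the (n_y, n_x, n_z) array and a metadata dict (method tag,
    grid spacing, axis coordinates).
    """
    config = config or DoseConfig()
    if coronal.shape != (grid.n_rows, grid.n_cols) or sagittal.shape != (
        grid.n_rows,
        grid.n_cols,
    ):
        raise InvalidSpecError("plane maps must match the scan grid")
    half = config.reconstruction_extent_mm / 2.0
    rows = grid.row_coords_mm()
    cols = grid.col_coords_mm()
    rsel = np.abs(rows) <= half + 1e-9
    csel = np.abs(cols) <= half + 1e-9
    Tc = coronal[np.ix_(rsel, csel)]  # (y, x)
    Ts = sagittal[np.ix_(rsel, csel)]  # (y, z)
    lc = _center_line(coronal, cols)[rsel]
    ls = _center_line(sagittal, cols)[rsel]
    scale = max(np.abs(lc).max(), np.abs(ls).max(), 1e-12)
    # consistency check is only meaningful once there is real heating
    if scale > 5.0 and np.max(np.abs(lc - ls)) > 0.2 * scale:
        warnings.warn(
            "coronal and sagittal line profiles disagree by more than 20%",
            RuntimeWarning,
            stacklevel=2,
        )
    line = 0.5 * (lc + ls)
    eps = max(eps_fraction * float(line.max(initial=0.0)), 1e-9)
    denom = np.maximum(line, eps)
    T3 = Tc[:, :, None] * Ts[:, None, :] / denom[:, None, None]
    hi = max(float(Tc.max(initial=0.0)), float(Ts.max(initial=0.0)))
    T3 = np.clip(T3, 0.0, hi)
    meta = {
        "method": RECONSTRUCTION_METHOD,
        "spacing_mm": grid.in_plane_voxel_mm,
        "y_mm": rows[rsel],
        "x_mm": cols[csel],
        "z_mm": cols[csel],
    }
    return T3, meta


def dose_volume(dose: DoseMap, threshold_EM: float | None = None) -> float:
    """Volume (ml) of voxels with dose strictly above the threshold."""
    thr = 240.0 if threshold_EM is None else threshold_EM
    count = int(np.count_nonzero(dose.values > thr))
    return count * dose.voxel_volume_mm3 / 1000.0


def max_unmasked_temperature(
    series: ThermalMapSeries,
    sigma_T_maps: np.ndarray,
    sigma_threshold_C: float,
) -> float:
    """Largest dT over frames and voxels passing the sigma_T rule
    (threshold 2 °C on unaveraged maps, 1 °C after x4 averaging)."""
    sigma_T_maps = np.asarray(sigma_T_maps, dtype=float)
    if sigma_T_maps.shape != series.dT.shape:
        raise InvalidSpecError("sigma_T maps must align with the series")
    ok = (sigma_T_maps <= sigma_threshold_C) & series.valid
    if not ok.any():
        raise DegenerateInputError("every voxel is masked")
    return float(series.dT[ok].max())


def edge_mean_temperature(
    dT_map: np.ndarray,
    grid: ScanGrid,
    inner_diameter_mm: float = 9.0,
    outer_diameter_mm: float = 12.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Mean dT over the edge annulus between the outer sonication
    trajectory and the nominal ablation diameter (28 voxels on the
    study grid)."""
    region = RegionSpec(
        kind="annulus",
        inner_diameter_mm=inner_diameter_mm,
        outer_diameter_mm=outer_diameter_mm,
        center=center,
    )
    voxels = voxel_centers_in_region(grid, region)
    if not voxels:
        raise DegenerateInputError("edge annulus contains no voxel centres")
    rows, cols = zip(*voxels)
    return float(np.asarray(dT_map)[list(rows), list(cols)].mean())


def apparent_marker_size(
    magnitude: np.ndarray,
    grid: ScanGrid,
    background_level: float | None = None,
) -> tuple[float, float]:
    """Width and length (mm) of the signal void on an averaged image.

    The void is the connected set of voxels below 50% of the background
    magnitude; its extents are measured along the principal axes of the
    voxel-centre cloud, plus one voxel to account for pixelation.
    Returns (0, 0) when no void is present; with several disjoint voids
    the largest is measured and a warning is issued.
    """
    mag = np.asarray(magnitude, dtype=float)
    bg = float(np.median(mag)) if background_level is None else background_level
    void = mag < 0.5 * bg
    labels, n = ndimage.label(void, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return (0.0, 0.0)
    if n > 1:
        warnings.warn("multiple disjoint voids; measuring the largest", RuntimeWarning)
        sizes = ndimage.sum_labels(void, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
    else:
        keep = 1
    rr, cc = np.nonzero(labels == keep)
    px = grid.in_plane_voxel_mm
    pts = np.column_stack([grid.col_coords_mm()[cc], grid.row_coords_mm()[rr]])
    if pts.shape[0] == 1:
        return (px, px)
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / pts.shape[0]
    _, vecs = np.linalg.eigh(cov)
    proj = centred @ vecs
    extents = np.sort(proj.max(axis=0) - proj.min(axis=0) + px)
    return (float(extents[0]), float(extents[1]))


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, str]:
    """Two-sided unequal-variance (Welch) t-test with star coding.

    Degenerate zero-variance groups with equal means report (0, 1, "")
    by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidSpecError("each group needs at least two values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return (0.0, 1.0, "")
        return (float(np.sign(a.mean() - b.mean()) * np.inf), 0.0, "***")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return (float(t), float(p), significance_stars(float(p)))


def significance_stars(p: float) -> str:
    """Star coding at the 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
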