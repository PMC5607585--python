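"""SNR-based masked-voxel identification, quantification and infilling.

A voxel's phase-derived temperature noise is sigma_T = sqrt(2) / (SNR k)
— the sqrt(2) because a temperature map is the difference of two noisy
phase images.  Voxels whose sigma_T exceeds a threshold (2 °C on
unaveraged maps, 1 °C after x4 temporal averaging) carry no reliable
temperature: inside a marker's signal void, or wherever heating-induced
T1 decay has depressed the magnitude.  Masked voxels are counted per
frame, aggregated with a strict majority rule across frames, and
infilled from neighbouring voxels before thermal-dose processing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidSpecError
from .geometry import MarkerSpec, ScanGrid, marker_model_volume
from .thermometry import AcquisitionParams, prf_rad_per_C

__all__ = [
    "MaskingConfig",
    "MaskReport",
    "estimate_noise_sigma",
    "temperature_std_map",
    "mask_frame",
    "majority_mask",
    "infill_masked",
    "mask_report",
]


@dataclass(frozen=True)
class MaskingConfig:
    """Masking thresholds and infill neighbourhood.

    ``sigma_threshold_C`` applies to unaveraged maps;
    ``sigma_threshold_averaged_C`` after x4 temporal averaging.
    """

    sigma_threshold_C: float = 2.0
    sigma_threshold_averaged_C: float = 1.0
    majority_fraction: float = 0.5
    noise_sigma_estimate: float | None = None
    neighborhood: int = 8

    def __post_init__(self) -> None:
        if self.sigma_threshold_C <= 0 or self.sigma_threshold_averaged_C <= 0:
            raise InvalidSpecError("sigma thresholds must be positive")
        if not 0 < self.majority_fraction < 1:
            raise InvalidSpecError("majority_fraction must be in (0, 1)")
        if self.neighborhood not in (4, 8):
            raise InvalidSpecError("neighborhood must be 4- or 8-connected")


@dataclass
class MaskReport:
    """Masked-voxel summary of one sonication on one slice orientation."""

    per_frame_counts: list[int]
    majority_count: int
    masked_volume_mm3: float
    ratio_to_marker_volume: float
    growth_factor: float | None  # end / start count; None if undefined
    orientation: str = "coronal"

    def to_dict(self) -> dict:
        return {
            "per_frame_counts": self.per_frame_counts,
            "majority_count": self.majority_count,
            "masked_volume_mm3": self.masked_volume_mm3,
            "ratio_to_marker_volume": self.ratio_to_marker_volume,
            "growth_factor": self.growth_factor,
            "orientation": self.orientation,
        }


def estimate_noise_sigma(magnitude: np.ndarray, corner: int = 16) -> float:
    """Robust noise sigma from a background corner ROI.

    Uses 1.4826 * MAD of the magnitude in the top-left corner block,
    which is insensitive to any structure crossing the ROI.
    """
    if magnitude.ndim != 2:
        raise InvalidSpecError("expected a single 2D magnitude map")
    block = magnitude[:corner, :corner]
    med = np.median(block)
    sigma = 1.4826 * float(np.median(np.abs(block - med)))
    if sigma <= 0:
        raise DegenerateInputError("background ROI has zero spread")
    return sigma


def temperature_std_map(
    magnitude: np.ndarray,
    noise_sigma: float,
    acq: AcquisitionParams,
    alpha_eff_ppm_per_C: float = 0.0094,
) -> np.ndarray:
    """Per-voxel temperature standard deviation sigma_T = sqrt(2)/(SNR k).

    SNR = magnitude / noise_sigma and k is the PRF constant at the
    effective coefficient.  Non-positive magnitudes map to infinity.
    """
    if noise_sigma <= 0:
        raise InvalidSpecError("noise sigma must be positive")
    k = prf_rad_per_C(acq, alpha_eff_ppm_per_C)
    mag = np.asarray(magnitude, dtype=float)
    with np.errstate(divide="ignore"):
        sigma_T = np.where(mag > 0, np.sqrt(2.0) * noise_sigma / (mag * k), np.inf)
    return sigma_T


def mask_frame(sigma_T_map: np.ndarray, threshold_C: float) -> np.ndarray:
    """Boolean mask of voxels whose sigma_T exceeds the threshold."""
    if threshold_C <= 0:
        raise InvalidSpecError("threshold must be positive")
    return np.asarray(sigma_T_map) > threshold_C


def majority_mask(per_frame_masks: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Voxels masked in strictly more than half of the frames."""
    masks = np.asarray(per_frame_masks, dtype=bool)
    if masks.ndim < 3 or masks.shape[0] == 0:
        raise DegenerateInputError("need at least one frame mask")
    return masks.sum(axis=0) > masks.shape[0] / 2.0


def _neighbor_sums(values: np.ndarray, valid: np.ndarray, neighborhood: int):
    """Sum of valid neighbour values and valid-neighbour counts."""
    if neighborhood == 4:
        shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    vals = np.where(valid, values, 0.0)
    total = np.zeros_like(values, dtype=float)
    count = np.zeros_like(values, dtype=float)
    vp = np.pad(vals, 1)
    cp = np.pad(valid.astype(float), 1)
    for dr, dc in shifts:
        total += vp[1 + dr : 1 + dr + values.shape[0], 1 + dc : 1 + dc + values.shape[1]]
        count += cp[1 + dr : 1 + dr + values.shape[0], 1 + dc : 1 + dc + values.shape[1]]
    return total, count


def infill_masked(
    dT_map: np.ndarray, mask: np.ndarray, neighborhood: int = 8
) -> np.ndarray:
    """Replace masked voxels by the mean of their valid in-plane
    neighbours, iterating from the mask boundary inward until every
    voxel is filled.  Unmasked voxels are preserved bit-exactly."""
    dT = np.array(dT_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dT.shape:
        raise InvalidSpecError("mask shape must match the map")
    if mask.all():
        raise DegenerateInputError("cannot infill a fully masked map")
    valid = ~mask
    while not valid.all():
        total, count = _neighbor_sums(dT, valid, neighborhood)
        fillable = ~valid & (count > 0)
        if not fillable.any():  # pragma: no cover - unreachable on connected grids
            raise DegenerateInputError("isolated masked region cannot be filled")
        dT[fillable] = total[fillable] / count[fillable]
        valid |= fillable
    return dT


def mask_report(
    per_frame_masks: Sequence[np.ndarray] | np.ndarray,
    grid: ScanGrid,
    marker: MarkerSpec,
    orientation: str = "coronal",
) -> MaskReport:
    """Quantify the masked voxels of one sonication.

    The masked volume is the strict-majority voxel count times the
    acquisition voxel volume; the ratio divides it by the marker's
    cylinder/sphere model volume.  The growth factor is the last-frame
    count over the first-frame count (undefined when the first frame
    masks nothing)."""
    mv = marker_model_volume(marker)
    if mv <= 0:
        raise InvalidSpecError("marker model volume must be positive")
    masks = np.asarray(per_frame_masks, dtype=bool)
    counts = [int(m.sum()) for m in masks]
    if not counts:
        raise DegenerateInputError("need at least one frame mask")
    maj = int(majority_mask(masks).sum())
    masked_volume = maj * grid.voxel_volume_mm3
    growth = counts[-1] / counts[0] if counts[0] > 0 else None
    return MaskReport(
        per_frame_counts=counts,
        majority_count=maj,
        masked_volume_mm3=masked_volume,
        ratio_to_marker_volume=masked_volume / mv,
        growth_factor=growth,
        orientation=orientation,
    )
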