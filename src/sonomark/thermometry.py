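"""PRF-shift thermometry: phase series to temperature-change series.

The water proton resonance frequency shifts by alpha = -0.0094 ppm/°C,
so a gradient-echo phase difference maps to a temperature change via

    dT = dphi / k,   k = 2*pi * gamma * B0 * alpha * TE

with gamma the proton gyromagnetic ratio.  At 1.5 T and TE = 20 ms this
gives k = 0.0754 rad/°C.  The sign convention stores k positive so that
rendering (phase = baseline + k*dT) and conversion are exact inverses.

Also implemented here: temporal block averaging of series and the
per-phantom absorption-correction coefficient — the mean focal heating
of a phantom's reference sonications divided by the cohort grand mean,
applied as a divisor to the PRF coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidSpecError
from .geometry import ScanGrid

__all__ = [
    "AcquisitionParams",
    "ThermometryConfig",
    "ImageSeries",
    "ThermalMapSeries",
    "AbsorptionCorrection",
    "prf_rad_per_C",
    "phase_to_temperature",
    "temporal_average",
    "absorption_correction",
    "corrected_prf",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """EPI gradient-echo thermometry protocol parameters."""

    te_ms: float = 20.0
    tr_ms: float = 85.0
    flip_deg: float = 20.0
    epi_factor: int = 19
    b0_T: float = 1.5
    gyromagnetic_MHz_per_T: float = 42.576
    frame_interval_s: float = 0.5

    def __post_init__(self) -> None:
        for name in ("te_ms", "tr_ms", "flip_deg", "epi_factor", "b0_T",
                     "gyromagnetic_MHz_per_T", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")


@dataclass(frozen=True)
class ThermometryConfig:
    """PRF coefficient and temporal-averaging factors."""

    prf_coeff_ppm_per_C: float = 0.0094
    temporal_average_factor: int = 4
    display_average_factor: int = 32

    def __post_init__(self) -> None:
        if self.prf_coeff_ppm_per_C <= 0:
            raise InvalidSpecError("PRF coefficient must be positive")
        if self.temporal_average_factor < 1 or self.display_average_factor < 1:
            raise InvalidSpecError("averaging factors must be >= 1")


def prf_rad_per_C(acq: AcquisitionParams, alpha_ppm_per_C: float) -> float:
    """Phase-to-temperature constant k = 2*pi*gamma*B0*alpha*TE (rad/°C)."""
    return (
        2.0
        * np.pi
        * acq.gyromagnetic_MHz_per_T
        * 1e6
        * acq.b0_T
        * alpha_ppm_per_C
        * 1e-6
        * acq.te_ms
        * 1e-3
    )


@dataclass
class ImageSeries:
    """Multi-frame complex MR image series as magnitude + phase maps."""

    magnitudes: np.ndarray  # (n_frames, n_rows, n_cols)
    phases: np.ndarray  # radians, same shape
    times_s: np.ndarray  # (n_frames,), strictly increasing
    orientation: str
    grid: ScanGrid
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.magnitudes.shape != self.phases.shape:
            raise InvalidSpecError("magnitude/phase shape mismatch")
        if self.magnitudes.shape[0] != self.times_s.shape[0]:
            raise InvalidSpecError("one timestamp per frame required")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise InvalidSpecError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    def complex_frames(self) -> np.ndarray:
        return self.magnitudes * np.exp(1j * self.phases)


@dataclass
class ThermalMapSeries:
    """Per-frame temperature-change maps with explicit validity masks.

    Invalid voxels are flagged in ``valid``; their dT values are kept
    but must not be consumed silently.
    """

    dT: np.ndarray  # (n_frames, n_rows, n_cols), °C
    times_s: np.ndarray
    valid: np.ndarray  # bool, same shape as dT
    orientation: str
    grid: ScanGrid
    effective_prf_coeff: float

    def __post_init__(self) -> None:
        self.dT = np.asarray(self.dT, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.dT.shape:
            raise InvalidSpecError("validity mask must match dT shape")
        if self.dT.shape[0] != self.times_s.shape[0]:
            raise InvalidSpecError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.dT.shape[0]


@dataclass(frozen=True)
class AbsorptionCorrection:
    """Per-phantom heating-efficiency coefficient (cohort mean = 1)."""

    phantom_id: str
    per_phantom_coefficient: float
    n_reference_sonications: int = 6
    roi_half_width: int = 1

    def __post_init__(self) -> None:
        if self.per_phantom_coefficient <= 0:
            raise InvalidSpecError("correction coefficient must be positive")


def _wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences to (-pi, pi]."""
    return np.angle(np.exp(1j * dphi))


def phase_to_temperature(
    series: ImageSeries,
    config: ThermometryConfig,
    reference_frames: int | Sequence[int] = 0,
    correction: float = 1.0,
) -> ThermalMapSeries:
    """Convert a phase series to a temperature-change series.

    Parameters
    ----------
    reference_frames
        Index or indices of pre-heating frames.  Several indices are
        combined as the phase of the complex mean, which lowers the
        reference noise (the default study pipeline passes every frame
        of the pre-sonication delay).
    correction
        Absorption-correction coefficient c (phantom heating relative
        to the cohort mean).  The converted temperatures are divided by
        c — equivalently the PRF coefficient is multiplied by it — so a
        phantom heating 5% harder reports reference-comparable values.

    Phase differences against the reference are wrapped to (-pi, pi];
    at 0.0754 rad/°C one wrap corresponds to about 83 °C, far above the
    dynamic range of the experiment, so no temporal unwrapping chain is
    needed.
    """
    if isinstance(reference_frames, (int, np.integer)):
        ref_idx = [int(reference_frames)]
    else:
        ref_idx = [int(i) for i in reference_frames]
    if not ref_idx:
        raise InvalidSpecError("at least one reference frame is required")
    for i in ref_idx:
        if not 0 <= i < series.n_frames:
            raise InvalidSpecError(f"reference frame {i} out of range")
    if correction <= 0:
        raise InvalidSpecError("correction must be positive")
    alpha_eff = config.prf_coeff_ppm_per_C * correction
    k = prf_rad_per_C(series.acq, alpha_eff)
    ref_phase = np.angle(np.mean(np.exp(1j * series.phases[ref_idx]), axis=0))
    dphi = _wrap_phase(series.phases - ref_phase[None])
    dT = dphi / k
    return ThermalMapSeries(
        dT=dT,
        times_s=series.times_s.copy(),
        valid=np.ones_like(dT, dtype=bool),
        orientation=series.orientation,
        grid=series.grid,
        effective_prf_coeff=alpha_eff,
    )


def temporal_average(series, factor: int):
    """Average a series over non-overlapping blocks of ``factor`` frames.

    Works on :class:`ImageSeries` (complex average, then magnitude and
    phase) and :class:`ThermalMapSeries` (arithmetic average; a block
    voxel is valid only if valid in every frame of the block).  Trailing
    frames that do not fill a block are dropped.  Timestamps become
    block means.
    """
    if factor < 1:
        raise InvalidSpecError("averaging factor must be >= 1")
    if factor == 1:
        return series
    n_blocks = series.n_frames // factor
    if n_blocks == 0:
        raise DegenerateInputError("series shorter than one averaging block")
    n_used = n_blocks * factor
    times = series.times_s[:n_used].reshape(n_blocks, factor).mean(axis=1)
    if isinstance(series, ImageSeries):
        cplx = series.complex_frames()[:n_used]
        cplx = cplx.reshape(n_blocks, factor, *cplx.shape[1:]).mean(axis=1)
        return ImageSeries(
            magnitudes=np.abs(cplx),
            phases=np.angle(cplx),
            times_s=times,
            orientation=series.orientation,
            grid=series.grid,
            acq=series.acq,
        )
    if isinstance(series, ThermalMapSeries):
        shape = series.dT.shape[1:]
        dT = series.dT[:n_used].reshape(n_blocks, factor, *shape).mean(axis=1)
        valid = series.valid[:n_used].reshape(n_blocks, factor, *shape).all(axis=1)
        return ThermalMapSeries(
            dT=dT,
            times_s=times,
            valid=valid,
            orientation=series.orientation,
            grid=series.grid,
            effective_prf_coeff=series.effective_prf_coeff,
        )
    raise InvalidSpecError(f"unsupported series type {type(series).__name__}")


def _end_frame_index(times_s: np.ndarray, end_time_s: float) -> int:
    """Index of the last frame acquired at or before ``end_time_s``."""
    idx = np.nonzero(times_s <= end_time_s + 1e-9)[0]
    if idx.size == 0:
        raise DegenerateInputError("no frame at or before the requested time")
    return int(idx[-1])


def focal_roi_mean(
    series: ThermalMapSeries,
    end_time_s: float,
    roi_half_width: int = 1,
    center_rc: tuple[int, int] | None = None,
) -> float:
    """Mean dT over a (2h+1)^2 voxel ROI at the focal centre, taken on
    the last frame at or before ``end_time_s`` (end of sonication)."""
    i = _end_frame_index(series.times_s, end_time_s)
    if center_rc is None:
        r0 = int(np.argmin(np.abs(series.grid.row_coords_mm())))
        c0 = int(np.argmin(np.abs(series.grid.col_coords_mm())))
    else:
        r0, c0 = center_rc
    h = roi_half_width
    roi = series.dT[i, r0 - h : r0 + h + 1, c0 - h : c0 + h + 1]
    return float(roi.mean())


def absorption_correction(
    reference_runs: Mapping[str, Sequence[ThermalMapSeries]],
    end_time_s: float,
    roi_half_width: int = 1,
    center_rc: tuple[int, int] | None = None,
) -> dict[str, AbsorptionCorrection]:
    """Per-phantom absorption-correction coefficients.

    For each phantom the end-of-sonication dT averaged over a 3 x 3
    focal ROI is averaged over its reference sonications, then divided
    by the grand mean over all phantoms.  By construction the returned
    coefficients average to exactly 1 (i.e. 100%).
    """
    if not reference_runs:
        raise DegenerateInputError("no reference runs supplied")
    per_phantom: dict[str, float] = {}
    counts: dict[str, int] = {}
    for pid, runs in reference_runs.items():
        if not runs:
            raise DegenerateInputError(f"phantom {pid!r} has no reference runs")
        vals = [
            focal_roi_mean(run, end_time_s, roi_half_width, center_rc)
            for run in runs
        ]
        per_phantom[pid] = float(np.mean(vals))
        counts[pid] = len(vals)
    grand = float(np.mean(list(per_phantom.values())))
    if grand == 0:
        raise DegenerateInputError("grand-mean reference heating is zero")
    return {
        pid: AbsorptionCorrection(
            phantom_id=pid,
            per_phantom_coefficient=m / grand,
            n_reference_sonications=counts[pid],
            roi_half_width=roi_half_width,
        )
        for pid, m in per_phantom.items()
    }


def corrected_prf(config: ThermometryConfig, correction: AbsorptionCorrection | float) -> float:
    """Literal corrected coefficient alpha/c for one phantom (ppm/°C).

    Note the direction: with c defined as phantom-over-cohort heating,
    *dividing* alpha by c amplifies rather than removes the absorption
    difference, so the processing chain applies the equalising
    direction instead (temperatures divided by c; see
    :func:`phase_to_temperature`).  This helper keeps the published
    arithmetic available as stated.
    """
    c = (
        correction.per_phantom_coefficient
        if isinstance(correction, AbsorptionCorrection)
        else float(correction)
    )
    if c <= 0:
        raise InvalidSpecError("correction coefficient must be positive")
    return config.prf_coeff_ppm_per_C / c
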