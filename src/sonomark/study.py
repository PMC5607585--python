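"""End-to-end study orchestration.

One *sonication* is analysed as in the original processing chain:
phase series -> temperature series (PRF, with the per-phantom
absorption correction as a divisor on the coefficient) -> sigma_T maps
and per-frame masks (2 °C rule unaveraged, 1 °C after x4 temporal
averaging) -> strict-majority masked-voxel count -> infilling ->
two-plane 3D reconstruction -> CEM43 accumulation over sonication plus
cooling -> per-sonication metrics (max unmasked dT, edge-annulus mean
dT, dose volume above 240 EM).

One *study* simulates a cohort of phantoms (a reference without marker
plus marker phantoms with variable absorption), runs reference and
on-marker sonications in each, derives the absorption correction from
the reference set, and compares each marker's metrics against the
reference phantom with Welch t-tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .dose import (
    DoseMap,
    SonicationMetrics,
    cem43,
    compare_groups,
    dose_volume,
    edge_mean_temperature,
    max_unmasked_temperature,
    reconstruct_3d,
)
from .errors import DegenerateInputError
from .geometry import marker_from_catalogue, marker_model_volume
from .masking import (
    estimate_noise_sigma,
    infill_masked,
    majority_mask,
    mask_frame,
    mask_report,
    temperature_std_map,
)
from .phantom import (
    PhantomSpec,
    calibrate_source,
    make_phantom_cohort,
    render_images,
    simulate_heating,
)
from .thermometry import (
    ImageSeries,
    absorption_correction,
    phase_to_temperature,
    temporal_average,
)

__all__ = ["SonicationAnalysis", "analyze_sonication", "run_study", "study_report_frames"]


@dataclass
class SonicationAnalysis:
    """Metrics plus the intermediate per-sonication artifacts."""

    metrics: SonicationMetrics
    per_frame_masked_counts: np.ndarray
    peak_dT_per_frame: np.ndarray
    times_s: np.ndarray
    dose_map: DoseMap
    extras: dict = field(default_factory=dict)


def _noise_sigma(images: ImageSeries, config: RunConfig) -> float:
    if config.masking.noise_sigma_estimate is not None:
        return config.masking.noise_sigma_estimate
    try:
        return estimate_noise_sigma(images.magnitudes[0])
    except DegenerateInputError:
        # noiseless rendering: vanishing sigma keeps every voxel unmasked
        return 1e-9


def analyze_sonication(
    images: dict[str, ImageSeries],
    config: RunConfig,
    correction: float = 1.0,
    phantom_id: str = "phantom",
    marker_name: str | None = None,
    sonication_index: int = 0,
) -> SonicationAnalysis:
    """Run the full processing chain on one rendered sonication."""
    protocol = config.protocol
    coronal, sagittal = images["coronal"], images["sagittal"]
    ref_idx = np.nonzero(coronal.times_s < protocol.pre_sonication_delay_s - 1e-9)[0]
    if ref_idx.size == 0:
        ref_idx = np.array([0])

    noise_sigma = _noise_sigma(coronal, config)
    alpha_eff = config.thermo.prf_coeff_ppm_per_C * correction

    tms = {
        p: phase_to_temperature(s, config.thermo, ref_idx, correction)
        for p, s in images.items()
    }

    # per-frame masks on the unaveraged coronal maps (2 degC rule)
    sigma_unavg = temperature_std_map(
        coronal.magnitudes, noise_sigma, coronal.acq, alpha_eff
    )
    masks_unavg = mask_frame(sigma_unavg, config.masking.sigma_threshold_C)
    counts = masks_unavg.reshape(masks_unavg.shape[0], -1).sum(axis=1)

    # x4 temporal averaging for the quantitative maps (1 degC rule)
    factor = config.thermo.temporal_average_factor
    avg_images = {p: temporal_average(s, factor) for p, s in images.items()}
    avg_tms = {p: temporal_average(t, factor) for p, t in tms.items()}
    noise_avg = noise_sigma / np.sqrt(factor)
    sigma_avg = {
        p: temperature_std_map(s.magnitudes, noise_avg, s.acq, alpha_eff)
        for p, s in avg_images.items()
    }
    masks_avg = {
        p: mask_frame(sig, config.masking.sigma_threshold_averaged_C)
        for p, sig in sigma_avg.items()
    }

    try:
        max_dT = max_unmasked_temperature(
            avg_tms["coronal"],
            sigma_avg["coronal"],
            config.masking.sigma_threshold_averaged_C,
        )
    except DegenerateInputError:
        max_dT = float("nan")

    # infill masked voxels before dose processing
    infilled = {}
    for p in ("coronal", "sagittal"):
        frames = avg_tms[p].dT.copy()
        for i in range(frames.shape[0]):
            m = masks_avg[p][i]
            if m.any() and not m.all():
                frames[i] = infill_masked(frames[i], m, config.masking.neighborhood)
        infilled[p] = frames

    end_idx = np.nonzero(avg_tms["coronal"].times_s <= protocol.sonication_end_s + 1e-9)[0]
    end_i = int(end_idx[-1]) if end_idx.size else infilled["coronal"].shape[0] - 1
    edge_dT = edge_mean_temperature(infilled["coronal"][end_i], config.scan_grid)

    # two-plane 3D reconstruction per frame, CEM43 accumulation
    frames3d = []
    for i in range(infilled["coronal"].shape[0]):
        T3, meta3d = reconstruct_3d(
            infilled["coronal"][i], infilled["sagittal"][i], config.scan_grid, config.dose
        )
        frames3d.append(T3)
    dose3d = cem43(np.stack(frames3d), avg_tms["coronal"].times_s, config.dose)
    dmap = DoseMap(
        values=dose3d,
        voxel_volume_mm3=config.scan_grid.in_plane_voxel_mm**3,
        meta={"reconstruction": meta3d["method"]},
    )
    vol_ml = dose_volume(dmap, config.dose.threshold_EM)

    marker = marker_from_catalogue(marker_name) if marker_name else None
    if marker is not None:
        report = mask_report(masks_unavg, config.scan_grid, marker)
        ratio = report.ratio_to_marker_volume
        growth = report.growth_factor
    else:
        ratio, growth = None, None
    maj_count = int(majority_mask(masks_unavg).sum())

    peak_per_frame = tms["coronal"].dT.reshape(counts.shape[0], -1).max(axis=1)
    metrics = SonicationMetrics(
        phantom_id=phantom_id,
        marker_name=marker_name,
        sonication_index=sonication_index,
        max_unmasked_dT_C=max_dT,
        edge_mean_dT_C=edge_dT,
        dose_volume_ml=vol_ml,
        masked_count=maj_count,
        masked_volume_mm3=maj_count * config.scan_grid.voxel_volume_mm3,
        ratio_to_marker_volume=ratio,
        growth_factor=growth,
    )
    return SonicationAnalysis(
        metrics=metrics,
        per_frame_masked_counts=counts,
        peak_dT_per_frame=peak_per_frame,
        times_s=coronal.times_s.copy(),
        dose_map=dmap,
        extras={"alpha_eff": alpha_eff, "noise_sigma": noise_sigma},
    )


def run_study(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Simulate and analyse a complete marker-compatibility study.

    Returns a report dict with per-sonication metrics, per-phantom
    correction coefficients and aggregates, and Welch-test comparisons
    of each marker phantom against the reference phantom.  Fully
    reproducible under ``config.study.seed``.
    """
    design = config.study
    markers = [None] + [marker_from_catalogue(name) for name in design.markers]
    cohort = make_phantom_cohort(
        len(markers), design.absorption_sd, design.seed, markers=markers
    )
    cohort[0] = replace(cohort[0], phantom_id="reference")

    scale = calibrate_source(
        design.target_peak_C,
        config.protocol,
        config.transducer,
        replace(cohort[0], absorption_factor=1.0),
        config.sim_grid,
        time_step_s=config.time_step_s,
        frame_interval_s=config.acq.frame_interval_s,
    )
    transducer = replace(config.transducer, source_scale=scale)

    rng = np.random.default_rng(design.seed)
    runs: dict[str, dict] = {}
    for phantom in cohort:
        field3d = simulate_heating(
            config.protocol,
            transducer,
            phantom,
            config.sim_grid,
            time_step_s=config.time_step_s,
            frame_interval_s=config.acq.frame_interval_s,
        )
        ref_images = [
            render_images(
                field3d, None, config.signal, config.acq, config.scan_grid,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                prf_coeff_ppm_per_C=config.thermo.prf_coeff_ppm_per_C,
            )
            for _ in range(design.n_reference)
        ]
        on_images = [
            render_images(
                field3d, phantom.marker, config.signal, config.acq, config.scan_grid,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                prf_coeff_ppm_per_C=config.thermo.prf_coeff_ppm_per_C,
            )
            for _ in range(design.n_on_marker)
        ]
        runs[phantom.phantom_id] = {
            "phantom": phantom,
            "ref_images": ref_images,
            "on_images": on_images,
        }

    # absorption correction from the reference sonications (uncorrected PRF)
    ref_tms = {}
    for pid, r in runs.items():
        series = []
        for imgs in r["ref_images"]:
            cor = imgs["coronal"]
            ref_idx = np.nonzero(cor.times_s < config.protocol.pre_sonication_delay_s - 1e-9)[0]
            tms = phase_to_temperature(cor, config.thermo, ref_idx)
            series.append(temporal_average(tms, config.thermo.temporal_average_factor))
        ref_tms[pid] = series
    corrections = absorption_correction(ref_tms, config.protocol.sonication_end_s)

    analyses: list[SonicationAnalysis] = []
    for pid, r in runs.items():
        c = corrections[pid].per_phantom_coefficient
        marker_name = r["phantom"].marker.name if r["phantom"].marker else None
        for i, imgs in enumerate(r["on_images"]):
            analyses.append(
                analyze_sonication(
                    imgs, config, correction=c, phantom_id=pid,
                    marker_name=marker_name, sonication_index=i,
                )
            )

    metrics_rows = [a.metrics.to_dict() for a in analyses]
    mdf = pd.DataFrame(metrics_rows)

    comparisons = []
    ref_vals = mdf[mdf["phantom_id"] == "reference"]
    for pid in mdf["phantom_id"].unique():
        if pid == "reference":
            continue
        for metric in ("max_unmasked_dT_C", "edge_mean_dT_C", "dose_volume_ml"):
            t, p, stars = compare_groups(
                mdf.loc[mdf["phantom_id"] == pid, metric],
                ref_vals[metric],
            )
            comparisons.append(
                {"phantom_id": pid, "metric": metric, "t": t, "p": p, "stars": stars}
            )

    report = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": design.seed,
        "source_scale": scale,
        "corrections": {
            pid: c.per_phantom_coefficient for pid, c in corrections.items()
        },
        "true_absorption": {p.phantom_id: p.absorption_factor for p in cohort},
        "metrics": metrics_rows,
        "comparisons": comparisons,
        "per_frame": {
            pid: {
                "masked_counts": np.mean(
                    [a.per_frame_masked_counts for a in analyses if a.metrics.phantom_id == pid],
                    axis=0,
                ).tolist(),
                "peak_dT": np.mean(
                    [a.peak_dT_per_frame for a in analyses if a.metrics.phantom_id == pid],
                    axis=0,
                ).tolist(),
            }
            for pid in mdf["phantom_id"].unique()
        },
    }
    if outdir is not None:
        _write_report(report, mdf, pd.DataFrame(comparisons), Path(outdir), config)
    return report


def study_report_frames(report: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metrics and comparison tables of a study report as DataFrames."""
    return pd.DataFrame(report["metrics"]), pd.DataFrame(report["comparisons"])


def _write_report(
    report: dict, mdf: pd.DataFrame, cdf: pd.DataFrame, outdir: Path, config: RunConfig
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {
        "package_version": report["package_version"],
        "config_hash": report["config_hash"],
        "seed": report["seed"],
    }
    for name, df in (("metrics.csv", mdf), ("comparisons.csv", cdf)):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# sonomark {stamp['package_version']} "
                     f"config={stamp['config_hash']} seed={stamp['seed']}\n")
            df.to_csv(fh, index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
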