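"""Shared fixtures: a miniature configuration for fast pipeline tests
and one session-scoped calibrated full-protocol heating field."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from sonomark.config import RunConfig
from sonomark.geometry import ScanGrid
from sonomark.phantom import (
    PhantomSpec,
    SimGrid3D,
    SonicationProtocol,
    calibrate_source,
    simulate_heating,
)


@pytest.fixture
def scan_grid() -> ScanGrid:
    return ScanGrid()


@pytest.fixture
def mini_config() -> RunConfig:
    """Short sonication on a 100 mm / 64-pixel grid: every pipeline
    stage exercised in well under a second per sonication."""
    base = RunConfig()
    return replace(
        base,
        protocol=SonicationProtocol(
            duration_s=10.0,
            pre_sonication_delay_s=4.0,
            post_observation_s=6.0,
            n_pattern_cycles=10,
        ),
        scan_grid=ScanGrid(fov_mm=99.84, n_rows=64, n_cols=64),
        study=replace(base.study, n_on_marker=2, n_reference=2),
    )


@pytest.fixture(scope="session")
def full_study_field():
    """Calibrated reference heating field under the full protocol
    (10 s delay + 30 s x 40 W sonication + 60 s cooling, 0.5 s frames,
    1.56 mm simulation grid on a 40 mm cube)."""
    cfg = RunConfig()
    phantom = PhantomSpec(phantom_id="reference")
    scale = calibrate_source(
        cfg.study.target_peak_C, cfg.protocol, cfg.transducer, phantom, cfg.sim_grid
    )
    transducer = replace(cfg.transducer, source_scale=scale)
    field = simulate_heating(cfg.protocol, transducer, phantom, cfg.sim_grid)
    return {"config": cfg, "field": field, "scale": scale, "phantom": phantom}
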