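"""Shared fixtures: simulated recordings reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from diffresp.config import load_preset
from diffresp.pipeline import run_pipeline
from diffresp.synthgen import BreathCycleSpec, ScenarioSpec, simulate_dual_imu


def periodic_cycles(period: float, ti: float, te: float, duration: float,
                    amplitude: float = 0.1) -> tuple[BreathCycleSpec, ...]:
    """Strictly periodic breath train filling ``duration``."""
    n = int(duration // period)
    return tuple(
        BreathCycleSpec(t_start=period * k, TI=ti, TE=te, amplitude=amplitude)
        for k in range(n)
    )


@pytest.fixture(scope="session")
def preset5():
    return load_preset(5)


@pytest.fixture(scope="session")
def seated_noiseless():
    """Noiseless seated recording: 20 BrPM, 10 analysis windows + slack."""
    spec = ScenarioSpec(
        condition="seated", duration=310.0, seed=3,
        cycles=periodic_cycles(3.0, 1.2, 1.8, 309.0),
        noise_sd=0.0, motion_amplitude=0.0, cardiac_amplitude=0.0,
    )
    front, back, truth = simulate_dual_imu(spec)
    return spec, front, back, truth


@pytest.fixture(scope="session")
def seated_noiseless_result(seated_noiseless, preset5):
    _, front, back, truth = seated_noiseless
    summaries, log = run_pipeline(front, back, preset5)
    return summaries, log, truth


@pytest.fixture(scope="session")
def walking_default():
    """Walking recording at full generator defaults, 20 windows + slack."""
    spec = ScenarioSpec(condition="walking", duration=615.0, seed=7)
    front, back, truth = simulate_dual_imu(spec)
    return spec, front, back, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
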