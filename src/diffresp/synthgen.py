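"""Seeded synthetic dual-IMU recordings with ground truth.

Stands in for the chest-band hardware: the front (chest) accelerometer
senses gravity, a breathing modulation on the chest-normal axis, a small
cardiac micro-artifact, whole-body motion and white noise; the back
(reference) accelerometer senses the same gravity and motion — up to a
configurable common-mode mismatch — but no breathing and no cardiac
component.  Both channels pass a 21 Hz low-pass (emulating the sensors'
integrated anti-alias filtering), are clipped to the ±2 g range, and are
emitted interleaved: each front sample at t is bracketed by back samples at
t ± 1/(2·fs), consecutive brackets being shared.

The breathing kernel is a raised-cosine bump with independent inhalation
(rise, duration TI) and exhalation (fall, duration TE) phases.  Gravity is
tilted by a torso pitch angle so that it has a component along the
chest-normal axis; the acceleration-magnitude signal then couples linearly
to the breathing modulation, |a| ≈ 1 g + b(t)·sin(pitch), as it does on a
seated or standing wearer whose trunk is not perfectly vertical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "BreathCycleSpec",
    "ScenarioSpec",
    "GroundTruth",
    "breathing_waveform",
    "breathing_cycles_from_rate",
    "walking_motion",
    "simulate_dual_imu",
    "write_scenario",
]

CONDITIONS = ("seated", "standing", "walking")

# default motion amplitudes per condition, g-units (postural sway vs gait)
_MOTION_DEFAULTS = {"seated": 0.010, "standing": 0.015, "walking": 0.080}

# default peak breathing modulation per condition, g-units; walking is
# deeper by ~1.5x (exercise hyperpnea raises tidal excursion)
_BREATH_DEFAULTS = {"seated": 0.10, "standing": 0.10, "walking": 0.15}


@dataclass(frozen=True)
class BreathCycleSpec:
    """One breath: inhalation of duration TI then exhalation of duration TE.

    ``amplitude`` is the peak chest-normal acceleration modulation in g.
    The exhalation onset is at ``t_start + TI``.
    """

    t_start: float
    TI: float
    TE: float
    amplitude: float
    plateau_fraction: float = 0.3
    recoil_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.TI <= 0 or self.TE <= 0:
            raise ValueError("TI and TE must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0.0 <= self.plateau_fraction < 1.0:
            raise ValueError("plateau_fraction must lie in [0, 1)")
        if not 0.0 < self.recoil_fraction <= 1.0:
            raise ValueError("recoil_fraction must lie in (0, 1]")

    @property
    def t_end(self) -> float:
        return self.t_start + self.TI + self.TE

    @property
    def exhalation_onset(self) -> float:
        return self.t_start + self.TI


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one synthetic recording scenario."""

    condition: str = "seated"
    duration: float = 330.0
    fs: float = 100.0
    seed: int = 0
    # breathing: explicit cycles, or generated from a rate
    cycles: tuple[BreathCycleSpec, ...] | None = None
    rate_brpm: float = 16.0
    rate_variability: float = 0.02     # fractional SD of cycle period
    ti_fraction: float = 0.4           # TI / (TI + TE)
    breathing_amplitude: float | None = None  # g; per-condition default if None
    # artifacts
    cardiac_amplitude: float = 0.003   # g
    cardiac_freq: float = 1.2          # Hz
    motion_amplitude: float | None = None  # g; per-condition default if None
    motion_mismatch: float = 0.05      # fraction of motion NOT common-mode
    step_freq: float = 1.8             # Hz, walking only
    noise_sd: float = 0.003            # g, per-axis white noise
    # geometry / sensor imperfections
    torso_pitch_deg: float = 15.0
    back_tilt_deg: float = 0.0         # misalignment rotation of back sensor
    back_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.motion_mismatch <= 1.0:
            raise ValueError("motion_mismatch must lie in [0, 1]")

    @property
    def motion_amp(self) -> float:
        if self.motion_amplitude is not None:
            return self.motion_amplitude
        return _MOTION_DEFAULTS[self.condition]

    @property
    def breath_amp(self) -> float:
        if self.breathing_amplitude is not None:
            return self.breathing_amplitude
        return _BREATH_DEFAULTS[self.condition]


@dataclass
class GroundTruth:
    """Per-cycle and per-window truth for parameter-recovery tests.

    Window k covers [k·Tw, (k+1)·Tw); its breath count is the number of
    cycle exhalation onsets inside it, and its TI/TE means average the
    cycles counted there.
    """

    cycles: list[BreathCycleSpec]
    tw: float
    window_counts: list[int]
    window_ti_mean: list[float | None]
    window_te_mean: list[float | None]
    short_recording: bool = False

    @classmethod
    def from_cycles(
        cls, cycles: list[BreathCycleSpec], duration: float, tw: float = 30.0
    ) -> "GroundTruth":
        n_windows = int(duration // tw)
        counts, ti_means, te_means = [], [], []
        for k in range(n_windows):
            lo, hi = k * tw, (k + 1) * tw
            inside = [c for c in cycles if lo <= c.exhalation_onset < hi]
            counts.append(len(inside))
            ti_means.append(float(np.mean([c.TI for c in inside])) if inside else None)
            te_means.append(float(np.mean([c.TE for c in inside])) if inside else None)
        return cls(
            cycles=list(cycles), tw=tw, window_counts=counts,
            window_ti_mean=ti_means, window_te_mean=te_means,
            short_recording=(n_windows == 0),
        )


def breathing_waveform(t: np.ndarray | float, cycle: BreathCycleSpec) -> np.ndarray | float:
    """Raised-cosine breathing kernel: 0 → amplitude over TI, back over TE.

    Inhalation: a raised-cosine rise over the first (1 − plateau_fraction)·TI
    followed by an end-inspiratory plateau at the peak amplitude (breath
    hold before the expiratory valve opens).  Exhalation: a raised-cosine
    fall over the first recoil_fraction·TE (elastic recoil of the chest
    wall, where expiratory flow concentrates), then an end-expiratory pause
    at baseline.  With complementary fractions
    (recoil_fraction = 1 − plateau_fraction, e.g. the plain bump
    plateau 0/recoil 1) the kernel is mirror-symmetric about t_start + TI
    whenever TI = TE.  Continuous at all phase boundaries; zero outside the
    cycle.
    """
    t_arr = np.asarray(t, dtype=float)
    rel = t_arr - cycle.t_start
    rise = (1.0 - cycle.plateau_fraction) * cycle.TI
    recoil = cycle.recoil_fraction * cycle.TE
    out = np.zeros_like(t_arr)
    rising = (rel >= 0) & (rel <= rise)
    plateau = (rel > rise) & (rel <= cycle.TI)
    falling = (rel > cycle.TI) & (rel <= cycle.TI + recoil)
    out = np.where(
        rising, 0.5 * cycle.amplitude * (1.0 - np.cos(np.pi * rel / rise)), out
    )
    out = np.where(plateau, cycle.amplitude, out)
    out = np.where(
        falling,
        0.5 * cycle.amplitude * (1.0 + np.cos(np.pi * (rel - cycle.TI) / recoil)),
        out,
    )
    return float(out) if np.isscalar(t) else out


def breathing_cycles_from_rate(
    rate_brpm: float,
    duration: float,
    amplitude: float,
    ti_fraction: float = 0.4,
    variability: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[BreathCycleSpec]:
    """Back-to-back breath cycles at a mean rate with optional jitter.

    Cycle periods are drawn as period·(1 + variability·z) with z standard
    normal (clipped at ±2.5 SD so periods stay positive and ordered);
    variability 0 gives a strictly periodic train.
    """
    if rate_brpm <= 0:
        raise ValueError("rate must be positive")
    if not 0 < ti_fraction < 1:
        raise ValueError("ti_fraction must lie in (0, 1)")
    period = 60.0 / rate_brpm
    if variability > 0 and rng is None:
        rng = np.random.default_rng(0)
    cycles: list[BreathCycleSpec] = []
    t = 0.0
    while True:
        p = period
        if variability > 0:
            z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
            p = period * max(1.0 + variability * z, 0.2)
        if t + p > duration:
            break
        cycles.append(
            BreathCycleSpec(
                t_start=t, TI=ti_fraction * p, TE=(1.0 - ti_fraction) * p,
                amplitude=amplitude,
            )
        )
        t += p
    return cycles


def _rotation_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def walking_motion(
    t: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray:
    """Gait acceleration (n, 3) in g: step-frequency harmonics + band noise.

    Vertical (y) axis carries the step fundamental and its second harmonic,
    the anterior-posterior (z) axis a weaker fundamental; a band-limited
    (0.8-4 Hz) noise floor models stride irregularity.  The same trace is
    applied to both sensors up to the configured mismatch.
    """
    amp = spec.motion_amp
    n = t.size
    if amp == 0.0:
        return np.zeros((n, 3))
    f = spec.step_freq
    phase = rng.uniform(0, 2 * np.pi, size=3)
    m = np.zeros((n, 3))
    m[:, 1] = amp * (
        np.sin(2 * np.pi * f * t + phase[0])
        + 0.4 * np.sin(2 * np.pi * 2 * f * t + phase[1])
    )
    m[:, 2] = 0.3 * amp * np.sin(2 * np.pi * f * t + phase[2])
    # stride-irregularity noise, band-limited to 0.8-4 Hz (band defined on
    # the actual grid spacing, which may be denser than the sensor rate)
    white = rng.standard_normal((n, 3)) * 0.15 * amp
    if n > 30:
        fs_grid = 1.0 / float(np.median(np.diff(t))) if n > 1 else spec.fs
        b, a = sps.butter(2, [0.8, 4.0], btype="bandpass", fs=fs_grid)
        white = sps.lfilter(b, a, white, axis=0)
    return m + white


def _postural_sway(
    t: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray:
    """Slow sway for seated/standing: low-frequency drift on y/z."""
    amp = spec.motion_amp
    n = t.size
    if amp == 0.0:
        return np.zeros((n, 3))
    f1, f2 = rng.uniform(0.05, 0.15), rng.uniform(0.2, 0.35)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    m = np.zeros((n, 3))
    m[:, 1] = 0.6 * amp * np.sin(2 * np.pi * f1 * t + phase[0])
    m[:, 2] = 0.4 * amp * np.sin(2 * np.pi * f2 * t + phase[1])
    return m


def simulate_dual_imu(
    spec: ScenarioSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one recording; returns (front, back, truth).

    Both DataFrames have columns ``t_s, ax_g, ay_g, az_g``.  Front samples
    lie at k/fs; back samples at (k − 1/2)/fs so that every front sample is
    bracketed.  Identical specs (same seed) give bit-identical output.
    """
    if spec.fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(spec.seed)
    fs, dur = spec.fs, spec.duration
    n_front = int(round(dur * fs))
    t_front = np.arange(n_front) / fs
    # back grid: (k - 1/2)/fs for k = 0 .. n_front  (brackets every front t)
    t_back = (np.arange(n_front + 1) - 0.5) / fs

    # breathing truth
    if spec.cycles is not None:
        cycles = list(spec.cycles)
        for a, b in zip(cycles, cycles[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValueError("breath cycles must be non-overlapping and ordered")
    else:
        cycles = breathing_cycles_from_rate(
            spec.rate_brpm, dur, spec.breath_amp,
            ti_fraction=spec.ti_fraction, variability=spec.rate_variability,
            rng=rng,
        )
    truth = GroundTruth.from_cycles(cycles, dur)
    if truth.short_recording:
        warnings.warn(
            "recording shorter than one 30 s analysis window", stacklevel=2
        )

    def breathing_series(t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t)
        for c in cycles:
            i0 = np.searchsorted(t, c.t_start)
            i1 = np.searchsorted(t, c.t_end, side="right")
            out[i0:i1] += breathing_waveform(t[i0:i1], c)
        return out

    # geometry: y = body-vertical projected, z = chest-normal; the torso
    # pitch tilts gravity into the chest-normal axis
    pitch = math.radians(spec.torso_pitch_deg)
    g_vec = np.array([0.0, math.cos(pitch), math.sin(pitch)])

    # motion common to both sensors (dense grid shared by both streams to
    # keep the common-mode component truly identical)
    t_all = np.union1d(t_front, t_back)
    if spec.condition == "walking":
        m_all = walking_motion(t_all, spec, rng)
    else:
        m_all = _postural_sway(t_all, spec, rng)
    idx_front = np.searchsorted(t_all, t_front)
    idx_back = np.searchsorted(t_all, t_back)
    m_front = m_all[idx_front]
    m_back = (1.0 - spec.motion_mismatch) * m_all[idx_back]

    # front channel: gravity + breathing + cardiac + motion + noise
    breath = breathing_series(t_front)
    cardiac = spec.cardiac_amplitude * np.sin(2 * np.pi * spec.cardiac_freq * t_front)
    front = np.tile(g_vec, (n_front, 1))
    front[:, 2] += breath + cardiac
    front += m_front
    front += rng.standard_normal(front.shape) * spec.noise_sd

    # back channel: gravity + (mismatched) motion + independent noise,
    # optionally seen through a misaligned / gain-imperfect sensor
    back_true = np.tile(g_vec, (t_back.size, 1)) + m_back
    if spec.back_tilt_deg != 0.0:
        back_true = back_true @ _rotation_x(spec.back_tilt_deg).T
    back = back_true * np.asarray(spec.back_gain, dtype=float)
    back += rng.standard_normal(back.shape) * spec.noise_sd

    # sensor-integrated 21 Hz anti-alias low-pass, then range clipping
    def sensor_filter(x: np.ndarray, fs_chan: float) -> np.ndarray:
        if fs_chan <= 2 * 21.0:
            return x
        b, a = sps.butter(2, 21.0, btype="low", fs=fs_chan)
        zi = sps.lfilter_zi(b, a)[:, None] * x[0][None, :]
        y, _ = sps.lfilter(b, a, x, axis=0, zi=zi)
        return y

    front = np.clip(sensor_filter(front, fs), -2.0, 2.0)
    back = np.clip(sensor_filter(back, fs), -2.0, 2.0)

    front_df = pd.DataFrame(
        {"t_s": t_front, "ax_g": front[:, 0], "ay_g": front[:, 1], "az_g": front[:, 2]}
    )
    back_df = pd.DataFrame(
        {"t_s": t_back, "ax_g": back[:, 0], "ay_g": back[:, 1], "az_g": back[:, 2]}
    )
    return front_df, back_df, truth


def write_scenario(
    spec: ScenarioSpec, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Simulate and write front/back sensor CSVs plus the ground-truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    front, back, truth = simulate_dual_imu(spec)
    f_front = outdir / "front.csv"
    f_back = outdir / "back.csv"
    f_truth = outdir / "truth.csv"
    front.to_csv(f_front, index=False, float_format="%.9g")
    back.to_csv(f_back, index=False, float_format="%.9g")
    pd.DataFrame(
        {
            "t_start_s": [c.t_start for c in truth.cycles],
            "TI_s": [c.TI for c in truth.cycles],
            "TE_s": [c.TE for c in truth.cycles],
            "amplitude_g": [c.amplitude for c in truth.cycles],
        }
    ).to_csv(f_truth, index=False, float_format="%.9g")
    return f_front, f_back, f_truth
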