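"""Breath events, cycle timing, per-window parameters, physiology formulas.

The label sequence from the dispersion detector is collapsed into breath
events (+1 run onset = inhalation, −1 run onset = exhalation).  Exhalation
events are debounced — an exhalation counts only if it falls more than a
minimum time after the previously accepted one — and drive the breath
counter NP.  Per cycle, inhalation duration TI = exhalation onset −
preceding inhalation onset and exhalation duration TE = inhalation onset −
preceding exhalation onset; candidates outside physiological plausibility
bounds are discarded.  At the end of each analysis window Tw the summary is

    RR     = NP · 60 / Tw                      [breaths/min]
    TI_med = TI_sum / TI_count                 [s]
    TE_med = TE_sum / TE_count                 [s]
    IER    = TI_med / TE_med                   [-]
    V      = Vt · 60 / TI_med                  [L/min]

with tidal volume Vt estimated from ideal body weight (Devine-style):
IBW = 50 + 0.91·(h_cm − 152.4) kg for men, 45.5 + 0.91·(h_cm − 152.4) for
women, and Vt = 7 mL/kg · IBW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, PipelineConfig

__all__ = [
    "INHALATION",
    "EXHALATION",
    "BreathEvent",
    "BreathTrackerState",
    "SubjectProfile",
    "WindowSummary",
    "collapse_runs",
    "debounce_exhalations",
    "update_cycle_times",
    "finalize_window",
    "track_breaths",
    "ideal_body_weight",
    "tidal_volume",
    "alignment_check",
]

INHALATION = +1
EXHALATION = -1


@dataclass(frozen=True)
class BreathEvent:
    """Onset of a detector run: +1 inhalation, −1 exhalation."""

    t: float
    kind: int  # INHALATION or EXHALATION

    def __post_init__(self) -> None:
        if self.kind not in (INHALATION, EXHALATION):
            raise ValueError(f"kind must be ±1, got {self.kind}")


@dataclass
class BreathTrackerState:
    """Running variables of the breath tracker.

    ``t1``/``t2`` hold the latest exhalation/inhalation onsets, the
    ``*_prev`` fields the ones from the previous cycle; ``peak_time_prev``
    is the last *accepted* exhalation time used by the debounce rule.  NP
    and the TI/TE accumulators are per-window and cleared when a window is
    finalized; the time markers persist so that debouncing and TI/TE
    pairing work across window boundaries.
    """

    start_time: float = 0.0
    t1: float = math.nan          # last exhalation onset
    t2: float = math.nan          # last inhalation onset
    t1_prev: float = math.nan
    t2_prev: float = math.nan
    peak_time_prev: float = math.nan
    NP: int = 0
    TI_sum: float = 0.0
    TE_sum: float = 0.0
    TI_count: int = 0
    TE_count: int = 0
    rejected_events: int = 0
    _last_event_t: float = field(default=-math.inf, repr=False)

    def reset_window(self, new_start: float) -> None:
        self.start_time = new_start
        self.NP = 0
        self.TI_sum = self.TE_sum = 0.0
        self.TI_count = self.TE_count = 0


@dataclass(frozen=True)
class SubjectProfile:
    """Subject anthropometrics used by the tidal-volume estimate."""

    sex: str           # "male" or "female"
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")

    @property
    def tidal_volume_liters(self) -> float:
        return tidal_volume(ideal_body_weight(self.height_cm, self.sex)) / 1000.0


@dataclass(frozen=True)
class WindowSummary:
    """Breathing parameters for one Tw window.

    Fields whose accumulators were empty are ``None`` (never silently 0);
    RR = 0 is meaningful and kept.
    """

    window_start: float
    tw: float
    NP: int
    RR: float
    TI_med: float | None
    TE_med: float | None
    IER: float | None
    V: float | None           # L/min
    Vt: float | None          # L


def collapse_runs(labels: np.ndarray, t: np.ndarray) -> list[BreathEvent]:
    """One event per maximal run of identical nonzero labels, at run onset."""
    labels = np.asarray(labels)
    t = np.asarray(t, dtype=float)
    if labels.shape != t.shape:
        raise ValueError("labels and t must be aligned")
    events: list[BreathEvent] = []
    prev = 0
    for lab, ti in zip(labels, t):
        if lab != 0 and lab != prev:
            events.append(BreathEvent(t=float(ti), kind=int(lab)))
        prev = int(lab)
    return events


def debounce_exhalations(
    events: list[BreathEvent], t_min: float
) -> tuple[list[BreathEvent], int]:
    """Drop exhalations closer than ``t_min`` to the last accepted one.

    Discarded exhalations do not move the reference time; inhalations pass
    through untouched.  Returns the kept events and the count NP of
    accepted exhalations.
    """
    kept: list[BreathEvent] = []
    np_count = 0
    last_accepted = -math.inf
    for ev in events:
        if ev.kind == EXHALATION:
            if ev.t - last_accepted > t_min:
                kept.append(ev)
                np_count += 1
                last_accepted = ev.t
        else:
            kept.append(ev)
    return kept, np_count


def update_cycle_times(
    state: BreathTrackerState,
    event: BreathEvent,
    ti_bounds: tuple[float, float],
    te_bounds: tuple[float, float],
) -> BreathTrackerState:
    """Feed one debounced event to the tracker, accumulating TI/TE.

    On an exhalation at t1 preceded by a fresh inhalation t2 (t2 > t1_prev)
    the candidate TI = t1 − t2; on an inhalation at t2 preceded by a fresh
    exhalation t1 the candidate TE = t2 − t1.  Candidates are accumulated
    only inside their plausibility bounds; the previous-cycle markers then
    advance.  Out-of-order events are rejected (counted, not raised).
    """
    if event.t < state._last_event_t:
        state.rejected_events += 1
        return state
    state._last_event_t = event.t

    if event.kind == EXHALATION:
        t1 = event.t
        t2 = state.t2
        if not math.isnan(t2) and (math.isnan(state.t1_prev) or t2 > state.t1_prev):
            ti = t1 - t2
            if ti_bounds[0] <= ti <= ti_bounds[1]:
                state.TI_sum += ti
                state.TI_count += 1
        state.t1_prev = state.t1 if not math.isnan(state.t1) else state.t1_prev
        state.t1 = t1
        state.peak_time_prev = t1
    else:
        t2 = event.t
        t1 = state.t1
        if not math.isnan(t1) and (math.isnan(state.t2_prev) or t1 > state.t2_prev):
            te = t2 - t1
            if te_bounds[0] <= te <= te_bounds[1]:
                state.TE_sum += te
                state.TE_count += 1
        state.t2_prev = state.t2 if not math.isnan(state.t2) else state.t2_prev
        state.t2 = t2
    return state


def finalize_window(
    state: BreathTrackerState, config: PipelineConfig, vt_liters: float | None
) -> WindowSummary:
    """Close the current Tw window, emit its summary, reset accumulators."""
    if config.tw <= 0:
        raise ConfigError("tw must be positive")
    tw = config.tw
    rr = state.NP * 60.0 / tw
    ti_med = state.TI_sum / state.TI_count if state.TI_count > 0 else None
    te_med = state.TE_sum / state.TE_count if state.TE_count > 0 else None
    ier = ti_med / te_med if (ti_med is not None and te_med is not None) else None
    v = (vt_liters * 60.0 / ti_med
         if (vt_liters is not None and ti_med is not None) else None)
    summary = WindowSummary(
        window_start=state.start_time, tw=tw, NP=state.NP, RR=rr,
        TI_med=ti_med, TE_med=te_med, IER=ier, V=v, Vt=vt_liters,
    )
    state.reset_window(state.start_time + tw)
    return summary


def track_breaths(
    events: list[BreathEvent],
    t_end: float,
    config: PipelineConfig,
    vt_liters: float | None = None,
    t_start: float = 0.0,
) -> tuple[list[WindowSummary], BreathTrackerState]:
    """Run the windowed breath tracker over a debounced event list.

    Windows are half-open [t_start + k·Tw, t_start + (k+1)·Tw); every
    window fully elapsed before ``t_end`` is summarized (a trailing partial
    window is not emitted).
    """
    state = BreathTrackerState(start_time=t_start)
    summaries: list[WindowSummary] = []
    idx = 0
    n = len(events)
    while state.start_time + config.tw <= t_end:
        w_end = state.start_time + config.tw
        while idx < n and events[idx].t < w_end:
            ev = events[idx]
            update_cycle_times(state, ev, config.ti_bounds, config.te_bounds)
            if ev.kind == EXHALATION:
                state.NP += 1
            idx += 1
        summaries.append(finalize_window(state, config, vt_liters))
    return summaries, state


def ideal_body_weight(height_cm: float, sex: str) -> float:
    """Devine-style ideal body weight in kg; clamped at 0 for tiny heights."""
    if height_cm <= 0:
        raise ValueError("height must be positive")
    if sex == "male":
        ibw = 50.0 + 0.91 * (height_cm - 152.4)
    elif sex == "female":
        ibw = 45.5 + 0.91 * (height_cm - 152.4)
    else:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if ibw < 0:
        import warnings

        warnings.warn(
            f"ideal body weight negative at height {height_cm} cm; clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return ibw


def tidal_volume(ibw_kg: float) -> float:
    """Tidal volume estimate in mL: 7 mL per kg of ideal body weight."""
    if ibw_kg < 0:
        raise ValueError("ideal body weight must be non-negative")
    return 7.0 * ibw_kg


def alignment_check(da_segment: np.ndarray, tol: float) -> bool:
    """Sensor-alignment test on a still, breath-held calibration segment.

    True iff mean(|Δa|) ≤ tol: with the two sensors well aligned and the
    body still, the differential magnitude stays proximal to zero.
    """
    da = np.asarray(da_segment, dtype=float)
    if da.size == 0:
        raise ValueError("empty calibration segment")
    return bool(np.mean(np.abs(da)) <= tol)
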