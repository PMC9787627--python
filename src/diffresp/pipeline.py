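"""End-to-end composition of the breathing pipeline, with a run log.

Mirrors the chest-band firmware loop: differential-signal construction →
causal low-pass → dispersion labelling → run collapse → exhalation
debounce → cycle timing → per-window summaries.  The composition is a pure
function of (streams, config, subject): identical inputs give identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import breath_params as bp
from . import signal_core as sc
from .config import PipelineConfig

__all__ = ["RunLog", "run_pipeline", "summaries_to_frame", "read_sensor_csv"]

SENSOR_COLUMNS = ["t_s", "ax_g", "ay_g", "az_g"]
SUMMARY_COLUMNS = [
    "window_start_s", "NP", "RR_brpm", "TI_med_s", "TE_med_s", "IER", "V_lpm",
]


@dataclass
class RunLog:
    """Machine-readable account of one pipeline run."""

    n_front_rows: int = 0
    n_back_rows: int = 0
    dropped_samples: int = 0
    skipped_rows: int = 0
    rejected_events: int = 0
    debounced_exhalations: int = 0
    undefined_windows: int = 0
    n_windows: int = 0
    config_hash: str = ""
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def read_sensor_csv(path: str | Path, sensor: str | None = None) -> tuple[pd.DataFrame, int]:
    """Read a sensor CSV; returns (frame, skipped-row count).

    Expects columns ``t_s, ax_g, ay_g, az_g``; a single-file dialect with a
    ``sensor`` column in {front, back} is accepted when ``sensor`` names
    which stream to extract.  Unparseable rows are skipped and counted.
    """
    df = pd.read_csv(path)
    if sensor is not None and "sensor" in df.columns:
        df = df[df["sensor"] == sensor]
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[SENSOR_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    skipped = int(bad.sum())
    df = df[~bad].reset_index(drop=True)
    return df, skipped


def run_pipeline(
    front: pd.DataFrame,
    back: pd.DataFrame,
    config: PipelineConfig,
    subject: bp.SubjectProfile | None = None,
    debug: bool = False,
):
    """Run the full breathing pipeline on two sensor streams.

    Returns ``(summaries, runlog)`` — or ``(summaries, runlog, debug_frame)``
    with the intermediate Δa/filtered/label series when ``debug`` is true.
    ``summaries`` is a list of :class:`~diffresp.breath_params.WindowSummary`.
    """
    log = RunLog(
        n_front_rows=len(front), n_back_rows=len(back),
        config_hash=config.config_hash(),
    )
    diff, dropped = sc.build_diff_signal(front, back, fs=config.fs)
    log.dropped_samples = dropped
    if len(diff) <= config.lag:
        raise ValueError(
            f"stream too short: {len(diff)} usable samples <= lag {config.lag}"
        )
    filt = sc.lowpass_filter(diff, config.fc, config.filter_order)
    labels = sc.dispersion_labels(filt, config.lag, config.threshold, config.influence)

    events = bp.collapse_runs(labels, filt.t)
    kept, _np_total = bp.debounce_exhalations(events, config.t_min_peak)
    log.debounced_exhalations = sum(
        1 for e in events if e.kind == bp.EXHALATION
    ) - _np_total

    vt = subject.tidal_volume_liters if subject is not None else None
    t_end = float(diff.t[-1]) + 1.0 / config.fs
    summaries, state = bp.track_breaths(kept, t_end, config, vt_liters=vt)
    log.rejected_events = state.rejected_events
    log.n_windows = len(summaries)
    log.undefined_windows = sum(1 for s in summaries if s.TI_med is None or s.TE_med is None)

    if debug:
        dbg = pd.DataFrame(
            {"t_s": diff.t, "da_g": diff.da, "da_filt_g": filt.da, "label": labels}
        )
        return summaries, log, dbg
    return summaries, log


def summaries_to_frame(summaries: list[bp.WindowSummary]) -> pd.DataFrame:
    """Window summaries as a DataFrame (undefined fields become NaN)."""
    return pd.DataFrame(
        {
            "window_start_s": [s.window_start for s in summaries],
            "NP": [s.NP for s in summaries],
            "RR_brpm": [s.RR for s in summaries],
            "TI_med_s": [np.nan if s.TI_med is None else s.TI_med for s in summaries],
            "TE_med_s": [np.nan if s.TE_med is None else s.TE_med for s in summaries],
            "IER": [np.nan if s.IER is None else s.IER for s in summaries],
            "V_lpm": [np.nan if s.V is None else s.V for s in summaries],
        }
    )
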