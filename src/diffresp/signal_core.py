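"""From two asynchronous accelerometer streams to breath labels.

The chest band reads the back (reference) sensor twice around every front
(chest) sensor read — back(t-Δ), front(t), back(t+Δ) — and estimates the
back reading at the front sample time as the mean of the two bracketing back
samples.  The breathing-carrying signal is the difference of the two
acceleration-vector magnitudes, Δa(t) = |a_front(t)| − |â_back(t)|: body
motion sensed identically by both sensors cancels, chest-wall motion does
not.  Δa is low-pass filtered with a causal Butterworth filter and fed to a
streaming smoothed z-score (dispersion) detector that labels each sample
+1 (above the moving band, inhalation), −1 (below, exhalation) or 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import ConfigError

__all__ = [
    "DiffSignal",
    "magnitude",
    "estimate_back_at_front",
    "build_diff_signal",
    "lowpass_filter",
    "dispersion_labels",
]


@dataclass
class DiffSignal:
    """Differential magnitude signal, one value per front sample."""

    t: np.ndarray        # seconds, strictly increasing
    da: np.ndarray       # g-units
    fs: float            # Hz (nominal front-sensor rate)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.da = np.asarray(self.da, dtype=float)
        if self.t.shape != self.da.shape:
            raise ValueError("t and da must have the same length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


def magnitude(v: np.ndarray) -> np.ndarray:
    """Euclidean norm of acceleration vectors (last axis), in g."""
    return np.linalg.norm(np.asarray(v, dtype=float), axis=-1)


def estimate_back_at_front(back_prev: np.ndarray, back_next: np.ndarray) -> np.ndarray:
    """Estimate the back-sensor vector at the front sample time.

    Component-wise mean of the two back samples bracketing the front read;
    exact for any component-wise linear acceleration when the brackets are
    symmetric in time.
    """
    return 0.5 * (np.asarray(back_prev, dtype=float) + np.asarray(back_next, dtype=float))


def build_diff_signal(
    front: pd.DataFrame,
    back: pd.DataFrame,
    fs: float | None = None,
) -> tuple[DiffSignal, int]:
    """Build Δa(t) = |a_front(t)| − |â_back(t)| from the two sensor streams.

    Parameters
    ----------
    front, back : DataFrame
        Columns ``t_s, ax_g, ay_g, az_g``; timestamps strictly increasing.
        Back samples are expected to bracket each front sample (interleaved
        acquisition back/front/back).
    fs : float, optional
        Nominal front sampling rate; inferred from the median timestamp
        spacing when omitted.

    Returns
    -------
    (DiffSignal, dropped)
        One Δa value per front sample that has a bracketing pair of back
        samples; ``dropped`` counts front samples discarded at the stream
        edges for lack of a bracket.
    """
    tf = front["t_s"].to_numpy(dtype=float)
    tb = back["t_s"].to_numpy(dtype=float)
    vf = front[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    vb = back[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    if tf.size == 0 or tb.size < 2:
        raise ValueError("need at least one front sample and two back samples")

    # index of the first back sample at or after each front sample
    nxt = np.searchsorted(tb, tf, side="left")
    prv = nxt - 1
    ok = (prv >= 0) & (nxt < tb.size)
    dropped = int(np.count_nonzero(~ok))

    back_est = estimate_back_at_front(vb[prv[ok]], vb[nxt[ok]])
    da = magnitude(vf[ok]) - magnitude(back_est)
    t = tf[ok]
    if fs is None:
        dt = np.median(np.diff(t)) if t.size > 1 else 1.0
        fs = 1.0 / dt
    return DiffSignal(t=t, da=da, fs=float(fs)), dropped


def lowpass_filter(x: DiffSignal, fc: float, order: int = 2) -> DiffSignal:
    """Causal Butterworth low-pass of the differential signal.

    Applied with a one-pass direct-form recursion (streaming-capable, no
    forward-backward smoothing), so the output carries the filter's phase
    delay exactly as the real-time firmware would.  Unit gain at DC.
    """
    if not 0 < fc < x.fs / 2:
        raise ConfigError(f"cut-off {fc} Hz must lie in (0, fs/2) = (0, {x.fs / 2})")
    if order < 1:
        raise ConfigError("filter order must be >= 1")
    b, a = sps.butter(order, fc, btype="low", fs=x.fs)
    # start at steady state for the first sample to avoid a spurious
    # startup transient in the first seconds of the recording
    zi = sps.lfilter_zi(b, a) * x.da[0]
    da, _ = sps.lfilter(b, a, x.da, zi=zi)
    return DiffSignal(t=x.t, da=da, fs=x.fs)


def dispersion_labels(
    x: DiffSignal | np.ndarray,
    lag: int,
    threshold: float,
    influence: float,
) -> np.ndarray:
    """Streaming smoothed z-score peak labels in {−1, 0, +1}.

    For each sample past the first ``lag``, the deviation of the raw value
    from the moving mean of the last ``lag`` *filtered* values is compared
    against ``threshold`` moving standard deviations (population form,
    divide by lag).  A flagged sample enters the filtered history damped by
    ``influence`` (influence·x + (1−influence)·previous filtered value); an
    unflagged sample enters raw.  The first ``lag`` samples seed the history
    raw and are labelled 0.  A zero moving SD degenerates to sign detection:
    any nonzero deviation is flagged.
    """
    y = x.da if isinstance(x, DiffSignal) else np.asarray(x, dtype=float)
    n = y.size
    if lag < 2:
        raise ConfigError("lag must be >= 2")
    if n <= lag:
        raise ValueError(f"need more than lag={lag} samples, got {n}")
    if not 0.0 <= influence <= 1.0:
        raise ConfigError("influence must lie in [0, 1]")
    if threshold <= 0:
        raise ConfigError("threshold must be positive")

    labels = np.zeros(n, dtype=np.int8)
    filt = y.copy()
    # running first/second moments of filt[i-lag:i]
    s1 = float(np.sum(filt[:lag]))
    s2 = float(np.sum(filt[:lag] ** 2))
    inv = 1.0 / lag
    for i in range(lag, n):
        mean = s1 * inv
        var = s2 * inv - mean * mean
        sd = np.sqrt(var) if var > 0.0 else 0.0
        dev = y[i] - mean
        # guard against flagging pure floating-point dust when sd ~ 0
        eps = 1e-12 * (1.0 + abs(mean))
        if abs(dev) > max(threshold * sd, eps):
            labels[i] = 1 if dev > 0 else -1
            filt[i] = influence * y[i] + (1.0 - influence) * filt[i - 1]
        else:
            labels[i] = 0
            filt[i] = y[i]
        # slide the window: drop filt[i-lag], add filt[i]
        out = filt[i - lag]
        s1 += filt[i] - out
        s2 += filt[i] * filt[i] - out * out
    return labels
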