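"""Method-agreement statistics: Pearson r, Bland–Altman, MAE%, % change.

These are the statistics used to characterize a breathing monitor against a
reference instrument (e.g., a spirometer): the product-moment correlation
between paired device/reference series, the Bland–Altman mean difference MD
and limits of agreement MD ± 1.96·SD (sample SD, n−1), the mean absolute
error relative to the reference in percent (plus an absolute-units
variant), and the percentage-change arithmetic used to compare two devices'
summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "pearson_r",
    "bland_altman",
    "mae_percent",
    "mae_abs",
    "percent_change",
    "agreement_report",
]


@dataclass(frozen=True)
class PairedSeries:
    """Paired device/reference measurements in the same units."""

    device: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "device", np.asarray(self.device, dtype=float))
        object.__setattr__(self, "reference", np.asarray(self.reference, dtype=float))
        if self.device.shape != self.reference.shape or self.device.ndim != 1:
            raise ValueError("device and reference must be 1-D and equal length")

    @property
    def n(self) -> int:
        return self.device.size


@dataclass(frozen=True)
class AgreementReport:
    """Agreement summary; undefined statistics are NaN."""

    r: float
    MD: float
    LoA_upper: float
    LoA_lower: float
    MAE_pct: float
    MAE_abs: float
    n: int

    def to_dict(self) -> dict:
        def _clean(v: float):
            return None if isinstance(v, float) and not math.isfinite(v) else v

        return {
            "r": _clean(self.r), "MD": _clean(self.MD),
            "LoA_upper": _clean(self.LoA_upper), "LoA_lower": _clean(self.LoA_lower),
            "MAE_pct": _clean(self.MAE_pct), "MAE_abs": _clean(self.MAE_abs),
            "n": self.n,
        }


def pearson_r(s: PairedSeries) -> float:
    """Product-moment correlation, computed in the classic sum form:

        r = [n·Σxy − Σx·Σy] / sqrt([n·Σx² − (Σx)²]·[n·Σy² − (Σy)²])

    NaN when either series has zero variance or n < 2.
    """
    x, y, n = s.device, s.reference, s.n
    if n < 2:
        return math.nan
    sx, sy = float(np.sum(x)), float(np.sum(y))
    sxy = float(np.sum(x * y))
    sx2, sy2 = float(np.sum(x * x)), float(np.sum(y * y))
    den2 = (n * sx2 - sx * sx) * (n * sy2 - sy * sy)
    if den2 <= 0:
        return math.nan
    return (n * sxy - sx * sy) / math.sqrt(den2)


def bland_altman(s: PairedSeries) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement.

    d = device − reference; MD = mean(d); LoA = MD ± 1.96·SD(d) with the
    sample standard deviation (n−1).  LoA are NaN for n < 2.
    """
    d = s.device - s.reference
    if d.size < 1:
        return math.nan, math.nan, math.nan
    md = float(np.mean(d))
    if d.size < 2:
        return md, math.nan, math.nan
    sd = float(np.std(d, ddof=1))
    return md, md + 1.96 * sd, md - 1.96 * sd


def mae_percent(s: PairedSeries) -> float:
    """Mean absolute error relative to the reference, in percent."""
    if np.any(s.reference == 0):
        raise ValueError("reference values must be nonzero for relative MAE")
    return float(np.mean(np.abs(s.device - s.reference) / s.reference) * 100.0)


def mae_abs(s: PairedSeries) -> float:
    """Mean absolute error in the series' own units."""
    return float(np.mean(np.abs(s.device - s.reference)))


def percent_change(new: float, old: float, use_magnitudes: bool = False) -> float:
    """(new − old)/old × 100; with ``use_magnitudes``, on absolute values.

    The magnitude form is what one uses to compare signed summary
    statistics (MD, lower LoA) between two devices, where "smaller" means
    smaller in magnitude.
    """
    if use_magnitudes:
        new, old = abs(new), abs(old)
    if old == 0:
        raise ValueError("old value must be nonzero")
    return (new - old) / old * 100.0


def agreement_report(device, reference) -> AgreementReport:
    """Full agreement summary for paired device/reference series."""
    s = PairedSeries(device=device, reference=reference)
    md, loa_up, loa_lo = bland_altman(s)
    return AgreementReport(
        r=pearson_r(s), MD=md, LoA_upper=loa_up, LoA_lower=loa_lo,
        MAE_pct=mae_percent(s), MAE_abs=mae_abs(s), n=s.n,
    )
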