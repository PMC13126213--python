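"""Confusion accounting along a screening trace and the performance metrics.

All metrics are functions of the trace prefix of length ``n`` screened
records.  With ``R`` relevant records in a screening set of ``N_s``:

* sensitivity (recall)      = TP / (TP + FN)
* screening cost   SC@s     = n*/N_s, where n* is the smallest depth at which
                              TP >= ceil(s * R)
* false-positive rate FPR@s = FP / (FP + TN) evaluated at the same depth n*
* RRF@p                     = sensitivity at depth floor(p * N_s)
* WSS@s                     = 1 - SC@s (work saved: the share of records not
                              needing screening at sensitivity s)

The threshold count is the *ceiling* ceil(s*R): at s = 0.95, 19 of 20 and
38 of 40 relevant records meet the level exactly.  Thresholds are computed
in exact rational arithmetic so 0.95 * 20 can never round to 20.
Values are stored as fractions in [0, 1]; the paper-style percentage is a
formatting concern (:func:`as_percent`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .simulate import ScreeningTrace


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN at a given screening depth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_screened(self) -> int:
        return self.tp + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricResult:
    metric_id: str  # sc | fpr | rrf | wss | sensitivity
    level: float    # the sensitivity level s or screened fraction p
    value: float    # fraction in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"metric value outside [0, 1]: {self.value}")


def as_percent(value: float, decimals: int = 2) -> float:
    """Render a fraction as a percentage rounded to ``decimals`` places."""
    return round(100.0 * value, decimals)


def _exact_fraction(x: float) -> Fraction:
    # levels like 0.95 are decimal in intent; snap away the binary expansion
    return Fraction(x).limit_denominator(10**6)


def required_tp(s: float, n_relevant: int) -> int:
    """ceil(s * R) in exact arithmetic — the TP count that meets level s."""
    return math.ceil(_exact_fraction(s) * n_relevant)


def confusion_at(trace: ScreeningTrace, n_screened: int) -> ConfusionCounts:
    """Confusion counts after the first ``n_screened`` trace positions."""
    n_s, r = trace.n_screened_total, trace.n_relevant
    if not 0 <= n_screened <= n_s:
        raise ValueError(f"n_screened must be in [0, {n_s}], got {n_screened}")
    tp = int(trace.labels[:n_screened].sum())
    fp = n_screened - tp
    return ConfusionCounts(tp=tp, fp=fp, fn=r - tp, tn=(n_s - r) - fp)


def sensitivity(counts: ConfusionCounts) -> float:
    """Recall: TP / (TP + FN).  Undefined when the set has no relevant records."""
    r = counts.tp + counts.fn
    if r < 1:
        raise ValueError("sensitivity undefined: no relevant records")
    return counts.tp / r


def _depth_at_sensitivity(trace: ScreeningTrace, s: float) -> int:
    r = trace.n_relevant
    if r < 1:
        raise ValueError("trace has no relevant records")
    if not 0.0 < s <= 1.0:
        raise ValueError(f"sensitivity level must be in (0, 1], got {s}")
    need = required_tp(s, r)
    cum = np.cumsum(trace.labels)
    hits = np.nonzero(cum >= need)[0]
    # the trace is exhaustive, so the threshold is always reached
    return int(hits[0]) + 1


def screening_cost_at_sensitivity(trace: ScreeningTrace, s: float = 0.95) -> MetricResult:
    """SC@s: fraction of the screening set screened when level s is reached."""
    n_star = _depth_at_sensitivity(trace, s)
    return MetricResult("sc", s, n_star / trace.n_screened_total)


def fpr_at_sensitivity(trace: ScreeningTrace, s: float = 0.95) -> MetricResult:
    """FPR@s: share of irrelevant records screened at the SC@s depth."""
    if trace.n_screened_total - trace.n_relevant < 1:
        raise ValueError("FPR undefined: no irrelevant records")
    n_star = _depth_at_sensitivity(trace, s)
    c = confusion_at(trace, n_star)
    return MetricResult("fpr", s, c.fp / (c.fp + c.tn))


def rrf_at(trace: ScreeningTrace, p: float = 0.10) -> MetricResult:
    """RRF@p: sensitivity after screening fraction p of the screening set."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"screened fraction must be in (0, 1], got {p}")
    depth = int(_exact_fraction(p) * trace.n_screened_total)  # floor
    c = confusion_at(trace, depth)
    return MetricResult("rrf", p, sensitivity(c))


def wss_at_sensitivity(trace: ScreeningTrace, s: float = 0.95) -> MetricResult:
    """WSS@s = 1 - SC@s: the share of records that never needed screening."""
    sc = screening_cost_at_sensitivity(trace, s)
    return MetricResult("wss", s, 1.0 - sc.value)


def metric_table(trace: ScreeningTrace, run_id: str = "",
                 s: float = 0.95, p: float = 0.10):
    """Tidy one-row-per-metric summary of a trace (as a DataFrame)."""
    import pandas as pd

    results = [
        screening_cost_at_sensitivity(trace, s),
        fpr_at_sensitivity(trace, s),
        wss_at_sensitivity(trace, s),
        rrf_at(trace, p),
    ]
    return pd.DataFrame(
        {
            "run_id": run_id,
            "metric_id": [m.metric_id for m in results],
            "level": [m.level for m in results],
            "value": [m.value for m in results],
        }
    )
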