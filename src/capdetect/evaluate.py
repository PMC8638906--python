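"""Event-level comparison of detected CAP A phases against a gold standard.

Matching is any-overlap on the 1-s grid, counted on the reference side: a
reference event is a true positive when at least ``min_overlap_s`` (default
1 s) of it is covered by some detected event — a single long detection may
validate several reference events — and a detected event overlapping no
reference event is a false positive.  From the TP/FN/FP counts the five
percentage metrics are derived:

    Sensitivity = TP/(TP+FN) x 100        FNR = FN/(FN+TP) x 100
    Precision   = TP/(TP+FP) x 100        FDR = FP/(FP+TP) x 100
    F1          = 2TP/(2TP+FP+FN) x 100
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .cap_sequences import CapParameters, build_sequences, cap_parameters
from .io import EventList, Hypnogram


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PerformanceMetrics:
    sensitivity_pct: float | None
    precision_pct: float | None
    fnr_pct: float | None
    fdr_pct: float | None
    f1_pct: float | None


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def match_events(detected: EventList, reference: EventList,
                 min_overlap_s: int = 1) -> ConfusionCounts:
    """TP/FN/FP by a sorted two-pointer sweep over both event lists."""
    det, ref = detected.events, reference.events
    ref_hit = [False] * len(ref)
    det_hit = [False] * len(det)
    i = j = 0
    while i < len(det) and j < len(ref):
        if _overlap(det[i], ref[j]) >= min_overlap_s:
            det_hit[i] = True
            ref_hit[j] = True
        # advance whichever interval ends first; ties advance both
        if det[i][1] <= ref[j][1]:
            i += 1
        else:
            j += 1
    tp = sum(ref_hit)
    return ConfusionCounts(tp=tp, fn=len(ref) - tp,
                           fp=len(det) - sum(det_hit))


def metrics(c: ConfusionCounts) -> PerformanceMetrics:
    """The five percentage metrics; undefined ratios are reported as None."""
    sens = fnr = prec = fdr = f1 = None
    if c.tp + c.fn > 0:
        sens = c.tp / (c.tp + c.fn) * 100.0
        fnr = c.fn / (c.fn + c.tp) * 100.0
    if c.tp + c.fp > 0:
        prec = c.tp / (c.tp + c.fp) * 100.0
        fdr = c.fp / (c.fp + c.tp) * 100.0
    if 2 * c.tp + c.fp + c.fn > 0:
        f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn) * 100.0
    return PerformanceMetrics(sensitivity_pct=sens, precision_pct=prec,
                              fnr_pct=fnr, fdr_pct=fdr, f1_pct=f1)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-distribution p-value.

    Returns ``(nan, nan)`` when either input has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))


def evaluate_run(detected_per_method: dict[str, EventList],
                 reference: EventList, hyp: Hypnogram,
                 min_overlap_s: int = 1) -> dict:
    """Per-method confusion counts, metrics, and CAP-parameter comparison."""
    ref_params = cap_parameters(build_sequences(reference, hyp), reference, hyp)
    report: dict = {
        "reference": {"n_events": len(reference),
                      "cap_parameters": _params_dict(ref_params)},
        "methods": {},
    }
    for name, det in detected_per_method.items():
        counts = match_events(det, reference, min_overlap_s)
        det_params = cap_parameters(build_sequences(det, hyp), det, hyp)
        deltas = {
            "n_a_events": det_params.n_a_events - ref_params.n_a_events,
            "mean_a_duration_s": _sub(det_params.mean_a_duration_s,
                                      ref_params.mean_a_duration_s),
            "cap_time_min": {k: det_params.cap_time_min[k] - ref_params.cap_time_min[k]
                             for k in det_params.cap_time_min},
            "cap_rate_pct": {k: _sub(det_params.cap_rate_pct[k],
                                     ref_params.cap_rate_pct[k])
                             for k in det_params.cap_rate_pct},
        }
        report["methods"][name] = {
            "counts": asdict(counts),
            "metrics": asdict(metrics(counts)),
            "cap_parameters": _params_dict(det_params),
            "delta_vs_reference": deltas,
        }
    return report


def _params_dict(p: CapParameters) -> dict:
    return {
        "cap_time_min": dict(p.cap_time_min),
        "cap_rate_pct": dict(p.cap_rate_pct),
        "n_a_events": p.n_a_events,
        "mean_a_duration_s": p.mean_a_duration_s,
    }


def _sub(a, b):
    if a is None or b is None:
        return None
    return a - b
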