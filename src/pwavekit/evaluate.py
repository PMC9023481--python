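"""Beat-level matching of detected vs reference peaks, and Se/PP scoring.

A detected peak is a true positive when it pairs one-to-one with a reference
peak within a time tolerance.  Matching walks both sorted sequences in time
order and pairs the current detected and reference peaks whenever they are
within tolerance, advancing past whichever lies further left otherwise; on a
line this greedy achieves the maximum possible number of pairs (it is
checked against a brute-force bipartite-matching oracle in the test suite).

Sensitivity Se = 100·TP/(TP+FN) and positive predictivity PP =
100·TP/(TP+FP) are computed per record and then averaged unweighted across
records (the headline figure), with a pooled micro-average alongside.
Records with no reference peaks and no detections have undefined Se/PP and
are excluded from the averages.

The matching tolerance is not part of the published method; the package
default is 100 ms (tighter than one P-wave width), configurable everywhere
it appears.  This is the main caveat when comparing scores across studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import WaveAnnotations

__all__ = ["EvalResult", "match", "score"]


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    se: float            # percent; NaN when undefined
    pp: float            # percent; NaN when undefined
    tolerance: float     # seconds
    per_record: dict = field(default_factory=dict)
    se_pooled: float = math.nan
    pp_pooled: float = math.nan

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "se_mean": self.se, "pp_mean": self.pp,
            "se_pooled": self.se_pooled, "pp_pooled": self.pp_pooled,
            "tolerance_s": self.tolerance,
            "per_record": {
                k: dict(zip(("tp", "fp", "fn", "se", "pp"), v))
                for k, v in self.per_record.items()
            },
        }


def _peaks(a) -> np.ndarray:
    if isinstance(a, WaveAnnotations):
        a = a.p_peaks
    return np.asarray(a, dtype=np.int64)


def match(
    detected, reference, tolerance: float, fs: float
) -> tuple[int, int, int]:
    """Count (tp, fp, fn) between two sorted index sequences.

    ``detected`` and ``reference`` are sample-index arrays or
    :class:`WaveAnnotations` (whose ``p_peaks`` are used);
    ``tolerance`` is in seconds, converted with ``fs``.
    """
    det = _peaks(detected)
    ref = _peaks(reference)
    tol = tolerance * fs
    i = j = tp = 0
    while i < len(det) and j < len(ref):
        d = det[i] - ref[j]
        if abs(d) <= tol:
            tp += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    fp = len(det) - tp
    fn = len(ref) - tp
    return tp, fp, fn


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def score(
    matches: Mapping[str, tuple[int, int, int]],
    tolerance: float = 0.100,
) -> EvalResult:
    """Aggregate per-record (tp, fp, fn) counts into Se/PP statistics.

    The headline ``se``/``pp`` are unweighted means of the per-record values
    (undefined records excluded); ``se_pooled``/``pp_pooled`` pool the raw
    counts across records.
    """
    per_record = {}
    ses, pps = [], []
    TP = FP = FN = 0
    for rid, (tp, fp, fn) in matches.items():
        se = _rate(tp, tp + fn)
        pp = _rate(tp, tp + fp)
        per_record[rid] = (tp, fp, fn, se, pp)
        if not math.isnan(se):
            ses.append(se)
        if not math.isnan(pp):
            pps.append(pp)
        TP += tp
        FP += fp
        FN += fn
    return EvalResult(
        tp=TP, fp=FP, fn=FN,
        se=float(np.mean(ses)) if ses else math.nan,
        pp=float(np.mean(pps)) if pps else math.nan,
        tolerance=tolerance,
        per_record=per_record,
        se_pooled=_rate(TP, TP + FN),
        pp_pooled=_rate(TP, TP + FP),
    )
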