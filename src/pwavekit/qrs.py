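"""R-peak detection on the phasor-transformed band-passed ECG.

Candidate peaks are the maxima of the phase signal in consecutive 300 ms
windows.  A candidate is kept when it exceeds an adaptive threshold of twice
the standard deviation computed in a centred 2 s moving window; duplicates
closer than a 200 ms refractory distance are merged to the larger peak.
Finally a backward search re-scans any RR interval more than 1.75 times
longer than its predecessor for peaks above 30% of the last accepted QRS
amplitude, recovering beats the threshold missed.

Because the phasor transform is strictly monotone, the candidate maxima are
identical whether taken on the phase signal or on the band-passed signal
itself; the amplitude comparisons (adaptive threshold, 30% backward-search
threshold) are made on the band-passed scale, where the standard deviation
is a meaningful, scale-free measure (see docs/methods.md on why the clipped
phase scale cannot carry them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DetectorConfig
from .phasor import phasor_transform
from .preprocess import FilteredSignal
from .util import round_half_even

__all__ = ["BeatSet", "detect_qrs", "backward_search"]


@dataclass
class BeatSet:
    """Detected beats with per-beat rhythm flags and wave positions.

    ``t_peaks`` / ``p_peaks`` hold sample indices with −1 meaning
    "not assigned".  All arrays are kept the same length as ``r_peaks``.
    """

    r_peaks: np.ndarray
    fs: float
    pvc: np.ndarray = field(default=None)
    afib: np.ndarray = field(default=None)
    t_peaks: np.ndarray = field(default=None)
    p_peaks: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.r_peaks.size and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        n = len(self.r_peaks)
        if self.pvc is None:
            self.pvc = np.zeros(n, dtype=bool)
        if self.afib is None:
            self.afib = np.zeros(n, dtype=bool)
        if self.t_peaks is None:
            self.t_peaks = np.full(n, -1, dtype=np.int64)
        if self.p_peaks is None:
            self.p_peaks = np.full(n, -1, dtype=np.int64)
        for name in ("pvc", "afib", "t_peaks", "p_peaks"):
            a = np.asarray(getattr(self, name))
            if len(a) != n:
                raise ValueError(f"{name} must have one entry per beat")
            setattr(self, name, a)

    def __len__(self) -> int:
        return len(self.r_peaks)

    @property
    def rr(self) -> np.ndarray:
        """RR intervals in seconds; rr[k] is the interval ending at beat k+1."""
        return np.diff(self.r_peaks) / self.fs

    def with_r_peaks(self, r_peaks: np.ndarray) -> "BeatSet":
        """A fresh BeatSet on new R positions (flags reset)."""
        return BeatSet(np.asarray(r_peaks, dtype=np.int64), self.fs)


def _moving_std(x: np.ndarray, win: int) -> np.ndarray:
    """Population std over a centred window of ``win`` samples, edge-clipped."""
    n = len(x)
    half = win // 2
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    cnt = hi - lo
    mean = (c1[hi] - c1[lo]) / cnt
    var = (c2[hi] - c2[lo]) / cnt - mean * mean
    return np.sqrt(np.maximum(var, 0.0))


def detect_qrs(sig: FilteredSignal, cfg: DetectorConfig | None = None) -> BeatSet:
    """Detect R peaks on the band-passed signal.

    Parameters
    ----------
    sig : FilteredSignal of kind ``qrs_band`` (output of
        :func:`pwavekit.preprocess.bandpass_qrs`), at least 2 s long.
    """
    cfg = cfg or DetectorConfig()
    x = sig.samples
    fs = sig.fs
    if len(x) < 2 * fs:
        raise ValueError("signal shorter than 2 s; QRS detection refused")
    pt = phasor_transform(x, cfg.rv_qrs)

    win = max(1, round_half_even(cfg.slide_window * fs))
    nwin = len(x) // win
    starts = np.arange(nwin) * win
    # argmax of the phase signal per non-overlapping window
    cand = np.array(
        [s + int(np.argmax(pt[s : s + win])) for s in starts], dtype=np.int64
    )
    tail = nwin * win
    if tail < len(x):
        cand = np.append(cand, tail + int(np.argmax(pt[tail:])))

    thr = cfg.std_factor * _moving_std(x, round_half_even(cfg.std_window * fs))
    cand = cand[x[cand] > thr[cand]]

    # refractory merge: collapse candidates closer than 200 ms to the larger
    refr = round_half_even(cfg.refractory * fs)
    kept: list[int] = []
    for c in cand:
        if kept and c - kept[-1] < refr:
            if x[c] > x[kept[-1]]:
                kept[-1] = int(c)
        else:
            kept.append(int(c))
    beats = BeatSet(np.array(kept, dtype=np.int64), fs)
    return backward_search(beats, sig, cfg)


def backward_search(
    beats: BeatSet, sig: FilteredSignal, cfg: DetectorConfig | None = None
) -> BeatSet:
    """Recover missed beats inside anomalously long RR intervals.

    For every interval more than ``rr_gap_factor`` (1.75) times longer than
    its predecessor, the open interval between the flanking R peaks (minus
    the refractory margins) is re-scanned; its maximum is inserted as a beat
    when it exceeds ``back_thresh`` (30%) of the amplitude of the last
    detected QRS before the gap.  The scan repeats until no interval changes,
    so the operation is idempotent.
    """
    cfg = cfg or DetectorConfig()
    x = sig.samples
    refr = round_half_even(cfg.refractory * sig.fs)
    r = list(int(v) for v in beats.r_peaks)
    changed = True
    while changed:
        changed = False
        k = 2
        while k < len(r):
            rr_prev = r[k - 1] - r[k - 2]
            rr_cur = r[k] - r[k - 1]
            if rr_cur > cfg.rr_gap_factor * rr_prev:
                lo, hi = r[k - 1] + refr, r[k] - refr
                if hi > lo:
                    seg = x[lo:hi]
                    j = lo + int(np.argmax(seg))
                    if x[j] > cfg.back_thresh * x[r[k - 1]]:
                        r.insert(k, j)
                        changed = True
                        continue  # re-examine the split interval
            k += 1
    return BeatSet(np.array(sorted(set(r)), dtype=np.int64), beats.fs)
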