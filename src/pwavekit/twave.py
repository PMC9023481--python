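"""T-peak localization per beat.

The search window for beat i spans R(i) + 0.12·RR(i) to
R(i) + 0.57·RR(i) + 60 ms, where RR(i) is the interval *following* R(i)
(the preceding interval substitutes for the final beat).  Inside the window
the maximum of the phase signal (R_V = 0.1) of the cleaned ECG marks the
T peak.  The signed phase maximum is used as published, so deeply inverted
T waves are a known limitation.  Ties break to the earliest sample.
"""

from __future__ import annotations

import numpy as np

from .config import DetectorConfig
from .io import EcgRecord
from .phasor import phasor_transform
from .preprocess import FilteredSignal, clean
from .qrs import BeatSet
from .util import round_half_even

__all__ = ["t_search_window", "detect_t"]


def t_search_window(
    beats: BeatSet, i: int, fs: float, n_samples: int,
    cfg: DetectorConfig | None = None,
) -> tuple[int, int] | None:
    """Closed sample interval to search for T of beat ``i``, or None.

    Returns None when the window is empty after clipping to the signal
    bounds (degenerate RR); the beat then has no T assigned.
    """
    cfg = cfg or DetectorConfig()
    r = int(beats.r_peaks[i])
    n = len(beats)
    if n >= 2:
        if i < n - 1:
            rr = int(beats.r_peaks[i + 1]) - r
        else:  # last beat: previous RR stands in
            rr = r - int(beats.r_peaks[i - 1])
    else:
        return None
    c0, c1, c2 = cfg.t_win
    a = r + round_half_even(c0 * rr)
    b = r + round_half_even(c1 * rr + c2 * fs)
    a, b = max(a, 0), min(b, n_samples - 1)
    if a > b or rr <= 0:
        return None
    return a, b


def detect_t(
    rec: EcgRecord | FilteredSignal, beats: BeatSet,
    cfg: DetectorConfig | None = None,
) -> BeatSet:
    """Assign a T peak to every beat whose search window is non-empty.

    Accepts either a raw record (cleaned internally) or an already-cleaned
    FilteredSignal.  T is always assigned when the window is non-empty, even
    over pure baseline — downstream rules, not this stage, judge plausibility.
    """
    cfg = cfg or DetectorConfig()
    sig = clean(rec, cfg) if isinstance(rec, EcgRecord) else rec
    x = sig.samples
    t_peaks = np.full(len(beats), -1, dtype=np.int64)
    for i in range(len(beats)):
        w = t_search_window(beats, i, sig.fs, len(x), cfg)
        if w is None:
            continue
        a, b = w
        seg = phasor_transform(x[a : b + 1], cfg.rv_t)
        t_peaks[i] = a + int(np.argmax(seg))
    return BeatSet(beats.r_peaks, beats.fs, pvc=beats.pvc, afib=beats.afib,
                   t_peaks=t_peaks, p_peaks=beats.p_peaks)
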