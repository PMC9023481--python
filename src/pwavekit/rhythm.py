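"""Per-beat rhythm context: PVC and AFIB flags and the pathology gate.

PVC flagging uses a single morphological feature, the area under the QRS
(AUC) over R(i) ± 150 ms of the baseline-free signal.  A beat is a PVC
candidate when its area exceeds 1.3 times the running median area of the
previously accepted (non-PVC) beats; if more than 75% of all beats end up
flagged, the flags are interpreted as a bundle-branch-block morphology and
cleared wholesale.

AFIB flagging characterizes RR irregularity through symbolic dynamics: the
per-beat heart rate is quantized into 5 bpm symbols, consecutive symbol
triplets form words, and the Shannon entropy of the word distribution over a
59-beat segment centred on the current beat (normalized to [0, 1] by ln 59)
is thresholded at 0.737.  Runs of PVCs perturb RR enough to mimic AFIB, so a
segment containing more than 30 PVC-flagged beats suppresses the AFIB flag.

The pathology check then gates the P-wave search: AFIB beats skip it
entirely, PVC beats skip the search before their QRS, and unflagged beats
proceed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .config import DetectorConfig
from .io import EcgRecord
from .preprocess import FilteredSignal, highpass_lynn
from .qrs import BeatSet
from .util import round_half_even

__all__ = [
    "AucSeries",
    "EntropySeries",
    "compute_auc",
    "detect_pvc",
    "make_auc_series",
    "symbolic_entropy",
    "word_entropy",
    "detect_afib",
    "pathology_check",
]


@dataclass
class AucSeries:
    """Per-beat QRS area (mV·s) and the running median it is judged against.

    ``running_median[i]`` is computed only from beats before ``i`` (NaN for
    the first beat, which therefore can never be flagged).
    """

    auc: np.ndarray
    running_median: np.ndarray

    def __post_init__(self) -> None:
        self.auc = np.asarray(self.auc, dtype=float)
        if np.any(self.auc < 0):
            raise ValueError("QRS areas must be non-negative")


@dataclass
class EntropySeries:
    hr: np.ndarray        # beats/min; NaN where no preceding RR exists
    symbols: np.ndarray   # int; -1 undefined
    words: np.ndarray     # int word codes; -1 undefined
    sh: np.ndarray        # normalized Shannon entropy in [0, 1]; NaN undefined


def compute_auc(
    rec: EcgRecord | FilteredSignal, beats: BeatSet,
    cfg: DetectorConfig | None = None,
) -> AucSeries:
    """Absolute area under each beat over R ± 150 ms of the baseline-free ECG.

    auc(i) = Σ |x̃(n)| / fs over the window, x̃ the Lynn-high-passed signal;
    windows are clipped at the record edges.  Absolute area is
    polarity-agnostic, which matches the PVC-is-bigger decision rule.
    """
    cfg = cfg or DetectorConfig()
    if isinstance(rec, EcgRecord):
        sig = highpass_lynn(rec, cfg)
    else:
        sig = rec
    x = np.abs(sig.samples)
    w = round_half_even(cfg.pvc_win * sig.fs)
    auc = np.empty(len(beats))
    for i, r in enumerate(beats.r_peaks):
        lo, hi = max(int(r) - w, 0), min(int(r) + w, len(x) - 1)
        auc[i] = x[lo : hi + 1].sum() / sig.fs
    med = _running_median_unflagged(auc, cfg.pvc_factor)
    return AucSeries(auc=auc, running_median=med)


def _running_median_unflagged(auc: np.ndarray, factor: float) -> np.ndarray:
    """Running median over previously *unflagged* beats, and NaN for beat 0.

    The median tracks the normal-beat population: beats whose area already
    tripped the PVC rule do not enter it, which keeps the reference stable
    through long ectopic runs (and makes the >75% bundle-branch-block
    override reachable at all).
    """
    n = len(auc)
    med = np.full(n, np.nan)
    normal: list[float] = []
    for i in range(n):
        if normal:
            m = len(normal)
            med[i] = (
                normal[m // 2]
                if m % 2
                else 0.5 * (normal[m // 2 - 1] + normal[m // 2])
            )
        flagged = normal and auc[i] > factor * med[i]
        if i == 0 or not flagged:
            bisect.insort(normal, float(auc[i]))
    return med


def make_auc_series(values, cfg: DetectorConfig | None = None) -> AucSeries:
    """Build an :class:`AucSeries` from bare area values (mainly for tests)."""
    cfg = cfg or DetectorConfig()
    values = np.asarray(values, dtype=float)
    return AucSeries(values, _running_median_unflagged(values, cfg.pvc_factor))


def detect_pvc(auc: AucSeries, cfg: DetectorConfig | None = None) -> np.ndarray:
    """Per-beat PVC flags from the area series.

    pvc(i) = auc(i) > 1.3 × running median; the first beat is never flagged.
    If the flagged fraction exceeds ``pvc_reset_frac`` (strictly more than
    75% of all beats) every flag is cleared: morphology that uniform is read
    as bundle branch block, not ectopy.
    """
    cfg = cfg or DetectorConfig()
    with np.errstate(invalid="ignore"):
        flags = auc.auc > cfg.pvc_factor * auc.running_median
    flags &= ~np.isnan(auc.running_median)
    if len(flags) and flags.mean() > cfg.pvc_reset_frac:
        flags = np.zeros_like(flags)
    return flags


def symbolic_entropy(
    beats: BeatSet, cfg: DetectorConfig | None = None
) -> EntropySeries:
    """Symbolic-dynamics word entropy of the heart-rate sequence.

    hr(i) = 60/RR(i) with RR(i) the interval ending at beat i (undefined for
    beat 0); symbols are fixed 5 bpm bins of hr clipped to [0, 315]; the word
    at beat i encodes the symbol triplet (Sy(i), Sy(i+1), Sy(i+2)) in base
    64.  sh(i) is the Shannon entropy of the empirical word distribution over
    wv(i−29 .. i+29), divided by ln 59 so that 59 all-distinct words give
    exactly 1.  Beats whose 59-word segment would leave the record keep
    sh = NaN and can never be flagged as AFIB.
    """
    cfg = cfg or DetectorConfig()
    n = len(beats)
    hr = np.full(n, np.nan)
    if n >= 2:
        hr[1:] = 60.0 / beats.rr
    nsym = int(cfg.hr_max / cfg.hr_bin) + 1
    symbols = np.full(n, -1, dtype=np.int64)
    valid = ~np.isnan(hr)
    symbols[valid] = np.minimum(
        np.floor(np.clip(hr[valid], 0, cfg.hr_max) / cfg.hr_bin), nsym - 1
    ).astype(np.int64)

    words = np.full(n, -1, dtype=np.int64)
    for i in range(n - 2):
        s = symbols[i : i + 3]
        if np.all(s >= 0):
            words[i] = (s[0] * nsym + s[1]) * nsym + s[2]

    half = cfg.sh_window // 2
    sh = np.full(n, np.nan)
    for i in range(n):
        lo, hi = i - half, i + half
        if lo < 0 or hi >= n:
            continue
        seg = words[lo : hi + 1]
        if np.any(seg < 0):
            continue
        sh[i] = word_entropy(seg, cfg.sh_window)
    return EntropySeries(hr=hr, symbols=symbols, words=words, sh=sh)


def word_entropy(words: np.ndarray, norm_count: int | None = None) -> float:
    """Normalized Shannon entropy of a word segment's empirical distribution.

    −Σ p_k·ln p_k over the word counts, divided by ln(norm_count) (the
    segment length by default) so a segment of all-distinct words scores
    exactly 1 and a constant segment 0.  Depends only on the multiset of
    words, not their order.
    """
    words = np.asarray(words)
    if norm_count is None:
        norm_count = len(words)
    if norm_count < 2:
        return 0.0
    _, counts = np.unique(words, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(norm_count))


def detect_afib(
    ent: EntropySeries,
    pvc_flags: np.ndarray,
    cfg: DetectorConfig | None = None,
) -> np.ndarray:
    """AFIB flags: sh above threshold, unless PVCs explain the irregularity.

    afib(i) = sh(i) > 0.737, suppressed when more than 30 of the 59 beats in
    the same segment are PVC-flagged.
    """
    cfg = cfg or DetectorConfig()
    pvc_flags = np.asarray(pvc_flags, dtype=bool)
    n = len(ent.sh)
    half = cfg.sh_window // 2
    with np.errstate(invalid="ignore"):
        flags = ent.sh > cfg.sh_thresh
    flags = np.where(np.isnan(ent.sh), False, flags)
    if flags.any():
        c = np.concatenate([[0], np.cumsum(pvc_flags.astype(np.int64))])
        for i in np.nonzero(flags)[0]:
            lo, hi = max(i - half, 0), min(i + half + 1, n)
            if c[hi] - c[lo] > cfg.sh_pvc_override:
                flags[i] = False
    return flags


def pathology_check(beats: BeatSet, i: int) -> str:
    """Gate for the P-wave search of beat ``i``.

    Returns ``"skip_afib"`` (no P search at all), ``"skip_pvc"`` (no P
    search before this QRS) or ``"proceed"``.  AFIB is checked first.
    """
    if beats.afib[i]:
        return "skip_afib"
    if beats.pvc[i]:
        return "skip_pvc"
    return "proceed"
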