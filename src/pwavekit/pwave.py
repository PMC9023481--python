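"""Normal and dissociated P-wave detection and candidate verification.

For each beat that passes the pathology gate, the conducted-P candidate is
the phase-signal maximum (R_V = 0.05) of the cleaned ECG inside

    R(i−1) + 0.71·RR(i)  ..  R(i) − 0.07·RR(i) − 60 ms

(with RR(i) the interval ending at R(i); the first beat uses the fixed
window R − 300 ms .. R − 80 ms).  Dissociated P waves — atrial activations
without a conducted QRS, the hallmark of second-degree AV block — are
searched inside anomalously long RR intervals that pass a small rule set,
in the segment T(i−1) + 200 ms .. P(i) − 400 ms.

Every candidate then faces two verification criteria, in order:

1. voltage: |U_P| > 0.05 · |U_QRS| of the current beat, both read off the
   cleaned signal (rules out nodal/idioventricular beats without atrial
   activity);
2. position: the candidate must lie after the previous T peak (otherwise it
   is that T wave, not a P).

Rejected candidates are retained with their rejection reason so every
decision of the rule set is auditable; only accepted candidates become
annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import DetectorConfig
from .io import EcgRecord, WaveAnnotations
from .phasor import phasor_transform
from .preprocess import FilteredSignal, bandpass_qrs, clean, highpass_lynn
from .qrs import BeatSet, detect_qrs
from .rhythm import (
    AucSeries,
    EntropySeries,
    compute_auc,
    detect_afib,
    detect_pvc,
    pathology_check,
    symbolic_entropy,
)
from .twave import detect_t
from .util import round_half_even

__all__ = [
    "PCandidate",
    "PipelineResult",
    "p_search_window",
    "detect_normal_p",
    "dissociation_gate",
    "detect_dissociated_p",
    "verify_p",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

REJECTION_REASONS = (
    "none", "low_voltage", "behind_T", "afib_skip", "pvc_skip",
    "no_dissociation",
)


@dataclass
class PCandidate:
    """One P-wave candidate and the verdict of the decision rules."""

    beat_index: int
    position: int | None          # sample index; None when no window existed
    amplitude: float              # signed value on the cleaned signal
    kind: str                     # {"normal", "dissociated"}
    accepted: bool = False
    rejection_reason: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "dissociated"):
            raise ValueError(f"unknown candidate kind {self.kind!r}")
        if self.rejection_reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.rejection_reason!r}")
        if self.accepted and self.rejection_reason != "none":
            raise ValueError("accepted candidates carry no rejection reason")


@dataclass
class PipelineResult:
    """Everything the pipeline decided, stage by stage."""

    beats: BeatSet
    candidates: list[PCandidate]
    auc: AucSeries | None = None
    entropy: EntropySeries | None = None

    @property
    def accepted(self) -> list[PCandidate]:
        return [c for c in self.candidates if c.accepted]

    @property
    def p_positions(self) -> np.ndarray:
        """All accepted P positions (normal and dissociated), sorted."""
        return np.array(
            sorted(c.position for c in self.accepted), dtype=np.int64
        )

    def to_annotations(self, record_id: str = "", n_samples: int | None = None
                       ) -> WaveAnnotations:
        t = np.asarray(self.beats.t_peaks)
        return WaveAnnotations(
            p_peaks=self.p_positions,
            t_peaks=np.unique(t[t >= 0]),
            r_peaks=self.beats.r_peaks,
            source="detected",
            record_id=record_id,
            n_samples=n_samples,
        )


def p_search_window(
    beats: BeatSet, i: int, fs: float, n_samples: int,
    cfg: DetectorConfig | None = None,
) -> tuple[int, int] | None:
    """Closed sample interval to search for the conducted P of beat ``i``.

    Returns None when the interval is empty after clipping (very short RR).
    """
    cfg = cfg or DetectorConfig()
    r = int(beats.r_peaks[i])
    if i == 0:
        w0, w1 = cfg.first_p_win
        a = r - round_half_even(w0 * fs)
        b = r - round_half_even(w1 * fs)
    else:
        rr = r - int(beats.r_peaks[i - 1])
        c0, c1, c2 = cfg.p_win
        a = int(beats.r_peaks[i - 1]) + round_half_even(c0 * rr)
        b = r - round_half_even(c1 * rr + c2 * fs)
    a, b = max(a, 0), min(b, n_samples - 1)
    if a > b:
        return None
    return a, b


def detect_normal_p(
    cleaned: FilteredSignal, beats: BeatSet, i: int,
    cfg: DetectorConfig | None = None,
) -> PCandidate | None:
    """Conducted-P candidate of beat ``i`` (unverified), or None if no window."""
    cfg = cfg or DetectorConfig()
    w = p_search_window(beats, i, cleaned.fs, len(cleaned.samples), cfg)
    if w is None:
        return None
    a, b = w
    seg = phasor_transform(cleaned.samples[a : b + 1], cfg.rv_p)
    pos = a + int(np.argmax(seg))
    return PCandidate(
        beat_index=i, position=pos,
        amplitude=float(cleaned.samples[pos]), kind="normal",
    )


def dissociation_gate(
    beats: BeatSet, i: int, prev_had_dissociated: bool,
    cfg: DetectorConfig | None = None,
) -> bool:
    """May the interval ending at beat ``i`` hold a dissociated P?

    With no dissociated P in the previous interval, three criteria must all
    hold: RR(i) > 1.6·RR(i−1), RR(i) > 1.6 s, and beat i is not a PVC.  With
    one, the single relaxed criterion RR(i) > 0.8·RR(i−1) applies.  RR(i−1)
    only exists for i ≥ 2; earlier beats gate to False.
    """
    cfg = cfg or DetectorConfig()
    if i < 2:
        return False
    rr_cur = (int(beats.r_peaks[i]) - int(beats.r_peaks[i - 1])) / beats.fs
    rr_prev = (int(beats.r_peaks[i - 1]) - int(beats.r_peaks[i - 2])) / beats.fs
    if prev_had_dissociated:
        return rr_cur > cfg.diss_rr_relax * rr_prev
    return (
        rr_cur > cfg.diss_rr_factor * rr_prev
        and rr_cur > cfg.diss_rr_min
        and not bool(beats.pvc[i])
    )


def detect_dissociated_p(
    cleaned: FilteredSignal, beats: BeatSet, i: int,
    p_ref: int | None = None,
    cfg: DetectorConfig | None = None,
) -> PCandidate | None:
    """Dissociated-P candidate inside the interval ending at beat ``i``.

    The window runs from T(i−1) + 200 ms to P(i) − 400 ms, where P(i) is the
    accepted conducted P of beat i when one exists and otherwise the left
    edge of beat i's conducted-P search window (``p_ref`` carries either).
    Returns None when T(i−1) is unassigned or the window is empty.
    """
    cfg = cfg or DetectorConfig()
    if i < 1 or beats.t_peaks[i - 1] < 0:
        return None
    if p_ref is None:
        w = p_search_window(beats, i, cleaned.fs, len(cleaned.samples), cfg)
        if w is None:
            return None
        p_ref = w[0]
    a = int(beats.t_peaks[i - 1]) + round_half_even(cfg.diss_after_t * cleaned.fs)
    b = int(p_ref) - round_half_even(cfg.diss_before_p * cleaned.fs)
    a, b = max(a, 0), min(b, len(cleaned.samples) - 1)
    if a > b:
        return None
    seg = phasor_transform(cleaned.samples[a : b + 1], cfg.rv_p)
    pos = a + int(np.argmax(seg))
    return PCandidate(
        beat_index=i, position=pos,
        amplitude=float(cleaned.samples[pos]), kind="dissociated",
    )


def verify_p(
    cand: PCandidate, beats: BeatSet, cleaned: FilteredSignal,
    cfg: DetectorConfig | None = None,
) -> PCandidate:
    """Apply the two acceptance criteria to a candidate (voltage first)."""
    cfg = cfg or DetectorConfig()
    i = cand.beat_index
    u_qrs = abs(float(cleaned.samples[int(beats.r_peaks[i])]))
    if not (abs(cand.amplitude) > cfg.up_factor * u_qrs):
        return PCandidate(i, cand.position, cand.amplitude, cand.kind,
                          accepted=False, rejection_reason="low_voltage")
    if i >= 1 and beats.t_peaks[i - 1] >= 0 and not (
        cand.position > int(beats.t_peaks[i - 1])
    ):
        return PCandidate(i, cand.position, cand.amplitude, cand.kind,
                          accepted=False, rejection_reason="behind_T")
    return PCandidate(i, cand.position, cand.amplitude, cand.kind,
                      accepted=True, rejection_reason="none")


def run_pipeline(
    rec: EcgRecord, cfg: DetectorConfig | None = None
) -> PipelineResult:
    """Run the full detection chain on one record.

    Stages, in order: QRS detection (band-pass + phasor + adaptive threshold
    + backward search), T detection, PVC flagging by QRS area, AFIB flagging
    by word entropy, then per beat the pathology gate, conducted-P search,
    dissociated-P search and the two-criterion verification.  A per-beat
    decision trace is emitted at DEBUG level.
    """
    cfg = cfg or DetectorConfig()
    rec.require_min_duration(2.0)
    bp = bandpass_qrs(rec, cfg)
    beats = detect_qrs(bp, cfg)
    if len(beats) == 0:
        return PipelineResult(beats=beats, candidates=[])

    cleaned = clean(rec, cfg)
    beats = detect_t(cleaned, beats, cfg)

    baseline_free = highpass_lynn(rec, cfg)
    auc = compute_auc(baseline_free, beats, cfg)
    beats.pvc = detect_pvc(auc, cfg)
    ent = symbolic_entropy(beats, cfg)
    beats.afib = detect_afib(ent, beats.pvc, cfg)

    candidates: list[PCandidate] = []
    prev_had_dissociated = False
    for i in range(len(beats)):
        verdict = pathology_check(beats, i)
        if verdict != "proceed":
            reason = "afib_skip" if verdict == "skip_afib" else "pvc_skip"
            candidates.append(PCandidate(i, None, 0.0, "normal",
                                         accepted=False,
                                         rejection_reason=reason))
            logger.debug("beat %d: %s", i, reason)
            prev_had_dissociated = False
            continue

        cand = detect_normal_p(cleaned, beats, i, cfg)
        accepted_pos: int | None = None
        if cand is not None:
            cand = verify_p(cand, beats, cleaned, cfg)
            candidates.append(cand)
            logger.debug(
                "beat %d: normal candidate at %s amp %.4f -> %s (%s)",
                i, cand.position, cand.amplitude,
                "accepted" if cand.accepted else "rejected",
                cand.rejection_reason,
            )
            if cand.accepted:
                accepted_pos = cand.position
                beats.p_peaks[i] = cand.position

        found_dissociated = False
        if dissociation_gate(beats, i, prev_had_dissociated, cfg):
            dcand = detect_dissociated_p(
                cleaned, beats, i, p_ref=accepted_pos, cfg=cfg
            )
            if dcand is not None:
                dcand = verify_p(dcand, beats, cleaned, cfg)
                candidates.append(dcand)
                logger.debug(
                    "beat %d: dissociated candidate at %s -> %s (%s)",
                    i, dcand.position,
                    "accepted" if dcand.accepted else "rejected",
                    dcand.rejection_reason,
                )
                found_dissociated = dcand.accepted
        prev_had_dissociated = found_dissociated

    return PipelineResult(beats=beats, candidates=candidates, auc=auc,
                          entropy=ent)
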