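"""Synthetic single-lead ECG with exact ground truth.

Each beat is a sum of Gaussian bumps (P, QRS, T) on a flat baseline.  The
generator controls exactly the quantities the detectors measure — peak
positions, amplitudes, QRS areas and RR statistics — which makes it a
sufficient truth-bearing model without a full dynamical ECG simulator.
It is first-class, tested code: every detector-recovery test in the package
compares against the truth it returns.

Default morphology (amplitudes in mV, times in seconds, RR-scaled):

* QRS apex at the beat time R, amplitude 1.0, sigma 0.010;
* P apex at R − (0.18·RR_prev + 0.03), amplitude 0.15, sigma 0.030 — placed
  so the conducted-P search region contains the apex at any heart rate in
  40–180 bpm (a purely proportional PR interval would leave the window above
  ~90 bpm because of its fixed 60 ms term);
* T apex at R + 0.30·min(RR_prev, RR_next), amplitude 0.30, sigma 0.050 —
  repolarization follows the beat's own cycle (RR_prev, the interval ending
  at the beat), capped by the following interval so the T sequence stays
  monotone under heavy RR jitter.

Pathology events emulate the rhythms the decision rules target:

* ``pvc`` — wide (×2.5 sigma), tall (×1.8) QRS with no preceding P;
* ``afib_segment`` — RR i.i.d. jittered (sd ≥ 25% of the mean) and P bumps
  removed over a beat range;
* ``avb2_drop`` — QRS and T removed, the P retained (dissociated P);
* ``rbbb_widen`` — every QRS widened ×1.8, P waves unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import EcgRecord, WaveAnnotations

__all__ = ["SynthSpec", "SynthTruth", "generate", "add_noise"]

PVC_WIDTH_FACTOR = 2.5
PVC_AMP_FACTOR = 1.8
RBBB_WIDTH_FACTOR = 1.8
AFIB_MIN_JITTER = 0.25
P_LEAD_FRACTION = 0.18   # P apex lead = fraction*RR + offset
P_LEAD_OFFSET = 0.03
T_LAG_FRACTION = 0.30


@dataclass(frozen=True)
class SynthSpec:
    """Everything that defines one synthetic record."""

    fs: float = 360.0
    duration: float = 60.0
    hr_bpm: float = 60.0
    rr_jitter: float = 0.0       # fractional sd of RR
    p_amp: float = 0.15
    qrs_amp: float = 1.0
    t_amp: float = 0.30
    p_sigma: float = 0.030
    qrs_sigma: float = 0.010
    t_sigma: float = 0.050
    events: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.p_amp, self.qrs_amp, self.t_amp) < 0:
            raise ValueError("wave amplitudes must be non-negative")
        if not (0 <= self.rr_jitter < 1):
            raise ValueError("rr_jitter must lie in [0, 1)")
        if self.fs <= 0 or self.duration <= 0 or self.hr_bpm <= 0:
            raise ValueError("fs, duration and hr_bpm must be positive")
        for ev in self.events:
            if ev.get("type") not in ("pvc", "afib_segment", "avb2_drop",
                                      "rbbb_widen"):
                raise ValueError(f"unknown event type {ev.get('type')!r}")


@dataclass
class SynthTruth:
    """Exact wave positions and per-beat labels for a generated record."""

    annotations: WaveAnnotations
    is_pvc: np.ndarray          # bool per r_peak
    in_afib: np.ndarray         # bool per r_peak
    p_dissociated: np.ndarray   # bool per p_peak (True for orphan P waves)

    @property
    def r_peaks(self) -> np.ndarray:
        return self.annotations.r_peaks

    @property
    def p_peaks(self) -> np.ndarray:
        return self.annotations.p_peaks

    @property
    def t_peaks(self) -> np.ndarray:
        return self.annotations.t_peaks


def _beat_schedule(spec: SynthSpec, rng: np.random.Generator):
    rr0 = 60.0 / spec.hr_bpm
    afib = [ev for ev in spec.events if ev["type"] == "afib_segment"]
    times = []
    t = 0.5
    tail = 0.6 * max(rr0, 1.0)
    k = 0
    while t < spec.duration - tail:
        times.append(t)
        jit = spec.rr_jitter
        for ev in afib:
            if ev["start"] <= k + 1 <= ev["end"]:
                jit = max(jit, ev.get("jitter", 0.30), AFIB_MIN_JITTER)
        rr = rr0 * (1.0 + jit * rng.standard_normal())
        t += float(np.clip(rr, max(0.25, 0.3 * rr0), 2.5 * rr0))
        k += 1
    return np.array(times), rr0


def generate(spec: SynthSpec) -> tuple[EcgRecord, SynthTruth]:
    """Render the record and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    times, rr0 = _beat_schedule(spec, rng)
    nbeat = len(times)
    if nbeat == 0:
        raise ValueError("duration too short to hold a single beat")

    has_qrs = np.ones(nbeat, dtype=bool)
    has_p = np.ones(nbeat, dtype=bool)
    qrs_amp = np.full(nbeat, spec.qrs_amp)
    qrs_sigma = np.full(nbeat, spec.qrs_sigma)
    is_pvc = np.zeros(nbeat, dtype=bool)
    in_afib = np.zeros(nbeat, dtype=bool)

    for ev in spec.events:
        kind = ev["type"]
        if kind == "rbbb_widen":
            qrs_sigma *= ev.get("factor", RBBB_WIDTH_FACTOR)
        elif kind == "afib_segment":
            if not (0 <= ev["start"] <= ev["end"] < nbeat):
                raise ValueError(
                    f"afib_segment beats {ev['start']}..{ev['end']} outside "
                    f"the {nbeat}-beat record"
                )
            sl = slice(ev["start"], ev["end"] + 1)
            has_p[sl] = False
            in_afib[sl] = True
        else:
            k = ev["beat"]
            if not (0 <= k < nbeat):
                raise ValueError(f"{kind} beat {k} outside the record")
            if kind == "pvc":
                qrs_sigma[k] *= PVC_WIDTH_FACTOR
                qrs_amp[k] *= PVC_AMP_FACTOR
                has_p[k] = False
                is_pvc[k] = True
            elif kind == "avb2_drop":
                has_qrs[k] = False

    rr_prev = np.empty(nbeat)
    rr_prev[0] = rr0
    rr_prev[1:] = np.diff(times)
    rr_next = np.empty(nbeat)
    rr_next[:-1] = np.diff(times)
    rr_next[-1] = rr_prev[-1]
    # T lag follows the beat's own cycle but is capped by the next interval
    # so the T sequence stays monotone under heavy RR jitter
    t_lag = T_LAG_FRACTION * np.minimum(rr_prev, rr_next)

    n = int(round(spec.duration * spec.fs))
    x = np.zeros(n)

    def bump(center_s: float, amp: float, sigma: float) -> int:
        c = center_s * spec.fs
        lo = max(int(np.floor(c - 6 * sigma * spec.fs)), 0)
        hi = min(int(np.ceil(c + 6 * sigma * spec.fs)) + 1, n)
        if hi > lo and amp > 0:
            idx = np.arange(lo, hi)
            x[idx] += amp * np.exp(-((idx - c) ** 2)
                                   / (2 * (sigma * spec.fs) ** 2))
        return int(np.rint(c))

    r_list, p_list, t_list = [], [], []
    p_diss = []
    r_pvc, r_afib = [], []
    for k in range(nbeat):
        if has_qrs[k]:
            r_list.append(bump(times[k], qrs_amp[k], qrs_sigma[k]))
            r_pvc.append(bool(is_pvc[k]))
            r_afib.append(bool(in_afib[k]))
            t_list.append(bump(times[k] + t_lag[k], spec.t_amp, spec.t_sigma))
        if has_p[k]:
            lead = P_LEAD_FRACTION * rr_prev[k] + P_LEAD_OFFSET
            p_list.append(bump(times[k] - lead, spec.p_amp, spec.p_sigma))
            p_diss.append(not has_qrs[k])

    rec = EcgRecord(x, fs=spec.fs, lead="synth", record_id=f"synth{spec.seed}")
    ann = WaveAnnotations(
        p_peaks=np.array(p_list, dtype=np.int64),
        t_peaks=np.array(t_list, dtype=np.int64),
        r_peaks=np.array(r_list, dtype=np.int64),
        source="reference",
        record_id=rec.record_id,
        n_samples=n,
    )
    truth = SynthTruth(
        annotations=ann,
        is_pvc=np.array(r_pvc, dtype=bool),
        in_afib=np.array(r_afib, dtype=bool),
        p_dissociated=np.array(p_diss, dtype=bool),
    )
    return rec, truth


def add_noise(
    rec: EcgRecord, kind: str, level: float,
    seed: int = 0, freq: float | None = None,
) -> EcgRecord:
    """Additive noise of a named kind; seeded and reproducible.

    ``gaussian`` adds white noise of sd ``level`` (mV); ``baseline_drift``
    and ``powerline`` add a sinusoid of amplitude ``level`` at ``freq``
    (defaults 0.2 Hz and 50 Hz) with a seeded random phase.
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(len(rec.samples)) / rec.fs
    if kind == "gaussian":
        noise = level * rng.standard_normal(len(rec.samples))
    elif kind == "baseline_drift":
        f = 0.2 if freq is None else freq
        noise = level * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    elif kind == "powerline":
        f = 50.0 if freq is None else freq
        noise = level * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    if level == 0:
        return EcgRecord(rec.samples.copy(), rec.fs, rec.lead, rec.record_id)
    return EcgRecord(rec.samples + noise, rec.fs, rec.lead, rec.record_id)
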