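# Methods

## Model and assumptions

`pwavekit` is a deterministic, rule-based delineator for single-lead ECG in
physical units (mV).  It assumes: (i) the record is at least 2 s long with a
sampling rate high enough to carry a 12–19 Hz QRS band (fs ≥ 40 Hz; the
shipped defaults are exercised at 128–360 Hz); (ii) QRS complexes are the
dominant deflections in the 12–19 Hz band; (iii) P and T waves are upright
enough that a signed phase maximum finds their apex (deeply inverted waves
are a known limitation, see below); (iv) noise is modest — the method is not
designed for heavily corrupted records.

The phasor transform `PT(n) = arctan(x(n)/R_V)` is strictly increasing in
`x(n)`, so within any fixed window the location of the phase maximum equals
the location of the signal maximum.  All argmax-based stages therefore
inherit exact peak-location preservation; the transform's role is amplitude
equalization, controlled per stage by `R_V` (0.001 QRS, 0.1 T, 0.05 P).

## Tunable parameters

All constants live in `DetectorConfig` (flat TOML override via the CLI).
The detection thresholds are the published operating point of the rule set;
the remaining choices are this package's own and are listed with their
rationale:

| parameter | default | meaning |
| --- | --- | --- |
| `rv_qrs`, `rv_t`, `rv_p` | 0.001, 0.1, 0.05 | phasor enhancement per stage |
| `qrs_band` | 12–19 Hz | QRS-dominant passband |
| `slide_window`, `std_window`, `std_factor` | 0.3 s, 2 s, 2 | candidate maxima windows and adaptive threshold |
| `refractory` | 0.2 s | duplicate-merge distance (physiological minimum RR) |
| `rr_gap_factor`, `back_thresh` | 1.75, 0.3 | backward-search trigger and amplitude fraction |
| `t_win` | 0.12, 0.57, 60 ms | T search window coefficients |
| `pvc_win`, `pvc_factor`, `pvc_reset_frac` | 150 ms, 1.3, 0.75 | QRS-area window, PVC ratio, BBB reset |
| `lynn_fc` | 0.67 Hz | baseline-removal cut-off |
| `sh_window`, `sh_thresh`, `sh_pvc_override` | 59, 0.737, 30 | entropy segment, AFIB threshold, PVC override |
| `hr_bin`, `hr_max` | 5 bpm, 315 bpm | heart-rate symbol quantization |
| `diss_*` | 1.6, 1.6 s, 0.8, 200 ms, 400 ms | dissociated-P gate and window margins |
| `p_win`, `first_p_win` | 0.71, 0.07, 60 ms; 300–80 ms | conducted-P windows |
| `up_factor` | 0.05 | voltage criterion vs QRS amplitude |
| `eval_tolerance` | 100 ms | Se/PP matching tolerance (see below) |

## Numerical choices

**Seconds→samples rounding.**  One shared helper (round-half-even) converts
every window formula; windows are computed as closed sample intervals and
clipped to the record, and an interval that empties after clipping means
"wave undefined for this beat".  Argmax ties break to the earliest sample,
globally.

**Filters.**  The QRS band-pass is a Hamming-window FIR of ~0.8·fs taps
(odd), giving transition bands under ~5 Hz; the mean tap is subtracted so a
constant input maps to exactly zero.  Baseline removal is a Lynn-type
linear-phase low-pass — two cascaded moving averages of length fs/0.67,
i.e. a triangular kernel — subtracted from the input.  All filters run
zero-delay (reflect padding, trimmed), so an isolated symmetric pulse moves
by at most one sample and detected positions live on the raw time axis.
The generic `clean` stage (baseline removal + 50/60 Hz zero-phase notches;
notches above 90% of Nyquist are skipped) is a deliberately simple
pre-cleaning stage and can be switched off.

**Amplitude domain of the QRS thresholds.**  Candidate R peaks are the
phase-signal maxima, but the adaptive threshold (2× moving std) and the
backward-search 30% rule are evaluated on the band-passed signal rather
than the phase signal.  With `R_V = 0.001`, any mV-scale input drives
`arctan(x/R_V)` into saturation near ±π/2: the phase signal then oscillates
between near-extreme values, its 2 s standard deviation exceeds half the
phase ceiling, and a threshold of twice that std would sit above every
attainable peak — no beat could ever be detected in that domain.  Because
the transform is monotone, comparing on the pre-transform scale selects
exactly the same candidates while keeping the std a scale-free, meaningful
spread measure.  This is the one place the implementation interprets rather
than transcribes the rule set.

**PVC running median.**  The reference median is maintained over previously
*unflagged* beats.  A median over all previous beats adapts towards the
ectopic areas during long PVC runs, which both weakens the 1.3× criterion
exactly where it matters and makes the >75% bundle-branch-block override
practically unreachable; tracking the normal-beat population keeps both
rules functional.  The first beat has no reference and is never flagged.

**Entropy construction.**  Heart rate is clipped to [0, 315] bpm and binned
at 5 bpm (64 symbols); a word encodes three consecutive symbols in base 64;
the entropy of the word distribution over the 59-word segment centred on
the beat is normalized by ln 59, so 59 distinct words score exactly 1 and
the 0.737 threshold lands inside [0, 1].  Beats whose segment would leave
the record keep an undefined entropy and are never flagged — conservative
at record edges, where a windowed statistic is unreliable anyway.  The
dissociation gate needs two preceding RR intervals and is therefore defined
false for the first two beats.

**Dissociated-P window right edge.**  The window ends 400 ms before the
current beat's P reference: its accepted conducted P when one exists,
otherwise the left edge of the conducted-P search window.  The fallback
keeps the dissociated search strictly left of any plausible conducted-P
territory when step (f) rejected its candidate.

## Synthetic data: what it emulates, and what it does not

The generator renders each beat as Gaussian bumps on a flat baseline — QRS
(1.0 mV, σ 10 ms) at the beat time, P (0.15 mV, σ 30 ms) before it, T
(0.30 mV, σ 50 ms) after it — because the detectors consume only peak
positions, amplitudes, areas and RR statistics, all of which bumps control
exactly.  The P apex leads the R peak by `0.18·RR + 30 ms`: a window-shape
constraint, since the conducted-P search region's fixed 60 ms term means a
purely proportional PR interval would exit the window above ~90 bpm,
while this placement keeps the apex centred in it across 40–180 bpm.  The
T apex trails by `0.30·min(RR_prev, RR_next)` — repolarization follows the
beat's own cycle, with the cap keeping the T sequence monotone under heavy
jitter.  Pathology events mirror the rhythms the rules target: PVCs
(×2.5 width, ×1.8 amplitude, no P), AFIB segments (i.i.d. RR jitter with
sd ≥ 25%, P removed), AVB II drops (QRS and T removed, P kept), and global
QRS widening (bundle-branch-block morphology).

What passing on these fixtures shows: the decision rules, window
arithmetic, flag logic and evaluator behave exactly as specified under
their stated conditions.  What it does not show: performance on real ECG —
no muscle or electrode noise, no f-waves during AFIB, no morphology
variability between or within patients, no biphasic or inverted waves.
Beat-level scores on annotated clinical databases are the right instrument
for that and are outside this test suite (they additionally depend on the
unpublished matching tolerance, which is why `eval_tolerance` is exposed
rather than fixed).

Problem sizes used by the test suite and the acceptance script — 30–200 s
records, a 12-point heart-rate × sampling-rate grid, 120-beat AFIB
segments, 1000-trial matching oracles — were chosen as the smallest sizes
at which every windowed statistic (the 2 s std, the 59-beat entropy
segment) is fully exercised away from its edge behaviour.

## Known limitations

* Signed phase maxima: deeply inverted P or T waves are mislocalized.
* One P per pause: a long pause holding several orphan P waves (high-grade
  or third-degree AV block) yields only the largest; third-degree block,
  with fully independent atrial and ventricular rhythms, is out of scope.
* Entropy edge delay: the first/last ~29 beats of an AFIB episode may
  escape flagging, producing false P searches at episode boundaries.
* No noise-stress hardening; the `clean` stage is minimal by design.
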