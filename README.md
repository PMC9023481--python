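# pwavekit

P wave delineation in single-lead ECG, built for signals where it is hardest:
pathological rhythms.  Most P-wave detectors assume every P wave is followed
by a QRS complex; that assumption fails under premature ventricular
contractions (PVC), atrial fibrillation (AFIB), second-degree AV block
(AVB II) and bundle branch blocks.  `pwavekit` implements a rule-based
detector that first identifies the rhythm context of every beat and then
either searches for the P wave in the right place — or deliberately does not
search at all.  It is aimed at ECG-algorithm researchers and engineers who
need a transparent, auditable delineator plus the tooling to test one:
WFDB/CSV I/O, a synthetic-ECG generator with exact ground truth, and a
beat-level Se/PP evaluator.

## Method

The enhancement primitive is the **phasor transform**: each sample is mapped
to the phase of `R_V + j·x(n)`,

    PT(n) = arctan(x(n) / R_V),   0 < R_V ≤ 1,

which magnifies low-amplitude deflections (the smaller `R_V`, the stronger)
while preserving peak locations exactly, since arctan is strictly
increasing.

The pipeline runs eight stages per record:

1. **QRS detection** — 12–19 Hz band-pass (Hamming FIR, zero-delay), phasor
   transform with `R_V = 0.001`, maxima in 300 ms windows against an
   adaptive threshold of 2× the standard deviation in a centred 2 s window;
   a backward search re-scans any RR interval > 1.75× its predecessor for
   peaks above 30% of the last QRS amplitude.
2. **T detection** — phase-signal maximum (`R_V = 0.1`) in
   `R(i)+0.12·RR(i) … R(i)+0.57·RR(i)+60 ms`.
3. **PVC flagging** — area under the QRS, `AUC(i) = Σ|x̃(n)|/fs` over
   `R(i)±150 ms` of the baseline-free signal; a beat is PVC when
   `AUC(i) > 1.3×` the running median of the normal beats.  If more than 75%
   of all beats are flagged, the morphology is read as bundle branch block
   and all flags are cleared.
4. **AFIB flagging** — heart rate quantized into 5 bpm symbols, consecutive
   symbol triplets encoded as words; a beat is AFIB when the normalized
   Shannon entropy of the word distribution over the surrounding 59 beats
   exceeds 0.737, unless more than 30 of those beats are PVCs.
5. **Pathology check** — AFIB beats skip the P search entirely; PVC beats
   skip the search before their QRS.
6. **Normal P detection** — phase-signal maximum (`R_V = 0.05`) in
   `R(i−1)+0.71·RR(i) … R(i)−0.07·RR(i)−60 ms`.
7. **Dissociated P detection** — long pauses passing a small rule set
   (`RR(i) > 1.6·RR(i−1)`, `RR(i) > 1.6 s`, beat not PVC; relaxed to
   `RR(i) > 0.8·RR(i−1)` after a found dissociated P) are searched in
   `T(i−1)+200 ms … P(i)−400 ms`.
8. **Verification** — a candidate is accepted iff `|U_P| > 0.05·|U_QRS|`
   and it lies after the previous T peak.  Rejected candidates are kept
   with their rejection reason, so every decision is auditable.

Scoring: sensitivity `Se = 100·TP/(TP+FN)` and positive predictivity
`PP = 100·TP/(TP+FP)`, per record and averaged unweighted across records.

See `docs/methods.md` for assumptions, parameter rationale, numerical
choices and limitations.

## Worked example

Generate a 60 s synthetic record with a dropped QRS at beat 20 (an AVB II
surrogate: the P wave of that beat has no ventricular answer), detect, and
score against the generator's truth:

```
$ cat avb_spec.json
{"duration": 60.0, "seed": 5, "events": [{"type": "avb2_drop", "beat": 20}]}

$ pwavekit synth --spec-file avb_spec.json --output avb
{
  "record": "avb",
  "n_beats": 58,
  "n_p": 59,
  "n_t": 58
}

$ pwavekit detect avb --output-dir out
{
  "record_id": "avb",
  "fs": 360.0,
  "n_beats": 58,
  "n_pvc": 0,
  "n_afib": 0,
  "n_p_accepted": 59,
  "n_p_rejected": 0
}

$ pwavekit evaluate out/avb_detected.csv avb_truth.csv --fs 360
{
  "tp": 59, "fp": 0, "fn": 0,
  "se_mean": 100.0, "pp_mean": 100.0, ...
}
```

The truth holds 59 P waves but only 58 beats — the orphan P inside the
pause.  The detector finds 58 conducted P waves plus the dissociated one
(`n_p_accepted: 59`), flags nothing as PVC or AFIB, and scores
Se = PP = 100% at the default 100 ms matching tolerance.  `pwavekit detect`
also writes the per-beat flag table (`avb_beats.csv`) and the detected
P/T/R annotations in both MIT and CSV form; `pwavekit -v detect` streams
the per-beat decision trace (window bounds, candidates, criteria verdicts).

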