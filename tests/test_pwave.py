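import numpy as np
import pytest

from pwavekit import (
    BeatSet,
    DetectorConfig,
    PCandidate,
    clean,
    dissociation_gate,
    run_pipeline,
    verify_p,
)
from pwavekit.preprocess import FilteredSignal
from pwavekit.pwave import p_search_window
from pwavekit.synthetic import SynthSpec, generate
from pwavekit.twave import t_search_window


class TestSearchWindow:
    def test_printed_formula(self):
        beats = BeatSet(np.array([0, 360]), fs=360.0)
        assert p_search_window(beats, 1, 360.0, 100000) == (256, 313)

    def test_first_beat_fixed_window(self):
        beats = BeatSet(np.array([720, 1080]), fs=360.0)
        assert p_search_window(beats, 0, 360.0, 100000) == (612, 691)

    def test_very_short_rr_gives_no_window(self):
        beats = BeatSet(np.array([0, 30]), fs=360.0)  # RR = 83 ms
        assert p_search_window(beats, 1, 360.0, 100000) is None

    def test_clipped_to_signal_start(self):
        beats = BeatSet(np.array([50, 410]), fs=360.0)
        a, b = p_search_window(beats, 0, 360.0, 100000)
        assert a == 0 and b == 50 - 29


class TestDissociationGate:
    def beats(self, rr_prev_s, rr_cur_s, pvc_last=False, fs=360.0):
        r = np.cumsum([1000, int(rr_prev_s * fs), int(rr_cur_s * fs)])
        pvc = np.array([False, False, pvc_last])
        return BeatSet(r, fs, pvc=pvc)

    def test_long_pause_opens_gate(self):
        assert dissociation_gate(self.beats(1.0, 2.0), 2, False)

    def test_pvc_beat_closes_gate(self):
        assert not dissociation_gate(self.beats(1.0, 2.0, pvc_last=True), 2, False)

    def test_relaxed_rule_after_found_dissociation(self):
        b = self.beats(1.0, 0.9)
        assert dissociation_gate(b, 2, True)     # 0.9 > 0.8 * 1.0
        assert not dissociation_gate(b, 2, False)

    def test_absolute_floor(self):
        # ratio satisfied but the pause is shorter than 1.6 s
        assert not dissociation_gate(self.beats(0.5, 1.0), 2, False)

    def test_undefined_previous_interval(self):
        b = BeatSet(np.array([100, 820]), fs=360.0)
        assert not dissociation_gate(b, 1, False)


class TestVerification:
    def setup_method(self):
        self.fs = 360.0
        x = np.zeros(2000)
        x[500] = 1.0     # current R
        self.x = x
        self.beats = BeatSet(
            np.array([200, 500]), self.fs,
            t_peaks=np.array([300, -1]),
        )

    def check(self, pos, amp):
        self.x[pos] = amp
        sig = FilteredSignal(self.x, self.fs, "cleaned")
        cand = PCandidate(1, pos, amp, "normal")
        return verify_p(cand, self.beats, sig)

    def test_strong_candidate_accepted(self):
        out = self.check(400, 0.1)
        assert out.accepted and out.rejection_reason == "none"

    def test_low_voltage_rejected(self):
        out = self.check(400, 0.04)
        assert not out.accepted and out.rejection_reason == "low_voltage"

    def test_candidate_before_previous_t_rejected(self):
        out = self.check(250, 0.1)
        assert not out.accepted and out.rejection_reason == "behind_T"

    def test_voltage_checked_before_position(self):
        out = self.check(250, 0.01)
        assert out.rejection_reason == "low_voltage"


class TestPipeline:
    def test_sinus_every_beat_gets_one_p(self, sinus):
        rec, truth = sinus
        res = run_pipeline(rec)
        assert len(res.p_positions) == len(truth.p_peaks)
        errs = np.abs(res.p_positions - truth.p_peaks)
        assert errs.max() <= 1
        assert all(c.accepted for c in res.candidates)
        assert not res.beats.pvc.any() and not res.beats.afib.any()

    @pytest.mark.parametrize("fs", [128.0, 250.0, 360.0])
    def test_p_localization_across_sampling_rates(self, fs):
        rec, truth = generate(SynthSpec(fs=fs, duration=40.0, seed=51))
        res = run_pipeline(rec)
        assert len(res.p_positions) == len(truth.p_peaks)
        assert np.abs(res.p_positions - truth.p_peaks).max() <= 1

    def test_afib_segment_suppresses_p_search(self):
        rec, truth = generate(
            SynthSpec(duration=200.0, seed=52,
                      events=({"type": "afib_segment", "start": 50,
                               "end": 150, "jitter": 0.30},))
        )
        res = run_pipeline(rec)
        interior = slice(80, 121)
        assert res.beats.afib[interior].all()
        lo = res.beats.r_peaks[interior.start]
        hi = res.beats.r_peaks[interior.stop]
        assert not np.any((res.p_positions >= lo) & (res.p_positions <= hi))

    def test_pvc_beat_skips_p_and_neighbors_unaffected(self):
        rec, truth = generate(
            SynthSpec(duration=60.0, seed=53,
                      events=({"type": "pvc", "beat": 20},))
        )
        res = run_pipeline(rec)
        assert res.beats.pvc[20] and res.beats.pvc.sum() == 1
        assert res.beats.p_peaks[20] == -1
        assert len(res.p_positions) == len(truth.p_peaks)
        assert np.abs(res.p_positions - truth.p_peaks).max() <= 1

    def test_avb2_dissociated_p_recovered(self):
        rec, truth = generate(
            SynthSpec(duration=60.0, seed=54,
                      events=({"type": "avb2_drop", "beat": 20},))
        )
        res = run_pipeline(rec)
        diss = [c for c in res.accepted if c.kind == "dissociated"]
        orphan = truth.p_peaks[truth.p_dissociated]
        assert len(diss) == 1 and len(orphan) == 1
        assert abs(diss[0].position - orphan[0]) <= 1
        assert len(res.p_positions) == len(truth.p_peaks)

    def test_alternating_drops_use_relaxed_gate(self):
        # 2:1-block pattern: the second pause follows one that already held
        # a dissociated P, so only the relaxed RR criterion applies
        rec, truth = generate(
            SynthSpec(duration=60.0, seed=55,
                      events=({"type": "avb2_drop", "beat": 15},
                              {"type": "avb2_drop", "beat": 17},))
        )
        res = run_pipeline(rec)
        diss = sorted(c.position for c in res.accepted
                      if c.kind == "dissociated")
        orphan = truth.p_peaks[truth.p_dissociated]
        assert len(diss) == len(orphan) == 2
        assert np.abs(np.array(diss) - orphan).max() <= 1

    def test_accepted_candidates_satisfy_both_criteria(self):
        """Re-assert the verification rules post hoc over mixed fixtures."""
        cfg = DetectorConfig()
        for events in ((), ({"type": "pvc", "beat": 10},),
                       ({"type": "avb2_drop", "beat": 12},)):
            rec, _ = generate(SynthSpec(duration=40.0, seed=56, events=events))
            res = run_pipeline(rec, cfg)
            cl = clean(rec, cfg).samples
            for c in res.accepted:
                i = c.beat_index
                u_qrs = abs(cl[res.beats.r_peaks[i]])
                assert abs(c.amplitude) > cfg.up_factor * u_qrs
                if i >= 1 and res.beats.t_peaks[i - 1] >= 0:
                    assert c.position > res.beats.t_peaks[i - 1]

    def test_no_p_inside_pvc_refractory(self):
        rec, _ = generate(
            SynthSpec(duration=60.0, seed=57,
                      events=tuple({"type": "pvc", "beat": k}
                                   for k in (10, 25, 40)))
        )
        res = run_pipeline(rec)
        refr = round(DetectorConfig().refractory * rec.fs)
        for i in np.nonzero(res.beats.pvc)[0]:
            r = res.beats.r_peaks[i]
            assert not np.any((res.p_positions >= r - refr)
                              & (res.p_positions <= r))

    def test_deterministic(self):
        rec, _ = generate(SynthSpec(duration=30.0, seed=58))
        a = run_pipeline(rec)
        b = run_pipeline(rec)
        assert np.array_equal(a.p_positions, b.p_positions)
        assert np.array_equal(a.beats.r_peaks, b.beats.r_peaks)
        assert np.array_equal(a.beats.t_peaks, b.beats.t_peaks)
        assert [(c.beat_index, c.position, c.accepted) for c in a.candidates] \
            == [(c.beat_index, c.position, c.accepted) for c in b.candidates]

    def test_too_short_record_refused(self):
        from pwavekit import EcgRecord

        with pytest.raises(ValueError):
            run_pipeline(EcgRecord(np.zeros(100), fs=360.0))
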