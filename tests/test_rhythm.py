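import numpy as np
import pytest

from pwavekit import (
    BeatSet,
    EcgRecord,
    compute_auc,
    detect_afib,
    detect_pvc,
    make_auc_series,
    pathology_check,
    symbolic_entropy,
    word_entropy,
)
from pwavekit.config import DetectorConfig
from pwavekit.preprocess import FilteredSignal
from pwavekit.rhythm import EntropySeries


class TestAuc:
    def test_rectangular_pulse_closed_form(self):
        fs = 360.0
        x = np.zeros(3600)
        r = 1800
        w = 54  # 150 ms at 360 Hz
        x[r - w : r + w + 1] = 1.0
        sig = FilteredSignal(x, fs, "baseline_free")
        auc = compute_auc(sig, BeatSet(np.array([r]), fs))
        assert auc.auc[0] == pytest.approx(0.3, abs=1.5 / fs)

    def test_zero_signal_zero_area(self):
        sig = FilteredSignal(np.zeros(2000), 360.0, "baseline_free")
        auc = compute_auc(sig, BeatSet(np.array([500, 1000]), 360.0))
        assert np.all(auc.auc == 0)

    def test_area_scales_linearly(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.3, 4000)
        beats = BeatSet(np.array([800, 1600, 2400]), 360.0)
        a1 = compute_auc(FilteredSignal(x, 360.0, "baseline_free"), beats)
        a2 = compute_auc(FilteredSignal(2 * x, 360.0, "baseline_free"), beats)
        np.testing.assert_allclose(a2.auc, 2 * a1.auc)


class TestPvcRule:
    def test_single_large_beat_flagged(self):
        flags = detect_pvc(make_auc_series([1, 1, 1, 2, 1]))
        assert list(flags) == [False, False, False, True, False]

    def test_constant_areas_never_flag(self):
        assert not detect_pvc(make_auc_series([1.0] * 20)).any()

    def test_exactly_75_percent_kept(self):
        # 3 of 4 flagged is not *more* than 75%: the override must not fire
        flags = detect_pvc(make_auc_series([1, 2, 2, 2]))
        assert list(flags) == [False, True, True, True]

    def test_above_75_percent_resets_to_bundle_branch_block(self):
        flags = detect_pvc(make_auc_series([1, 2, 2, 2, 2]))
        assert not flags.any()

    def test_scale_free(self):
        vals = [1.0, 1.1, 2.2, 0.9, 1.0, 3.0]
        f1 = detect_pvc(make_auc_series(vals))
        f2 = detect_pvc(make_auc_series([17.3 * v for v in vals]))
        assert np.array_equal(f1, f2)

    def test_first_beat_never_pvc(self):
        assert not detect_pvc(make_auc_series([100.0, 1.0]))[0]


def beats_from_rr_samples(rr, fs=360.0):
    return BeatSet(np.cumsum(np.asarray(rr, dtype=np.int64)), fs)


class TestSymbolicEntropy:
    def test_constant_rhythm_zero_entropy(self):
        es = symbolic_entropy(beats_from_rr_samples([360] * 100))
        mid = es.sh[50]
        assert mid == pytest.approx(0.0, abs=1e-12)

    def test_all_distinct_words_unit_entropy(self):
        # symbol sequence 0,1,0,2,0,3,... gives 59 pairwise-distinct triplets
        syms = []
        for k in range(1, 32):
            syms += [0, k]
        hr = 2.5 + 5.0 * np.array(syms)  # bin centres
        rr = np.rint(60.0 / hr * 360.0).astype(int)
        es = symbolic_entropy(beats_from_rr_samples(np.concatenate([[360], rr])))
        # words exist at beats 1..60; beat 30's 59-word segment covers 1..59
        assert es.sh[30] == pytest.approx(1.0, abs=1e-9)

    def test_two_word_split_closed_form(self):
        # alternating RR -> words alternate between two codes, 30/29 split
        es = symbolic_entropy(beats_from_rr_samples([288, 432] * 50))
        expected = -(30 / 59 * np.log(30 / 59) + 29 / 59 * np.log(29 / 59)) / np.log(59)
        assert es.sh[50] == pytest.approx(expected, abs=1e-9)

    def test_undefined_near_edges_and_short_records(self):
        es = symbolic_entropy(beats_from_rr_samples([360] * 40))
        assert np.all(np.isnan(es.sh))
        es = symbolic_entropy(beats_from_rr_samples([360] * 100))
        assert np.isnan(es.sh[:30]).all() and np.isnan(es.sh[-31:]).all()

    def test_entropy_depends_only_on_word_multiset(self):
        rng = np.random.default_rng(3)
        words = rng.integers(0, 7, 59)
        shuffled = rng.permutation(words)
        assert word_entropy(words) == pytest.approx(word_entropy(shuffled))


def entropy_series(sh):
    n = len(sh)
    return EntropySeries(
        hr=np.full(n, 60.0), symbols=np.zeros(n, int),
        words=np.zeros(n, int), sh=np.asarray(sh, dtype=float),
    )


class TestAfibRule:
    def test_threshold(self):
        sh = np.full(100, np.nan)
        sh[40:60] = 0.9
        sh[60:70] = 0.5
        flags = detect_afib(entropy_series(sh), np.zeros(100, bool))
        assert flags[40:60].all()
        assert not flags[:40].any() and not flags[60:].any()

    def test_pvc_override_suppresses(self):
        sh = np.full(100, np.nan)
        sh[50] = 0.9
        pvc = np.zeros(100, bool)
        pvc[30:65] = True  # 35 PVCs inside the 59-beat segment of beat 50
        assert not detect_afib(entropy_series(sh), pvc)[50]
        pvc[:] = False
        pvc[40:60] = True  # only 20: not enough to explain the irregularity
        assert detect_afib(entropy_series(sh), pvc)[50]

    def test_jittered_rhythm_flagged_metronome_not(self):
        rng = np.random.default_rng(9)
        rr = np.rint(360 * (1 + 0.3 * rng.standard_normal(200)).clip(0.4, 2.0))
        beats = beats_from_rr_samples(rr.astype(int))
        es = symbolic_entropy(beats)
        flags = detect_afib(es, np.zeros(len(beats), bool))
        assert flags[60:140].mean() > 0.9
        steady = symbolic_entropy(beats_from_rr_samples([360] * 200))
        assert not detect_afib(steady, np.zeros(200, bool)).any()


class TestPathologyCheck:
    @pytest.mark.parametrize(
        "afib, pvc, expected",
        [
            (True, True, "skip_afib"),   # AFIB takes precedence
            (False, True, "skip_pvc"),
            (False, False, "proceed"),
        ],
    )
    def test_gate_order(self, afib, pvc, expected):
        beats = BeatSet(np.array([100]), fs=360.0,
                        pvc=np.array([pvc]), afib=np.array([afib]))
        assert pathology_check(beats, 0) == expected
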