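import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecgsqi.fuzzy import (build_fuzzy_matrix, decide, evaluate_segment,
                          membership_bassqi, membership_ksqi, membership_psqi,
                          membership_qsqi, recommend, synthesize)
from ecgsqi.io import AnalysisConfig, UndefinedIndexError
from ecgsqi.sqi import SqiGradeVector, SqiVector
from ecgsqi.synthetic import SynthesisSpec, add_noise, generate


def vec(q=100.0, p=0.6, c=0.1, s=0.0, k=7.0, b=1.0, hr=60.0):
    return SqiVector(q, p, c, s, k, b, hr)


class TestQsqiMembership:
    def test_printed_anchor_points(self):
        r_e, r_b, r_u = membership_qsqi(60.0)
        assert r_u == pytest.approx(0.5)            # falling Cauchy at 60
        assert membership_qsqi(100.0)[0] == 1.0     # q/100 branch endpoint
        assert membership_qsqi(75.0)[1] == 1.0      # full Cauchy peak
        # left limit at 90 of the rising half-Cauchy branch equals 0.9
        assert membership_qsqi(90.0 - 1e-9)[0] == pytest.approx(0.9, abs=1e-6)
        assert membership_qsqi(90.0)[0] == pytest.approx(0.9)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            membership_qsqi(101.0)
        with pytest.raises(ValueError):
            membership_qsqi(-0.1)

    @given(st.floats(0.0, 100.0))
    def test_range_and_monotonicity(self, q):
        r_e, r_b, r_u = membership_qsqi(q)
        assert 0.0 <= r_e <= 1.0 and 0.0 <= r_b <= 1.0 and 0.0 <= r_u <= 1.0
        r_e2, _, r_u2 = membership_qsqi(min(100.0, q + 1.0))
        assert r_e2 >= r_e - 1e-12   # E membership non-decreasing
        assert r_u2 <= r_u + 1e-12   # U membership non-increasing


class TestPsqiMembership:
    def test_plateaus(self):
        assert membership_psqi(0.40)[0] == 1.0
        assert membership_psqi(0.25)[1] == 1.0
        assert membership_psqi(0.10)[2] == 1.0

    def test_corrected_ramp_midpoint(self):
        assert membership_psqi(0.30)[0] == pytest.approx(0.5)
        assert membership_psqi(0.20)[2] == pytest.approx(0.5)

    def test_literal_mode_keeps_printed_slopes(self):
        assert membership_psqi(0.30, "literal")[0] == pytest.approx(0.005)
        assert membership_psqi(0.20, "literal")[2] == pytest.approx(0.005)
        # discontinuity of the printed form at the plateau edge
        assert membership_psqi(0.35, "literal")[0] == 1.0

    @given(st.floats(0.0, 1.0))
    def test_range(self, p):
        for mode in ("continuity_corrected", "literal"):
            assert all(0.0 <= r <= 1.0 for r in membership_psqi(p, mode))


class TestKsqiMembership:
    @pytest.mark.parametrize("k,row", [
        (6.0, (1.0, 0.0, 0.0)), (5.0, (0.0, 0.0, 1.0)), (3.0, (0.0, 0.0, 1.0)),
    ])
    def test_rectangle(self, k, row):
        assert membership_ksqi(k) == row


class TestBassqiMembership:
    def test_anchor_points(self):
        assert membership_bassqi(92.0)[1] == 1.0
        assert membership_bassqi(90.0)[2] == pytest.approx(0.5)
        # printed alpha=0.8718 makes the rising branch continuous at 95
        assert membership_bassqi(95.0 - 1e-9)[0] == pytest.approx(0.95, abs=1e-3)
        assert membership_bassqi(95.0)[0] == pytest.approx(0.95)

    @given(st.floats(0.0, 100.0))
    def test_range_and_monotonicity(self, b):
        r_e, r_b, r_u = membership_bassqi(b)
        assert all(0.0 <= r <= 1.0 for r in (r_e, r_b, r_u))
        r_e2, _, r_u2 = membership_bassqi(min(100.0, b + 1.0))
        assert r_e2 >= r_e - 1e-12
        assert r_u2 <= r_u + 1e-12


class TestMatrixAndSynthesis:
    def test_saturating_rows(self):
        m = build_fuzzy_matrix(vec(q=100.0, p=0.40, k=7.0, b=1.0))
        np.testing.assert_allclose(m[:, 0], [1.0, 1.0, 1.0, 1.0])
        m = build_fuzzy_matrix(vec(q=50.0, p=0.05, k=3.0, b=0.5))
        np.testing.assert_allclose(m[:, 2], [1.0, 1.0, 1.0, 1.0])

    def test_undefined_propagates(self):
        with pytest.raises(UndefinedIndexError):
            build_fuzzy_matrix(vec(q=float("nan")))

    def test_bounded_sum_examples(self):
        w = (0.4, 0.4, 0.1, 0.1)
        all_e = np.tile([1.0, 0.0, 0.0], (4, 1))
        np.testing.assert_allclose(synthesize(w, all_e), [1.0, 0.0, 0.0])
        all_u = np.tile([0.0, 0.0, 1.0], (4, 1))
        np.testing.assert_allclose(synthesize(w, all_u), [0.0, 0.0, 1.0])
        mixed = np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        np.testing.assert_allclose(synthesize(w, mixed), [0.5, 0.4, 0.1])

    @given(st.integers(0, 10_000))
    def test_bound_never_bites_for_normalized_weights(self, seed):
        # with sum(w)=1 and r<=1 the bounded sum equals the weighted mean
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(4))
        r = rng.uniform(size=(4, 3))
        np.testing.assert_allclose(synthesize(w, r), w @ r, rtol=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            synthesize((0.5, 0.5), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            synthesize((0.4, 0.4, 0.1, 0.1), np.full((4, 3), 1.5))


class TestDecision:
    @pytest.mark.parametrize("s,v,label", [
        ((1.0, 0.0, 0.0), 1.0, "E"),
        ((0.0, 0.0, 1.0), 3.0, "U"),
        ((0.5, 0.4, 0.1), 1.428571, "E"),
    ])
    def test_examples(self, s, v, label):
        got_v, got_label = decide(s)
        assert got_v == pytest.approx(v, abs=1e-4)
        assert got_label == label

    def test_all_zero_reports_unacceptable(self):
        v, label = decide((0.0, 0.0, 0.0))
        assert (v, label) == (3.0, "U")

    @given(st.integers(0, 10_000))
    def test_score_range_and_row_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(4))
        r = rng.uniform(size=(4, 3))
        v, _ = decide(synthesize(w, r))
        assert 1.0 - 1e-9 <= v <= 3.0 + 1e-9
        perm = rng.permutation(4)
        v2, _ = decide(synthesize(w[perm], r[perm]))
        assert v2 == pytest.approx(v, rel=1e-12)


class TestRecommendation:
    def _grades(self, **kw):
        base = dict(qsqi="optimal", psqi="optimal", csqi="optimal",
                    ksqi="optimal", bassqi="optimal")
        base.update(kw)
        return SqiGradeVector(**base)

    def test_branches(self):
        assert recommend("E", self._grades()) == "accept"
        assert recommend("B", self._grades()) == "reassess"
        assert recommend("U", self._grades(ksqi="unqualified")) == "denoise_and_reassess"
        assert recommend("U", self._grades(bassqi="unqualified")) == "denoise_and_reassess"
        assert recommend("U", self._grades(qsqi="unqualified")) == "recollect"


class TestEndToEnd:
    def test_clean_is_excellent(self, clean_record, config):
        res = evaluate_segment(clean_record, config)
        assert res.label == "E" and res.recommendation == "accept"
        assert res.v < 1.5

    def test_heavy_emg_is_unacceptable(self, emg_heavy_labeled, config):
        res = evaluate_segment(emg_heavy_labeled.record, config)
        assert res.label == "U"
        assert res.recommendation in ("denoise_and_reassess", "recollect")

    def test_mild_drift_never_unacceptable(self, clean_labeled, config):
        # drift sized to land basSQI inside the suspicious band [0.90, 0.95]
        p_sig = float(np.mean((clean_labeled.record.samples
                               - clean_labeled.record.samples.mean()) ** 2))
        amp = float(np.sqrt(2 * 0.04 / 0.96 * p_sig))  # drift fraction ~4 %
        spec = dataclasses.replace(clean_labeled.spec,
                                   noise_amplitudes={"baseline_wander": amp})
        rec = add_noise(clean_labeled, spec).record
        res = evaluate_segment(rec, config)
        assert 0.90 <= res.sqis.bassqi <= 0.95
        assert res.label in ("E", "B")

    def test_flatline_reported_unacceptable(self, config):
        from ecgsqi.io import EcgRecord
        res = evaluate_segment(EcgRecord(np.zeros(9000), fs=300.0), config)
        assert res.label == "U" and res.v == 3.0

    def test_determinism(self, clean_record, config):
        r1 = evaluate_segment(clean_record, config)
        r2 = evaluate_segment(clean_record, config)
        assert r1.v == r2.v and r1.label == r2.label
        np.testing.assert_array_equal(r1.matrix, r2.matrix)
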