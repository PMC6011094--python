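import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecgsqi.io import EcgRecord, UndefinedIndexError
from ecgsqi.rpeaks import RPeakMatch, RPeakSet
from ecgsqi.sqi import (compute_all_sqis, compute_bassqi, compute_csqi,
                        compute_moments, compute_psqi, compute_qsqi,
                        estimate_spectrum, grade_bassqi, grade_csqi,
                        grade_ksqi, grade_psqi, grade_qsqi)
from ecgsqi.synthetic import SynthesisSpec, add_noise, generate_clean


def tone(freq_hz, fs=300.0, dur=30.0, amp=1.0, phase=0.0):
    t = np.arange(0, dur, 1 / fs)
    return EcgRecord(amp * np.sin(2 * np.pi * freq_hz * t + phase), fs=fs)


class TestQsqi:
    @pytest.mark.parametrize("n,na,nb,expect", [
        (30, 30, 30, 100.0),
        (9, 10, 10, 90.0),
        (0, 5, 3, 0.0),
    ])
    def test_values(self, n, na, nb, expect):
        assert compute_qsqi(RPeakMatch(n, na, nb, 0.15)) == expect

    def test_no_beats_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            compute_qsqi(RPeakMatch(0, 0, 0, 0.15))

    @pytest.mark.parametrize("q,grade", [
        (95.0, "optimal"), (90.0, "suspicious"), (60.0, "suspicious"),
        (59.9, "unqualified"), (0.0, "unqualified"), (100.0, "optimal"),
    ])
    def test_grades(self, q, grade):
        assert grade_qsqi(q) == grade


class TestSpectrumAndBands:
    def test_single_tone_concentration(self):
        spec = estimate_spectrum(tone(10.0))
        peak = spec.freqs[np.argmax(spec.power)]
        assert abs(peak - 10.0) <= 0.25
        # resolution requirement for the 0-1 Hz numerator
        assert np.max(np.diff(spec.freqs)) <= 0.25

    def test_white_noise_is_flat(self):
        rng = np.random.default_rng(3)
        rec = EcgRecord(rng.standard_normal(90000), fs=300.0)
        spec = estimate_spectrum(rec)
        lo = spec.band_power(5.0, 20.0) / 15.0
        hi = spec.band_power(20.0, 35.0) / 15.0
        assert abs(lo / hi - 1.0) < 0.1

    def test_too_short(self):
        with pytest.raises(Exception):
            estimate_spectrum(EcgRecord(np.zeros(500), fs=300.0))

    @pytest.mark.parametrize("freq,expect,tol", [
        (10.0, 1.0, 0.02), (30.0, 0.0, 0.02),
    ])
    def test_psqi_pure_tones(self, freq, expect, tol):
        assert compute_psqi(estimate_spectrum(tone(freq))) == pytest.approx(expect, abs=tol)

    def test_psqi_equal_tone_split(self):
        t = np.arange(0, 30.0, 1 / 300.0)
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 30 * t + 1.0)
        p = compute_psqi(estimate_spectrum(EcgRecord(x, fs=300.0)))
        assert p == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("freq,expect,tol", [
        (10.0, 1.0, 0.02), (0.3, 0.0, 0.05),
    ])
    def test_bassqi_pure_tones(self, freq, expect, tol):
        assert compute_bassqi(estimate_spectrum(tone(freq))) == pytest.approx(expect, abs=tol)

    def test_bassqi_equal_power_split(self):
        t = np.arange(0, 30.0, 1 / 300.0)
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 0.3 * t + 0.5)
        b = compute_bassqi(estimate_spectrum(EcgRecord(x, fs=300.0)))
        assert b == pytest.approx(0.5, abs=0.05)

    def test_zero_power_undefined(self):
        with pytest.raises(UndefinedIndexError):
            compute_bassqi(estimate_spectrum(EcgRecord(np.zeros(9000), fs=300.0)))


class TestPsqiGrading:
    @pytest.mark.parametrize("p,hr,grade", [
        (0.6, 80.0, "optimal"),
        (0.45, 80.0, "suspicious"),
        (0.85, 80.0, "unqualified"),
        (0.35, 80.0, "unqualified"),
        (0.45, 140.0, "optimal"),     # second band: l1=0.4
        (0.35, 140.0, "suspicious"),
    ])
    def test_bands(self, p, hr, grade):
        assert grade_psqi(p, hr) == grade

    def test_out_of_band_uses_nearest(self):
        assert grade_psqi(0.6, 40.0) == "optimal"    # nearest band 60-130
        assert grade_psqi(0.45, 200.0) == "optimal"  # nearest band 130-160


class TestCsqi:
    def _peaks(self, rr_s, fs=1000.0):
        times = np.concatenate([[0.0], np.cumsum(rr_s)])
        return RPeakSet(np.round(times * fs).astype(int), "hilbert_adaptive", fs)

    def test_constant_rr(self):
        assert compute_csqi(self._peaks([1.0] * 10)) == 0.0

    def test_hand_computed(self):
        # sample SD of (0.8, 1.0, 1.2) = 0.2, mean = 1.0
        assert compute_csqi(self._peaks([0.8, 1.0, 1.2])) == pytest.approx(0.2, rel=1e-6)

    def test_too_few_peaks(self):
        with pytest.raises(UndefinedIndexError):
            compute_csqi(self._peaks([1.0]))

    @pytest.mark.parametrize("c,grade", [
        (0.1, "optimal"), (0.45, "suspicious"), (0.5, "suspicious"),
        (0.64, "suspicious"), (0.7, "unqualified"),
    ])
    def test_grades(self, c, grade):
        assert grade_csqi(c) == grade


class TestMoments:
    def test_gaussian_kurtosis(self):
        rng = np.random.default_rng(12)
        rec = EcgRecord(rng.standard_normal(100_000), fs=1000.0)
        ssqi, ksqi = compute_moments(rec)
        assert ksqi == pytest.approx(3.0, abs=0.1)
        assert ssqi == pytest.approx(0.0, abs=0.1)

    def test_sinusoid_closed_form(self):
        ssqi, ksqi = compute_moments(tone(7.0, dur=100.0))
        assert ksqi == pytest.approx(1.5, abs=0.02)
        assert ssqi == pytest.approx(0.0, abs=0.02)

    def test_constant_undefined(self):
        with pytest.raises(UndefinedIndexError):
            compute_moments(EcgRecord(np.ones(100), fs=100.0))

    @given(st.integers(0, 10_000))
    def test_moment_inequality(self, seed):
        # kurtosis >= skewness^2 + 1 for any distribution
        rng = np.random.default_rng(seed)
        x = rng.gamma(shape=rng.uniform(0.2, 5.0), size=500)
        ssqi, ksqi = compute_moments(EcgRecord(x, fs=100.0))
        assert ksqi >= ssqi ** 2 + 1 - 1e-9

    @pytest.mark.parametrize("k,grade", [
        (7.2, "optimal"), (5.0, "unqualified"), (2.9, "unqualified"),
    ])
    def test_ksqi_grades(self, k, grade):
        assert grade_ksqi(k) == grade


class TestBassqiGrading:
    @pytest.mark.parametrize("b,grade", [
        (0.966, "optimal"), (0.95, "optimal"), (0.92, "suspicious"),
        (0.90, "suspicious"), (0.5, "unqualified"),
    ])
    def test_grades(self, b, grade):
        assert grade_bassqi(b) == grade


class TestFullExtraction:
    def test_clean_record_all_optimal(self, clean_record, config):
        sqis, grades = compute_all_sqis(clean_record, config)
        assert all(g == "optimal" for g in vars(grades).values())
        assert sqis.qsqi == 100.0
        assert 55.0 <= sqis.heart_rate_bpm <= 65.0

    def test_heavy_drift_fails_bassqi(self, clean_labeled, config):
        # drift amplitude set so drift power >= 1/3 of the total (Parseval)
        p_sig = float(np.mean((clean_labeled.record.samples
                               - clean_labeled.record.samples.mean()) ** 2))
        amp = float(np.sqrt(p_sig))  # a^2/2 = p_sig/2 -> drift fraction 1/3
        spec = dataclasses.replace(clean_labeled.spec,
                                   noise_amplitudes={"baseline_wander": amp})
        noisy = add_noise(clean_labeled, spec)
        sqis, grades = compute_all_sqis(noisy.record, config)
        assert sqis.bassqi < 0.9
        assert grades.bassqi == "unqualified"

    def test_flatline_all_unqualified(self, config):
        sqis, grades = compute_all_sqis(EcgRecord(np.zeros(9000), fs=300.0), config)
        assert all(g == "unqualified" for g in vars(grades).values())
        assert np.isnan(sqis.qsqi) and np.isnan(sqis.ksqi)

    def test_scale_invariance(self, clean_record, config):
        a, _ = compute_all_sqis(clean_record, config)
        scaled = EcgRecord(clean_record.samples * 12.5, fs=clean_record.fs)
        b, _ = compute_all_sqis(scaled, config)
        for k, v in a.as_dict().items():
            assert v == pytest.approx(b.as_dict()[k], rel=1e-9), k

    def test_monotone_noise_response(self, clean_labeled):
        """More drift -> lower basSQI; more muscle noise -> lower pSQI."""
        bas, psq = [], []
        for amp in (0.0, 0.1, 0.3, 0.9):
            s = dataclasses.replace(clean_labeled.spec,
                                    noise_amplitudes={"baseline_wander": amp})
            rec = add_noise(clean_labeled, s).record
            bas.append(compute_bassqi(estimate_spectrum(rec)))
        assert all(x > y for x, y in zip(bas, bas[1:]))
        for amp in (0.0, 0.2, 0.6, 1.5):
            s = dataclasses.replace(clean_labeled.spec,
                                    noise_amplitudes={"emg": amp})
            rec = add_noise(clean_labeled, s).record
            psq.append(compute_psqi(estimate_spectrum(rec)))
        assert all(x > y for x, y in zip(psq, psq[1:]))
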