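import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhrkit.fhr_detection import (
    EnhancedSignal,
    compute_fhr,
    detect_foetal_peaks,
    enhance_peaks,
    naive_threshold_peaks,
    threshold_norm,
)
from fhrkit.records import SignalRecord

from .oracles import literal_threshold_norm, trailing_mean_of_squared_diff

FS = 1000.0


def rec(x):
    return SignalRecord(np.asarray(x, dtype=float), FS)


def enhanced_from(sdm):
    sdm = np.asarray(sdm, dtype=float)
    inv_n = 1.0 / sdm.size
    m1 = 0.0
    for v in sdm:  # streamed mean, as the enhancement stage accumulates it
        m1 += float(v) * inv_n
    return EnhancedSignal(sdm=sdm, m1=m1, P=1, fs=FS)


class TestEnhancePeaks:
    def test_constant_input_gives_zero_envelope(self):
        es = enhance_peaks(rec(np.full(50, 2.5)), P=8)
        # the zero-initialised differentiator sees one artificial first step
        assert not es.sdm[9:].any()
        assert es.m1 == pytest.approx(es.sdm.mean())

    def test_unit_impulse_matches_windowed_mean_oracle(self):
        x = np.zeros(60)
        x[20] = 1.0
        for P in (1, 5, 40):
            es = enhance_peaks(rec(x), P=P)
            np.testing.assert_allclose(es.sdm, trailing_mean_of_squared_diff(x, P), atol=1e-12)
            if P >= 2:
                # sdiff is 1 at the impulse and 1 one sample later: where the
                # window covers both, the mean plateaus at 2/P
                assert es.sdm[21] == pytest.approx(2.0 / P)

    def test_ramp_settles_at_squared_slope(self):
        s = 0.3
        es = enhance_peaks(rec(s * np.arange(200.0)), P=10)
        assert es.sdm[-1] == pytest.approx(s * s, rel=1e-9)

    def test_envelope_is_nonnegative(self, rng):
        es = enhance_peaks(rec(rng.standard_normal(1000)), P=40)
        assert np.all(es.sdm >= 0)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            enhance_peaks(rec(np.zeros(5)), P=0)


class TestThresholdNorm:
    def test_worked_example(self):
        # sdm = [0,4,0,2,0,6,0,0]: m1 = 1.5; maxima latched at 1, 3, 5 and
        # emitted on the following below-mean samples; the counter trigger
        # happens after sample 6, where m2 has accumulated 4/8+2/8+6/8 = 1.5
        lm = threshold_norm(enhanced_from([0, 4, 0, 2, 0, 6, 0, 0]))
        assert lm.m1 == pytest.approx(1.5)
        np.testing.assert_array_equal(lm.pl, [1, 3, 5])
        np.testing.assert_allclose(lm.pv, [4.0, 2.0, 6.0])
        assert lm.m2 == pytest.approx(1.5)
        assert lm.th == pytest.approx(1.5)

    def test_all_zero_input(self):
        lm = threshold_norm(enhanced_from(np.zeros(32)))
        assert lm.th == 0.0 and lm.m1 == 0.0 and lm.m2 == 0.0
        assert lm.pl.size == 0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(c=st.floats(1e-3, 1e3), seed=st.integers(0, 2**16))
    def test_positive_scaling_homogeneity(self, c, seed):
        r = np.random.default_rng(seed)
        sdm = r.exponential(1.0, size=64)
        a = threshold_norm(enhanced_from(sdm))
        b = threshold_norm(enhanced_from(c * sdm))
        np.testing.assert_array_equal(a.pl, b.pl)
        assert b.th == pytest.approx(c * a.th, rel=1e-9)
        assert b.m1 == pytest.approx(c * a.m1, rel=1e-9)
        assert b.m2 == pytest.approx(c * a.m2, rel=1e-9)

    def test_matches_literal_pseudocode_oracle_on_random_sequences(self):
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            n = int(rng.integers(8, 5001))
            kind = rng.integers(0, 3)
            if kind == 0:
                sdm = rng.exponential(1.0, n)
            elif kind == 1:
                sdm = rng.uniform(0, 1, n) ** 2
            else:  # spiky, ECG-envelope-like
                sdm = 0.01 * rng.exponential(1.0, n)
                spikes = rng.integers(0, n, max(1, n // 100))
                sdm[spikes] += rng.uniform(1, 10, spikes.size)
            lm = threshold_norm(enhanced_from(sdm))
            o = literal_threshold_norm(sdm)
            assert lm.pl.tolist() == o["pl"]
            assert lm.pv.tolist() == pytest.approx(o["pv"], abs=0.0)
            assert lm.th == pytest.approx(o["th"], abs=0.0)
            assert lm.m2 == pytest.approx(o["m2"], abs=0.0)

    def test_threshold_at_least_half_mean(self, rng):
        for _ in range(50):
            sdm = rng.exponential(1.0, 256)
            lm = threshold_norm(enhanced_from(sdm))
            assert lm.th >= lm.m1 / 2 - 1e-15

    def test_streaming_variant_runs_and_agrees_on_clean_humps(self):
        # well-separated unimodal humps over a zero floor: both readings
        # latch the same maxima locations
        sdm = np.zeros(400)
        for c in (50, 150, 250, 350):
            sdm[c - 3 : c + 4] = [1, 4, 8, 9, 8, 4, 1]
        two_pass = threshold_norm(enhanced_from(sdm))
        streaming = threshold_norm(enhanced_from(sdm), streaming_m1=True)
        np.testing.assert_array_equal(two_pass.pl, streaming.pl)


class TestDetectFoetalPeaks:
    def make(self, pl, pv, th):
        return type(
            "LM", (), {"pl": np.asarray(pl, dtype=np.int64), "pv": np.asarray(pv, float), "th": th}
        )()

    def test_all_within_one_refractory_window_largest_wins(self):
        lm = self.make([1, 3, 5], [4.0, 2.0, 6.0], 1.5)
        np.testing.assert_array_equal(detect_foetal_peaks(lm, 200), [5])

    def test_isolated_maxima_all_kept(self):
        lm = self.make([100, 600, 1100], [5.0, 5.0, 5.0], 1.0)
        np.testing.assert_array_equal(detect_foetal_peaks(lm, 200), [100, 600, 1100])

    def test_close_pair_resolved_then_isolated_kept(self):
        lm = self.make([100, 150, 600], [5.0, 9.0, 4.0], 3.0)
        np.testing.assert_array_equal(detect_foetal_peaks(lm, 200), [150, 600])

    def test_below_threshold_maxima_ignored(self):
        lm = self.make([100, 600], [0.5, 0.4], 1.0)
        assert detect_foetal_peaks(lm, 200).size == 0

    def test_returned_peaks_respect_refractory_spacing(self, rng):
        pl = np.sort(rng.choice(50_000, size=300, replace=False))
        pv = rng.exponential(1.0, 300)
        lm = self.make(pl, pv, float(np.median(pv)))
        out = detect_foetal_peaks(lm, 200)
        if out.size > 1:
            assert np.all(np.diff(out) > 200)

    def test_naive_thresholding_keeps_every_candidate(self):
        lm = self.make([100, 150, 600], [5.0, 9.0, 4.0], 3.0)
        np.testing.assert_array_equal(
            naive_threshold_peaks(lm, threshold=3.0), [100, 150, 600]
        )


class TestComputeFHR:
    def test_exact_half_second_spacing_gives_120_bpm(self):
        r = compute_fhr(np.array([12000, 12500, 13000]), fs=1000.0, burn_in=12000)
        np.testing.assert_allclose(r.rr_s, [0.5, 0.5])
        assert r.fhr_bpm == pytest.approx(120.0)

    def test_400_sample_spacing_gives_150_bpm(self):
        peaks = np.arange(12000, 30000, 400)
        r = compute_fhr(peaks, fs=1000.0, burn_in=12000)
        assert r.fhr_bpm == pytest.approx(150.0)

    def test_single_qualifying_peak_is_undefined(self):
        r = compute_fhr(np.array([500, 13000]), fs=1000.0, burn_in=12000)
        assert r.fhr_bpm is None and not r.defined

    def test_burn_in_excludes_early_peaks(self):
        # early (pre-burn-in) peaks at odd spacing must not affect the rate
        peaks = np.concatenate([[100, 137, 542], np.arange(12000, 20000, 500)])
        r = compute_fhr(peaks, fs=1000.0, burn_in=12000)
        assert r.fhr_bpm == pytest.approx(120.0)
        assert np.all(r.peaks_used >= 12000)
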