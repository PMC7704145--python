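import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from fhrkit.preprocessing import (
    PAPER_LOWPASS,
    PAPER_NOTCH,
    IIRCoefficients,
    butterworth_lowpass,
    design_filters,
    notch,
    preprocess,
    remove_baseline,
)
from fhrkit.records import SignalRecord

from .oracles import nested_double_sum_baseline

FS = 1000.0


def rec(samples, fs=FS):
    return SignalRecord(np.asarray(samples, dtype=float), fs)


class TestRecurrences:
    def test_zero_input_gives_zero_output(self):
        z = rec(np.zeros(100))
        assert not butterworth_lowpass(z, PAPER_LOWPASS).samples.any()
        assert not notch(z, PAPER_NOTCH).samples.any()

    def test_lowpass_step_response_reaches_closed_form(self):
        c = PAPER_LOWPASS
        out = butterworth_lowpass(rec(np.ones(6000)), c).samples
        expected = c.alpha / (1 - c.beta - c.gamma - c.delta - c.epsilon)
        assert out[-1] == pytest.approx(expected, rel=1e-9)

    def test_lowpass_attenuates_50hz(self):
        # |H| at 50 Hz from the recurrence constants themselves
        assert PAPER_LOWPASS.response_at(50.0, FS) < 1.0

    def test_notch_constant_input_steady_state(self):
        c = PAPER_NOTCH
        out = notch(rec(np.ones(5000)), c).samples
        expected = (c.alpha + c.beta + c.gamma) / (1 - c.delta - c.epsilon)
        assert out[-1] == pytest.approx(expected, rel=1e-9)

    def test_notch_kills_its_own_zero_frequency(self):
        # the numerator has alpha == gamma, so its zeros sit on the unit
        # circle at omega0 = arccos(-beta / (2 alpha)); |H| there is ~0
        c = PAPER_NOTCH
        w0 = np.arccos(-c.beta / (2 * c.alpha))
        _, h = sps.freqz(c.b, c.a, worN=[w0])
        assert abs(h[0]) < 1e-10
        t = np.arange(30000)
        out = notch(rec(np.sin(w0 * t)), c).samples
        tail_rms = np.sqrt(np.mean(out[-5000:] ** 2))
        assert tail_rms < 10 ** (-40 / 20) / np.sqrt(2)  # >40 dB down

    def test_recurrences_match_transposed_direct_form_reference(self, rng):
        # independent reference: transposed direct-form II state recursion
        def tdf2(b, a, x):
            nb, na = len(b), len(a)
            order = max(nb, na) - 1
            bb = np.concatenate([b, np.zeros(order + 1 - nb)])
            aa = np.concatenate([a, np.zeros(order + 1 - na)])
            z = np.zeros(order)
            y = np.empty_like(x)
            for i, xi in enumerate(x):
                yi = bb[0] * xi + z[0]
                for k in range(order - 1):
                    z[k] = bb[k + 1] * xi + z[k + 1] - aa[k + 1] * yi
                z[order - 1] = bb[order] * xi - aa[order] * yi
                y[i] = yi
            return y

        x = rng.standard_normal(10_000)
        for c, op in ((PAPER_LOWPASS, butterworth_lowpass), (PAPER_NOTCH, notch)):
            ours = op(rec(x), c).samples
            ref = tdf2(c.b, c.a, x)
            scale = np.max(np.abs(ref))
            assert np.max(np.abs(ours - ref)) / scale < 1e-9

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError):
            butterworth_lowpass(rec(np.ones(4)), PAPER_NOTCH)

    def test_unstable_coefficients_rejected_at_construction(self):
        with pytest.raises(ValueError, match="unstable"):
            IIRCoefficients(1.0, 0.0, 0.0, 2.0, -0.5, "notch_recurrence")
        with pytest.raises(ValueError):
            IIRCoefficients(1.0, np.nan, 0.0, 0.0, 0.0, "notch_recurrence")


class TestDesign:
    def test_paper_mode_reproduces_printed_constants_exactly(self):
        lpf, ntc = design_filters(1000.0, mode="auto")
        assert (lpf.alpha, lpf.beta, lpf.gamma, lpf.delta, lpf.epsilon) == (
            0.00308, 3.28391, -4.08689, 2.28117, -0.48140,
        )
        assert (ntc.alpha, ntc.beta, ntc.gamma, ntc.delta, ntc.epsilon) == (
            0.99405, -1.31278, 0.99405, 1.31272, -0.98804,
        )
        assert design_filters(250.0, mode="paper") == (lpf, ntc)

    @pytest.mark.parametrize("fs", [250.0, 500.0, 1000.0])
    def test_designed_notch_attenuates_50hz(self, fs):
        _, ntc = design_filters(fs, mode="designed")
        assert ntc.response_at(50.0, fs) < 0.01

    def test_designed_lowpass_unit_dc_gain(self):
        lpf, _ = design_filters(1000.0, mode="designed")
        assert lpf.dc_gain() == pytest.approx(1.0, rel=0.05)

    def test_too_low_fs_rejected(self):
        with pytest.raises(ValueError):
            design_filters(100.0, mode="designed")


class TestBaselineRemoval:
    def test_constant_input_fully_removed_after_warmup(self):
        cleaned, baseline = remove_baseline(rec(np.full(1200, 3.7)), 200, 200)
        assert baseline.samples[-1] == pytest.approx(3.7, rel=1e-12)
        assert abs(cleaned.samples[-1]) < 1e-9

    def test_matches_nested_double_sum_oracle(self, rng):
        x = rng.standard_normal(300)
        for n1, n2 in [(1, 1), (7, 3), (40, 40)]:
            cleaned, baseline = remove_baseline(rec(x), n1, n2)
            oc, ob = nested_double_sum_baseline(x, n1, n2)
            np.testing.assert_allclose(baseline.samples, ob, atol=1e-12)
            np.testing.assert_allclose(cleaned.samples, oc, atol=1e-12)

    def test_45hz_sinusoid_averages_out_of_baseline(self):
        # 9 full cycles fit in the 200-sample window, so the baseline
        # estimate reduces to the DC offset
        t = np.arange(3000) / FS
        c = 0.8
        x = c + 0.5 * np.sin(2 * np.pi * 45.0 * t)
        _, baseline = remove_baseline(rec(x), 200, 200)
        assert np.max(np.abs(baseline.samples[500:] - c)) < 0.01 * 0.5

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, a, b, seed):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal((2, 120))
        fx, _ = remove_baseline(rec(x), 20, 10)
        fy, _ = remove_baseline(rec(y), 20, 10)
        fxy, _ = remove_baseline(rec(a * x + b * y), 20, 10)
        np.testing.assert_allclose(fxy.samples, a * fx.samples + b * fy.samples, atol=1e-9)

    def test_window_size_must_be_positive(self):
        with pytest.raises(ValueError):
            remove_baseline(rec(np.ones(10)), 0, 5)


def test_full_chain_attenuates_interference_but_keeps_r_peaks(sim_recording):
    """Preprocessing removes 50 Hz strongly, reduces the baseline band, and
    leaves maternal R-peak amplitudes roughly intact."""
    fs = sim_recording.fs
    lpf, ntc = design_filters(fs, mode="designed")
    raw = sim_recording.abdominal
    out = preprocess(raw, lpf, ntc, 200, 200)

    def band_power(sig, lo, hi):
        f, p = sps.periodogram(sig, fs=fs)
        return p[(f >= lo) & (f <= hi)].sum()

    # 50 Hz powerline: > 20 dB down
    assert band_power(out.samples, 49, 51) < 1e-2 * band_power(raw.samples, 49, 51)
    # baseline band (the trailing subtraction has ~0.2 s lag, limiting the
    # attenuation of a 0.3 Hz drift to roughly 8-9 dB): > 6 dB down
    assert band_power(out.samples, 0.0, 0.7) < 0.25 * band_power(raw.samples, 0.0, 0.7)
    # maternal R peaks survive within 20%
    peaks = sim_recording.maternal_peaks
    sel = peaks[(peaks > 1000) & (peaks < raw.n - 50)]
    amp_raw = np.median([np.max(np.abs(raw.samples[p - 30 : p + 30])) for p in sel])
    amp_out = np.median([np.max(np.abs(out.samples[p - 30 : p + 30])) for p in sel])
    assert abs(amp_out - amp_raw) / amp_raw < 0.20
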