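"""ECG preprocessing: low-pass, powerline notch, baseline-wander removal.

The chain mirrors a streaming hardware realisation: every filter is causal,
runs with zero initial conditions, and is length-preserving.  Two IIR
recurrences are used —

* a 4th-order Butterworth low-pass (45 Hz cut-off) collapsed to a single
  feedforward term::

      O[k] = a*I[k] + b*O[k-1] + g*O[k-2] + d*O[k-3] + e*O[k-4]

* a two-pole notch (50 Hz, Q = 25)::

      O[k] = a*I[k] + b*I[k-1] + g*I[k-2] + d*O[k-1] + e*O[k-2]

— followed by subtraction of a two-stage trailing moving average (window
sizes N1, N2) that approximates the baseline wander.

Two coefficient sets are supported for the recurrences: the fixed reference
constants of the original hardware design (valid at fs = 1 kHz; note their
notch zeros actually sit near 135 Hz, see docs/methods.md) and coefficients
designed with :mod:`scipy.signal` for the actual sampling frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps

from .records import SignalRecord

__all__ = [
    "IIRCoefficients",
    "PAPER_LOWPASS",
    "PAPER_NOTCH",
    "design_filters",
    "butterworth_lowpass",
    "notch",
    "remove_baseline",
    "preprocess",
]

FilterKind = Literal["lowpass_recurrence", "notch_recurrence"]


@dataclass(frozen=True)
class IIRCoefficients:
    """Recurrence constants of one preprocessing IIR stage.

    For ``lowpass_recurrence`` the transfer function is
    ``alpha / (1 - beta z^-1 - gamma z^-2 - delta z^-3 - epsilon z^-4)``;
    for ``notch_recurrence`` it is
    ``(alpha + beta z^-1 + gamma z^-2) / (1 - delta z^-1 - epsilon z^-2)``.
    BIBO stability (all feedback roots strictly inside the unit circle) is
    checked at construction.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    epsilon: float
    kind: FilterKind

    def __post_init__(self) -> None:
        vals = (self.alpha, self.beta, self.gamma, self.delta, self.epsilon)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("IIR coefficients must be finite")
        if self.kind not in ("lowpass_recurrence", "notch_recurrence"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        roots = np.roots(self.a)
        if roots.size and np.max(np.abs(roots)) >= 1.0:
            raise ValueError(
                f"unstable {self.kind}: feedback root magnitude "
                f"{np.max(np.abs(roots)):.6f} >= 1"
            )

    @property
    def b(self) -> np.ndarray:
        """Feedforward (numerator) polynomial for :func:`scipy.signal.lfilter`."""
        if self.kind == "lowpass_recurrence":
            return np.array([self.alpha])
        return np.array([self.alpha, self.beta, self.gamma])

    @property
    def a(self) -> np.ndarray:
        """Feedback (denominator) polynomial, leading 1."""
        if self.kind == "lowpass_recurrence":
            return np.array([1.0, -self.beta, -self.gamma, -self.delta, -self.epsilon])
        return np.array([1.0, -self.delta, -self.epsilon])

    def dc_gain(self) -> float:
        return float(np.sum(self.b) / np.sum(self.a))

    def response_at(self, freq_hz: float, fs: float) -> float:
        """|H| evaluated at one frequency (Hz) for sampling rate fs."""
        _, h = sps.freqz(self.b, self.a, worN=[2.0 * np.pi * freq_hz / fs])
        return float(np.abs(h[0]))


#: Reference hardware constants (fs = 1 kHz design).
PAPER_LOWPASS = IIRCoefficients(0.00308, 3.28391, -4.08689, 2.28117, -0.48140, "lowpass_recurrence")
PAPER_NOTCH = IIRCoefficients(0.99405, -1.31278, 0.99405, 1.31272, -0.98804, "notch_recurrence")

LOWPASS_CUTOFF_HZ = 45.0
NOTCH_FREQ_HZ = 50.0
NOTCH_Q = 25.0


def design_filters(
    fs: float, mode: Literal["auto", "designed", "paper"] = "auto"
) -> tuple[IIRCoefficients, IIRCoefficients]:
    """Return (low-pass, notch) recurrence coefficients for sampling rate fs.

    ``mode="paper"`` returns the fixed reference constants regardless of fs;
    ``mode="designed"`` designs a 45 Hz 4th-order Butterworth (feedforward
    terms summed into a single alpha, so the DC gain is exactly 1) and a
    50 Hz / Q=25 notch for the given fs; ``mode="auto"`` uses the reference
    constants at fs = 1000 and designs otherwise.
    """
    if mode == "paper" or (mode == "auto" and fs == 1000.0):
        return PAPER_LOWPASS, PAPER_NOTCH
    if fs <= 2.0 * (NOTCH_FREQ_HZ + 5.0):
        raise ValueError(f"fs={fs} Hz too low to place a 50 Hz notch (need > 110 Hz)")
    b, a = sps.butter(4, LOWPASS_CUTOFF_HZ, fs=fs)
    lpf = IIRCoefficients(float(np.sum(b)), -a[1], -a[2], -a[3], -a[4], "lowpass_recurrence")
    bn, an = sps.iirnotch(NOTCH_FREQ_HZ, NOTCH_Q, fs=fs)
    ntc = IIRCoefficients(bn[0], bn[1], bn[2], -an[1], -an[2], "notch_recurrence")
    return lpf, ntc


def _apply(x: SignalRecord, c: IIRCoefficients, kind: FilterKind) -> SignalRecord:
    if c.kind != kind:
        raise ValueError(f"expected {kind} coefficients, got {c.kind}")
    return x.with_samples(sps.lfilter(c.b, c.a, x.samples))


def butterworth_lowpass(x: SignalRecord, c: IIRCoefficients) -> SignalRecord:
    """Causal 5-term low-pass recurrence, zero initial conditions."""
    return _apply(x, c, "lowpass_recurrence")


def notch(x: SignalRecord, c: IIRCoefficients) -> SignalRecord:
    """Causal biquad notch recurrence, zero initial conditions."""
    return _apply(x, c, "notch_recurrence")


def remove_baseline(
    x: SignalRecord, n1: int, n2: int
) -> tuple[SignalRecord, SignalRecord]:
    """Subtract the two-stage trailing moving average from the signal.

    The first stage M1[n] is the mean of the last ``n1`` inputs, the second
    stage M2[n] the mean of the last ``n2`` values of M1; both memories start
    at zero (streaming semantics), and M2 is subtracted from the *current*
    sample with no delay compensation.  Returns ``(cleaned, baseline)``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("moving-average window sizes must be >= 1")
    m1 = sps.lfilter(np.ones(n1) / n1, [1.0], x.samples)
    m2 = sps.lfilter(np.ones(n2) / n2, [1.0], m1)
    return x.with_samples(x.samples - m2), x.with_samples(m2, label=f"{x.label}:baseline")


def preprocess(
    x: SignalRecord,
    lpf: IIRCoefficients,
    ntc: IIRCoefficients,
    n1: int,
    n2: int,
) -> SignalRecord:
    """Full chain: low-pass, notch, baseline-wander removal (in that order)."""
    y = butterworth_lowpass(x, lpf)
    y = notch(y, ntc)
    cleaned, _ = remove_baseline(y, n1, n2)
    return cleaned
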