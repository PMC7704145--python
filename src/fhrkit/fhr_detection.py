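"""Fetal R-peak detection and heart-rate computation.

The extracted signal e[n] is differentiated, squared and mean-filtered
(window P) into a nonnegative envelope ``sdm`` in which fetal R peaks —
sharper than the residual maternal ones — dominate.  A single record-wide
threshold is then derived by the *threshold norm*: local maxima of sdm above
its mean m1 are latched sample-by-sample, every sample below m1 accumulates
the currently latched maximum value pv into m2 (scaled by 1/N), and when the
sample counter reaches N-1 the threshold latches as th = (m1 + m2)/2.

Maxima above th are finally filtered by a refractory rule: of two maxima
closer than the refractory window (200 samples at 1 kHz), the larger one is
kept.  FHR is 60 over the mean RR interval of the accepted peaks occurring
after the burn-in period during which the canceller is still converging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import SignalRecord

__all__ = [
    "EnhancedSignal",
    "LocalMaxima",
    "FHRResult",
    "enhance_peaks",
    "threshold_norm",
    "detect_foetal_peaks",
    "naive_threshold_peaks",
    "compute_fhr",
]


@dataclass(frozen=True)
class EnhancedSignal:
    """Differentiated-squared-mean-filtered detection envelope."""

    sdm: np.ndarray
    m1: float
    P: int
    fs: float

    @property
    def n(self) -> int:
        return int(self.sdm.size)


@dataclass(frozen=True)
class LocalMaxima:
    """Latched local maxima of sdm and the record-wide threshold."""

    pl: np.ndarray  # locations (sample indices)
    pv: np.ndarray  # values at those locations
    th: float
    m1: float
    m2: float  # accumulated statistic at the threshold trigger


@dataclass(frozen=True)
class FHRResult:
    """Accepted fetal R peaks and the heart rate they imply."""

    peaks: np.ndarray
    rr_s: np.ndarray
    fhr_bpm: float | None
    #: peaks at or after the burn-in index, used for the RR intervals
    peaks_used: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def defined(self) -> bool:
        return self.fhr_bpm is not None


def enhance_peaks(e: SignalRecord, P: int) -> EnhancedSignal:
    """Square the first difference and mean-filter it over P samples.

    The differentiator's previous-value register and the P-sample mean
    memory start at zero, so sdiff[0] = e[0]^2 and the mean window is
    trailing.  m1 is the mean of sdm over the whole record.
    """
    if P < 1:
        raise ValueError("mean-filter length P must be >= 1")
    diff = np.diff(e.samples, prepend=0.0)
    sdiff = diff * diff
    sdm = sps.lfilter(np.ones(P) / P, [1.0], sdiff)
    # m1 is accumulated exactly as the streamed datapath does it: each sample
    # multiplied by the reciprocal constant 1/N and added in stream order.
    inv_n = 1.0 / sdm.size
    m1 = 0.0
    for v in sdm * inv_n:
        m1 += float(v)
    return EnhancedSignal(sdm=sdm, m1=m1, P=P, fs=e.fs)


def threshold_norm(es: EnhancedSignal, streaming_m1: bool = False) -> LocalMaxima:
    """Latch local maxima of sdm above m1 and derive the single threshold.

    Per sample (in = sdm[n], R1 = previous sample, R2 = sample counter,
    all state zero-initialised):

    1. if in > m1 and in > R1:  latch R3 = in, R4 = R2
    2. elif in < m1:            pv, pl = R3, R4 and m2 += pv / N
    3. R1 = in;  R2 += 1
    4. when R2 == N - 1:        th = (m1 + m2) / 2

    The emission in step 2 repeats on every sample below m1; a latched
    maximum is *recorded* (into pl/pv) only on its first emission.  The
    default uses the whole-record mean m1 computed up front (two-pass);
    ``streaming_m1=True`` instead accumulates m1 on the fly exactly as a
    single-pass streaming datapath would, comparing against the partial mean.
    """
    x = es.sdm
    n = x.size
    if streaming_m1:
        return _threshold_norm_streaming(x, n, es.fs)
    m1 = es.m1

    prev = np.concatenate(([0.0], x[:-1]))  # R1 before each sample
    latch = np.nonzero((x > m1) & (x > prev))[0]
    below = x < m1

    # R3/R4 at sample k = value/location of the most recent latch <= k.
    # seg[k] = number of latches at indices <= k, so seg-1 indexes the latch.
    if latch.size:
        seg = np.searchsorted(latch, np.arange(n), side="right") - 1
        r3 = np.where(seg >= 0, x[latch[np.maximum(seg, 0)]], 0.0)
    else:
        r3 = np.zeros(n)

    # m2 accumulates pv/N on every below-mean sample, in stream order; the
    # counter reaches N-1 after processing sample N-2, which latches th.
    # The sum is accumulated sequentially (not pairwise) to reproduce the
    # streamed datapath bit-for-bit.
    stop = n - 1 if n >= 2 else n
    idx = np.nonzero(below[:stop])[0]
    m2_trigger = 0.0
    for v in r3[idx] * (1.0 / n):
        m2_trigger += float(v)
    th = (m1 + m2_trigger) / 2.0

    # A latch is recorded the first time a below-m1 sample follows it.
    pl_list, pv_list = [], []
    for i, li in enumerate(latch):
        nxt = latch[i + 1] if i + 1 < latch.size else n
        if np.any(below[li + 1 : nxt]):
            pl_list.append(li)
            pv_list.append(x[li])
    return LocalMaxima(
        pl=np.asarray(pl_list, dtype=np.int64),
        pv=np.asarray(pv_list, dtype=np.float64),
        th=float(th),
        m1=float(m1),
        m2=m2_trigger,
    )


def _threshold_norm_streaming(x: np.ndarray, n: int, fs: float) -> LocalMaxima:
    # Single-pass variant: m1 grows by in/N each cycle and comparisons use
    # the partial mean, mirroring a streaming hardware datapath.
    inv_n = 1.0 / n
    m1 = 0.0
    m2 = 0.0
    r1 = 0.0
    r3 = 0.0
    r4 = 0
    th = None
    latched_fresh = False
    pl_list: list[int] = []
    pv_list: list[float] = []
    for k in range(n):
        cur = x[k]
        m1 += cur * inv_n
        if cur > m1 and cur > r1:
            r3, r4 = cur, k
            latched_fresh = True
        elif cur < m1:
            m2 += r3 * inv_n
            if latched_fresh:
                pl_list.append(r4)
                pv_list.append(r3)
                latched_fresh = False
        r1 = cur
        if k == n - 2:
            th = (m1 + m2) / 2.0
    m2_trigger = m2 if th is not None else m2
    if th is None:
        th = (m1 + m2) / 2.0
    return LocalMaxima(
        pl=np.asarray(pl_list, dtype=np.int64),
        pv=np.asarray(pv_list, dtype=np.float64),
        th=float(th),
        m1=float(m1),
        m2=float(m2_trigger),
    )


def detect_foetal_peaks(lm: LocalMaxima, refractory: int) -> np.ndarray:
    """Refractory selection among the above-threshold maxima.

    R1/R2 hold the pending peak's location/value, initialised from the first
    maximum with pv > th.  A later maximum beyond the refractory window
    commits the pending peak and becomes pending itself; within the window
    the larger of the two survives as pending.  The final pending peak is
    committed at stream end, so consecutive returned peaks are always more
    than ``refractory`` samples apart.
    """
    keep = lm.pv > lm.th
    pl, pv = lm.pl[keep], lm.pv[keep]
    if pl.size == 0:
        return np.empty(0, dtype=np.int64)
    out: list[int] = []
    r1, r2 = int(pl[0]), float(pv[0])
    for loc, val in zip(pl[1:], pv[1:]):
        if loc - r1 > refractory:
            out.append(r1)
            r1, r2 = int(loc), float(val)
        elif val > r2:
            r1, r2 = int(loc), float(val)
    out.append(r1)
    return np.asarray(out, dtype=np.int64)


def naive_threshold_peaks(lm: LocalMaxima, threshold: float | None = None) -> np.ndarray:
    """Plain global-maximum thresholding with no refractory rule.

    Every local maximum of the envelope above a single global threshold
    (default: the envelope mean m1, the signal threshold a single-subject
    QRS detector would apply to its integrated waveform) is reported as a
    peak.  This is the comparison baseline that the two-statistic threshold
    and the refractory "larger wins" rule improve on: residual maternal
    bumps and noise maxima above the mean all become detections here.
    """
    thr = lm.m1 if threshold is None else threshold
    return lm.pl[lm.pv > thr].astype(np.int64)


def compute_fhr(peaks: np.ndarray, fs: float, burn_in: int) -> FHRResult:
    """FHR = 60 / mean RR(s) over peaks at or after the burn-in index.

    With fewer than two qualifying peaks the rate is undefined
    (``fhr_bpm is None``).
    """
    peaks = np.asarray(peaks, dtype=np.int64)
    used = peaks[peaks >= burn_in]
    if used.size < 2:
        return FHRResult(peaks=peaks, rr_s=np.empty(0), fhr_bpm=None, peaks_used=used)
    rr = np.diff(used) / fs
    return FHRResult(
        peaks=peaks,
        rr_s=rr,
        fhr_bpm=float(60.0 / rr.mean()),
        peaks_used=used,
    )
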