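"""Core in-memory containers shared by all pipeline stages.

A :class:`SignalRecord` is the package's universal currency: one uniformly
sampled channel with its sampling frequency.  An :class:`AnnotatedRecording`
bundles the thoracic/abdominal channel pair with ground-truth R-peak
annotations, as produced by the simulator and consumed by the evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SignalRecord", "AnnotatedRecording"]


@dataclass(frozen=True)
class SignalRecord:
    """A single uniformly sampled channel.

    Parameters
    ----------
    samples:
        Real amplitudes (arbitrary units; the synthetic data are unitless).
    fs:
        Sampling frequency in Hz, strictly positive.
    label:
        Channel name, e.g. ``"thoracic"`` or ``"abdominal"``.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"channel {self.label!r} contains NaN/Inf samples")
        if not (self.fs > 0):
            raise ValueError(f"sampling frequency must be > 0, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based grid)."""
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "SignalRecord":
        """A new record at the same fs (stages are length-preserving)."""
        return SignalRecord(samples, self.fs, self.label if label is None else label)


def _check_peaks(peaks: np.ndarray, n: int, name: str) -> np.ndarray:
    peaks = np.asarray(peaks, dtype=np.int64)
    if peaks.size:
        if np.any(np.diff(peaks) <= 0):
            raise ValueError(f"{name} indices must be strictly increasing")
        if peaks[0] < 0 or peaks[-1] >= n:
            raise ValueError(f"{name} indices must lie in [0, {n})")
    return peaks


@dataclass(frozen=True)
class AnnotatedRecording:
    """A thoracic/abdominal channel pair with ground-truth annotations.

    ``foetal_peaks`` / ``maternal_peaks`` are sorted 0-based sample indices of
    the true R peaks; both are empty for recordings read from plain files.
    ``true_fhr_bpm`` is the simulator's nominal foetal rate, if known.
    """

    thoracic: SignalRecord
    abdominal: SignalRecord
    foetal_peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    maternal_peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    true_fhr_bpm: float | None = None

    def __post_init__(self) -> None:
        if self.thoracic.fs != self.abdominal.fs:
            raise ValueError(
                f"sampling-frequency mismatch: thoracic {self.thoracic.fs} Hz "
                f"vs abdominal {self.abdominal.fs} Hz"
            )
        if self.thoracic.n != self.abdominal.n:
            raise ValueError(
                f"length mismatch: thoracic has {self.thoracic.n} samples, "
                f"abdominal has {self.abdominal.n}"
            )
        n = self.thoracic.n
        object.__setattr__(self, "foetal_peaks", _check_peaks(self.foetal_peaks, n, "foetal_peaks"))
        object.__setattr__(
            self, "maternal_peaks", _check_peaks(self.maternal_peaks, n, "maternal_peaks")
        )

    @property
    def fs(self) -> float:
        return self.thoracic.fs

    @property
    def n(self) -> int:
        return self.thoracic.n
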