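"""Signal/annotation I/O, pipeline configuration, and the end-to-end driver.

Signals travel as delimited text (one value per line, or two columns of
time,value; a non-numeric header row is skipped).  WFDB records are
supported as an optional input path when the ``wfdb`` package is installed.
:func:`run_pipeline` chains every stage — preprocessing of both channels,
channel scaling, LMS extraction, peak enhancement, the threshold norm,
refractory peak selection and FHR computation — and returns all
intermediates for inspection.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import fhr_detection, lms_extraction, preprocessing
from .fhr_detection import EnhancedSignal, FHRResult, LocalMaxima
from .lms_extraction import LMSTrace
from .preprocessing import IIRCoefficients
from .records import AnnotatedRecording, SignalRecord

__all__ = [
    "PipelineConfig",
    "DetectionResult",
    "read_signal",
    "read_recording",
    "write_signal",
    "write_result",
    "read_peaks",
    "write_peaks",
    "run_pipeline",
]


class ParseError(ValueError):
    """A delimited-text file contained a non-numeric row."""


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the detection chain, durations in seconds.

    Window durations are converted to samples with round(seconds * fs), so
    the 1 kHz defaults give the reference sample counts exactly (N1 = N2 =
    200, P = 40, refractory 200, burn-in 12,000) while remaining correct at
    other sampling rates.
    """

    baseline_window_s: float = 0.2
    lms_order: int = 19
    lms_mu: float = 7e-5
    mean_filter_s: float = 0.04
    refractory_s: float = 0.2
    burn_in_s: float = 12.0
    match_tolerance_s: float = 0.05
    scaling_mode: str = "unit_rms"
    fixed_gains: tuple[float, float] | None = None
    #: True selects the thoracic-as-desired assignment (d = thoracic,
    #: x = abdominal) instead of the default classical noise-canceller
    #: assignment (d = abdominal, x = thoracic reference)
    swap_channels: bool = False
    #: "designed" fits the 45 Hz low-pass and 50 Hz notch to fs; "paper"
    #: uses the fixed reference constants; "auto" = paper at 1 kHz
    coeff_mode: str = "designed"
    lpf_coeffs: IIRCoefficients | None = None
    notch_coeffs: IIRCoefficients | None = None

    def __post_init__(self) -> None:
        for name in ("baseline_window_s", "mean_filter_s", "refractory_s",
                     "burn_in_s", "match_tolerance_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lms_order < 1:
            raise ValueError("lms_order must be >= 1")
        if self.lms_mu <= 0:
            raise ValueError("lms_mu must be > 0")

    def samples(self, duration_s: float, fs: float) -> int:
        return max(1, int(round(duration_s * fs)))

    def coefficients(self, fs: float) -> tuple[IIRCoefficients, IIRCoefficients]:
        if self.lpf_coeffs is not None and self.notch_coeffs is not None:
            return self.lpf_coeffs, self.notch_coeffs
        return preprocessing.design_filters(fs, mode=self.coeff_mode)

    # -- flat key/value config files ------------------------------------
    def to_file(self, path: str | Path, fs: float | None = None) -> None:
        """Dump as flat ``key = value`` text, including resolved coefficients."""
        lines = []
        for f in fields(self):
            if f.name in ("lpf_coeffs", "notch_coeffs", "fixed_gains"):
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        if fs is not None:
            lpf, ntc = self.coefficients(fs)
            for prefix, c in (("lpf", lpf), ("notch", ntc)):
                for k in ("alpha", "beta", "gamma", "delta", "epsilon"):
                    lines.append(f"{prefix}_{k} = {getattr(c, k)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat key/value file; missing keys keep their defaults."""
        kwargs: dict[str, object] = {}
        coeff: dict[str, float] = {}
        valid = {f.name: f for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            if key.startswith(("lpf_", "notch_")) and key not in valid:
                coeff[key] = float(val)
                continue
            if key not in valid:
                raise ParseError(f"{path}:{lineno}: unknown key {key!r}")
            if key in ("scaling_mode", "coeff_mode"):
                kwargs[key] = val.strip("'\"")
            elif key == "swap_channels":
                kwargs[key] = val in ("True", "true", "1")
            elif key == "lms_order":
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        for prefix, kind, name in (
            ("lpf", "lowpass_recurrence", "lpf_coeffs"),
            ("notch", "notch_recurrence", "notch_coeffs"),
        ):
            keys = [f"{prefix}_{k}" for k in ("alpha", "beta", "gamma", "delta", "epsilon")]
            if all(k in coeff for k in keys):
                kwargs[name] = IIRCoefficients(*(coeff[k] for k in keys), kind)
        return cls(**kwargs)


@dataclass
class DetectionResult:
    """Everything one pipeline run produced, including intermediates."""

    preprocessed_thoracic: SignalRecord
    preprocessed_abdominal: SignalRecord
    gains: tuple[float, float]
    trace: LMSTrace
    enhanced: EnhancedSignal
    maxima: LocalMaxima
    peaks: np.ndarray
    fhr: FHRResult
    config: PipelineConfig
    fs: float
    warnings: list[str] = field(default_factory=list)

    @property
    def fhr_bpm(self) -> float | None:
        return self.fhr.fhr_bpm


def _chain_delay(lpf: IIRCoefficients, ntc: IIRCoefficients, P: int, fs: float) -> int:
    """Deterministic group delay of the detection chain, in samples.

    The trailing mean filter contributes (P-1)/2 and the low-pass/notch
    stages their passband group delay (evaluated at 10 Hz, representative of
    QRS energy).  Reported peak indices are corrected by this amount so they
    align with the R peaks of the raw input.
    """
    from scipy.signal import group_delay

    w = [2.0 * np.pi * 10.0 / fs]
    gd = 0.0
    for c in (lpf, ntc):
        gd += float(group_delay((c.b, c.a), w=w)[1][0])
    return int(round((P - 1) / 2.0 + gd))


def run_pipeline(recording: AnnotatedRecording, config: PipelineConfig | None = None) -> DetectionResult:
    """Run the full detection chain on a two-channel recording."""
    config = config or PipelineConfig()
    fs = recording.fs
    notes: list[str] = []

    lpf, ntc = config.coefficients(fs)
    n1 = n2 = config.samples(config.baseline_window_s, fs)
    pre_t = preprocessing.preprocess(recording.thoracic, lpf, ntc, n1, n2)
    pre_a = preprocessing.preprocess(recording.abdominal, lpf, ntc, n1, n2)

    thor, abdo, gains = lms_extraction.scale_channels(
        pre_t, pre_a, config.scaling_mode, config.fixed_gains
    )
    # Classical noise-canceller assignment by default: the fetal-free
    # thoracic channel is the reference, the abdominal mixture the desired.
    d, x = (thor, abdo) if config.swap_channels else (abdo, thor)
    trace = lms_extraction.run_lms(d, x, config.lms_order, config.lms_mu)

    e_rec = SignalRecord(trace.e, fs, "extracted_fecg")
    P = config.samples(config.mean_filter_s, fs)
    enhanced = fhr_detection.enhance_peaks(e_rec, P)
    maxima = fhr_detection.threshold_norm(enhanced)
    peaks = fhr_detection.detect_foetal_peaks(maxima, config.samples(config.refractory_s, fs))
    peaks = np.maximum(peaks - _chain_delay(lpf, ntc, P, fs), 0)

    burn_in = config.samples(config.burn_in_s, fs)
    if recording.n <= burn_in:
        msg = (
            f"recording ({recording.n} samples) is shorter than the burn-in "
            f"({burn_in} samples); FHR computed on all detected peaks"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
        burn_in = 0
    fhr = fhr_detection.compute_fhr(peaks, fs, burn_in)
    if not fhr.defined:
        notes.append("fewer than 2 qualifying peaks: FHR undefined")

    return DetectionResult(
        preprocessed_thoracic=pre_t,
        preprocessed_abdominal=pre_a,
        gains=gains,
        trace=trace,
        enhanced=enhanced,
        maxima=maxima,
        peaks=peaks,
        fhr=fhr,
        config=config,
        fs=fs,
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_signal(path: str | Path, fs: float, label: str = "") -> SignalRecord:
    """Read a one- or two-column (time,value) delimited text file."""
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            row = [c.strip() for c in row if c.strip() != ""]
            if not row:
                continue
            try:
                nums = [float(c) for c in row]
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric row {row!r}") from None
            if len(nums) == 1:
                values.append(nums[0])
            elif len(nums) == 2:
                values.append(nums[1])
            else:
                raise ParseError(f"{path}:{lineno}: expected 1 or 2 columns, got {len(nums)}")
    if not values:
        raise ParseError(f"{path}: no numeric samples found")
    return SignalRecord(np.asarray(values), fs, label or Path(path).stem)


def read_recording(
    path_thoracic: str | Path, path_abdominal: str | Path, fs: float
) -> AnnotatedRecording:
    """Read a thoracic/abdominal pair of delimited-text files (no annotations)."""
    thor = read_signal(path_thoracic, fs, "thoracic")
    abdo = read_signal(path_abdominal, fs, "abdominal")
    if thor.n != abdo.n:
        raise ValueError(
            f"length mismatch: {path_thoracic} has {thor.n} samples but "
            f"{path_abdominal} has {abdo.n}"
        )
    return AnnotatedRecording(thoracic=thor, abdominal=abdo)


def read_wfdb_recording(
    record_name: str, thoracic_channel: str | int, abdominal_channel: str | int
) -> AnnotatedRecording:
    """Read two named channels of a WFDB record (requires the ``wfdb`` package)."""
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb)"
        ) from exc
    rec = wfdb.rdrecord(str(record_name))  # pragma: no cover
    sig = rec.p_signal  # pragma: no cover

    def _col(ch):  # pragma: no cover
        return ch if isinstance(ch, int) else rec.sig_name.index(ch)

    return AnnotatedRecording(  # pragma: no cover
        thoracic=SignalRecord(sig[:, _col(thoracic_channel)], rec.fs, "thoracic"),
        abdominal=SignalRecord(sig[:, _col(abdominal_channel)], rec.fs, "abdominal"),
    )


def write_signal(rec: SignalRecord, path: str | Path) -> None:
    np.savetxt(path, rec.samples, fmt="%.10g")


def write_peaks(peaks: np.ndarray, path: str | Path) -> None:
    """One 0-based sample index per line."""
    Path(path).write_text("".join(f"{int(p)}\n" for p in np.asarray(peaks).ravel()))


def read_peaks(path: str | Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return np.asarray([int(ln) for ln in lines], dtype=np.int64)


def write_result(result: DetectionResult, path: str | Path) -> None:
    """Write peak indices and a summary (FHR, th, m1, m2) as delimited text.

    ``<path>`` receives the peaks (one index per line, readable with
    :func:`read_peaks`); ``<path stem>_summary.csv`` receives the summary.
    """
    path = Path(path)
    write_peaks(result.peaks, path)
    summary = path.with_name(path.stem + "_summary.csv")
    fhr = result.fhr_bpm
    with open(summary, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fhr_bpm", "th", "m1", "m2", "n_peaks"])
        writer.writerow(
            [
                "" if fhr is None else f"{fhr:.6g}",
                f"{result.maxima.th:.10g}",
                f"{result.maxima.m1:.10g}",
                f"{result.maxima.m2:.10g}",
                len(result.peaks),
            ]
        )
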