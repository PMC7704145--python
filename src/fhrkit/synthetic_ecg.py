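"""Synthetic thoracic/abdominal ECG mixtures with ground-truth annotations.

The generator emulates the structure of non-invasive fetal ECG recordings:
the thoracic channel carries the maternal ECG plus broadband noise, while the
abdominal channel carries an attenuated maternal ECG, a lower-amplitude fetal
ECG, sinusoidal baseline wander, 50 Hz powerline interference and broadband
noise.  Beats are rendered as sum-of-Gaussians PQRST templates placed at
cumulative RR times with per-beat jitter; the exact R-peak sample indices of
both sources are returned as ground truth.

The maternal template seen by the abdominal electrode may optionally be
morphologically distorted relative to the thoracic one
(``mecg_morphology_distortion``), which produces the residual maternal peaks
an adaptive canceller cannot remove — the distractor class the peak detector
must reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import AnnotatedRecording, SignalRecord

__all__ = [
    "GaussianComponent",
    "BeatTemplate",
    "MATERNAL_TEMPLATE",
    "FETAL_TEMPLATE",
    "SimulationConfig",
    "generate_beat_train",
    "simulate_recording",
]

#: Physiological ceiling for the fetal heart rate (beats per minute).
MAX_FHR_BPM = 200.0


@dataclass(frozen=True)
class GaussianComponent:
    """One PQRST wave: ``amplitude * exp(-(t - center_s)^2 / (2 width_s^2))``."""

    amplitude: float
    center_s: float
    width_s: float


@dataclass(frozen=True)
class BeatTemplate:
    """Sum-of-Gaussians beat morphology, R wave centred at t = 0."""

    components: tuple[GaussianComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("template needs at least one component")
        widths = [c.width_s for c in self.components]
        if any(w <= 0 for w in widths):
            raise ValueError("component widths must be positive")
        amps = np.array([abs(c.amplitude) for c in self.components])
        centers = np.array([abs(c.center_s) for c in self.components])
        r = int(np.argmax(amps))
        if centers[r] != 0.0:
            raise ValueError("the largest-amplitude component (R) must sit at t=0")

    @property
    def r_amplitude(self) -> float:
        return max(self.components, key=lambda c: abs(c.amplitude)).amplitude

    @property
    def support_s(self) -> float:
        """Total effective support width (4 sigma beyond the outermost centres)."""
        left = min(c.center_s - 4.0 * c.width_s for c in self.components)
        right = max(c.center_s + 4.0 * c.width_s for c in self.components)
        return right - left

    def scaled(self, time_scale: float = 1.0, amp_scale: float = 1.0) -> "BeatTemplate":
        return BeatTemplate(
            tuple(
                GaussianComponent(c.amplitude * amp_scale, c.center_s * time_scale, c.width_s * time_scale)
                for c in self.components
            )
        )

    def perturbed(self, rng: np.random.Generator, frac: float) -> "BeatTemplate":
        """A morphologically mismatched copy: non-R wave amplitudes, widths
        and timings jitter by ~``frac``; the R wave keeps its amplitude and
        position (the channel gain already covers overall scaling) but its
        width may change, which leaves a sharp uncancellable residue."""
        if frac == 0.0:
            return self
        r_idx = int(np.argmax([abs(c.amplitude) for c in self.components]))
        comps = []
        for i, c in enumerate(self.components):
            wfac = float(np.clip(1.0 + 0.5 * frac * rng.standard_normal(), 0.5, 1.5))
            if i == r_idx:
                comps.append(GaussianComponent(c.amplitude, c.center_s, c.width_s * wfac))
                continue
            afac = float(np.clip(1.0 + frac * rng.standard_normal(), 0.2, 1.8))
            shift = 0.3 * frac * c.width_s * rng.standard_normal()
            comps.append(
                GaussianComponent(c.amplitude * afac, c.center_s + shift, c.width_s * wfac)
            )
        return BeatTemplate(tuple(comps))


# Adult PQRST morphology, R amplitude normalised to 1; QRS duration ~100 ms.
MATERNAL_TEMPLATE = BeatTemplate(
    (
        GaussianComponent(0.15, -0.190, 0.022),  # P
        GaussianComponent(-0.08, -0.052, 0.009),  # Q
        GaussianComponent(1.00, 0.000, 0.020),  # R
        GaussianComponent(-0.12, 0.056, 0.009),  # S
        GaussianComponent(0.35, 0.200, 0.035),  # T
    )
)

# Fetal beats seen from the abdomen: a narrow QRS spike (~30 ms) dominates;
# P and T waves are barely visible in abdominal leads.
FETAL_TEMPLATE = BeatTemplate(
    (
        GaussianComponent(0.05, -0.085, 0.010),  # P
        GaussianComponent(-0.05, -0.017, 0.007),  # Q
        GaussianComponent(1.00, 0.000, 0.005),  # R
        GaussianComponent(-0.05, 0.018, 0.007),  # S
        GaussianComponent(0.09, 0.100, 0.018),  # T
    )
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated recording (all amplitudes unitless)."""

    fs: float = 1000.0
    duration_s: float = 60.0
    maternal_hr_bpm: float = 80.0
    foetal_hr_bpm: float = 140.0
    #: fetal-to-maternal R amplitude ratio on the abdominal channel
    fecg_to_mecg_ratio: float = 0.25
    #: maternal gain on the abdominal channel (thoracic gain is 1)
    abdominal_mecg_gain: float = 0.7
    baseline_amp: float = 0.3
    baseline_freq_hz: float = 0.3
    powerline_amp: float = 0.05
    powerline_freq_hz: float = 50.0
    broadband_noise_sd: float = 0.02
    #: per-beat RR jitter standard deviation, seconds
    hr_jitter_sd_s: float = 0.005
    #: fractional morphology mismatch of the abdominal maternal template
    mecg_morphology_distortion: float = 0.0
    seed: int = 0
    maternal_template: BeatTemplate = field(default=MATERNAL_TEMPLATE)
    foetal_template: BeatTemplate = field(default=FETAL_TEMPLATE)

    def __post_init__(self) -> None:
        if not (0 < self.foetal_hr_bpm <= MAX_FHR_BPM):
            raise ValueError(f"foetal_hr_bpm must be in (0, {MAX_FHR_BPM}]")
        if self.maternal_hr_bpm <= 0:
            raise ValueError("maternal_hr_bpm must be > 0")
        if not (0 < self.fecg_to_mecg_ratio <= 1):
            raise ValueError("fecg_to_mecg_ratio must be in (0, 1]")
        for name in ("abdominal_mecg_gain", "baseline_amp", "powerline_amp",
                     "broadband_noise_sd", "hr_jitter_sd_s", "mecg_morphology_distortion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration_s * self.fs < 1:
            raise ValueError("duration_s * fs must be >= 1 sample")

    @property
    def n(self) -> int:
        return int(round(self.duration_s * self.fs))


def _beat_times(
    hr_bpm: float, duration_s: float, jitter_sd_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative beat times (s): first beat at RR/2, RR = 60/hr + jitter."""
    rr_nominal = 60.0 / hr_bpm
    n_max = int(np.ceil(duration_s / rr_nominal)) + 8
    rr = rr_nominal + jitter_sd_s * rng.standard_normal(n_max)
    rr = np.maximum(rr, 0.3 * rr_nominal)  # keep RR positive and physiological
    t = 0.5 * rr_nominal + np.concatenate(([0.0], np.cumsum(rr[:-1])))
    return t[t < duration_s]


def _render_train(
    peak_indices: np.ndarray, n: int, fs: float, template: BeatTemplate
) -> np.ndarray:
    """Place one template at every peak index (R centre on the sample grid)."""
    out = np.zeros(n)
    for comp in template.components:
        half = int(np.ceil((abs(comp.center_s) + 5.0 * comp.width_s) * fs))
        win = np.arange(-half, half + 1)
        kernel = comp.amplitude * np.exp(
            -0.5 * ((win / fs - comp.center_s) / comp.width_s) ** 2
        )
        for p in peak_indices:
            lo, hi = p - half, p + half + 1
            klo, khi = max(0, -lo), len(win) - max(0, hi - n)
            out[max(0, lo) : min(n, hi)] += kernel[klo:khi]
    return out


def generate_beat_train(
    hr_bpm: float,
    duration_s: float,
    fs: float,
    template: BeatTemplate,
    jitter_sd_s: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a clean single-source ECG trace and its R-peak sample indices."""
    if hr_bpm <= 0:
        raise ValueError("hr_bpm must be > 0")
    rr_nominal = 60.0 / hr_bpm
    if template.support_s >= rr_nominal:
        raise ValueError(
            f"template support ({template.support_s:.3f} s) is not shorter "
            f"than the RR interval ({rr_nominal:.3f} s): beats would overlap"
        )
    n = int(round(duration_s * fs))
    peaks = np.round(_beat_times(hr_bpm, duration_s, jitter_sd_s, rng) * fs).astype(np.int64)
    peaks = peaks[peaks < n]
    return _render_train(peaks, n, fs, template), peaks


def simulate_recording(config: SimulationConfig) -> AnnotatedRecording:
    """Simulate one annotated thoracic/abdominal recording (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    n, fs = config.n, config.fs
    t = np.arange(n) / fs

    m_sig, m_peaks = generate_beat_train(
        config.maternal_hr_bpm, config.duration_s, fs,
        config.maternal_template, config.hr_jitter_sd_s, rng,
    )
    f_sig, f_peaks = generate_beat_train(
        config.foetal_hr_bpm, config.duration_s, fs,
        config.foetal_template, config.hr_jitter_sd_s, rng,
    )

    # Maternal morphology as seen by the abdominal electrode: identical by
    # default, optionally distorted so the canceller leaves residual peaks.
    ab_template = config.maternal_template.perturbed(rng, config.mecg_morphology_distortion)
    m_sig_ab = (
        m_sig
        if config.mecg_morphology_distortion == 0.0
        else _render_train(m_peaks, n, fs, ab_template)
    )

    f_amp = config.fecg_to_mecg_ratio * abs(config.foetal_template.r_amplitude)
    m_amp = config.abdominal_mecg_gain * abs(ab_template.r_amplitude)
    if f_amp >= m_amp:
        raise ValueError(
            "abdominal fetal R amplitude must stay below the maternal one "
            f"(got fetal {f_amp:.3f} vs maternal {m_amp:.3f})"
        )

    phase_b, phase_p = rng.uniform(0, 2 * np.pi, size=2)
    thoracic = m_sig + config.broadband_noise_sd * rng.standard_normal(n)
    abdominal = (
        config.abdominal_mecg_gain * m_sig_ab
        + config.fecg_to_mecg_ratio * f_sig
        + config.baseline_amp * np.sin(2 * np.pi * config.baseline_freq_hz * t + phase_b)
        + config.powerline_amp * np.sin(2 * np.pi * config.powerline_freq_hz * t + phase_p)
        + config.broadband_noise_sd * rng.standard_normal(n)
    )

    return AnnotatedRecording(
        thoracic=SignalRecord(thoracic, fs, "thoracic"),
        abdominal=SignalRecord(abdominal, fs, "abdominal"),
        foetal_peaks=f_peaks,
        maternal_peaks=m_peaks,
        true_fhr_bpm=config.foetal_hr_bpm,
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: the same study conditions under a different seed."""
    return replace(config, seed=seed)
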