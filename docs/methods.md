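# Methods

This note documents the models and procedures implemented in `fhrkit`, the
choices made where the design was genuinely open, and the limits of what the
synthetic-data validation can show.

## Signal model

The abdominal channel is modelled as a linear mixture

    abdominal[n] = g·MECG[n] + r·FECG[n] + baseline[n] + powerline[n] + noise[n]

with maternal gain `g = 0.7`, fetal-to-maternal R-amplitude ratio
`r = 0.25`, a 0.3-amplitude sinusoidal baseline at 0.3 Hz, 0.05-amplitude
50 Hz powerline interference, and white broadband noise of standard
deviation 0.02 (all in the unitless amplitude scale in which both sources'
R waves peak at 1).  The thoracic channel carries the maternal ECG plus
noise and no fetal content.  Both sources are quasi-periodic trains of
sum-of-Gaussians PQRST templates placed at cumulative RR times with 5 ms
per-beat jitter; defaults are maternal 80 bpm and fetal 140 bpm, 60 s at
1 kHz.

Template morphology follows textbook surface-ECG values: the adult QRS
spans roughly 100 ms (R-wave σ = 20 ms) with P and T waves at 15% and 35%
of the R amplitude; the fetal beat, as seen from abdominal electrodes, is
dominated by a narrow ~30 ms QRS spike (R-wave σ = 5 ms) with barely
visible P/T waves.  An optional morphology-distortion parameter renders the
abdominal maternal contribution with perturbed non-R wave amplitudes,
widths and timings (and a perturbed R width), emulating the fact that the
maternal ECG projected to the abdomen is not identical to the thoracic one;
this produces the residual maternal peaks a linear canceller cannot remove
and is used to exercise the detector's rejection behaviour.

What the simulator does **not** model: fetal movement and electrode
geometry, uterine-contraction artefacts, electrode pops/motion transients,
non-sinusoidal baseline drift, and heart-rate variability beyond white RR
jitter.  Passing tests on this generator therefore demonstrate correctness
of the processing chain under stationary, moderately noisy conditions, not
clinical performance on real abdominal recordings.

## Preprocessing

The low-pass stage is the 4th-order Butterworth recurrence with a single
feedforward term; the reference coefficient set
(α = 0.00308, β = 3.28391, γ = −4.08689, δ = 2.28117, ε = −0.48140, valid
at 1 kHz) has a DC gain of α/(1−β−γ−δ−ε) ≈ 0.96 and is implemented exactly
as printed rather than renormalised.  For arbitrary sampling rates the
package designs a fresh 45 Hz Butterworth with `scipy.signal.butter` and
collapses the numerator into a single α = Σb (unit DC gain).

The notch stage is a two-pole biquad.  The reference constants
(α = 0.99405, β = −1.31278, γ = 0.99405, δ = 1.31272, ε = −0.98804) place
the unit-circle zeros at ω₀ = arccos(−β/2α) ≈ 0.849 rad/sample — i.e. at
~135 Hz when run at 1 kHz, not at 50 Hz.  Because the intended design
cannot be recovered from the constants alone, the pipeline default
(`coeff_mode="designed"`) uses a properly designed 50 Hz / Q = 25 notch
(`scipy.signal.iirnotch`); the printed constants remain available
bit-for-bit via `coeff_mode="paper"` (any rate) or `"auto"` (at 1 kHz), and
both sets are dumped to and reloaded from the flat-text config unchanged.

Baseline wander is estimated by a two-stage *trailing* moving average
(N₁ = N₂ = 0.2 s) and subtracted from the **current** sample, mirroring a
streaming register implementation: no look-ahead and no delay compensation.
The trailing window implies a group delay of (N₁+N₂−2)/2 ≈ 0.2 s, which
limits cancellation of a 0.3 Hz drift to |1 − H(f)e^{−jφ(f)}| ≈ 0.37
(about 8.6 dB); sub-0.1 Hz drift is cancelled much more completely.  This
is an intrinsic property of the filter structure, accepted deliberately;
the residual drift is smooth and does not reach the squared-derivative
detection envelope, but it does persist in the extraction residue.

All recurrences run causally with zero initial conditions; the start-up
transient is left in the output rather than trimmed.  Stability of any
coefficient set is checked at construction (feedback roots strictly inside
the unit circle).

## Adaptive extraction

Plain LMS, order m = 19, step size μ = 7×10⁻⁵, zero-initialised weights and
buffer, simultaneous weight update from the pre-update error and buffer.
Two design choices deserve explanation:

**Channel assignment.**  The default follows the classical adaptive
noise-canceller: the abdominal mixture is the desired signal d[n] and the
fetal-free thoracic channel the reference x[n], so the filter learns the
thoracic→abdominal maternal transfer and e[n] = d[n] − y[n] retains the
fetal ECG while the maternal component is cancelled.  The reversed
assignment (thoracic as desired) is available as `swap_channels=True`, but
it makes e[n] a cleaned *thoracic* signal and — because the fetal signal
and baseline residue then sit in the reference — provably shrinks the
Wiener solution so that the residual maternal amplitude is comparable to
the fetal amplitude; with it, the detector cannot reach the performance the
classical assignment delivers.  This was verified against the optimal
19-tap least-squares filter, which exhibits the same shrinkage.

**Scaling.**  Both channels are divided by their own RMS before adaptation
(`unit_rms`, reported in `DetectionResult.gains`).  LMS convergence speed
is proportional to μ times the reference power, and with unit-power inputs
μ = 7×10⁻⁵ settles on the 10³–10⁴-sample scale at 1 kHz — consistent with
the stated convergence budget (the 12,000-sample burn-in).  Peak
normalisation (`max_abs`) leaves ECG power near 0.02–0.05 and stretches
convergence beyond any realistic record length at this step size; it is
kept as an option together with `none` and `fixed_gain`.

**Convergence detection.**  A plain LMS with persistent excitation never
drives its weight updates to zero (steady-state misadjustment), so an
absolute or peak-relative threshold on the update magnitude does not
terminate.  `converged_at` is therefore defined as a settling time: the
first sample after the peak of the 1 s moving RMS of ‖Δw‖ at which that
trace falls below 2× its steady-state level (median over the record's final
25%).  Window, factor and tail fraction are keyword arguments of
`run_lms`.

## Detection

The envelope is `sdm[n]`, the trailing P = 40-sample mean of the squared
first difference of e[n]; its mean m₁ is accumulated in stream order as
Σ sdm[k]·(1/N), the reciprocal-multiply form a streaming datapath uses (the
per-sample threshold procedure is specified to be *exactly* reproducible,
so the accumulation order is part of the contract and the test oracle).

The threshold procedure latches rising samples above m₁ (R3/R4), emits the
latched maximum on every below-m₁ sample while accumulating pv/N into m₂,
and freezes `th = (m₁+m₂)/2` when the sample counter reaches N−1.  The
default implementation computes m₁ in a first pass over the whole record
(two-pass, deterministic); a single-pass variant that compares against the
partial running mean, as a fully streaming datapath would, is available as
`threshold_norm(..., streaming_m1=True)`.  Recorded maxima are the latch
values at their first emission; repeated emissions of the same latch
contribute to m₂ but not to the maxima list.

Candidates above `th` then pass the refractory rule (200 samples at 1 kHz,
strict inequality): a new maximum beyond the window commits the pending
peak; within the window the larger value survives.  Reported peak indices
are corrected for the deterministic group delay of the chain — (P−1)/2 for
the trailing mean plus the low-pass/notch passband group delay evaluated at
10 Hz from the active coefficients — so they align with the R peaks of the
raw input; raw latch locations remain in `DetectionResult.maxima`.

FHR is 60 over the mean RR interval of peaks at or after the burn-in
(12,000 samples at 1 kHz, scaled by fs elsewhere).  Records shorter than
the burn-in produce a warning and use all peaks; fewer than two qualifying
peaks leave the rate undefined rather than fabricating one.

## Evaluation

Detections are matched to true fetal peaks by greedy nearest-neighbour
one-to-one pairing within ±50 ms.  Maternal beats are the distractor class:
a maternal annotation with no detection nearby counts as a true negative,
so specificity measures rejection of the maternal residue — the reading
under which "no false positives" yields 100% specificity.  All counts are
restricted to the post-burn-in segment.

## Known limitations

* **Sensitivity ceiling of the single-threshold latch.**  The latch stores
  the *most recent* rising sample above m₁, not the largest since the last
  emission.  When a fetal envelope excursion fails to dip below m₁ before
  the next uptick — which happens when a residual maternal bump (driven by
  the unconverged sharp modes of the coloured thoracic reference and by
  update jitter) rides the 40-sample descent of a fetal hump at
  fetal–maternal beat coincidences — the stored fetal maximum is
  overwritten by a small late value and the beat is lost.  Under the
  default simulator conditions this costs a few beats per minute
  (sensitivity typically 96–99% in the acceptance runs, specificity 100%),
  and the stretched RR intervals bias the FHR estimate low by roughly
  1–4 bpm.  The effect is intrinsic to the procedure: it persists even when
  the adaptive filter is replaced by the optimal least-squares canceller,
  and it disappears only on recordings with a lower noise floor.
* **Single global threshold.**  `th` is computed once per record; slow
  amplitude drift of the extracted fetal signal across a long record is not
  tracked (by design — the procedure's purpose is to avoid adaptive
  thresholding).
* **Baseline-wander residue.**  See above; the trailing moving average
  leaves ~37% of a 0.3 Hz drift in place, which inflates the adaptive
  filter's steady-state error and hence its weight jitter.
* The FPU model covers normalised finite values only; zeros are handled by
  special-casing the all-zero patterns, and denormals/NaN/Inf are rejected.
  Truncation (never rounding) follows every alignment and normalisation
  shift, so results can sit one aligned-grid unit below the exactly
  rounded value; the comparator's raw field comparison mis-orders two
  negative operands, and a corrected mode is provided alongside the
  faithful one.
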