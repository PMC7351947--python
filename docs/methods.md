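# Methods

`gevisim` simulates wide-field voltage-imaging recordings of neurons labeled
with genetically encoded voltage indicators (GEVIs), detects spikes from the
resulting movies, and quantifies how indicator *polarity* — whether the
fluorophore brightens (positive-going) or dims (negative-going) on
depolarization — interacts with labeling density and sensitivity to set the
spike-detection error. This note documents the models, the defaults and why,
the numerical choices, and what the synthetic benchmark does and does not
show about real data.

## Indicator model

An indicator is summarized by two brightness levels, `F_min` and `F_max`
(arbitrary counts), and a polarity. Normalized voltage `v` (0 = rest,
1 = mean spike height) maps linearly into fluorescence:

    positive:  F(t) = F_min + v(t) · (F_max − F_min)
    negative:  F(t) = F_max − v(t) · (F_max − F_min)

Sensitivity is the fractional response ΔF/F_min = (F_max − F_min)/F_min.
The sensitivity axis of all sweeps holds `F_max` fixed (a dye ligand's
maximum brightness is a property of the fluorophore) and moves `F_min`:
`F_min = F_max / (1 + s)`. Consequences worth keeping in mind:

* a rest→spike step has ΔF/F = +s for positive polarity and −s/(1+s) for
  negative polarity, each against its own resting baseline;
* the *absolute* spike amplitude `F_max − F_min` is identical for the two
  polarities at equal sensitivity — what differs is the resting brightness,
  `F_min` vs `F_max`, a factor of (1+s).

The map is linear and unclipped by default (the rhodopsin response is fast
and linear over the physiological range; fluorescence is floored at zero).
Hard saturation at `[F_min, F_max]` is available via
`voltage_to_fluorescence(clip="range")` but is not the default: at rest it
half-rectifies subthreshold fluctuations into one-sided bumps that an event
detector with a robust adaptive threshold will mistake for small spikes —
in noiseless test recordings the rectified fluctuations reached ~9 robust SD
in the detection band versus ~4.5 unclipped. First-order on/off kinetics
(`tau_on`, `tau_off`) can be enabled; they are off by default because the
simulated indicators respond within one frame at 400 Hz.

## Synthetic recordings

* **Spike trains.** Refractory Poisson process: inter-spike intervals are a
  4-frame absolute refractory period (10 ms at 400 Hz) plus a geometric wait
  whose rate is chosen so the expected count equals `mean_spikes` exactly in
  the stationary regime. Defaults: 100 spikes per 40,000-frame recording at
  400 Hz (~1 Hz tonic firing); the reduced-scale benchmark uses 10 per 4,000.
* **Action potential waveform.** 2-frame linear rise to unit peak, then
  exponential decay with a 3-frame time constant (≈12 ms full width at
  400 Hz). The ground-truth spike label is the frame of the waveform peak.
  Overlapping waveforms combine by pointwise maximum, not summation — two
  near-coincident spikes do not produce a double-height event.
* **Subthreshold activity.** Ornstein–Uhlenbeck process, SD 0.05 of the
  spike height, correlation time 40 frames (100 ms) — small, slow
  fluctuations typical of in vivo membrane potential between spikes.
* **Footprints.** In-focus somata are isotropic Gaussians (radius parameter
  = 2 SD, default 3 px), normalized to unit total weight so every neuron
  contributes the same photon flux. Out-of-focus background neurons reuse a
  target's footprint displaced to a random nearby centroid and blurred with
  a 6-px Gaussian (defocus preserves flux, spreads it); their spike trains
  are the target's circularly time-shifted by a random offset — "temporal
  shuffling" that preserves both the count and the interval structure while
  destroying timing correlation. Five background neurons accompany every
  in-focus neuron.
* **Bleaching.** A shared single-exponential multiplier `exp(−t/τ)`
  (default τ = 10,000 frames = 25 s) stands in for an empirically measured
  dye bleaching curve; the analysis code fits and divides out an exponential
  regardless of how the decay was produced, and accepts real curves.
* **Noise.** Per-pixel Gaussian, drawn per frame. Default model:
  SD = `noise_coeff` × instantaneous pixel signal (illumination/shot-type
  noise — brighter pixels are noisier). An `additive` model with constant SD
  is provided as a control that removes the brightness dependence; it is the
  mechanism-isolating condition of the polarity-null test. Pixels are
  clipped at zero after noise.

Every generator is a pure function of its arguments and an integer seed
(NumPy `SeedSequence` spawning), so recordings regenerate bit-identically.

## Trace analysis

* **Bleach correction** fits `A·exp(−t/τ) + C` by robust (soft-L1)
  least squares with log-spaced multi-start in τ, then divides the fitted
  curve out, rescaled to preserve the initial brightness. Near-constant
  traces short-circuit to τ = ∞; a failed fit falls back to a flagged linear
  detrend. The additive offset `C` absorbs non-bleaching background.
* **ΔF/F** uses either a scalar baseline (mean over a pre-stimulus window)
  or a per-frame moving-percentile baseline: bottom 10th percentile of a
  centered 1-s window for positive-going indicators, top 10th for
  negative-going ones, with truncated windows at the edges. Division (not
  subtraction) is used throughout, consistent with multiplicative bleaching.
* **Kinetics** fits `a1·exp(−t/τ1) + a2·exp(−t/τ2) + c` to step responses
  (3,200 Hz sampling by default) with multi-start over log-spaced τ pairs;
  time constants are reported ordered (τ1 ≤ τ2) and single-exponential data
  degenerate gracefully to one near-zero amplitude.
* **F–V curves** average the steady-state ΔF/F of each voltage step (the
  clamp protocol spans −110 to +50 mV in 20-mV increments, nine steps) and
  report the sign of the least-squares slope.

## Spike detection

**Wavelet event detector** (trace level): z-transform the ΔF/F trace;
decompose with a shift-invariant (maximal-overlap) discrete wavelet
transform, sym4, six levels, implemented as PyWavelets' stationary-wavelet
MRA with reflection padding to a multiple of 2⁶; rebuild a
frequency-localized signal from detail levels 3–6 (≈3–50 Hz at 400 Hz, where
spike transients concentrate); square it; threshold the power. The default
threshold is (5 × 1.4826 × MAD of the band signal)² — five robust SD in
amplitude, expressed on the power — with a matched-length white-noise null
percentile available as an alternative. Suprathreshold local maxima no
closer than `min_separation` (4 frames) become events, negative-going band
deflections (the sidelobes of strong spikes) are discarded, and each event
is then snapped to the maximum of the z-scored trace within ±2 frames of
the power peak: the band-pass of an asymmetric spike waveform peaks one
frame late, and the snap pins events to the true spike frame — necessary
because scoring is exact-frame. Because of the z-transform and the relative
threshold, detection is invariant to trace scale and, after the
polarity-appropriate baseline and sign correction, identical for both
polarities at matched SNR.

**Movie extractor** (an operationally documented variant in the spirit of
Spike Pursuit): start from the seed-footprint-weighted pixel mean (the
movie is sign-flipped first for negative polarity so spikes are upward);
high-pass the trace (subtract a Gaussian smooth, ≈1.6 Hz cutoff); detect
provisional events; regress every pixel's time series onto the spike-band
regressor (the high-pass trace masked to windows around events — the
smoothing is symmetric, so the projection is computed by filtering the
regressor rather than the movie); keep positive coefficients within a
dilated neighbourhood of the seed; and weight each coefficient by the
pixel's inverse noise variance, estimated from first differences outside
event windows and floored at the support median. The inverse-variance step
matters: with noise proportional to brightness, the brightest pixels are
the noisiest, and unweighted footprint-matched weights are measurably worse
than the refined ones. Iterate (default 3) or stop when the event set is
stable. End-to-end (`detect_from_movie`): extract → bleach-correct →
moving-percentile baseline by polarity → ΔF/F → sign-correct → wavelet
detect. The composition is deterministic given its inputs.

## Evaluation

Spike inference is scored as IoU of binary per-frame labels at the imaging
rate without binning (tolerance 0; a greedy nearest-first matcher supports
positive tolerances). Error = 1 − IoU; two empty trains score IoU 1. Exact
frame matching makes the metric harsh: a one-frame timing jitter counts as
both a miss and a false positive.

The benchmark sweep simulates every (polarity, sensitivity, density,
replicate) cell with seeds derived from a base seed and the cell's grid
coordinates, detects spikes for the first two in-focus neurons of each
recording (all in-focus neurons are statistically equivalent; scoring a
fixed number bounds the cost of dense fields), and aggregates error by cell.
Two summaries follow:

* **Matched-density ratio**: interpolate mean error vs density per polarity
  (log-density interpolation, monotonicity enforced by a running maximum)
  at a fixed error target (default 0.5) and report
  density(positive)/density(negative) at the five-fold sensitivity. If a
  curve never reaches the target inside the swept range, the crossing is
  right/left-censored at the range edge and flagged — the ratio is then a
  bound, not a point estimate.
* **Fidelity ratio**: fidelity is 1 − error by default (the mean event
  z-score is implemented as the alternative definition, since "detection
  fidelity" admits both readings); the ratio positive/negative is evaluated
  at the densest, most sensitive cell.

## Study conditions and calibration

The reduced-scale benchmark uses 4,000-frame recordings (one tenth of the
reference length) with 10 expected spikes per neuron, a 40×40-px field,
densities {1, 2, 4, 8, 16}, sensitivities {0.2, 1.0} (baseline and
five-fold), both polarities, and 20 seeds per cell — 400 recordings, a few
minutes on one CPU.

The noise proportionality constant is not something the benchmark can take
from measurement, so it was calibrated once, by a rule fixed in advance:
choose `noise_coeff` such that the negative-polarity, five-fold-sensitivity
error-vs-density curve crosses 50 % error at the geometric middle of the
density grid (density ≈ 4), placing the whole sweep in the informative
regime where error traverses (0, 1). The calibrated value is 0.35. Only
that single curve was consulted. The additive-noise control uses SD 0.5
counts, chosen once to give mid-range errors for a single neuron (pixel
signals are 0–7 counts with unit-flux footprints at `F_max` = 100).

### A structural note on the polarity advantage

With noise SD strictly proportional to brightness and `F_max` held fixed,
the resting brightness of every neuron — target and background alike — is
`F_min = F_max/(1+s)` for positive polarity and `F_max` for negative. Any
additive brightness floor cancels when matching error levels, so the
matched-error density ratio is bounded above by `F_max/F_min = 1 + s`. At
the five-fold sensitivity used here (s = 1) that bound is **2**: under
these study conditions the benchmark cannot produce a four-fold density
advantage, whatever the detector does; reaching 4 would require s ≈ 3
(an unrealistically large per-spike response) or a noise model that is not
purely signal-proportional. The fidelity ratio at the densest cell is not
bounded this way — it is a ratio of two tail fidelities and can be large
when the negative-going indicator has collapsed while the positive-going
one still partially works. The benchmark reports both as measured.

## What the synthetic data does not emulate

No optical PSF beyond Gaussian defocus blur; no camera read noise, fixed
pattern, or quantization; no motion; no overlapping in-focus somata
demixing; no real tissue background (the reference analysis superimposed
simulated neurons on a real cortical recording — here the background is
fully synthetic, which preserves the polarity comparison since both
polarities see identical backgrounds). Passing tests therefore demonstrate
correctness of the pipeline and the direction and rough magnitude of the
polarity mechanism, not performance on any particular real preparation.

## Numerical choices and degenerate inputs

Constant traces: bleach fit returns the input (τ = ∞); z-transform of a
constant trace yields zero events. Ties in event peaks resolve to the
earlier frame. Empty seed-footprint overlap raises. Sweep cell failures are
recorded as NaN rows rather than aborting the grid. Wavelet detection
requires ≥ 64 samples and says so. All interpolation for the density ratio
is monotone; the two interpolation scales (log and linear density) agree
within 10 % on smooth curves and both are available.
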