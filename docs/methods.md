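# Methods

`dsstream` re-implements, as a tested library, the analysis chain used to
ask how retinal direction selectivity shapes responses in mouse higher
visual areas: per-cell tuning metrics from two-photon calcium recordings
under drifting-grating protocols, a population decomposition that compares
control and mutant groups on a PCA grid, and intrinsic-signal optical
imaging (ISOI) retinotopy with visual-field-sign area segmentation.  No raw
recordings are redistributed; every analysis is exercised on a synthetic
generator whose ground truth makes the whole chain falsifiable.

## Trace processing

Raw per-ROI fluorescence F(t) (sampled at 30.9 Hz for cortical somata) is
normalized to a slow baseline F0 computed as a rolling 60-s 10th-percentile
filter followed by a zero-phase low-pass Butterworth at 0.01 Hz
(order 2, applied forward-backward; the order is our choice — a standard
minimal-ripple default).  dF/F0 = (F − F0)/F0 is decimated by block
averaging to half the acquisition rate (30.9 → 15.45 Hz), and the response
amplitude of each 3-s stimulus presentation is the mean of the larger 50%
of dF/F0 samples in the drift window (⌈n/2⌉ samples, so an odd window is
never empty).

Numerical choices:

* The percentile window is truncated at the trace boundaries (no padding).
* The percentile stage may be evaluated on a 1-s lattice of window centers
  and linearly interpolated (`percentile_step_s`); the subsequent 0.01 Hz
  low-pass removes all content the lattice could alias, so the result is
  numerically indistinguishable from the exact per-sample filter while an
  order of magnitude cheaper.  The exact mode (`step=1`) remains the
  low-level default and is what the unit tests compare against.
* F0 is floored at a small positive epsilon so dF/F0 is always defined.
* This baseline has a small inherent positive bias (~0.001 dF/F at
  realistic response amplitudes) because indicator decay tails occupy part
  of the bottom decile of the window when stimuli run at a 50% duty cycle.
  The bias is condition-independent; it cancels in the ratio-type tuning
  indices and is characterized explicitly in the test suite.
* On noisy traces two further biases are properties of the printed method
  itself: the 10th percentile of frame noise sits ~1.28 σ below the true
  baseline (inflating dF/F0 slightly), and the top-half-mean amplitude
  estimator carries an additive floor of ~0.8 σ per window, since among
  near-equal samples it selects the upper noise excursions.  Both floors
  add to R_pref and R_opp alike, compressing the DSI multiplicatively by
  roughly 1/(1 + 2·floor/amplitude).  DSI recovery is therefore only
  meaningful for cells well above the noise floor; the shipped recovery
  checks use strong responders (peak dF/F0 of order 1–2, typical for
  well-labeled GCaMP6f neurons) at frame noise σ = 0.05.

Responsiveness gates: cortical cells are visually responsive when the mean
amplitude of their best direction exceeds 0.06 dF/F0 at at least one
temporal frequency (TF); the gate uses trial-mean amplitudes (the per-trial
reading would be noise-dominated) and defines "preferred direction" at this
stage as the direction of maximal mean amplitude, since the vector-sum
preference is not yet computed.  Retinal cells are responsive when any
trial-mean amplitude exceeds mean + 2 SD of the cell's own dF/F trace,
computed on the stimulus-free segments (padded 1 s past each offset for
indicator decay) — the threshold is per-cell, and the stimulus-free
segments are the natural reference for a cell's noise level.

## Tuning metrics

For mean responses R_i at directions d_i (12 directions, 30° spacing, for
cortex; 8 for retina) and a given TF:

* preferred direction θ = atan2(Σ R_i sin d_i, Σ R_i cos d_i), the
  full-quadrant form of the vector sum (negative means floored at 0);
* DSI = (R_pref − R_opp)/(R_pref + R_opp) with R_pref read at the sampled
  direction nearest θ and R_opp 180° away; 0/0 → 0;
* OSI = (R_pref − R_orth)/(R_pref + R_orth) on axis means (preferred +
  opposite vs the orthogonal pair);
* a cell is direction selective (DS) iff responsive and DSI > 0.3 (strict)
  at ≥ 1 TF; the preferred TF is the TF of maximal peak amplitude, ties
  toward the lower TF;
* the TF-response ratio is the peak amplitude at 1.2 Hz over that at
  0.3 Hz (missing when the denominator is non-positive);
* horizontal/vertical axis classes split at ±45° around 0°/180°, the 45°
  boundary deterministically assigned to horizontal.

Flash-spot ON-OFF classification uses OOI = (R_ON − R_OFF)/(R_ON + R_OFF)
per spot size (peak dF/F0 during vs after the 2-s illumination); a cell is
ON-OFF when the mean of |OOI| across the five sizes (50–800 µm) is < 0.3.
The absolute value is a deliberate reading: a signed mean < 0.3 would class
pure-OFF cells (OOI = −1) as ON-OFF.

Known property: DSI ∈ [0, 1] holds for unimodal (von-Mises-like) curves,
where the vector-sum preference coincides with the peak; on adversarial
multimodal curves the nearest-sampled-direction reading can dip marginally
below 0.  With 30° sampling, very narrow cells (κ ≳ 7) whose true peak
falls midway between two sampled directions under-read DSI by up to ~0.06;
recovery guarantees are therefore stated on population medians.

## Population decomposition and grid comparison

Every DS cell contributes eight numbers — peak amplitude and DSI at each of
the four TFs (0.3, 0.75, 1.2, 1.8 Hz) — to a response matrix pooling both
groups, rows sorted by preferred TF.  Columns are z-scored before PCA
(amplitudes and DSI live on different scales; the scaling is our choice),
and cells are embedded on the top two components.  PCA signs are fixed by
requiring a non-negative loading of the highest-TF amplitude column on
each component (first nonzero loading as fallback) so embeddings are
reproducible.

The pooled embedding's bounding box is split into an n × n grid (default
8 × 8; bins half-open with the top/right boundary closed).  Per grid, the
two groups' in-grid/out-of-grid counts form a 2 × 2 table tested with a
Yates-corrected χ²; grids with p < 0.05 are classed *decreased* or
*increased* in the mutant by the sign of the fraction difference, otherwise
*unchanged*.  No multiple-testing correction is applied across the 64
grids by default (an optional Benjamini–Hochberg flag exists).  Per-grid
composition indices: MI = (F_ctrl − F_mut)/(F_ctrl + F_mut) and
PTI = (F_RLp − F_PMp)/(F_RLp + F_PMp), both in [−1, 1] with 0/0 → 0.

Circular statistics: the Rayleigh test uses the mean resultant length R̄,
z = nR̄², and the standard small-sample-corrected p approximation
p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)) with R = nR̄ (accurate to ~1e−3
by n = 10; its empirical type-I error at α = 0.05 is verified ≤ 0.07 by
simulation).  Preferred-direction distributions are compared with a
two-sample two-sided Kolmogorov–Smirnov test after linearizing angles on
[0°, 360°) with the cut at 0° = posterior; scalar group comparisons
delegate to Mann–Whitney U (unpaired) and Wilcoxon signed-rank (paired).

## ISOI retinotopy and area segmentation

Each pixel's time course under a periodically sweeping bar is reduced to
the phase and magnitude of its Fourier coefficient at the DFT bin nearest
the sweep frequency (speed/extent: 9°/s over 134.46° azimuth → 0.067 Hz,
over 102.75° elevation → 0.088 Hz).  Opposite sweep directions share the
hemodynamic delay but flip the retinotopic phase; the delay is estimated
as the circular mean of the per-pixel half-sum of forward and reverse
phases, weighted by response magnitude, and subtracted from the forward
map.  (The naive circular half-difference is ambiguous by π outside
[−π/2, π/2); delay-first subtraction recovers the full range, assuming
delays below half a sweep period.)  Phase maps convert linearly to visual
degrees about the midpoint of the swept range.

The visual-field sign is I = sin(angle(∇elevation) − angle(∇azimuth)) per
pixel, after Gaussian smoothing (σ = 2 px default) of the coordinate maps;
pixels without a genuine response (Fourier magnitude below a floor) are
excluded from the smoothing by normalized masked convolution and set to
I = 0, since their phases are noise.  Border detection is three steps:
(1) threshold at mean(|I|) + SD(|I|) — the absolute-value reading, because
a signed threshold on a map with mean ≈ 0 would discard all
negative-sign areas — followed by a 3 × 3 median filter; (2) an 8-neighbor
pass keeping pixels with > 4 non-zero neighbors and then filling gaps
(zero pixels with ≥ 5 kept neighbors) in a single sweep after the retain
pass; (3) Sobel edge detection and connected-component labeling, with
positive- and negative-sign pixels labeled separately so adjacent
mirror-polarity areas stay distinct.  Area sizes convert to mm² via the
pixel size; centroids are re-expressed relative to the largest area's
centroid (V1 by construction).  Areal grating responses are the per-pixel
peak FFT power in 0.05–0.1 Hz of the pre-stimulus-normalized signal, with
each area's strength the maximum inside its ROI; normalizing the signal
(not the power) makes strengths invariant to a global gain.

## Synthetic data generator

The generator defines the study conditions rather than tuning itself to
the analysis.  Protocols: 12 directions × 4 TFs × 6 trials of 3 s drift +
3 s gray at 30.9 Hz (cortex); 8 directions × 3 trials (retina); 2-s flash
spots of 50–800 µm; periodic sweeps and 20-s (0.05 Hz) ISOI grating
cycles.  Direction convention: 0° = posterior (temporal-to-nasal on the
screen), angles counter-clockwise; retinal recordings report the same
angles with nasal↔posterior correspondence.

A cell's noiseless tuning is R(d) = A_tf · [(1 − dsi)/2 + dsi · g(d)] with
g a von Mises bump rescaled to g(θ) = 1, g(θ + 180°) = 0, which makes the
curve's DSI equal the generator parameter exactly.  The per-TF amplitude
A_tf couples to the preferred direction via a coupling coefficient that
ramps with TF, so posterior-preferring cells can grow their responses with
TF — the response motif whose prevalence differs between the control
(45% of cells) and mutant (12%) mixtures.  Those mixture weights, the
tuning-width range (κ ∈ [2, 6]), DSI range, TF-gain profiles and
trial noise (0.05 dF/F0) are the generator's defaults and double as the
conditions of all end-to-end tests.

Traces are F(t) = baseline · (1 + drift(t) + s(t)) + ε with s the drive
convolved with a single-exponential indicator kernel (τ = 0.6 s,
GCaMP6f-like; the kernel is our modeling choice), drift a sum of sinusoids
with periods > 120 s at 2% amplitude (so the 60-s percentile baseline is
actually exercised), and ε white Gaussian noise.  The expected pipeline
amplitude has a closed form (the top-half mean of the saturating
exponential step response), recovered to < 1% when the true baseline is
supplied.  A fast amplitude-level path draws trial amplitudes directly
from the closed form plus Gaussian noise; the population analyses consume
tuning curves, so this path exercises them fully at a fraction of the
cost.

Retinotopy stacks encode each pixel's coordinate as the phase of a
sinusoid at the sweep frequency (snapped to an exact DFT bin so recordings
span an integer number of periods — no leakage), plus a uniform delay
phase identical in forward and reverse sweeps, exactly the assumption the
subtraction method requires.  The six-area layout (V1 + LM/AL/RL/AM/PM
with alternating mirror polarity) keeps ≥ 8-px gaps between areas so the
σ = 2 smoothing cannot merge neighbors.

What the generator does *not* emulate: biophysical calcium dynamics and
spike-to-fluorescence nonlinearity, imaging noise beyond additive
Gaussian, motion artifacts, neuropil contamination, eye movements, and
hemodynamic point-spread.  Passing tests therefore demonstrate the
correctness and statistical behavior of the analysis chain, not the
robustness of the biology-facing preprocessing that the pipeline
deliberately leaves out of scope (motion correction, ROI segmentation).

## Problem sizes in the shipped checks

The end-to-end checks run at sizes chosen to exercise the statistics
meaningfully on a single CPU: 2000 cells for trace-level parameter
recovery (processed in chunks of 100), 800 cells per group for the
population-grid comparison (amplitude-level generation; stability checked
at 6×6, 8×8 and 10×10 grids), 160 × 192-px stacks over 4 sweep periods for
the ISOI round trip, and 2000 simulations of n = 50 for the Rayleigh
type-I rate.

## Known limitations

* The per-grid χ² tests are not independent across grids and are reported
  uncorrected by design; the optional FDR flag changes the classification.
* The Rayleigh p approximation loses accuracy below n ≈ 10.
* The delay estimator assumes one spatially uniform hemodynamic delay.
* The sign-map threshold mean(|I|) + SD(|I|) degenerates when responsive
  cortex covers nearly the whole field of view (threshold can exceed 1).
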