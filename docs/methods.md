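# Methods

This note documents the models, conventions and design choices behind
alffkit, in the order the pipeline runs.

## Preprocessing

Per subject: discard the first `n_discard` volumes (default 20, keeping
240 of a 260-volume acquisition at TR = 2 s), voxel-wise linear detrend,
then Gaussian spatial smoothing. The order is fixed and logged.

- **Detrending** removes the least-squares line *including the mean*, so no
  DC component can leak into the total-power denominator of f-ALFF.
- **Smoothing** uses a separable Gaussian with σ = FWHM/(2√(2 ln 2)) per
  axis in voxel units. The FWHM is not specified by the reference design;
  the default is 6 mm, the common single-subject choice, and configurable.
  Boundaries are handled by symmetric reflection: this keeps constant
  volumes exactly invariant (a property we test) while conserving total
  intensity for interior-supported inputs; zero padding would violate the
  former at the edges.
- **Band restriction** is an ideal spectral mask (DFT → zero out-of-band
  bins → inverse DFT) rather than a Butterworth/FIR filter, so the filter
  and the amplitude spectrum are exactly consistent. A bin at frequency f
  is in-band iff low ≤ f ≤ high (closed interval), applied identically in
  the filter and in the amplitude maps. The bandpass is exposed as an
  operation but is *not* part of the per-subject chain: both amplitude
  measures are computed spectrally from the unfiltered (detrended,
  smoothed) series, because filtering first would make the f-ALFF
  denominator equal its numerator.

## ALFF and f-ALFF

The one-sided amplitude convention is a_k = (2/n)|X_k| for interior bins,
with the unpaired DC and Nyquist bins not doubled; per-bin power a²/2
(a² at DC/Nyquist) satisfies Parseval against the series variance. ALFF is
the *mean amplitude* (square root of power) over the 0.02–0.07 Hz bins —
the field's standard, even though "energy" and "power" vocabularies are
often mixed; a `use_power` switch computes both measures on squared
amplitudes instead. f-ALFF is the in-band amplitude sum over the
(0, 0.25] Hz sum: DC excluded (detrending zeroes it anyway), Nyquist
included. The frequency grid is the unpadded DFT grid, so bin counts are
exact: n = 240 at TR = 2 s gives in-band bins k = 10..33 (24 bins) of 120,
hence the white-noise expectation E[f-ALFF] ≈ 0.2 used as a calibration
target (the single real-valued Nyquist bin makes the exact expectation
24/119.45; both are well within the ±0.01 test band). Subject maps are
standardized by the within-mask mean (divide mode, output mean exactly 1)
or z-scored.

Note on the noise-suppression property: a *multiplicative* broadband
amplitude difference between groups (gain- or vasculature-like, scaling
signal and noise alike) is flagged everywhere by ALFF and cancelled by the
scale-invariant f-ALFF ratio; this is the mechanism behind the fractional
measure's reputation for suppressing ventricle/cistern noise, and is what
the directional Monte-Carlo test asserts. An *additive* white-noise level
difference moves both measures (it dilutes the band fraction), so it is not
a valid test of suppression.

## Group statistics and clusters

Two-sample comparisons use the pooled-variance Student t (groups are
equal-sized by design; Welch is not offered), df = n_A+n_B−2, two-sided p.
Paired comparisons are one-sample t on differences. Degenerate voxels are
defined, not exceptional: zero pooled variance gives t = 0, p = 1 (logged);
a zero-variance nonzero paired difference gives t = ±∞, p = 0.

Cluster-extent thresholding binarizes p < 0.001, splits by the sign of t
(increase/decrease analyzed separately, mirroring separate higher/lower
tables), labels connected components (26-connectivity default; 6 and 18
available), and discards components with size ≤ 36 voxels — strictly
greater-than survives, per the printed "voxel size > 36" rule, and the
extent is configurable. No random-field or permutation cluster-level
p-value is computed: the reference analysis states a fixed extent rule and
provides nothing to calibrate against; this is a documented limitation.
Cluster peaks (max |t|) are reported in 0-based voxel indices and world mm
via the affine, and labelled by the atlas name at the peak.

## Depth autoencoder and classifiers

Encoder layers compute H = σ(Wx + d); the decoder mirrors the encoder's
dimensions and ends in a sigmoid so the summed binary cross-entropy
reconstruction loss is well defined on inputs in [0, 1] (reconstructions
are clamped to [1e-12, 1−1e-12] before the logs). The decoder maps the
hidden code, not the input. Hidden widths default to the three-hidden-layer
geometric schedule M → ⌈M/2⌉ → ⌈M/4⌉ → ⌈M/8⌉ and must decrease strictly
toward the code. Weights initialize Uniform(−1/√fan-in, 1/√fan-in) from the
seeded generator; biases start at zero.

Training is deterministic full-batch gradient descent, chosen over
stochastic updates for exact reproducibility: greedy layer-wise pretraining
(each layer as a one-hidden-layer autoencoder on the previous codes) then
end-to-end fine-tuning. The step size backtracks — halved whenever a step
would increase the loss, growing slowly (×1.2, capped at 100× the initial
rate) after accepted steps — which makes the recorded per-epoch loss
history nonincreasing by construction.

The classifier coupling: a softmax head on the code layer is trained
jointly with the encoder by gradient descent on the classification
cross-entropy (the classifier's loss adjusts the hidden weights). Because
full-batch descent on a tiny sigmoid stack can stall in a poor basin (the
classic exclusive-or local minimum), the supervised stage runs up to 5
seed-derived restarts with progressively jittered encoder weights, keeps
the run with the lowest final *training* loss, and stops early once the
loss is below 1e-3; determinism given the seed is preserved. The
"fine" features are the tuned encoder's code-layer activations. SVM
baselines (linear and RBF) come from scikit-learn; the autoencoder and
softmax are implemented from their equations, and the softmax's
probabilities row-sum to 1 within 1e-10.

## Efficacy scoring

The VAS weighted value (before − after)/before requires before > 0 and is
scale-invariant. Category boundaries are closed below and open above at
0.75/0.50/0.25; the total effective rate equals 1 − ineffective fraction.
Weighted values are fractions internally, percentages in reports; VAS
summaries print to one decimal, the scale's reporting precision.
Within-group weekly comparisons against baseline are paired; between-group
comparisons are pooled two-sample t, also available directly from printed
mean/SD/n triples (`two_sample_t_from_summary`).

## Synthetic data

The BOLD generator is sinusoids plus white noise: each voxel's series is a
baseline (100) plus 3 sinusoids with frequencies drawn uniformly in
0.02–0.07 Hz, unit amplitude, random phases, plus N(0, 1) noise; an
optional 1/f background adds spectral realism. Sinusoids-plus-noise is
chosen over filtered 1/f noise because the band-limited amplitude ground
truth is then analytic (a noiseless unit sinusoid has variance 1/2 and a
known bin amplitude). Inside planted atlas regions, treatment-group
sinusoid amplitudes are multiplied by the configured factor — a pure
band-limited group effect with known location and size. Every generator is
a pure function of its configuration and seed (cohorts derive per-subject
seeds via seed sequences).

Geometry: the full acquisition grid (64×64×30, 260 volumes, TR 2 s) is
available as a preset; the default experiment grid is 24×24×12 with
6×6×10 mm voxels so that the grid spans a head-like field of view, default
smoothing stays sub-voxel (keeping null voxel-wise tests nearly
independent, so binomial calibration bounds are meaningful), and a full
20-per-group cohort maps in seconds. The default mask is an ellipsoid
(~2500 voxels); the atlas plants a 60-voxel box ("region_1") in one
hemisphere with a mirrored unplanted box ("region_2") as a built-in
negative control.

Clinical tables draw each cell Normal(mean, SD) at the printed weekly group
summaries (treatment VAS 8.3±1.1 → 2.3±0.4; control 8.3±1.2 → 4.6±0.5;
sleep 3.6±0.3 → 5.8±0.6 vs 2.5±0.4 → 4.1±0.4), truncating VAS to [0, 10]
and sleep to ≥ 0 (rare at these SDs, and documented as deliberate). The
control group's week-1/2 VAS values are not printed anywhere and are
linearly interpolated (7.4 ± 0.8, 6.4 ± 0.8) — flagged as non-printed
values.

Feature tables: "linear" is two Gaussian blobs separated along a random
direction; "nonlinear" (the default for the raw-vs-fine comparison) places
each class in two diagonally opposite corners of the unit square in two
informative coordinates (cluster SD 0.06) among Gaussian nuisance
dimensions (SD 0.25) — no separating hyperplane exists, while a nonlinear
transform of two coordinates separates the classes with essentially zero
Bayes error. Concentric hyperspherical shells are available as
`structure="shells"`; they were not used for the directional comparison
because in moderate dimension the shell geometry favours distance-based
kernels over any small sigmoid encoder, making the comparison a test of
model capacity rather than of representation learning. Defaults (8
features, 150/class) were fixed once for test power; no effect sizes exist
to emulate. All features are min-max scaled to [0, 1], the loss domain.

## What the synthetic experiments do and do not show

Passing the planted-region recovery and calibration suites shows the
pipeline's statistics and cluster logic are correct and well calibrated
under a known generative model with near-independent voxel noise. Real
BOLD data adds spatially correlated physiological noise, motion, slice
timing, registration error and hemodynamic dynamics, none of which are
simulated; recovery rates here say nothing about sensitivity on real
scans, and the fixed-extent cluster rule's false-positive behaviour under
strong spatial correlation is untested by design.

## Problem sizes of the standard experiments

Recovery and null calibration run 20 independent cohorts of 20 subjects
per group on the reduced grid (≈50,000 voxel tests pooled for the null
check); the white-noise f-ALFF check uses 10,000 series of 240 points; the
classifier comparison uses 20 stratified 75/25 splits of a 300-row table.
The cluster decomposition is cross-checked against a brute-force flood
fill on 200 random masks at all three connectivities.

## Known limitations

- No Welch test, covariates, FDR/FWE or permutation inference.
- No motion/slice-timing/nuisance preprocessing; inputs are assumed
  co-registered (no resampling is performed anywhere).
- The autoencoder is plain (no denoising/sparse/variational variants), CPU
  full-batch only.
- Only the 0.02–0.07 Hz band and the (0, 0.25] Hz total band are
  implemented; no slow-4/slow-5 sub-band decomposition.
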