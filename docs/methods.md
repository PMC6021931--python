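# Methods

## The problem and the pipeline

Bitter-orange peel oil composition evolves with fruit ripening, and the
evolution is not monotone compound-by-compound: β-pinene-like volatiles dip
before rising, myrcene-like ones rise before falling, and many peaks barely
move at all.  `chromclass` classifies a headspace GC-MS total ion
chromatogram (TIC) into one of four ripening classes by (i) enhancing the
trace, (ii) extracting logged peak heights as features, (iii) training a
small multilayer perceptron under replicate-grouped double cross-validation,
(iv) pruning the input set by network sensitivity, and (v) anchoring the
accuracy claim with a label-permutation test.

## Chromatogram enhancement

**Log transform.**  Peak heights span several orders of magnitude (the
limonene-like peak alone sits ~2.5 decades above its neighbours), so the
trace is mapped through log10(intensity + offset), offset 1 intensity unit
by default.  The offset keeps zero-intensity points finite; because the
transform is monotone, apex positions are unchanged.

**psalsa baseline.**  The slowly varying background is estimated by
peaked-signal asymmetric least squares: iterate the Whittaker smoother
z = argmin Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²zᵢ)² with weights
wᵢ = p·exp(−(yᵢ−zᵢ)/k) where yᵢ > zᵢ and wᵢ = 1−p otherwise, until the
weight vector changes by less than `tol` (relative L1), at most `max_iter`
times.  The exponential decay makes points far above the baseline — peaks —
exert essentially no upward pull, which is what distinguishes psalsa from
plain asymmetric least squares and makes it robust across parameter
settings.  The linear system is pentadiagonal and solved with a symmetric
banded factorization (O(n) per iteration).

Defaults: λ = 10⁶, p = 0.001, k = 1% of the signal range (per trace),
max_iter = 50, tol = 10⁻³; all overridable.  Two defaults deserve comment:

* *k near the noise scale.*  k controls how quickly above-baseline points
  lose weight.  If k is of the order of peak amplitudes (e.g. 10% of the
  signal range), the broad log-domain wings of the dominant peak retain
  enough weight to drag the baseline up by ~0.15 logged units in the crowded
  10–13 min region, biasing every height there by ~30%.  With k at 1% of the
  range (≈ the logged noise scale) the measured bias on noiseless traces is
  under 0.7%.
* *λ = 10⁶.*  The instrument baseline drifts over tens of minutes, so a
  stiff penalty (smoothing length ≈ 30 grid points ≈ 0.25 min) follows it
  easily while refusing to bend into peak clusters.

**Noise statistics.**  The detection threshold is the noise mean plus three
standard deviations, estimated from the quiet region: the 20% of grid points
with smallest absolute corrected intensity.  Selecting the central fraction
of a (roughly Gaussian) noise distribution truncates it — the sd of the
central 20% of a Gaussian is only 0.146σ — so the raw sd of the selected
points is divided by the analytic truncation factor
√(1 − 2aφ(a)/(2Φ(a)−1)), a = Φ⁻¹((1+q)/2).  On pure N(0, σ) noise the
threshold then lands at ≈3σ as intended; without the correction it would sit
at ≈0.44σ and detection would drown in false positives.

## Peak detection and matching

Peaks are strict local maxima above the threshold (plateaus take the
leftmost point); apex height is the corrected intensity at the maximum.
With a 3σ threshold a few noise apexes per trace still survive, so matching
across traces must tolerate sparse spurious apexes.  Single-linkage chaining
of all pooled apexes is *not* robust here: a few hundred stray apexes pooled
over 303 traces are dense enough on the RT axis to bridge neighbouring
clusters into one.  `match_peaks` therefore uses support-weighted greedy
matching: repeatedly find the RT window of half-width `rt_tol` covering
apexes from the most *traces*, assign each trace's closest in-window apex to
a new cluster (median apex RT becomes the consensus RT), remove them, and
stop when no window reaches the presence requirement.  Clusters present in
at least `presence_threshold` of traces (default 1.0 — "consistently
detected in all chromatograms") form the registry.  Defaults: rt_tol
0.1 min, presence 1.0.  A trace with no detection matching a registry peak
is imputed with its own detection floor (the threshold) and flagged.

## Classifier and validation

The network has 1–2 hidden layers (hyperbolic-tangent or logistic sigmoid),
four linear outputs, one-hot targets, and a least-squares objective, trained
full-batch with resilient backpropagation in the iRprop⁻ variant: per-weight
step sizes grown by 1.2 on a stable gradient sign, shrunk by 0.5 on a flip
(with the gradient zeroed that step), bounded to [10⁻⁶, 50], initial step
0.07.  Rprop adapts only to gradient signs, which suits the badly scaled
least-squares surface of a sigmoid network and needs no learning-rate
tuning.

Validation is a three-way random subsampling repeated R times: per class,
round-to-nearest 70% of *oils* to training and 10% to internal validation,
remainder (≈20%) to external validation; all three replicates of an oil
always travel together (a hard assertion guards this in every partition, so
replicate identity can never leak across subsets).  A 27-oil class sends
exactly 19 oils to training.  Features are z-scored with training-row
statistics only.  Early stopping monitors the internal-validation CCR with a
patience of 30 epochs; ties in the (discrete) CCR are broken by the
validation squared error so the chosen epoch keeps improving margins after
the CCR saturates.  The architecture with the best mean internal CCR wins,
with candidates within one standard deviation resolved in favour of the
fewest weights; the winner is retrained per partition on the fused
train+internal data (for the early-stopped epoch count) and scored on the
untouched external set.  CCR is computed over replicate-level rows; an
oil-level majority-vote CCR is reported alongside but never used for
selection.  Per-partition external confusion matrices are row-normalized and
averaged in percent.

The reference partition count is R = 1000; the test suite and examples run
R = 2–100 depending on what the check needs, set explicitly at each call.

## Sensitivity analysis and sequential selection

For a trained network, the sensitivity of input j for class c is the range
(max − min) of output c while input j sweeps `grid_steps` (default 50)
equally spaced values over its observed [min, max] and every other input is
locked at its column mean.  Sensitivities are computed per partition model
(each probed through its own scaler) and averaged before ranking; using the
single best-CCR partition instead is a supported option.  The range
statistic is the simplest single non-negative summary of the response
profile consistent with reporting "sensitivity about the mean".

Per class, peaks are ranked by descending sensitivity (ties by ascending
peak id).  The sequential rank-addition search then grows the input set:
with a rank pointer starting at 1, advance to the lowest rank whose union of
per-class rank-r peaks contains at least one new peak, add all such peaks as
one step, and repeat until all P peaks are included — ranks contributing
nothing new are skipped without producing a step.  Each step's cumulative
set is scored under the same double CV (input layer resized), and the step
with the highest mean internal CCR wins, ties going to fewer peaks.  On the
shipped reference rankings of the 22-peak bitter-orange profile this rule
produces 13 steps with cumulative counts 3, 5, 7, 8, 9, 11, 13, 15, 16, 17,
19, 21, 22, the first step adding peaks {1, 11, 19}.

## Permutation significance

Class labels are permuted at the oil level (replicates keep one common
label; class sizes are preserved by construction), the cross-validation
procedure is re-run per permutation with the architecture held fixed, and
the mean external CCR of each permuted run builds the null distribution.
The observed (real-label) per-partition external CCRs are compared with the
null by a Mann–Whitney U test of equal medians — U of the observed sample
counts (observed > null) pairs with midrank tie handling; the p-value is
exact (full tie-aware permutation distribution via a subset-sum dynamic
program) when n₁·n₂ ≤ 400, otherwise from the tie-corrected normal
approximation with continuity correction — plus the empirical permutation
p-value (1 + #{null ≥ mean observed}) / (1 + n_perm).  Null runs default to
a reduced partition count (20) per permutation: the statistic is a
distribution comparison and is insensitive to this reduction, which keeps
n_perm = 200–1000 tractable; a flag restores full fidelity.

Calibration of the test under a true null (uniformity of the empirical
p-value) is checked on a deliberately small problem — 24 oils in classes of
4/6/8/6, six peaks, a single 3-unit hidden layer, two CV partitions per run,
100 independent repeats of a 99-permutation test — small enough to repeat
hundreds of pipeline runs while preserving the grouped-label, stratified
structure of the full design.

## The synthetic generator

The generator emulates the reference study design: 101 oils in classes of
11/27/36/27, triplicate measurement (303 traces), 22 Gaussian peaks at the
reference retention times (1.99–26.07 min) on a uniform grid of two points
per second over 0.5–28 min.  Each trace is

baseline(t) + Σⱼ 10^(hⱼ(class) + eo + rep) · exp(−(t−RTⱼ)²/2wⱼ²) + ε,

with ε ~ N(0, noise_sd) i.i.d. per grid point, a strictly positive baseline
(linear drift plus one broad cosine), and log10 apex heights composed of a
per-peak class mean, a per-oil effect (sd 0.15 log units, shared by the
oil's replicates), and a per-replicate effect (sd 0.05).  The oil and
replicate effects are *global* — they shift every peak of a trace equally,
modelling extraction-yield and injection-volume variation — which also means
a zero-separability study carries genuinely no class information usable by
the classifier.  Class trajectories are increasing, decreasing, U-shaped, or
flat; 15 of the 22 peaks are informative and 7 (including the limonene-like
giant at 10.45 min, base log-height 5.8 vs ≤3.5 for the rest) are flat.
Between-class contrast is ±0.25 log units scaled by a `separability` knob
(0 = chance-level problem, ≥5 = nearly separable), so calibration tests can
dial the difficulty without touching anything else.

Peak widths grow from 0.05 to 0.11 min (σ) with retention time; the closely
eluting 8.27/8.41 min pair is kept at σ = 0.04 min so both remain strict
local maxima — at wider settings the valley between them rises above the
smaller apex and the pair merges.

`simulate_log_heights` draws the identical statistical model directly at
the feature level (plus a 0.02-log measurement jitter standing in for
detection noise), skipping chromatogram rendering; classifier and
significance calibrations use it so their run times are dominated by
training, while chromatogram-level fidelity is exercised by the
preprocessing, detection, and matching tests on full rendered studies.

What the generator does **not** emulate: retention-time drift between runs
(no alignment is implemented, matching relies on stable RTs), non-Gaussian
or heteroscedastic detector noise, co-eluting isomers, saturation, and
per-scan mass spectra.  Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical model, not instrument-grade
robustness.

## Numerical and degenerate-input choices

* Whittaker system solved via `scipy.linalg.solveh_banded`; a dense solver
  cross-checks one fixed-weight iteration to 10⁻⁸ in the tests.
* Non-convergence of the psalsa weight iteration returns the last iterate
  with `converged=False` rather than raising.
* Zero-variance feature columns standardize to zero with a warning (unit
  divisor).
* All-identical Mann–Whitney samples give p = 1 by definition.
* Plateau maxima resolve to the leftmost point; rank ties to the smaller
  peak id; architecture ties to fewer weights; selection-step ties to fewer
  peaks; oil-level majority-vote ties to the smallest class label.
* Every stochastic component takes a `numpy` Generator or integer seed;
  per-partition and per-training seeds derive deterministically from the
  master seed via `SeedSequence`, so equal seeds give bit-identical runs.

## Known limitations

* Levenberg–Marquardt training is not implemented; resilient
  backpropagation is the only trainer.
* No peak-area integration or overlap deconvolution; heights only.
* The matcher assumes retention times stable within `rt_tol` across runs.
* The default synthetic study at separability 1 is considerably easier than
  real ripening data (external CCR near 1.0 vs ~0.7–0.8 expected on real
  oils); the separability knob, not the default, is the instrument for
  studying classifier behaviour near chance.
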