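# Methods

`axisdyn` implements a time-resolved linear-encoding analysis of visual
neural populations, organized around one question: does a population of
face-selective cells keep a single fixed preferred axis in a deep-network
feature space, or does its code switch — abruptly and only for faces — from a
category-detection axis to a face-specific discrimination code? Because the
neural recordings that motivate the analysis are not publicly distributable,
every stage is driven by a synthetic population generator with known ground
truth, and the test suite scores the pipeline on its ability to recover that
truth and to stay quiet on matched controls.

## The encoding model

A cell's response to a stimulus with feature vector **f** ∈ ℝᴷ is modelled as

    r = ⟨c, f⟩ + r₀,

where **c** is the cell's *preferred axis* (Hz per feature unit) and r₀ an
offset. Features are obtained by PCA of stimulus embeddings (K = 60 by
default) with each component rescaled so the fitting stimuli have zero mean
and unit s.d. per dimension. Axes are estimated per cell and per time window
by ordinary least squares on a training split and evaluated as R² on a
held-out split (R² = 1 − SSE/SST with SST about the test-set mean; R² := 0
when SST vanishes; negative values are reported as-is).

The closed form `c = (r − r̄) F (FᵀF)⁻¹` pins the intercept at the mean rate
and equals OLS only when the features have zero mean over the regression
set. Under the global normalization, the face category has a decidedly
nonzero feature mean, which biases face-axis directions even for exactly
linear noiseless cells (we measured a median cosine of 0.90 to the
generating axes). We therefore read the closed form as shorthand for linear
regression with a free intercept and center features on the training subset
by default (`center_features=True`); the raw closed form remains available
and is covered by tests.

## The synthetic population generator

`make_stimulus_set` draws Gaussian embeddings with a decaying variance
spectrum (s.d. ∝ k^(−1/2)), mimicking the PCA spectrum of deep-network
features where leading dimensions carry most stimulus variance. Faces are
displaced from objects by an offset (default 4 embedding-s.d. units on the
first two dimensions), so the category contrast collapses onto the first
feature PC — the *detection direction* — and the within-face variance along
it is compressed, the "DC component" of faces.

`make_switching_truth` builds per-cell ground truth:

- **early axes**: positive loadings on the first `flip_dims` dimensions
  (default 1, the detection direction) plus small random high-dimensional
  components (`highdim_sd = 0.02`), guaranteeing positive alignment with the
  population detection direction;
- **late face axes**: the detection loadings negated, plus fresh independent
  loadings on the next `new_dims` dimensions (default: all remaining) —
  reversal in low dimensions, novel tuning in high ones;
- **object axes**: identical to the early axes at all times.

`loading_style="halfnormal"` spreads the detection loadings more widely, for
experiments that need a diverse low-dimensional early code (the decoding
trade-off below). Per-cell gain ~ U(4, 8) Hz per feature unit and baseline
~ U(10, 20) Hz keep expected rates essentially nonnegative, so the
population actually samples the linear model the analyses assume;
rectification engages only in the extreme tails (< 1% of bins).

The response of cell *j* to stimulus *i* is

    rate(t) = baseline_j + gain_j · ⟨axis_j(t, category_i), f_i⟩ · k(t − latency_j),

rectified at zero. The temporal kernel k is a difference of exponentials
(rise 10 ms, decay 40 ms) riding on a saturating sustained plateau (relative
amplitude 0.35, peak-normalized): visually driven inferotemporal responses
are transient-then-sustained, not transient-then-silent, and a purely
transient kernel would make *any* cross-window decoder fail for trivial
amplitude reasons rather than because of a code change. Response latency is
50 ms plus per-cell jitter U(0, 20) ms, placing the population response peak
near 80–90 ms and leaving signal inside the earliest analysis windows (which
begin at 50–60 ms). The axis switch is instantaneous at 100 ms (an optional
10-ms linear crossfade exists but is off) and applies to face stimuli only.

Noise is either Gaussian per 1-ms bin per repeat (rectified after adding, the
repeat average stored) or Poisson (per-bin counts with the rectified mean as
intensity; the sum over repeats is drawn as a single Poisson variate, which
is exact). `calibrate_gaussian_sd` chooses the Gaussian s.d. so that a
stated analysis window reaches a target held-out R², accounting for both the
window/repeat averaging and the K/n inflation of OLS test error:
σ² = s²(1 − t)/(t + K/n_train), with s the across-stimulus signal s.d.

Three *cell-intrinsic artifact* generators produce populations whose axes
never change but whose response time courses could be mistaken for a switch:
gain that drops after 100 ms ("magnitude"), per-stimulus latency inversely
related to drive ("delayed_weak"), and a raised firing threshold after the
transient ("threshold"). Reversal detectors must report no flip on all three.

### What the generator does not emulate

Spike-train structure (rates only), adaptation beyond the threshold
scenario, correlated noise across cells, eye movements, stimulus-history
effects, and the full geometry of real deep-network embeddings (our
embeddings are Gaussian; real fc6 features are non-Gaussian and the
face/object manifolds are curved). Passing tests therefore certify the
*analysis machinery* — estimator correctness, detector sensitivity and
specificity, the logic of the controls — not the empirical claims about
cortex, which require the original recordings.

## Time-resolved analyses

Axes are fit in half-open, non-overlapping [t, t+20) ms windows over 0–300
ms, with one train/test split per category reused across windows. From the
axis time courses we compute window × window mean-cosine matrices for
(object, object), (face, face) and (face, object) pairs; the diagonal of the
last is the face–object alignment time course. Per-cell *flips* are declared
when the angle between the early (80–100 ms) and late (120–140 ms) face-axis
projections onto the first two feature dimensions exceeds 120° (120° rather
than 90° to capture only clear reversals; the threshold is a parameter) and
both windows pass the held-out R² > 0 inclusion rule. The flip time is the
first window whose 2-D cosine to the early axis falls below cos 120°;
divergence time is the first of two consecutive windows with negative cosine
to the trial-wide (50–220 ms) object axis. A per-cell adaptive short-latency
window (first 20-ms window ≥ 2 s.d. above the −25–25 ms baseline, with a 0.1
Hz s.d. floor for silent baselines) accommodates latency heterogeneity.

Anterior-patch (AM) analyses use the same machinery with all windows delayed
20 ms (`area_offset_ms`/`offset_ms` parameters); no other area-specific
logic exists.

## Population statistics

- **d′ per 1-ms bin**: standardized face-object mean difference; peak d′ is
  the maximum 20-ms sliding-window mean with window starts in [80, 120] ms.
  When both category variances vanish, d′ is 0 for equal means, else clipped
  to ±10.
- **FSI**: (r_face − r_nonface)/(r_face + r_nonface) over 50–220 ms.
- **Visual responsiveness**: two-sided t-test of −50–0 ms against 50–300 ms
  mean rates, paired across stimuli (the tensor stores repeat averages, so
  pairing across raw trials is not available; unpaired is an option).
- **Population sparseness**: S = 1 − (Σⱼrⱼ)²/(N Σⱼrⱼ²) per stimulus and
  time; 0 for uniform, 1 − 1/N for one-hot, NaN for silent vectors. An
  optional 20-ms boxcar smooths rates first — at realistic repeat counts,
  per-bin noise otherwise dominates the statistic.
- **PSI**: mean pairwise Euclidean distance between group-mean population
  vectors divided by the pooled response s.d. of the window. Categorization
  uses the face/object groups; discrimination treats each face stimulus as
  its own identity. PSI is invariant to scaling and to a common additive
  rate.
- **Dimensionality**: the number of PCs explaining 90% of the variance of
  the per-cell z-scored window response matrix, with stimulus bootstrap and
  paired early/late comparison.
- **Single-stimulus axis-change score**: for each stimulus, the Pearson
  correlation across cells between the raw 60–80 ms and 100–120 ms
  population vectors (no per-cell normalization; cells with extreme 50–220
  ms mean rates — outside the 1st–99th percentile band — excluded), mapped to
  a face probability by an unregularized single-feature logistic regression
  with inverse-frequency class weights, trained on a 50% split and scored on
  all stimuli. Rank reversal is expressed in the ratio of evoked to baseline
  rate spread, so tests of this score use an evoked-dominated population
  (gain U(8, 16), baseline U(2, 6)).

## Tuning geometry

The late axis ν₂ is split into ν∥ + ν⊥ relative to the early axis ν₁, with
ν₁ normalized to unit length first (the printed projection formula is
dimensionally consistent only then). ν⊥ is the newly emergent tuning
direction; the "principal orthogonal direction" is the first PC of the
stimulus features after removal of their ν⊥ component, used as a
visualization ordinate. Feature-space points along ν⊥ are sampled at
[−4, −2, −1, 0, 1, 2, 4] σ of the stimulus projections; image synthesis from
those points is out of scope.

## Decoding experiments

Latent feature vectors (the unnormalized PCA scores of the embeddings, whose
decaying spectrum mirrors a generative model's latent space) are decoded
from stacked responses in two 25-ms sub-windows per named window — short
(50–75, 75–100), long (120–145, 145–170) and combined (62–87, 132–157) ms,
equal total duration, sub-windows treated as distinct cells. Decoders are
ridge regressions with the penalty chosen on a validation fold. Decoded
latents are identified by nearest-neighbor matching (Euclidean, optionally
through a linear metric map) against the held-out references; ties break to
the lowest index.

On a switching population, a short-window decoder applied to long-window
responses identifies at chance while in-window decoders do not; a matched
no-switch control (same noise level, late axes equal to early) shows no such
collapse, though transfer is degraded by per-cell amplitude differences
between windows — the discriminating contrast is collapse-to-chance, not
perfect transfer. The redundancy-versus-diversity trade-off (few cells: a
redundant low-dimensional code wins; many cells: a diverse full-dimensional
code wins) is reproduced both with simulated linear units (random
combinations of the first 5 of 60 latent dimensions vs of all 60, Gaussian
noise) and with neural populations whose early axes span the leading five
dimensions diversely (`flip_dims=5, loading_style="halfnormal"`, noise
calibrated at the early window).

## Recurrent mechanism model

A 100-unit rate network, h_t = tanh(x_t + W h_{t−1}), is trained for 10,000
iterations of Adam (learning rate 10⁻³, batch size one) to output the
reversal −x at the second of two timesteps given the same random linear
gradient x at both steps. Gradients are x_i = a·(i/n) + b with a, b ~
N(0, 0.2²); the amplitude matters: with unit-scale draws the target −x
routinely exceeds the tanh output range and the loss has a large irreducible
floor, making the task unlearnable in principle. At amplitude 0.2 the
trained solution approaches W ≈ −2I — lateral inhibition — and the smoothed
loss falls by well over 90%. (An alternative "random direction with graded
magnitude" input and a linear readout are provided as options.) Gradients
are computed by hand-derived backprop through the two-step unroll
(`loss_and_grad`) and verified against central finite differences to 10⁻⁶.
After training, each unit's activation at t = 1 and t = 2 is regressed on
the gradient parameters (a, b); the population-mean cosine between the two
tuning vectors is strongly negative for the reversal target, positive for an
identity-target control, and exactly +1 for W = 0.

## Numerical conventions

- Windows are half-open [start, end) ms everywhere; time is in ms relative
  to stimulus onset on a 1-ms grid starting at −50 ms.
- PC signs are fixed by making each component's largest-magnitude loading
  positive, so feature spaces and axis signs are reproducible bit-for-bit.
- R² uses a relative SST floor (10⁻²⁰ of the response energy) so that
  constant responses contaminated only by float rounding still report 0.
- Cosines of zero-norm vectors are NaN and excluded by nanmeans; the
  normalized face–object correlation refuses to normalize (returns NaN) when
  its split-half upper bound is below 0.1.
- All randomness flows through explicit integer seeds; there is no global
  random state. Identical seeds give bit-identical populations, fits and
  summaries.

## Problem sizes

Unit tests run on 120 + 120 stimuli, 24-D embeddings, K = 12, 25 cells.
Acceptance-level experiments use 300 + 300 stimuli, 80-D embeddings, K = 60
and 100 cells with 10 repeats — large enough that axis fits have n/K ≈ 4.5
and identification uses 45 held-out faces, small enough that the whole suite
completes in minutes on one core. These sizes are the package's simulation
defaults, scaled down from the motivating experiments (~1,500 faces, ~1,400
objects, hundreds of cells) while preserving every qualitative regime.

## Known limitations

- The generator's embedding model is Gaussian; conclusions about real
  deep-network feature geometry do not follow.
- The no-switch cross-window decoding control retains an amplitude-transfer
  penalty (latency jitter × kernel shape); only the collapse-to-chance
  contrast is diagnostic.
- The flip classifier is a fixed-threshold proxy for what a human rater
  would call a "clear" reversal; the 120° threshold is exposed and its
  sensitivity can be scanned.
- The identity-PSI late peak depends on the early code being
  detection-dominated (little identity variance); populations with rich
  early identity tuning can peak earlier without contradicting the
  machinery.
- The dimensionality-for-90%-variance comparison has no power under
  isotropic measurement noise at the calibrated level (noise inflates both
  windows' spectra toward the full rank); it is scored on the noiseless
  population, where the late window cleanly needs more dimensions than the
  early one.
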