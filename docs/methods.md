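# Methods

## Data model and conventions

All analyses operate on `PopulationDataset`: a rate tensor indexed
`(condition, time, neuron)` on a uniform time grid with step `dt_ms`.
Wherever conditions are stacked (`StackedMatrix`), rows are time samples
and columns are neurons — one fixed orientation throughout, since the
literature alternates between `X` and `Xᵀ` conventions.  Time derivatives
are always taken per condition block with `numpy.gradient` (second-order
central differences inside a block, one-sided at block edges) and never
across the seam between two conditions.

## The travelling-wave generator

`generate_dataset` draws

    rate[l, t, j] = (A_l + ε_A) · exp(−((t − (b·j + a + ε_k)) / (σ + ε_σ))²)

with per-(condition, neuron) noise ε_A ~ N(0, eps_A), ε_k ~ N(0, eps_k),
ε_σ ~ U(0, eps_sigma).  Noise perturbs wave *parameters*, not samples:
every trace remains a smooth Gaussian bump, only its amplitude, timing and
width jitter across the population.  (The width noise is Uniform rather
than Normal so that σ + ε_σ can never go non-positive.)

Defaults (the reference conditions used in tests and the acceptance
script): 8 conditions, 200 neurons, 200 time samples, amplitudes `A_l`
evenly spaced over [0.5, 1.0], a = 0, b = 1 sample/neuron, σ = 10 samples,
all noise zero, `dt_ms = 1`.  Two of these deserve comment:

- **a = 0, t = 200 (corner-clipped wave).**  With the wave placed well
  inside the window, the differential covariance of noise-free data is
  skew-symmetric to machine precision — the decay axis of the gyration
  plane is then degenerate (x ≡ 0) and a near-standing wave (b → 0)
  reduces to an exactly planar flat ellipse with y = 1, which is not the
  behaviour the measure is meant to expose.  Starting the wave at the
  window corner clips its leading edge, which is exactly what produces the
  decay component: with b → 0.01 every neuron's bump is cut in half at
  t = 0, the population merely relaxes to baseline, and the measure
  correctly reports pure decay (x ≈ 1, y ≈ 0).  Increasing `a` shrinks the
  decay component continuously.
- **Amplitude spacing.**  `A_l` is evenly spaced by default (a
  `random_amplitudes` flag switches to uniform draws).  The amplitude
  spread across conditions is the inter-conditional variation that
  structural rotation feeds on; the noise scales control the
  intra-conditional variation that destroys it.

What the generator does *not* emulate: multiphasic or multimodal responses,
non-constant wave speed, baseline firing, trial-to-trial variability, and
any sampling/binning noise.  Tests passing on this model therefore
demonstrate correctness of the *measures*, not fidelity of the model to any
particular recording.

## Preprocessing

The standard chain (`preprocess.apply`) is Gaussian smoothing → optional
crop → soft-normalization → cross-condition mean subtraction.

- Smoothing std defaults to 20 ms (middle of the conventional 10–30 ms
  range), kernel truncated at ±4 std, reflect boundaries.  Kernel width
  materially changes rotation scores: smoothing suppresses the
  high-frequency modes that phase jitter injects, and without it the
  rotation coordinate bottoms out at a noise floor instead of decreasing
  monotonically with phase noise.  Conversely, a 20 ms kernel applied to a
  wave whose whole sweep lasts ~20 samples flattens it into near-synchrony
  (pure decay) — choose the kernel relative to the wave's time scale.
- Soft-normalization divides each neuron by its pooled (all conditions,
  all times) range plus a constant, default 5: low-rate neurons are tamed
  rather than amplified.  The range is pooled, not per condition, so
  relative condition amplitudes survive.
- Cross-condition mean subtraction is an idempotent linear projection; it
  recentres trajectories but does not change whether the stacked data
  rotate, so `gyration_number` results are stable to this flag.

## Gyration number

Three steps: stack conditions, eigendecompose the differential covariance
(`XᵀẊ` when n ≤ c·t, otherwise `ẊXᵀ` — the nonzero spectra coincide, and
zero eigenvalues contribute nothing to the normalization), then

    x = (|Re λ₁| + |Re λ₂|) / Σ|λᵢ|,   y = (|Im λ₁| + |Im λ₂|) / Σ|λᵢ|

with (λ₁, λ₂) the modulus-leading conjugate pair (relative conjugacy
tolerance 1e-6), or the two largest-modulus eigenvalues when the spectrum
is real.  Both coordinates are bounded by the pair's power share, hence lie
in [0, 1].

**Classification.**  A dataset is called structurally rotational when
y ≥ x (the empirical main-diagonal rule) *and* the leading pair's power
share exceeds `dominance_threshold`.  The threshold defaults to 0: a
genuinely multi-mode travelling wave (the reference dataset) concentrates
only ~0.2 of its unsmoothed spectral power in the leading pair, so any
sizeable default would reject datasets that are plainly rotational by every
other diagnostic.  The share is always reported, and callers who want the
stricter "pair dominates the spectrum" reading can set the threshold.

Interpretation notes established on the generator: phase noise, amplitude
noise and condition-rearranging shuffles all pull y toward the origin
(higher intrinsic dimensionality); faster, narrower waves empty the decay
axis (x → 0) while *spreading* power over more imaginary pairs (lower y);
slower, wider waves concentrate power in fewer pairs (higher y) until the
corner cutoff turns them into pure decay.

## jPCA

`fit_skew` reduces to k PCA dimensions (default 6, must be even), then
minimizes ‖Ẋ − XMᵀ‖_F over skew-symmetric M.  The minimizer solves the
Lyapunov equation `A W + W A = B − Bᵀ` (A = XᵀX, B = XᵀẊ, M = Wᵀ),
computed with `scipy.linalg.solve_sylvester` and symmetrized so the skew
constraint holds exactly; the problem is convex, so this is the global
optimum.  The rotation plane is the real invariant subspace of the
eigenvalue pair with the largest |Im|, oriented so the mean signed angular
velocity across conditions is counter-clockwise.  `fit_r2` is the fraction
of derivative variance explained; the unconstrained least-squares fit is
available as a baseline that the constrained fit can never beat.

Caveat on cross-method frequency comparisons: jPCA ranks planes by
rotation *frequency* within the retained PCA subspace, while the
differential covariance ranks modes by *power*.  On multi-mode data the two
orderings pick different modes; they agree (to within ~10%) only when the
data are essentially planar, which is how the agreement test is set up.

## Curvature

`κ = √(|x′|²|x″|² − (x′ᵀx″)²)/|x′|³` with numerical gradients; equal to
the 3-D cross-product formula (verified to 1e-8 on random smooth curves)
and invariant to orthogonal maps, translations and time reparameterization.
The first and last two samples involve one-sided stencils and are excluded
from the `interior` view and from `curvature_mae` by default.  Zero-velocity
samples yield NaN (undefined), never 0 or ∞.  `curvature_mae` clips both
profiles at 1000 before averaging so near-cusps created by projection do
not dominate; κ is unsigned, so S-shaped direction reversals are invisible
to it.

## Numerical choices and degenerate inputs

- PETH: Min-Max normalization is per neuron pooled over conditions; peak
  times come from the across-condition average of the normalized data
  (computing them after mean subtraction would be vacuous — the
  across-condition mean of mean-subtracted data is identically zero); sort
  is stable with ties broken by original index; constant neurons map to
  zero rows with a logged warning.
- Wave fits: initialization A₀ = max, k₀ = argmax, σ₀ from the half-width
  at half-maximum; bounds σ ∈ (0, span], k within grid ± span/2; at most
  10⁴ function evaluations; non-convergence and zero-variance series are
  flagged, not raised.  No baseline term is fitted.
- Shuffles are seeded reconstructions of the published controls
  (approximate — the original definitions live in external articles):
  per-neuron condition permutation, time reversal for a random half of
  neurons, and per-neuron condition resampling with replacement.  The two
  condition-rearranging kinds reliably lower y on wave data; time reversal
  of half the population does *not* (on noise-free waves it leaves the
  skew structure essentially intact, even slightly increasing y), so no
  blanket "shuffles reduce rotation" claim is made.
- Eigensolvers: `numpy.linalg.eigvals/eigh`; spectra are sorted by modulus
  with deterministic tie-breaks; conjugate closure of real-matrix spectra
  is asserted in tests at 1e-8 relative tolerance.

## Problem sizes

Tests and the acceptance script run the reference geometry (8 × 200 × 200)
for gyration analyses, 10⁴-sample analytic curves for curvature, 8 × 800
samples for generator recovery, and 400 per-neuron fits for the wave-fit
recovery; noise sweeps and shuffle comparisons use 20 seeds per condition.
These sizes make every quantity stable to three significant figures while
keeping the full suite under a minute on one CPU.

## Known limitations

- The gyration number is scale-free but not noise-model-aware: it reports
  where a dataset sits, not a significance level.  No null distribution is
  provided.
- A perfectly planar flat ellipse scores y ≈ 1 even when its minor axis is
  microscopic; with corner-clipped data this regime instead appears as
  decay, but uncropped near-standing waves will look maximally rotational.
- Curvature is unsigned and undefined at stationary points; trajectories
  that pause mid-window produce NaN gaps.
- File formats are deliberately minimal (one archive dialect, one
  delimited-text dialect); readers for specific public datasets are out of
  scope.
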