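# Methods

This note documents the models implemented in `peakshift`, the estimation
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Morphometrics

**Superimposition.** Landmark configurations are centred, scaled to unit
centroid size, and rotated to a consensus by least squares; the consensus
is the mean of the aligned shapes, re-centred and re-scaled, iterated until
it changes by less than 1e-10 (hard cap 200 iterations at the inner level,
50 at the sliding level). Species means are computed first, from a
within-species superimposition, and the grand alignment then operates on
the species means, so the consensus is a grand average of species
averages. Because a Procrustes alignment is only determined up to a global
rotation, the consensus is rotated to its principal axes with a
deterministic sign rule; this makes the output invariant (to ~1e-8) under
arbitrary rotation/translation/scaling of the inputs. The convention is
unstable only in the degenerate case of an isotropic consensus.

**Scale.** Configurations are fixed at unit centroid size during alignment
(partial Procrustes); centroid sizes are recorded beforehand, per species
as the mean over specimens. The Procrustes *distance* between two shapes
additionally optimizes a relative scale, giving the full Procrustes
distance d = sqrt(1 − |⟨z₁, z₂⟩|²) in the complex representation,
evaluated through the explicit residual to stay accurate near zero.

**Semilandmark sliding** minimizes the Procrustes criterion, not bending
energy: each semilandmark is projected onto the line through its current
position along the chord between its curve neighbours (curve order = point
order), which is the exact one-dimensional minimizer of its distance to
the consensus. One sliding pass alternates with re-superimposition; the
total Procrustes sum of squares is non-increasing and iteration stops when
it improves by less than 1e-8 or after 50 rounds. Sliding on a sampled
curve has a near-degenerate mode — the whole point sequence can creep
along the curve with almost no change in fit — which is why convergence is
defined on the criterion, not on coordinates, and capped.

**Component retention.** Horn's parallel analysis compares eigenvalues on
the correlation-matrix scale (the observed data are standardized before
eigendecomposition) against the 95th percentile of eigenvalues from
standard-normal data of the same n × p, because the random reference is
generated with unit variances; covariance-scale eigenvalues of Procrustes
coordinates would not be commensurable with it. Retention stops at the
first component that fails. Defaults: 1000 replicates, 95th percentile.

## Phylogenetic machinery

Trees are rooted, strictly binary, with branch lengths in time units (My
throughout the defaults). Ancestral states for continuous traits are the
joint Brownian-motion ML values, obtained by solving the weighted-Laplacian
linear system (each node value a branch-length-weighted average of its
neighbours); the root estimate equals the GLS grand mean. Discrete states
use an equal-rates Mk model — the minimal ML choice when no model is
specified — with the rate fitted by bounded search on the pruning
likelihood and marginal node probabilities from the down-pass/up-pass
recursion with a flat root prior. Regime painting assigns each node its
maximum-probability state (ties resolve toward the parent; root ties to
the first label) and each branch the state of its child node: a branch's
evolution is attributed to the regime it evolves toward. Within-branch
regime switches are not modelled; users who need a switch partway along a
branch can subdivide the branch and supply the painting directly.

## PGLS under the OU covariance

The regression error covariance is V_ij = γ·exp(−α·t_ij) with t_ij the
patristic distance: the influence of shared ancestry decays exponentially
at rate α (units 1/My) as stabilizing selection erases history, and γ is
the equilibrium interspecific variance. γ concentrates out analytically as
the GLS residual variance per response; α is profiled by bounded 1-D
search on the log scale over [1e-6, 1e3]/My, with both boundary values
checked. One α is shared across all responses (a single V). At small α the
matrix exp(−α·t) approaches the singular all-ones matrix; a 1e-10 ridge is
added only if the Cholesky factorization fails. Inference: per-predictor t
statistics on the whitened data with df = n − m − 1, partial correlations
r = t/sqrt(t² + df), R² = 1 − RSS/TSS on whitened data, GLS variance
inflation factors, and a Wilks'-lambda multivariate test via Rao's F
approximation. Null p-values are uniform by simulation (KS test in the
suite).

## Disparity through time

Disparity is the mean pairwise distance among species: squared Euclidean
for multivariate shape (an `squared=False` flag gives plain Euclidean, as
the two conventions coexist in the literature), Manhattan for rank-valued
diet profiles (raw ranks, not diet PCs). The DTT curve evaluates, at each
internal node ordered by time from the root, the mean of clade disparity /
total disparity over every lineage alive immediately after that event;
singletons contribute zero, the relative time axis is node time / tree
depth, and a terminal point (1, 0) is appended. The null envelope
simulates Brownian motion with the rate covariance estimated from the
observed contrasts and takes pointwise 2.5/97.5 percentiles of the
simulated curves (median as the central line); a simultaneous band is not
attempted. Rank-deficient rate matrices (e.g. diet ranks with a
nearly-constant column) are regularized by a small ridge with a warning.

## Multi-peak Ornstein–Uhlenbeck model

The phenotype follows dX = A(θ_r − X)dt + S·dB with A symmetric positive
definite and shared by all regimes, Σ = SSᵀ, and θ_r the optimum of the
regime painted on the current branch. Conditional on a fixed root state
(non-stationary formulation), the expected tip phenotype is a weighted sum
of optima: a lineage segment (t_a, t_b] in regime r contributes the matrix
weight e^{−A(T−t_b)} − e^{−A(T−t_a)}, and the root state carries weight
e^{−AT}; the weights sum to the identity. Tip covariances follow from the
eigen-decomposition A = UΛUᵀ: in the eigenbasis, entry (k, l) for tips
with shared time s and depths T_i, T_j is
D_kl·e^{−λ_k(T_i−s)}·e^{−λ_l(T_j−s)}·(1 − e^{−(λ_k+λ_l)s})/(λ_k+λ_l),
with the bracket replaced by s in the (λ_k+λ_l) → 0 Brownian limit
(evaluated via expm1 for stability).

**Estimation.** For given (A, S) the optima are concentrated out by GLS
against the full (np × np) covariance; the root state is tied to the
root-regime optimum (its weight is folded into that regime's design
column), since the parameter counts of the reference analyses leave no
room for a separate root parameter. The outer problem maximizes the
Gaussian likelihood over the log-Cholesky factor of A (guaranteeing
symmetric positive-definiteness) and a lower-triangular S with
log-parameterized diagonal, starting from identity matrices. The outer
search uses L-BFGS-B with numerical gradients (tolerance 1e-8, default cap
5000 evaluations, one restart from the first solution): the surface is
smooth in this parameterization and the quasi-Newton search reliably
reaches a better optimum than a derivative-free simplex in roughly a tenth
of the evaluations. Near-singular design or covariance matrices receive a
minimal ridge with a warning. Under very strong selection the tips sit at
stationarity and only θ and the ratio of Σ to A remain well identified — A
itself can be estimated much larger than its generating value with no
likelihood cost; optima remain accurately recovered in that regime.

**Model set and selection.** Candidates: Brownian motion plus OU.2–OU.5,
derived from one five-regime painting by merging labels (two masticatory
super-categories; splitting out sanguivory and nectarivory; lumping
insectivory and carnivory as animalivory; all five). Free parameters:
2·p(p+1)/2 + p·n_θ for OU (at p = 1 this is 2 + n_θ: one α, one σ shared
by all peaks), p(p+1)/2 + p for BM. AICc = −2lnL + 2k + 2k(k+1)/(n−k−1)
and SIC = −2lnL + k·ln n use effective sample size n = n_species × p
(total observations): with ~49 species and k up to 55 the per-species
convention would make the AICc denominator negative, so total observations
is the only workable reading; it is exposed as the `n` recorded in every
score. Weights: w_i ∝ exp(−Δ_i/2), Δ_i = value_i − min.

**Bootstrap.** Parametric: datasets are simulated from the fitted model
(root at the root-regime optimum) and optima re-estimated per replicate.
(A, S) are re-estimated by default (full parametric bootstrap, warm-started
at the fitted values) with a flag to hold them fixed, which reduces each
replicate to a single precomputed GLS solve and is the setting used for
the large simulation studies in the test suite. 95% regions: percentile
intervals (univariate) or mean + sample-covariance ellipsoid at the
chi-square 0.95 quantile (multivariate). Replicates that fail are dropped;
more than 10% dropped is an error. Default 5000 replicates.

## Synthetic data

The generators reproduce the statistical assumptions of the analysis, at
the scale of the motivating study system:

- **Trees**: random pairwise-join (Yule-topology) ultrametric trees,
  rescaled to exact depth (default 30 My, 49 tips). The analysis
  conditions on the tree, so any ultrametric shape serves as a null.
- **Regime histories**: symmetric Markov jumps at `switch_rate` events/My
  (fixture default 0.03, giving on the order of one switch per root-to-tip
  path, matching a radiation where most diet shifts happened once); jumps
  always move to a different regime, so recorded per-path jump counts are
  Poisson(rate × depth).
- **Traits**: exact branch-by-branch sampling from the OU transition
  distribution (mean via matrix exponential, covariance via the integral
  above); A = 0 reduces exactly to Brownian motion. Fixture: p = 5 traits,
  leading selection eigenvalue ≈ 0.15/My (phenotypic half-life ≈ 4.6 My),
  stationary SD ≈ 0.1, optima separated by 0.35 — strong, detectable
  regime structure. Skull length is a univariate OU with optima 17–26 mm
  around an insectivore optimum of 20 mm.
- **Diet ranks**: the focal item of a species' regime gets rank 2–3,
  sanguivores are strict (0,0,0,0,3), and complementary rank-1 items are
  drawn with regime-specific probabilities chosen to build in the
  animalivory structure (insectivory and carnivory co-occur, frugivory
  trades off against them) that the diet PCA is expected to expose.
- **Landmarks**: per-regime mean shapes perturbed by isotropic Gaussian
  point noise, then randomly rotated, translated and scaled so that
  superimposition is non-trivial.

What the generators do **not** emulate: measurement error distinct from
biological variation, within-species phylogenetic structure, non-ultrametric
sampling, correlated (non-isotropic) landmark noise, diet variation inside
a regime beyond the rank probabilities above, and any form of
diversification-rate variation. Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to their violation.

## Problem sizes used in the validation suite

Simulation studies in the test suite run at the sizes that make their
claims meaningful while staying desk-scale: model recovery and bootstrap
coverage use 128-tip trees with 50 replicates (p = 2 traits for the
multivariate checks, univariate for the Brownian-data checks; fixed-(A,S)
bootstrap with 200 replicates); DTT calibration uses 32-tip trees, 200
null simulations and 50 replicates; the stochastic-process oracle compares
the analytic tip covariance with an Euler–Maruyama simulation at step
1e-3 and 2×10⁵ paths on a three-tip tree. The Monte-Carlo tolerance is
three standard errors wherever a simulation is compared with a closed
form.

## Known limitations

- Binary trees only; polytomies must be resolved upstream.
- One regime per branch; mid-branch switches require branch subdivision.
- Shared A and S across regimes (the model's own simplification); no
  regime-specific selection strength.
- No measurement-error model for tip means.
- 2-D landmarks only; no thin-plate-spline visualization layer.
- The parallel-analysis retention count is computed on the correlation
  scale even when the subsequent PCA is covariance-based; for strongly
  heteroscedastic coordinates the two scales can disagree.
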