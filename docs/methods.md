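# Methods

## The augmented model and why it mixes

The sampler targets p(X, θ | y) for a discrete latent state X with
entries in {1..S}.  It augments the joint with an auxiliary state U of
the same shape and the conditional

    p(U | X) = Π_i  Z⁻¹ exp(−λ d(u_i, x_i)) · I(d(u_i, x_i) ≤ m),

a (possibly center-weighted, λ ≥ 0; uniform at λ = 0) distribution over
the radius-m Hamming ball around each block x_i.  The normalizer
M_λ = Σ_{j≤m} e^{−λj}(S−1)^j C(K, j) is center-independent, so Gibbs
steps on the augmented model leave p(X, θ | y) invariant marginally.
One iteration draws U from the balls around X, updates θ, then draws X
from the model restricted to the balls around U.  Between iterations X
can change in up to 2m entries per block: the slice first moves (X→U),
then the state moves inside the moved slice (U→X').  Single-site Gibbs
is the m = K = 1 corner; fully marginalized sampling is m = K.  The
M-SSS comparator proposes from the slice around X directly and corrects
with the volume-ratio acceptance min{1, Z_m(X)/Z_m(X′)}; it is included
because it reaches only half as far (mP entries) at the same cost and
can reject.

All kernel arithmetic is in log space with max-subtraction before
normalization; categorical draws use inverse-CDF on the normalized
weights (the deconvolution column draws use Gumbel-max, which is the
same distribution computed without normalization).  A candidate with
log-weight −∞ is legal with probability zero; a slice whose candidates
are all −∞ raises `ImpossibleSliceError` rather than silently
resampling.  Generic kernels requiring a tractable restricted joint
(plain HB-Gibbs, marginal M-H, M-SSS with several blocks) demand a
per-block factorized model; block-structured sweeps
(`block_hb_sweep`) work for arbitrary dependence by conditioning on
the other blocks.  Markov-structured (forward–backward) restricted
draws are out of scope.

Random blocks: each sweep permutes the entry indices uniformly and
chops them into chunks of size K (last chunk may be shorter).  The
permutation is redrawn every sweep, including for the block-Gibbs
special cases.

## Sparse g-prior regression

With centered y and Z, β_X | σ² ~ N(0, g σ²(Z_X'Z_X)⁻¹),
σ² ~ InvGamma(a_σ, b_σ), x_d ~ Bernoulli(π₀), π₀ ~ Beta(a_π, b_π), the
marginalized joint is

    p(y, X | ·) ∝ (1+g)^{−D_X/2} Γ(D_X+a_π) Γ(D−D_X+b_π)
                  · [2b_σ + S(X)]^{−(2a_σ+N−1)/2},
    S(X) = y'y − g/(1+g) · y'Z_X (Z_X'Z_X)⁻¹ Z_X'y.

The (N−1)/2 exponent corresponds to an intercept with a flat prior
integrated out, which is why `RegressionData` centers both the response
and the design columns by default; the test suite verifies the
closed form against dense-grid numerical integration of the
un-marginalized model.  Defaults g = N, a_σ = b_σ = 0.1, a_π = 0.001,
b_π = 1 (strongly sparse).

Rank-deficient Z_X'Z_X — reachable by construction in duplicated
designs — leaves the g-prior undefined; such X receive zero posterior
mass.  Singularity is declared when a Schur-complement pivot falls
below 1e−10 of the column norm (condition ≈ 1e10).  A consequence used
by the tests: the sampler never holds both copies of a duplicated
column, and replica switching happens exactly when both copies land in
the same random block (probability (K−1)/(D−1) per sweep), where a
u-draw that drops one copy makes the swap a single-flip candidate.
This makes switching a rare event at D = 1200 — the reason the
benchmark runs are long — and the chain's inclusion-probability
estimates carry Monte-Carlo error of order 1/√(#switches).

Implementation: the sampler maintains the inverse Gram of the current
support and precomputes, once per support, the Schur pivots and
numerators of every single-column addition; radius-1 block updates then
cost one gather plus at most one rank-one correction (for two-column
additions), with removals read off the cached inverse.  A
`SupportSolver` class provides the same up/down-dates generically and
backs the m > 1 path; incremental results are tested against
from-scratch factorizations at 1e−8 relative error.  The chain starts
at the empty model: with D > N a dense random initialization has zero
mass under the rank rule, and the empty model is reachable from
everywhere.  The trace stores sparse support sets, not dense vectors.

## Tumor deconvolution

Counts r_i ~ Binomial(d_i, φ_i), φ_i = (1−e)p_i + e(1−p_i),
p_i = ½ Σ_k θ_k X_ki, with K exchangeable subclone components.  Weights
are represented through v_k = log γ_k, γ_k ~ Gamma(α/K, 1)
(θ = γ/Σγ marginally Dirichlet(α/K…); α ≤ 1 shrinks unused components,
acting as automatic model selection for the number of subclones).
Genotypes x_ki ~ Bernoulli(f_i), f_i ~ Beta(f_α, f_β).  Defaults K = 8,
α = 1, f_α = f_β = 0.5, e = 0.01, m = 4, ε = 0.01.

One iteration: (1) U resampled column-wise from uniform balls around
the columns of X; (2) a joint (v, X) M-H step — v′ proposed
componentwise from the ε-mixture of a Normal(v, σ_v²) random walk and
an independent log-gamma prior draw, accepted with the ratio of
restricted marginals p̃(v, U, y) = Σ_i log Σ_{x∈H_m(u_i)}
p(y_i|x, θ(v)) p(x|f_i) + log prior(v) and the Hastings correction; on
acceptance every column of X is redrawn from its restricted ball
conditional under θ(v′), on rejection both v and X are kept; (3) f
updated by its conjugate Beta conditional.  The mixture indicator is
marginalized in the Hastings density — valid without augmentation —
and all K components are proposed in one step.  The ball sums
vectorize over columns and candidates (N × M × K tensors; M = 163 for
m = 4, K = 8), so an iteration is a handful of dense operations.

Proposal tuning: σ_v² is adjusted multiplicatively (×2 or ×½) every
100 iterations during the first 1,000 burn-in iterations toward an
acceptance rate in [0.10, 0.40], hard-clipped to [0.01, 10], and
frozen afterwards so the stationary distribution is untouched.

Multi-sample data share X across samples with per-sample weights
θ_s; the restricted marginal multiplies likelihood terms over samples
inside each column's ball sum, all v_s vectors are proposed and
accepted jointly, and S = 1 reduces to the single-sample update
exactly (same code path).  Whether a joint or per-sample weight update
is preferable was an open design choice; the joint update was chosen
because it keeps the accept/reject consistent with the shared-X
redraw.

Reported summaries — max(θ), posterior-mean φ, VAF residuals
r/d − E[φ] — are invariant to permutations of the component labels, so
no label-switching correction is needed.  Posterior modes of the
max(θ) trace are located by Gaussian-KDE peak finding with samples
assigned to peaks at density valleys; the linear-phylogeny mode is
identified structurally as the lowest-location mode carrying at least
10% of the mass (the branched solution has the strictly larger maximum
weight), never by proximity to a target value.

## Synthetic data

Three seeded generators define the study conditions; every generator
returns a ground-truth sidecar and is a pure function of its seed.

- `gen_toy`: n = 200 samples, 10 U(0,1) covariates duplicated to 20,
  y_i = z_{i,6} + N(0, σ²), σ² ∈ {0.5, 2, 5}.  Known unit coefficient,
  known noise; the posterior over inclusion vectors has two exactly
  symmetric modes (covariate 6 vs its replica 16).
- `gen_regression`: 100 × 600 design uniform on {0,1,2} (SNP coding),
  y_i = z_{i,11} + N(0, 0.1²), design duplicated to 100 × 1200.
- `gen_tumor`: depth-800 binomial counts at
  φ = (0.5, 0.5, 0.5, 0.3, 0.3, 0.3, 0.15, 0.15, 0.15) from three
  nested subclones with weights (0.3, 0.3, 0.4).  The benchmark count
  table [405, 397, 393, 239, 245, 247, 123, 121, 123] is a single
  frozen draw shipped as a constant (`fresh=False`); `fresh=True`
  redraws.  The branched alternative θ = (0.1, 0.6, 0.3) with trunk
  variants shared reproduces the same φ exactly and is the second
  posterior mode the samplers must find; it is an algebraically derived
  solution, not a reported value.
- `gen_multisample_tumor`: 17 variants × 13 samples by default, one
  shared nested genotype matrix, Dirichlet per-sample weights, and a
  normal-tissue control whose weight sits entirely on a mutation-free
  clone (expected VAF = e).

What the generators do *not* emulate: real sequencing error profiles
beyond the scalar e, copy-number effects on expected VAF, linkage
structure among SNPs, non-Gaussian phenotype noise.  Tests passing on
these data show the *samplers* target their posteriors correctly and
recover planted structure under the stated models; they say nothing
about model adequacy on real tumors or cohorts.

## Diagnostics

Integrated autocorrelation time uses Geyer's initial-positive-sequence
truncation on FFT autocorrelations (IAT = 1 + 2Σρ_t, pairs summed while
positive, clipped at 1); ESS = length/IAT.  A constant series is
reported as IAT = length with a warning.  Mode-switch counting ignores
iterations belonging to no mode.  The switches-per-second "overall
efficiency" ratio is exposed for ranking schemes on one machine only —
it is hardware-dependent and never asserted against reference values,
as are wall-clock comparisons generally.

## Problem sizes and run lengths

Desk-scale defaults used by the tests and the acceptance script, chosen
as the package's reference workloads: regression benchmark 100 burn-in
plus 50,000–100,000 sweeps (HB1 sweeps cost ~6 ms at D = 1200);
deconvolution 5,000 burn-in (first 1,000 tuning) plus 25,000 samples.
Exhaustive-enumeration oracles cap the joint space at 4,096 states and
use ≥ 10⁵ iterations, putting Monte-Carlo error well below the
total-variation tolerance of 0.02.  Kernel-correctness claims rest on
those oracles, not on long-run benchmarks.

## Known limitations

- Replica switching in the regression benchmark is a rare event; at
  5,000 sweeps the inclusion-probability estimator still carries
  standard error ≈ 0.2, which is why longer defaults are used.
- The deconvolution M-H step updates all K components of v jointly;
  for K much larger than ~20 the acceptance rate of a joint proposal
  degrades and per-component scans would be preferable.
- `block_hb_sweep` evaluates candidates sequentially per block; no
  parallel or GPU evaluation of ball sums is provided.
- Radius distributions for the random-radius kernel are user-supplied;
  no adaptation of m during sampling is implemented.
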