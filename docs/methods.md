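# Methods

## Model

`icarh` fits a three-layer Bayesian hierarchical model to longitudinal
multi-omic data X (N individuals × T time points × M metabolites) and Y
(N × T × K companion omic variables), with individuals split into cases
and controls.

**Observation layer (pathway CAR).**  Conditional on its mean, each
observation vector is multivariate normal,
x_it^e ~ N(mu_it, (I_M − C(φ^e))^{-1} σ²), with
C(φ) = Σ_p φ_p W_p and W_p = (G_p A_p + A_p G_p)/2.  A_p is the
within-pathway adjacency matrix (entries are reciprocals of shortest-path
lengths when path lengths are supplied, or 1 for plain co-membership with
the diagonal zeroed, matching the conditional-autoregressive requirement
c_mm = 0); G_p is diagonal with the reciprocal of each member's neighbour
count.  The symmetrization in W_p is exact (a no-op) whenever all members
of a pathway have equal neighbour counts — in particular for co-membership
adjacency — and makes the covariance a valid symmetric matrix for
distance-weighted adjacency with unequal degrees, where G_p A_p alone is
not symmetric.  Metabolites mapped to no pathway have zero rows in every
A_p and are conditionally independent.

**Admissible domain of φ.**  I − C(φ) must be positive definite.  With
ξ¹_p ≤ ξ²_p the extreme eigenvalues of W_p and κ the largest number of
(connected, non-inert) pathways any single metabolite belongs to, every
φ with φ_p ∈ (1/(κξ¹_p), 1/(κξ²_p)) gives a positive definite I − C:
since W_p ⪯ ξ²_p Π_p (Π_p the projector onto pathway p's connected
members) and ⪰ ξ¹_p Π_p, each |φ_p W_p| ⪯ (1/κ) Π_p, so
Σ_p φ_p W_p ⪯ (1/κ) diag(c_m) ⪯ I, where c_m counts m's pathway
memberships.  κ is the sharp worst-case constant for this argument; the
cruder constant P (the total number of pathways) corresponds to the
worst case in which a single metabolite could belong to every pathway and
shrinks the admissible box by P/κ (≈ 2.75 under the default membership
distribution).  That distinction matters scientifically: CAR models only
express strong within-pathway correlation when φ_p approaches a boundary
of its admissible interval, and under the P-scaled box the attainable
cross-metabolite correlation is capped near 0.1 — too weak to support
either the intra-pathway correlation levels seen in real data or reliable
perturbation detection.  Under the κ-scaled box, boundary-anchored φ
produce realistic correlation strength while positive definiteness
remains guaranteed for every admissible draw.  Pathways with fewer than
two connected members (or vanishing extreme eigenvalues, |ξ| < 1e−10)
are flagged *inert*: their φ_p is fixed at 0 and they are excluded from
perturbation assessment.

**φ prior.**  p(φ_p) ∝ (φ_p − lower)^{−1/2}(upper − φ_p)^{−1/2} — a
Beta(1/2, 1/2) rescaled to the admissible interval and normalized by the
interval length so it integrates to one (a proper prior keeps WAIC
comparisons meaningful).  The density places substantial mass near the
boundaries, where dependence is expressible.  A uniform alternative
(`phi_prior="uniform"`) is provided for the prior-sensitivity comparison.

**Shrinkage layer.**  β_mk | λ_mk, σ_βm ~ N(0, λ²_mk σ²_βm),
λ_mk ~ St⁺(τ, 0, 1).  τ = 1 is the horseshoe prior.  The shrinkage
coefficient κ_mk = 1/(1 + λ²_mk σ²_βm/τ) has density

    p(κ | τ, σ_β) = σ_β^τ / B(τ/2, 1/2) · κ^{τ/2−1} (1−κ)^{−1/2}
                    · (1 − κ + κσ_β²)^{−(τ+1)/2},

obtained by direct change of variables from the half-Student-t; it
integrates to one and reduces to Beta(τ/2, 1/2) at σ_β = 1 (and to the
horseshoe-shaped Beta(1/2, 1/2) when additionally τ = 1).
`expected_kappa` evaluates E[κ | τ] by adaptive quadrature, either at
fixed σ_β or with σ_β marginalized under the improper 1/σ² prior
truncated to a configurable range (the improper integral is only defined
up to such a truncation); it is monotone increasing in τ and can be used
to fix τ from a target proportion of shrunk coefficients.  σ_βm is given
a half-Cauchy(1) prior in sampling — a proper stand-in for the improper
1/σ² used in the closed-form analysis — keeping the posterior proper and
WAIC well defined.

**Design layer.**  α_m is the treatment effect (wide-normal stand-in for
a flat prior, scale 100); in continuous-treatment mode the term is
β^α_m · y_drug,it.  γ_im ~ N(0, σ²_γm) are individual effects with
σ²_γm ~ InvGamma(1, 0.1) (low within-group biological variability);
ν_itm follows a per-metabolite AR(1), ν_itm ~ N(θ_m ν_{i,t−1,m}, σ²_νm),
with the stationary initialization ν_i1m ~ N(0, σ²_νm/(1−θ_m²)) —
consistent with the stationary variance appearing in the conditional
posterior-mean identity for β_m — θ_m ~ U(−1, 1), and
σ²_νm ~ InvGamma(T/4, T/4 − 1).  σ² ~ InvGamma(ψ, ψ−1) with ψ = NT/4,
contributing 2ψ pseudo-observations against the NT available ones.

## Inference

The sampler targets the marginal posterior with γ and ν integrated out
analytically: each individual's T·M observation block is Gaussian with
covariance kron(σ²(I−C(φ^e))^{-1}, I_T) + blockdiag_m[σ²_γm J_T +
σ²_νm/(1−θ²_m)·θ_m^{|t−t'|}], identical within a group.  This leaves a
few hundred structural parameters whose posterior is mathematically
identical to the full hierarchy but free of the latent-variance funnel
that cripples samplers in the 7000-dimensional latent space.  One sweep
combines:

1. **Dynamic HMC** (multinomial tree doubling with u-turn termination,
   dual-averaging step size targeting 0.8 acceptance, Stan-style warmup
   windows estimating a dense metric, tree depth capped at 6, divergence
   threshold 1000) on the covariance block (θ, σ², σ²_γ, σ²_ν, φ^e) with
   analytic gradients — trace identities for the covariance derivatives,
   verified against finite differences in the test suite.
2. An **exact Gaussian conditional draw** of (α, β): generalized least
   squares under the marginal covariance with the shrinkage prior as
   ridge penalty.
3. **Univariate slice updates** of λ_mk and σ_βm, which are conditionally
   independent of the data given β.

Unconstrained transforms: log for scales, tanh for θ, and a scaled logit
for each φ_p so every draw lies strictly inside the admissible box (and
hence yields a positive definite covariance by construction).  Chains are
initialized at a jittered approximate posterior mode found by a short
alternating L-BFGS/GLS optimization; without it, the φ = 0 start costs
several hundred iterations of burn-in that a 300-iteration warmup cannot
afford.  Draws of γ and ν are recovered after sampling by exact
conditional Gaussian draws given each retained draw (Rao-Blackwellized
recovery), so the returned object carries every latent block.

Defaults mirror the reference analysis: 2000 iterations, 1000 warmup,
2 chains.  R-hat/ESS are computed via ArviZ; the fit warns (never errors)
at split R-hat > 1.05 or >1% divergent transitions.  Identical seed,
configuration and data give identical draws.

**Standardization.**  `fit` centers and scales each metabolite and Y
column by default, which is the right practice for real data on
heterogeneous scales.  For data simulated from the model itself the
simulation-study harness fits on the native scale (`standardize=False`):
per-metabolite rescaling maps a CAR covariance out of the CAR family
(the diagonal of (I−C)^{-1} is heterogeneous when pathway dependence is
strong), and fitting standardized simulated data demonstrably biases σ²
downward and weakens φ recovery.

## Synthetic data

`simulate_dataset` draws from the generative process itself: a random
binary membership matrix Z whose per-metabolite pathway counts follow a
fixed KEGG-like table (55% of metabolites in one pathway, 25% in two,
13% in three, 7% in four — configurable; resampled until no pathway is
empty), co-membership adjacency A_p = z_p z_p^T with zeroed diagonal,
Y ~ N(0, 1) i.i.d., λ ~ St⁺(τ), β from the shrinkage prior with
σ_β = 1, α_m ~ N(0, 1), θ_m ~ U(−0.7, 0.7), γ with σ²_γ = 0.1, ν from
the stationary AR(1) with σ²_ν = 0.25, and σ² = 1.  The study preset is
N=22 (11 controls / 11 cases), T=7, M=40, K=1, P=11, τ=1.2.

**Pathway perturbation.**  Each pathway is perturbed independently with
probability 1/2 (ω_p = 1; resampled so both classes occur).  φ draws are
anchored at the boundaries, where dependence is strong: an "on" pathway
draws φ_p around 0.9 × upper bound, an "off" pathway around 0.3 × lower
bound (opposite-sign dependence), each with 3% relative jitter, truncated
to the open admissible interval.  Unperturbed pathways are "on" in both
groups and share one draw; perturbed pathways are "on" in controls and
"off" in cases.  Mid-interval φ separations of any size are provably
undetectable (the likelihood is nearly flat there), so the on/off
boundary contrast is what makes a perturbation study informative; with it,
maximum-likelihood recovery with a known mean structure attains AUC ≈
0.98 at the study preset, and the full Bayesian pipeline ≈ 0.97.

**Corruption.**  `corrupt_membership` falsely reassigns ⌊fraction ×
members⌋ metabolites of every pathway either to no pathway ("drop") or to
a uniformly chosen other pathway ("reassign"), never emptying a pathway;
untouched rows are bit-identical.

What the generator does *not* emulate: real spectral artifacts (peak
overlap, retention-time drift, annotation ambiguity), non-Gaussian
abundance distributions, missing values, irregular sampling times, and
KEGG's actual pathway topology (shortest-path-weighted adjacency is
supported as input but the simulator uses co-membership).  Passing tests
therefore demonstrate correctness of the machinery and recoverability
under the model's own assumptions, not performance on any particular real
assay.

## Scoring and diagnostics

A pathway is *called* perturbed when the equal-tailed 95% credible
interval of φ^controls_p − φ^cases_p excludes zero.  For ROC analysis
each pathway is ranked by 2·|Pr(φ^c_p − φ^t_p > 0) − 1/2| (ties inside
the posterior counted half), which reproduces the interval rule when
thresholded at the interval level.  AUC is Mann-Whitney (ties averaged),
checked in the tests against exhaustive pairwise comparison.  For the
corruption-robustness curves, pathway scores are pooled across the
replicate datasets of a fraction before computing one ROC per fraction
(`pooled_auc_by_fraction`); per-dataset AUCs are also reported.

WAIC uses one (i, t) observation vector as the pointwise unit — the
model's exchangeable unit under the CAR likelihood; per-metabolite terms
are not independent given the pathway coupling.  The posterior-predictive
covariance check replicates datasets from the posterior predictive,
computes each replicate's empirical covariance pooled over both groups
after group-wise centering (group covariances differ by design), and
summarizes mean absolute element-wise deviations from the observed
covariance, alongside replicate-vs-replicate deviations as the reference
distribution.  The normality check whitens residuals by the inverse
Cholesky factor of the fitted group covariance at posterior means (with a
per-draw fallback if the mean covariance is not positive definite) and
reports the pooled residuals' mean, a CLT-scaled zero-mean flag and a
Kolmogorov-Smirnov statistic for QQ plotting.

## Problem sizes used by the test suite and acceptance script

The full study grid (10 datasets × 6 corruption fractions × 2000
iterations) is an hours-scale computation; the shipped checks use the
package's scaled-down protocol:

* Headline check: study preset, 3 datasets, corruption fractions 0 and
  0.5, 600 iterations / 300 warmup, one chain per fit.
* Uniform-vs-beta prior contrast: same preset and budget, 2 datasets at
  fraction 0.
* Monotonicity across the corruption grid {0, 0.18, 0.35, 0.44, 0.5,
  0.62}: a reduced preset (N=12, T=7, M=14, P=5, K=1) with 6 datasets per
  fraction, 400/200 iterations, scored by pooled-score ROC per fraction.
* Parameter recovery and null false-positive rate: 10 seeded datasets at
  N=12, T=6, M=8, P=3 with 400/200 iterations.

## Known limitations

* The marginal-likelihood factorizations cost O((TM)³) per density
  evaluation; very large M (hundreds) needs longer runtimes or fewer
  iterations.
* Missing values are rejected, not imputed.
* The admissibility box for φ is per-pathway; the joint positive-definite
  region is larger, and strongly negative φ on many overlapping pathways
  simultaneously is admissible but near-degenerate numerically.
* Treatment effects are per-metabolite constants (or proportional to a
  measured dose); richer time-varying treatment effects are out of scope.
* WAIC and the predictive checks condition on the recovered latent draws
  and inherit their Monte Carlo noise; fewer than ~100 draws triggers a
  warning.
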