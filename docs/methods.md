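# Methods

`phylomorph` implements a complete macroevolutionary analysis of 2D landmark
shape on time-calibrated fossil phylogenies: superimposition, phylogenetic
ordination, phylogenetic signal and regression, disparity through time,
multivariate evolutionary-model selection over regime paintings, stepwise
regime-shift discovery, and parametric-bootstrap model adequacy.  This note
records the models, the numerical choices, and the places where the design
was genuinely open.

## Shape variables

**Superimposition.** Generalized Procrustes analysis removes translation,
scale and rotation: each configuration is centred, scaled to unit centroid
size (CS = √Σ‖xᵢ − x̄‖²), and rotated to the running consensus by SVD with
the determinant constrained to +1 — reflection is never introduced during
alignment; mirroring of right-side elements is an explicit preprocessing step
(`mirror_config`).  The classical iteration (rotate → re-estimate consensus)
runs until the summed squared Procrustes residual stabilizes (tolerance 1e-8,
max 500 iterations).  Aligned coordinates are orthogonally projected to the
tangent space at the consensus (sizes then sit just above 1 by a second-order
amount), and the output frame is standardized: the consensus is rotated to
its principal axes with the extreme landmark pointing in +x, which makes the
result invariant to arbitrary per-specimen similarity transforms of the
input.

**Sliding semilandmarks.** The interior points of each declared curve slide
along tangent directions (finite differences of their curve neighbours;
curve endpoints are fixed).  Sliding minimizes thin-plate-spline bending
energy against the consensus by default (the Procrustes-distance criterion is
available), solving t = −(UᵀEU)⁻¹UᵀEv per specimen.  Because joint sliding
has near-flat directions (an almost-straight curve can translate along itself
with almost no bending penalty), sliding runs as discrete cycles — slide,
re-superimpose, re-evaluate — and a cycle is kept only if the criterion
objective decreases (relative tolerance 1e-6, max 10 cycles).  This keeps the
procedure monotone in its own objective and convergent on data where a free
running slide drifts.

**Missing landmarks.** Incomplete specimens are completed by an exact 2D
thin-plate-spline interpolant (kernel U(r) = r² log r²) mapping the
reference's shared landmarks onto the specimen's observed ones; missing
coordinates are the mapped reference points.  The reference is the mean of
the complete specimens after a preliminary GPA restricted to them.  The
interpolant reproduces affine deformations exactly (zero bending), which the
tests exploit as an oracle.

## Phylogenetic ordination

Both phylogenetic ordinations GLS-centre the flattened shape data
(landmark-major x₁,y₁,…) with a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y, where C is the
Brownian-motion covariance of the tree (shared root-to-MRCA path lengths;
generally non-ultrametric diagonals).

* **Phylo-PCA** eigendecomposes the evolutionary rate estimate
  R = (Y−1a)ᵀC⁻¹(Y−1a)/(n−1); variance proportions come from these
  eigenvalues (tip-score dispersion per axis is also reported, since the two
  conventions differ).
* **PACA** eigendecomposes (Y−1a)ᵀC(Y−1a), concentrating phylogenetic signal
  in the leading axes; importance per axis is the proportion of tip-score
  dispersion.

Both reduce exactly to ordinary PCA on a star phylogeny.  Axis signs follow
a largest-loading-positive convention for cross-platform determinism.
Downstream analyses use the smallest axis prefix reaching 90% cumulative
importance (variance for Phylo-PCA, tip dispersion for PACA).

## Phylogenetic signal and PGLS

**Kmult** generalizes Blomberg's K to multivariate data:
K = [tr(YᶜᵀYᶜ)/tr(YᶜᵀC⁻¹Yᶜ)] ÷ [(trC − n/(1ᵀC⁻¹1))/(n−1)], calibrated to 1
under BM on the given tree.  p-values come from permuting tip rows
((b+1)/(B+1), B = 999 by default); the effect size Z standardizes the
observed statistic within the log-transformed permutation distribution.
When λ scaling is requested, λ̂ maximizes the profiled ML multivariate GLS
likelihood on [0,1] (off-diagonals of C scaled by λ); λ̂ = 0 means a star
phylogeny fits best and K, p, Z and the log-likelihood are reported as NaN
sentinels.  Note that on non-ultrametric trees no λ makes C proportional to
the identity, so λ̂ under independent data is variable rather than pinned at
0.  ML (not REML) is used; the choice is visible in the reported
log-likelihoods only.

**PGLS / Procrustes ANOVA.** shape ~ strategy × log(centroid size), with the
response and design whitened by the symmetric C^{−1/2}.  Sums of squares are
sequential (type I) with the strategy factor first; R² = SS/SS_total with the
partition summing to 1.  Inference is by residual randomization (RRPP):
reduced-model residuals are permuted (one shared, seeded permutation schedule
across terms), F recomputed, p = (b+1)/(B+1), Z from log-F.  Centroid size
enters log-transformed by default (standard allometric practice; a flag keeps
it raw).

## Evolutionary models

All model likelihoods are exact joint Gaussians of the nm tip observations
(n tips, m retained Phylo-PC scores), assembled blockwise from shared-path
times; no pruning approximations.  Means that are linear in the root state or
regime optima are profiled out by GLS; rate matrices stay positive-definite
through a log-diagonal Cholesky parameterization.

* **BM**: vec(Y) ~ N(1⊗μ, C⊗R); μ and R have closed-form ML estimates.
* **BMM**: the between-tip covariance weighs each regime's R_k by the time
  spent in regime k on the shared path, taken from the regime painting
  (deterministic clade paintings for the a-priori hypotheses; lists of
  stochastic maps are fitted individually with the median-log-likelihood fit
  reported and the spread logged).
* **EB**: BM with rate σ²e^{bt}, b ≤ 0; b is profiled by a bounded 1-D search
  (lower bound log(10⁻⁶)/tree height) with R closed-form at each b.
* **OU1/OUM**: fixed-root Ornstein–Uhlenbeck with diagonal pull matrix α
  (default; scalar option available).  Cov_ab(i,j) =
  R_ab·e^{−αa(Ti−s)−αb(Tj−s)}·(1−e^{−(αa+αb)s})/(αa+αb) with s the MRCA
  depth, recovering BM as α→0.  The root state sits at the root-regime
  optimum; per-regime optima θ_k enter the mean through segment-wise
  e^{−α(T−u)} weights and are profiled by GLS.  A full α matrix is not
  offered: with 17 tips and 4 traits it would add 16 parameters to an already
  saturated model.

Optimization is L-BFGS-B on the free covariance parameters with a
finite-difference step of 1e-5 (the likelihood's numerical noise floor makes
smaller steps produce garbage gradients), ftol 1e-11, up to 1000 iterations,
from 3 seeded starts (moment-based initialization; BM-fit rates, α at
half-life = half tree height).  Parameter counts per model (used in AIC =
2k − 2logL): BM m+T, BMM m+2T, EB m+T+1, OU1 m_α+T+m, OUM m_α+T+2m, with
T = m(m+1)/2 and m_α = m (diagonal) or 1 (scalar).  AICc adds
2k(k+1)/(nm−k−1).  Akaike weights are computed within a declared comparison
set after verifying all fits share the same data hash.

**Simulation** from any (fitted) model draws exactly from the model-implied
joint normal via Cholesky — no Euler discretization.

## Regime paintings

The a-priori hypotheses paint the smallest clade containing all derived-state
taxa, shift at the clade's stem branch (a crown option exists); if the
derived taxa are not monophyletic the painting falls back to stochastic
character mapping.  The binary strategy trait is modelled as the symmetric
(equal-rates) Markov chain with uniform root prior; q̂ by bounded 1-D ML over
log q using Felsenstein pruning.  Stochastic maps draw node states from their
conditional distributions, then endpoint-conditioned branch histories by
rejection sampling with a uniformization fallback after 1000 rejections (for
the 2-state symmetric chain the uniformized jump chain is a deterministic
flip, so only a parity-constrained Poisson jump count is needed).

## Regime-shift search

The forward search starts from a single-regime Hansen (OU) model, proposes a
new regime originating on every branch, keeps the best proposal by summed
per-trait AICc (each trait an independent univariate OU with α optimized and
σ², θ profiled), and stops when the improvement is ≤ 2 AICc units.  Two
guards control selection-induced overfitting, which is severe on small trees
(maximizing over ~2n−2 candidate branches makes spurious AICc gains of 5–10
units routine at n = 17): each shift's branch placement is counted as one
extra parameter per trait, and acceptance requires the classic "substantial
support" margin of 2.  With both, the false-positive rate under a true
single-regime OU is ≈0–10% at n = 17 while a clade displaced by a few
within-group standard deviations is still recovered essentially always.
The backward (regime-merging) phase is not implemented.

## Disparity through time

Disparity is the average squared pairwise Euclidean distance.  Relative
subclade disparities (subclade/whole-clade) are averaged, at each divergence
time in root-to-tip order, over the internal-node subclades whose stem branch
crosses that time (the first value is 1 by construction; times with no
crossing internal lineage contribute 0).  The 95% envelope is the pointwise
2.5/97.5 percentile band over BM simulations (default 1000) whose rate matrix
is the GLS evolutionary covariance estimated from the data.

## Model adequacy

Parametric bootstrap: simulate from the fitted model (default 500 datasets),
refit the same model to each (single start, initialized at the fitted
parameters), and take percentile 95% intervals per diagonal parameter (rate
diagonals, α, EB exponent).  The model is called adequate when every observed
diagonal lies inside its interval.  Refit failures are excluded and counted
(>10% triggers a warning).

## Synthetic data

The generator produces every input the analysis needs: birth–death trees
(birth 0.06/Myr, death 0.02/Myr) with a configurable fraction of pendant
edges truncated to emulate fossil tips; binary strategy traits under the
equal-rates Markov chain; and landmark sets built by adding exact-Gaussian
model draws (in the tangent space of a hard-coded maxilla-like 19-point mean
configuration, 6 fixed + 13 sliding on three curves) to the mean, plus
i.i.d. digitization noise, random specimen-specific image frames (rotation,
scale 0.5–2×, translation), and optional missing-landmark masks.

The deterministic fixture used throughout the integration tests has 17 taxa
(9 abelisaurids including an Early Cretaceous one, 8 outgroups) on a
non-ultrametric tree spanning ~235 Myr, and simulates maxilla shape under a
two-regime Brownian motion: generalist rate 2×10⁻⁴ units²/Myr per coordinate
spread over an anisotropic spectrum (eigenvalue ratio 0.5 between successive
shape directions, reproducing the steep scree of real landmark data),
specialists 4× faster, plus a stem saltation of the specialist clade sized at
~4.5× the Brownian shape dispersion so the clade forms the non-overlapping
morphospace cluster that motivates a distinct-optimum reading.  Two taxa
carry missing jugal-ramus landmarks to exercise the estimation and
taxa-removal paths.  What the fixture does **not** emulate: real anatomical
covariance structure, digitizer error correlated along curves, allometric
mean–size coupling, or taphonomic biases — so green integration tests show
the pipeline recovers known generating structure at realistic size and noise,
not that any biological conclusion transfers to real data.

## Problem sizes in the test harness

The statistical property checks run at sizes chosen for a single-CPU
workstation: Kmult calibration 60–80 replicates, PGLS type-I error 200–250
replicates at 60–79 permutations, shift-search false positives 15–20
replicates, adequacy coverage 25 meta-replicates × 100 bootstrap draws
(closed-form BM refits), parameter recovery 25 replicates with 2 traits.
Monte-Carlo allowances in the assertions are computed from each run's own
replicate count.  The acceptance script uses 999 permutations, 500 dtt
simulations and 50 adequacy refits.

## Known limitations

* OU σ² and α are jointly weakly identified when the pull is strong
  (αT ≳ 3): only the stationary variance σ²/2α is then stable, and raw-rate
  recovery degrades — visible in the recovery tests, which therefore use a
  moderate-pull scenario.
* Printed AIC comparisons assume the standard 2k − 2logL convention with the
  parameter counts listed above; tools differing in count conventions will
  differ by constants within a model family.
* The SURFACE-style search here is forward-only and its overfitting guards
  (placement parameters, ΔAICc > 2) are deliberately more conservative than
  the original tool's defaults; on very small effects it will report no shift
  where a laxer search would report one.
* Tangent-space coordinates are orthogonal projections; for the shape
  dispersions in scope the projection distortion is second-order, but the
  package does not implement stereographic alternatives.
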