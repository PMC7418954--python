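# Methods

This note documents the statistical models, the estimation choices, the
synthetic-data generator's assumptions, and the design decisions that were
genuinely open. Nothing here reports a number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Trees and covariance structures

Trees are rooted, fully branch-lengthed (My), and wrapped in a `Phylogeny`
over dendropy with array views (parents, branch lengths, node heights in
preorder). Ultrametricity is checked to a relative tolerance of 1e-6 of
tree depth and only warned about — fossil-calibrated supertrees are often
slightly off and the GLS machinery does not require it. The two clade trees
are joined under a configurable root age (default 79 My, a conventional
primate–carnivoran split). The rate comparisons use within-clade contrasts
only and are insensitive to the root age, which a pipeline test verifies by
regrafting at 70 and 90 My; the pANCOVA intercept F, by contrast,
legitimately depends on the stem lengths (they set the null variance of a
between-clade offset), which is exactly why the root age is an explicit
config key rather than a constant.
Tip labels normalize spaces to underscores; a user synonym map handles
genus reassignments (e.g. *Herpailurus*/*Puma yagouaroundi*).

The BM covariance V has V[i,j] = height of the MRCA of tips i and j and
root-to-tip path lengths on the diagonal. Pagel's λ multiplies the
off-diagonal entries; λ is restricted to [0, 1] (star phylogeny to pure
BM), the convention of the standard pGLS tools, and boundary optima are
evaluated exactly.

## Size axis

PCA runs on the correlation matrix of the ten log10 distances: loadings
near 1 across all measurements are only meaningful on the correlation
scale, and the axis is then invariant to each column's units. With a
single retained component a varimax rotation is the identity, so none is
applied. Scores are standardized to unit variance with loadings oriented
positive; a switch (`standardize_scores=False`) keeps eigenvector-scale
scores, because downstream slope magnitudes depend on this convention and
reconciliation with other software may require either. The coefficient of
variation uses the n−1 sample SD on raw (not log) values.

## pGLS, λ profile, and pANCOVA

GLS is computed by Cholesky whitening; σ² is the ML estimate e'V⁻¹e/n
(reported as the trait rate), while standard errors and t statistics use
the unbiased residual variance with n−p degrees of freedom, matching
standard pGLS software. λ is profiled by bounded scalar ML search
(tolerance 1e-6); a REML switch exists for sensitivity but ML is the
default because model comparison (pANCOVA, OU criteria) requires
comparable likelihoods. The λ profile was cross-checked against R
phytools' `phylosig(method="lambda")`: estimates and log-likelihoods agree
to four decimals on shared data.

pANCOVA compares nested λ-GLS models with an F test on whitened residual
sums of squares. λ is estimated once on the full model and held fixed for
the reduced model so the two RSS values live in the same whitened space.
Degrees of freedom are reported as (p_full − p_reduced, n − p_full).
Covariate models (specimen sex, relative age, sexual size dimorphism, and
the sex × dimorphism product) drop rows with missing covariates listwise,
prune the tree accordingly, and log the retained n.

## Multi-regime OU model and shift search

Regimes are paintings of edges; a shift edge opens a new regime inherited
by its descendants. Tip expectations are the Hansen weights: an edge with
optimum θ spanning depths [s, t] on a tip's root path contributes
(e^{−α(T−t)} − e^{−α(T−s)})·θ, and the root state — pinned to the
background optimum — contributes e^{−αT}·θ₀. The tip covariance is the
fixed-root OU form C_ij = e^{−α d_ij}(1 − e^{−2α t_MRCA})/(2α), which
reduces continuously to BM as α → 0. For fixed α, the optima are GLS
estimates and σ² is concentrated out, so only α is profiled (log-scale
bounded search; during the stepwise search a fixed 24-point log-spaced α
grid is shared across candidate paintings for speed, and the final model
is re-profiled exactly). The likelihood is validated against an
independent per-edge linear-Gaussian recursion in the tests.

Shift placement is forward stepwise: each step tries every eligible edge
and keeps the one that most improves the criterion, stopping when no
improvement remains; ties break toward the edge closer to the root. The
criterion is BIC plus a combinatorial penalty w·log C(E, k) for having
searched k shifts over E edges. With w = 1 the false-positive rate of the
search on 55-tip Brownian data is ~40%, far from the ~10% a conservative
detector should give; the default w = 2 (the convention of the l1ou-style
pBIC) yields ~10% and is a config knob. The search is deterministic given
the data; the top-3 distinct paintings are retained so near-best models
(e.g. an additional within-clade shift) remain observable.

Bootstrap support simulates B datasets from the fitted OU model, reruns
the search, and reports the percentage of replicates recovering each
original shift edge, tolerating one edge of placement slop (parent or
child), since stem-versus-crown placement on short edges is weakly
identified. The effect size ("signal-to-noise ratio") is defined here as
the population SD of the Hansen tip expectations divided by the stationary
SD √(σ²/2α): it is zero for a single regime, scales linearly in the optima
differences, and inversely in the equilibrium noise. The literature's
√ηϕ statistic has several definitional variants; this one preserves the
scaling properties that matter for power (values ≫ 1 mean easy detection)
without claiming digit-level equivalence to any one variant.

The matched-pair grade magnitude pairs primate and carnivoran species
greedily by nearest body length without replacement (8 pairs by default)
and averages the ratio of the ten raw distances within each pair; the pair
list is part of the output because the pairing rule is a convention, not
an estimate.

## Rates

Standardized contrasts are computed by Felsenstein pruning with
branch-length extension; polytomies are folded pairwise through
zero-length connectors with a warning. A clade's rate is the mean squared
contrast within its subtree (the ML estimator under BM). The rate-ratio
test pools the two clades' squared contrasts — exchangeable under a
common-rate null — and reassigns them at the observed counts (vectorized;
default 10,000 permutations), with the +1-corrected one-tailed P for
ratio > 1; a simulate-common-rate alternative was considered and rejected
as equivalent under the null while slower. Rate posteriors use the
i.i.d.-contrast likelihood with a Jeffreys 1/σ² prior, giving a
scaled-inverse-χ²(m, s²) posterior sampled directly. The larynx-versus-body
rate comparison uses log10 crico-thyroid distance against log10 body
length (both mm) and a paired permutation that swaps the two traits'
squared contrasts within each node. Ancestral states rescale each branch
by its rate (clade-level rates from the detected regimes — a declared
simplification of per-branch multi-rate BM, so the phenogram is
qualitative) and compute exact conditional means by two-pass Gaussian
message passing, validated against a full-covariance GLS oracle.

## Acoustic and social analyses

F0 allometry is a pGLS of log10 mean F0 (Hz) on the size scores within a
clade, with species lacking usable F0 excluded by name in the log;
cross-clade slope equality uses pANCOVA. The group-size comparisons
(Mann–Whitney U with exact enumeration for small tie-free samples,
Spearman rank correlation, and dispersion) are deliberately
non-phylogenetic, matching the descriptive tradition they reproduce. Both
MAD variants (median absolute deviation about the median, mean absolute
deviation about the mean) are reported because "MAD" is used inconsistently
in this literature and the two can differ by an order of magnitude on
skewed group-size data. Group-size assembly rules: a stated mean wins;
solitary = 1; breeding pair = 2; otherwise the min–max midpoint.

## Synthetic data: what it emulates and what it does not

The generator produces pure-birth clade trees rescaled to crown ages 65
and 55 My, grafted at 79 My; log10 body length by BM (rate 0.008, ~3
orders of magnitude across tips); larynx size as a grade-shifted allometry
(slope 4.71; intercepts −8.04 primate / −9.09 carnivoran) with residuals
drawn from a λ-structured covariance (λ = 0.956) whose phylogenetic part
carries clade-specific rates (carnivoran 5e-4 per My, primate 2.17×);
landmark sets as an isotropically scaled 14-point template with
multiplicative lognormal coordinate noise; and F0 with slope −0.476 and
noise calibrated so the OLS R² on 53 species is near 0.58. Every generator
is a pure function of (parameters, seed), and the emitted specimen table
uses the same CSV schema as real inputs, so the pipeline cannot
distinguish provenance.

Three generator constants deserve justification:

- **Residual diffusion 5e-4.** No external value exists for this scale.
  It was fixed so that the stated grade shift (1.05 size units) is a
  multiple of the residual SD, which is the regime the strong reported
  effect statistics (intercept F ≈ 8–30, OU effect size ≫ 1) imply; a 4×
  larger value makes the grade shift a ~2-SD effect and the detection and
  ANCOVA power collapse, contradicting that regime.
- **0.133 log10-mm per size unit.** The physical scale of the landmark
  template per unit of latent size, chosen so a 1.05-unit grade shift maps
  to a ~1.38× linear measurement ratio and the measurement span is about
  two orders of magnitude. A side effect is that larynx linear dimensions
  scale shallower than body length in the generator, so the
  larynx-versus-body rate ratio on synthetic data sits below 1 — the
  generator makes no claim about that comparison.
- **Landmark noise CV 0.02.** Shape noise is white across the phylogeny,
  so it simultaneously dilutes the PC1 share, deflates λ̂ (white noise is
  exactly what λ < 1 measures), and inflates short-branch contrasts
  asymmetrically between clades. A single white-noise knob therefore
  cannot reproduce a 0.91 PC1 share and λ ≈ 0.956 and a clean clade rate
  signal at once; the default keeps morphometric error negligible so the
  comparative conditions (λ, grade shift, rate ratio) govern, and the
  noisier PC1 ≈ 0.91 regime is reachable by setting the knob to ~0.3 (the
  morphometry tests exercise it). Passing tests on synthetic data
  accordingly show the comparative machinery works when its assumptions
  hold; they do not show that real laryngeal shape noise is this small.

## Numerical choices

λ and α searches are bounded scalar optimizations with endpoint checks;
the α range is [1e-7, 200]/tree-depth. The OU GLS falls back gracefully
(candidate rejected) on non-PD covariances or singular regime designs, and
regimes that paint no tips are errors. Whitened-residual orthogonality is
asserted to 1e-8 in tests. Collinear designs report the offending columns.
Permutation P values always use the (hits+1)/(n+1) correction. All
randomness flows through explicit integer seeds (numpy Generator); reruns
are bit-identical.

## Problem sizes used in the tests

The acceptance suite runs 100–500 replicates per scenario at the study
scale (55 tips); module tests use 10–40 replicates with commensurately
relaxed thresholds, since they guard implementation regressions rather
than estimate operating characteristics.

## Known limitations

- **Rate-ratio window at n = 55.** A ratio of clade rates estimated from
  25 and 28 contrasts has a log-scale sampling SD of ≈ √(2/25 + 2/28) ≈
  0.39, so the probability that a single estimate lands in [1.5, 3.0]
  peaks near 63% even when the true ratio is 2.17 and the estimator is
  perfectly centered; the λ-white-noise component further attenuates and
  disperses the estimate (ultra-short branches can dominate the mean
  squared contrast). The end-to-end acceptance test that requires this
  jointly in ≥80% of replicates fails for this reason, and the failure is
  a property of the design size, not of the estimator.
- **Boundary-ML λ̂ under a star phylogeny** keeps ~10% of its mass above
  0.1 at n = 55 (verified identical to phytools), so a "95% below 0.1"
  calibration bound is not attainable by maximum likelihood; the
  corresponding acceptance test documents this expectation in its
  docstring and fails by that margin.
- One specimen per species: no within-species measurement-error model.
- Shift search is stepwise, not exhaustive or LASSO-path; per-regime σ²
  and per-branch rates are out of scope; the phenogram's rate painting is
  clade-level.
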