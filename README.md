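# phylarynx

Phylogenetic comparative analysis of larynx-size evolution in primates and
carnivorans: landmark morphometrics → a PCA "larynx size" axis → pGLS
allometry with Pagel's λ → grade-shift inference (phylogenetic ANCOVA and
multi-regime Ornstein–Uhlenbeck modeling) → Brownian-motion rate
comparisons → acoustic (F0) and social-group-size correlates.

The package is aimed at comparative morphologists and evolutionary
bioacousticians who have (a) two time-calibrated clade phylogenies
(Newick/Nexus, branch lengths in My) and (b) a per-species specimen table
of laryngeal landmark distances, body size, covariates, and optional
ecology columns — or who want to study the behavior of these methods on
synthetic data with known truth, which the built-in generator provides for
every stage.

## The models

**Size axis.** Ten interlandmark distances (mm) per larynx are log10
transformed and reduced by PCA on the correlation matrix; the leading
component is "larynx size" (standardized scores, sign-oriented, loadings on
the correlation scale).

**Allometry with phylogenetic signal.** Across species,

&nbsp;&nbsp;&nbsp;&nbsp;size = α + β·log₁₀(body length) + ε,
&nbsp;&nbsp;ε ~ N(0, σ²·V(λ)),

where V is the Brownian-motion covariance of the tree (shared root-to-MRCA
path lengths) and Pagel's λ multiplies its off-diagonal entries; λ is
profiled by maximum likelihood over [0, 1].

**Grade shifts.** A grade shift is a change in the allometric intercept in
part of the tree with the slope conserved. Two complementary inferences:
phylogenetic ANCOVA compares nested λ-GLS models by an F test in whitened
space (equal slopes, then equal intercepts); and a multi-regime OU model
(optimum θ per regime, shared selection strength α and diffusion σ²) is
searched stepwise over candidate shift edges under a penalized BIC, with
parametric-bootstrap support and a signal-to-noise effect size for the
chosen painting.

**Rates.** The BM rate σ² (trait variance per My) is estimated per clade as
the mean squared phylogenetically independent contrast; the
primate/carnivoran rate ratio is tested against 1 by permuting squared
contrasts between clades, and rate posteriors (Jeffreys prior →
scaled-inverse-χ²) feed density plots. A multi-rate ancestral-state
reconstruction supplies the phenogram.

## Worked example

Generate the default synthetic study (26 primates + 29 carnivorans on a
79-My grafted tree, grade shift 1.05, λ = 0.956, rate ratio 2.17) and run
the core chain:

```python
import numpy as np
from phylarynx import (SimulationConfig, make_dataset, pancova, residual_trait,
                       detect_shifts, rate_ratio_test, snr, grade_magnitude)
from phylarynx.morphometry import MEASUREMENT_NAMES, size_axis
from phylarynx.comparative import pgls_lambda, design_with_intercept

data = make_dataset(SimulationConfig(seed=0))
tree, table = data["tree"], data["table"]

meas = table.set_index("species")[list(MEASUREMENT_NAMES)]
axis = size_axis(np.log10(meas))
size = axis.scores.loc[tree.tip_labels].to_numpy()
bl = np.log10(table.set_index("species").loc[tree.tip_labels, "body_length_mm"].to_numpy())

X, _ = design_with_intercept(bl)
fit = pgls_lambda(size, X, tree, names=["intercept", "log10_body_length"])
clade = table.set_index("species").loc[tree.tip_labels, "clade"].tolist()
res = pancova(size, bl, clade, tree, hypothesis="intercepts")
resid = residual_trait(size, bl, tree)
shifts = detect_shifts(resid, tree)
prim = [l for l in tree.tip_labels if l.startswith("Primate")]
carn = [l for l in tree.tip_labels if l.startswith("Carnivoran")]
rr = rate_ratio_test(resid, tree, prim, carn, n_perm=9999, seed=1)
```

which prints (via the example's `print` statements):

```
PC1 'larynx size' explains 99.9% of log-measurement variance
pGLS allometry: slope = 1.615, Pagel's lambda = 0.979
pANCOVA (equal intercepts): F = 34.16, P = 3.4e-07
matched-pair grade magnitude: 1.43x (SD 0.09)
OU shift search: 1 regime shift(s); effect size = 3.76
BM rate ratio (primate/carnivoran) = 1.57, one-tailed P = 0.242
```

Reading the output: nearly all measurement variance sits on one size
factor; larynx size scales with body length with strong phylogenetic
signal (λ ≈ 0.98); the clades share a slope but differ in intercept
(F = 34.2) — the grade shift — and, matched at body length, primate
larynges are ~1.4× larger; the OU search places one regime shift
(separating the clades); the primate rate estimate is 1.57× the carnivoran
one in this particular draw (the generating ratio is 2.17; a ratio of two
clade rate estimates from ~25 contrasts each is variable, and this draw's
one-tailed permutation P of 0.24 reflects that).

The same chain is available as a CLI over YAML configs:

```sh
phylarynx simulate --seed 3 --out synthetic_data
phylarynx run config.yaml --out results/
```

`run` writes `results.json` (versioned schema; every statistic carries its
stage and seed), a markdown report, and the phenogram SVG + CSV sidecar.

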