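# icarh

Bayesian integrative analysis of short longitudinal metabolomics
experiments measured alongside a second omic data type (bacterial
abundances, transcripts, drug levels, ...), with pathway-level
interpretation: the **integrative CAR-horseshoe (iCARH) model**.

Metabolomics time courses are short (often fewer than ten time points),
highly multivariate, and structured: metabolites in the same metabolic
pathway are co-regulated and therefore correlated, individuals differ
systematically, and measurements are autocorrelated in time.  `icarh`
models all of these sources of variation in a single hierarchical model
and, as a by-product, infers **which pathways are perturbed by the
treatment** and **which cross-omic associations are real**.

## The model

For individual *i* at time *t* in experimental group *e* ∈ {cases,
controls}, the metabolite vector **x**<sub>it</sub> ∈ ℝ<sup>M</sup> follows

```
x_it^e | mu_it ~ N( mu_it , (I_M − C(phi^e))^{-1} sigma² )
mu_itm = alpha_m + gamma_im + beta_m' y_it + nu_itm
```

* **Pathway CAR component** — C(φ) = Σ<sub>p</sub> φ<sub>p</sub>
  G<sub>p</sub>A<sub>p</sub> couples metabolites that share a pathway
  (A<sub>p</sub>: within-pathway adjacency weighted by reciprocal
  shortest-path length; G<sub>p</sub>: reciprocal neighbour counts).  Each
  φ<sub>p</sub> measures how strongly pathway *p*'s members hang together;
  fitting separate φ<sup>cases</sup> and φ<sup>controls</sup> and comparing
  them flags **perturbed pathways**: a pathway is called when the 95%
  credible interval of φ<sup>controls</sup><sub>p</sub> −
  φ<sup>cases</sup><sub>p</sub> excludes zero.  φ<sub>p</sub> is given a
  boundary-favouring Beta(1/2, 1/2)-type prior on its admissible interval,
  because CAR models only express strong interaction near the interval
  boundaries.
* **Horseshoe shrinkage** — associations between metabolite *m* and the
  K companion variables: β<sub>mk</sub> | λ<sub>mk</sub>, σ<sub>βm</sub> ~
  N(0, λ²<sub>mk</sub>σ²<sub>βm</sub>) with local scales λ<sub>mk</sub> ~
  St⁺(τ, 0, 1).  τ = 1 recovers the horseshoe prior; larger τ shrinks
  harder.  The shrinkage coefficient κ<sub>mk</sub> = 1/(1 +
  λ²σ²<sub>β</sub>/τ) has a closed-form prior density (`kappa_pdf`), and
  `expected_kappa(tau)` lets you pick τ from the expected fraction of
  shrunk coefficients a priori.
* **Experimental design** — per-metabolite treatment effects α<sub>m</sub>
  (or β<sup>α</sup><sub>m</sub>·y<sub>drug</sub> for a continuous dose),
  individual random effects γ<sub>im</sub>, and AR(1) temporal effects
  ν<sub>itm</sub> with stationary initialization.

Inference is Markov chain Monte Carlo on the marginal posterior (γ and ν
integrated out analytically): dynamic Hamiltonian Monte Carlo with a dense
adapted metric for the covariance block, exact Gaussian conditional draws
for the mean block, and slice updates for the shrinkage scales.  Model
criticism ships with the package: WAIC, posterior-predictive checks on the
metabolite covariance (mean absolute deviation), and whitened-residual
normality checks.

## Worked example

```python
import numpy as np
from icarh import (SimulationSpec, simulate_dataset, build_design_matrices,
                   ModelSpec, SamplerSettings, fit, pathway_perturbation)

# a synthetic study: 22 individuals, 7 time points, 40 metabolites in 11
# pathways, 1 bacterial covariate; about half the pathways truly perturbed
dataset, truth = simulate_dataset(SimulationSpec(seed=12))
pm = build_design_matrices(truth.Z)

spec = ModelSpec(tau=1.2, sampler=SamplerSettings(
    iterations=600, warmup=300, chains=1, seed=5))
samples = fit(dataset, pm, spec, standardize=False)

report = pathway_perturbation(samples, omega=truth.omega)
print(report.table[["pathway", "mean", "lower", "upper", "call", "score"]]
      .round(2).to_string(index=False))
print(f"AUC vs ground truth: {report.auc:.3f}")
```

Output:

```
 pathway  mean  lower  upper  call  score
       0  0.62   0.07   1.16  True   0.97
       1  0.01  -0.19   0.22 False   0.13
       2  0.34  -0.22   1.01 False   0.83
       3  0.26  -0.10   0.74 False   0.79
       4  0.23  -0.11   0.65 False   0.75
       5  0.01  -0.32   0.27 False   0.10
       6  0.65   0.27   1.11  True   1.00
       7 -0.00  -0.37   0.34 False   0.15
       8 -0.02  -0.31   0.26 False   0.02
       9 -0.01  -0.29   0.14 False   0.03
      10 -0.32  -0.83   0.09 False   0.89
AUC vs ground truth: 0.929
```

The truly perturbed pathways here are 0, 2, 3 and 6.  Pathways whose
interval excludes zero (`call = True`) are the inferred perturbed
pathways (0 and 6); `score` is the posterior two-sided tail probability
used to rank pathways for ROC analysis — the four perturbed pathways
occupy four of the top five ranks (AUC 0.93).

The same workflow is available from the shell:

```bash
icarh simulate --preset paper --seed 1 --out-dir sim/
icarh fit --x sim/X.tsv --y sim/Y.tsv --groups sim/groups.tsv \
          --membership sim/membership.tsv --seed 2 --out-dir fit/
icarh report --draws-dir fit/draws --truth sim/truth.json --out-dir report/
icarh replicate-paper --datasets 3 --fractions 0,0.5 --seed 1 --out study.tsv
```

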