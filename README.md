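# milknet

Causal-network discovery and quantification among correlated traits in
pedigreed populations, developed around bovine milk fatty-acid composition.

## The problem

Milk fatty acids are strongly correlated, both genetically and residually,
because they share synthesis pathways (de novo elongation, desaturation,
biohydrogenation) and a common genetic background. Correlations alone cannot
distinguish a direct causal link between two fatty acids from an indirect
one, or from confounding by correlated additive-genetic effects. This
package implements the full analysis chain for separating those sources:

1. **Multi-trait Bayesian animal model** — `y = Xβ + Zu + e` with
   `u ~ N(0, G₀ ⊗ A)` and `e ~ N(0, R₀ ⊗ I)`, where `A` is the pedigree-derived
   numerator relationship matrix. Both covariance matrices carry a
   latent-factor structure (`R₀[i,j] = Σₖ r₍ₖ,ᵢ₎r₍ₖ,ⱼ₎ + δᵢⱼ τ²ₑ,ᵢ`, likewise
   `G₀` with loadings `s` and remainders `τ²ᵤ`), with a floor of 0.02 on the
   remaining variances that keeps the Gibbs sampler mixing when traits are
   nearly collinear. Fitted by a fully conjugate Gibbs sampler
   (`milknet.mixed_model`).
2. **Inductive causation (IC) on posterior covariance samples** — the
   residual covariance `R₀` is the trait covariance conditional on genetic
   and systematic confounders, so the causal search runs on its posterior:
   for every trait pair `(i, j)` and every conditioning subset `S` of the
   remaining traits, a partial-correlation draw `−Ω᷉ᵢⱼ/√(Ω᷉ᵢᵢΩ᷉ⱼⱼ)` is computed
   per posterior sample, and the pair is declared dependent given `S` when
   the highest-posterior-density (HPD) interval excludes zero. Skeleton,
   collider orientation and orientation propagation follow
   (`milknet.network_search`).
3. **Structural equation model (SEM)** — for an acyclic structure `Λ`,
   `y = (Λ ⊗ I)y + Xβ* + Zu* + e*` with diagonal `Ψ₀` (which identifies the
   structural coefficients `λ`) and direct genetic effects
   `u* ~ N(0, G₀* ⊗ A)`. Compared against the multi-trait model with the
   deviance information criterion, `DIC = D̄ + pD` (`milknet.sem`).

A synthetic-data module (`milknet.synthetic_data`) generates pedigreed
populations and phenotypes from a known recursive model — by default the de
novo synthesis chain C4:0 → C6:0 → C8:0 → C10:0 → C12:0 with structural
coefficients between 0.85 and 1.05 — so every stage is testable end to end
without proprietary data.

## Worked example

Simulate a small study from the default causal chain, fit both models and
compare them:

```python
from milknet import synthetic_data as sd
from milknet.mixed_model import (ModelSpec, build_design_matrices,
                                 run_mcmc, standardize_phenotypes)
from milknet.relationships import build_numerator_relationship_matrix
from milknet.sem import LambdaStructure, compare_models, fit_sem

truth = sd.default_truth()
design = sd.StudyDesign(n_cows=600, n_herds=8, n_generations=3)
ped, phenotypes = sd.simulate_study(truth, design, seed=1)

std, scale = standardize_phenotypes(phenotypes, truth.traits)
X, _ = build_design_matrices(phenotypes)
A = build_numerator_relationship_matrix(ped)
animals = phenotypes["animal"].tolist()
A_obs = A.loc[animals, animals]

mcmc = dict(chains=2, iterations=3000, burn_in=1000, thin=5)
mtm = run_mcmc(std, X, A_obs, ModelSpec(traits=truth.traits, k=2), seed=2, **mcmc)
sem = fit_sem(std, X, A_obs, LambdaStructure.from_chain(truth.traits),
              k=2, seed=3, **mcmc)

for (parent, child), lam in sem.lambda_mean().items():
    print(f"lambda[{child} <- {parent}] = {lam:.2f}")
report = compare_models(mtm, sem)
print(f"DIC: multi-trait {report.dic_a:.0f}, SEM {report.dic_b:.0f} "
      f"(delta {report.delta_dic:.0f})")
```

Output:

```
lambda[C6:0 <- C4:0] = 1.01
lambda[C8:0 <- C6:0] = 0.89
lambda[C10:0 <- C8:0] = 0.84
lambda[C12:0 <- C10:0] = 0.83
DIC: multi-trait 427, SEM -9076 (delta -9503)
```

The structural coefficients (here on the standardized scale) recover the
generating chain, and the strongly negative ΔDIC says the SEM — which
explains each downstream fatty acid through its causal parent with a
diagonal residual covariance — is far better supported than the unstructured
multi-trait model on data generated from a causal chain.

## Analysis scripts and CLI

The numbered scripts under `analysis/` run the study end to end at the full
sampling design (1902 cows, 397 herds, four pedigree generations), writing
artifacts to `results/study/`:

```bash
python analysis/01_simulate.py        # pedigree + phenotypes + truth
python analysis/02_fit_multitrait.py  # Gibbs sampler, posterior (G0, R0)
python analysis/03_ic_search.py       # IC at HPD 95/90/85/80%
python analysis/04_fit_sem.py         # prior-knowledge chain -> SEM
python analysis/05_compare_models.py  # variance components + DIC table
```

The same stages are available as a CLI (`milknet simulate|fit-mtm|ic-search|
fit-sem|compare|run-all --config cfg.yaml --out rundir`), plus
`milknet molar-mass-ratio C6:0 C4:0` for the saturated fatty-acid molar-mass
utility (prints `1.32`).

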