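# Methods

This note documents the models, algorithmic choices, default parameters and
known limitations of the package, in the order the pipeline runs them.

## Pedigree and relationship matrix

The numerator relationship matrix **A** is built with the tabular
(recursive) method: animals in parents-before-offspring order,
`A[i,j] = ½(A[sire_i,j] + A[dam_i,j])` with unknown parents contributing
zero, and `A[i,i] = 1 + ½ A[sire_i, dam_i]`. The method is exact and
adequate for pedigrees up to tens of thousands of animals; faster
A-inverse constructions are deliberately out of scope. Pedigree parsing
enforces unique ids and acyclicity, topologically reorders rows, and
auto-inserts undeclared parents as founders with a warning. Inbreeding
coefficients for the simulator use memoized recursive kinship instead of
the full tabular matrix, so very large founder-only pedigrees cost O(N).
The analysis uses **A** over the full pedigree restricted to the phenotyped
animals (marginalizing ancestors is exact for covariance estimation);
`Pedigree.subset_to_ancestors` offers pruning when a smaller matrix is
wanted.

## Synthetic study generator

The generator emulates a winter milk-sampling field study: by default 1902
first-lactation cows on 397 herds (at least 3 per herd, remainder
multinomial), days in milk uniform on [63, 282], age at first calving
N(24, 2²) months, three calving seasons, two sire codes, and a pedigree of
four generations in which each ancestral layer halves in size and roughly
10% of ancestors are males used as sires — producing the paternal half-sib
families typical of dairy data. Fixed effects enter on the latent scale as
a Wilmink lactation curve (`dim`, `exp(−0.05·dim)`), centred AFC and AFC²,
season and sire-code offsets, and herd effects drawn once per herd from
N(0, 0.3²).

Phenotypes come from the reduced form of a recursive structural model,
`y = (I − Λ)⁻¹(Xβ* + u* + e*)`, with breeding values gene-dropped down the
pedigree (founders ~ N(0, G₀*); offspring get the parent average plus a
Mendelian term with covariance `G₀*(½ − ¼(F_s + F_d))`), so that
`Var(vec u) = G₀* ⊗ A` exactly. Outputs are shifted and scaled to g/kg
using the fatty-acid panel means and SDs.

Default truth: the causal structure is the de novo synthesis chain
C4:0 → C6:0 → C8:0 → C10:0 → C12:0 with coefficients
(1.05, 0.90, 0.85, 0.95). The chain traits' direct-genetic variances
(0.460, 0.114, 0.073, 0.066, 0.026), their direct-genetic correlations, and
the direct residual variances (0.455, 0.003, 0.002, 0.006, 0.059) are set
to the magnitudes a SEM fit of such a panel reports on standardized data —
in particular, downstream residual variances one to two orders of magnitude
below the chain head, because each fatty acid is nearly determined by its
causal parent. (A printed value of 0.000 at three decimals is represented
as 0.002, half the printing resolution, to keep the generative model
non-degenerate.) This near-determinism is the feature that drives the DIC
comparison below. Traits outside the chain are causally unlinked with
genetic variance 0.30, genetic correlation 0.50 among themselves and 0.20
to the chain (eigenvalue-clipped to PSD where the mixed blocks require it).

The generator does **not** emulate gas-chromatography measurement error,
selection or assortative mating, or non-linear causal links. Passing tests
therefore demonstrate correctness of the estimators under a linear,
causally sufficient, multivariate-normal world — not robustness to the
measurement process of real milk-fat phenotyping.

## Multi-trait model and sampler

Standardized traits (sample mean 0, SD 1) are modelled as
`y = Xβ + Zu + e`. Trait i's residual is `Σₖ r₍ₖ,ᵢ₎ vₖ + εᵢ` with
`vₖ ~ N(0, I)`, `εᵢ ~ N(0, τ²ₑ,ᵢ I)`; its genetic effect is
`Σₖ s₍ₖ,ᵢ₎ wₖ + δᵢ` with `wₖ ~ N(0, A)`, `δᵢ ~ N(0, τ²ᵤ,ᵢ A)`. Loadings get
flat priors; the remaining variances get uniform priors on [0.02, ∞). On
standardized traits the floor means at least 2% of each trait's residual
and genetic variance is trait-specific, which bounds heritabilities away
from 0 and 1 and keeps the sampler mixing when traits are nearly collinear.
The factor dimension k is chosen as the smallest number of correlation-
matrix principal components explaining 90% of the variance (k = 4 for the
14-trait panel; k = 2 for the 5 chain traits, at which point the structure
carries 15 parameters — as many as an unstructured 5×5 covariance).

All conditionals are conjugate, so the sampler is pure Gibbs: normal draws
for β, latent vectors, and loadings; scaled inverse chi-square draws for
the remaining variances, truncated to [floor, ∞) by inverse-CDF sampling of
the precision (never by clamping). Computationally the model is rotated
into the eigenbasis of A (`A = QDQᵀ`, computed once): there every latent
vector has an independent-component prior and all updates vectorise, making
a full iteration a handful of O(n·t) array operations. Chains are seeded
independently via spawned seed sequences; identical (config, seed) gives
identical trajectories.

Only the reconstructed covariances `R₀ = rᵀr + diag(τ²ₑ)` and
`G₀ = sᵀs + diag(τ²ᵤ)` are identified (loadings are sign/rotation
invariant); recovery tests and convergence diagnostics therefore monitor
covariance entries, never loadings. Effective sample size uses Geyer's
initial-positive-sequence truncation of the autocorrelation sum, summed
over chains.

## IC search on posterior covariance samples

For t traits the full plan is t(t−1)/2 pairs × 2^(t−2) conditioning subsets
(91 × 4096 = 372 736 partial correlations per posterior sample at t = 14);
an optional `max_cond_size` caps subset size for larger panels, with the
default being full enumeration. Partial correlations come from the inverse
of the covariance submatrix over `{i, j} ∪ S`; draws whose submatrix is
numerically singular are excluded and counted. HPD intervals use the
shortest sorted window containing ⌈content·N⌉ draws, ties broken by the
lowest window start.

Step 1 places an edge iff every subset's HPD excludes zero and records all
zero-covering subsets of non-adjacent pairs as separating sets. Step 2
orients an unshielded triple i–m–j as a collider iff m belongs to no
recorded separating set of (i, j); conflicting demands on one edge abort
with a report listing the triples rather than being resolved silently.
Step 3 applies the two orientation-propagation rules (direct b→c when a→b
and a, c non-adjacent; direct a→c when a→b→c and a–c) to a fixpoint and
verifies that no cycle or new unshielded collider was introduced.

Decisions depend only on the multiset of posterior samples, and relaxing
the HPD content can only add edges in practice (a narrower credible
interval that excluded zero keeps excluding it for any unimodal posterior);
both properties are exercised by tests on simulated posteriors.

## SEM and DIC

For a fixed acyclic pattern Λ, each trait's equation regresses on the
shared fixed effects plus the observed phenotypes of its causal parents;
residuals are independent across traits (diagonal Ψ₀), which is what makes
the structural coefficients likelihood-identified. `G₀*` carries the same
latent-factor device and 0.02 floor as the multi-trait model; the λ and β*
get flat priors. Ψ₀ itself gets only a small positivity floor (10⁻⁶): a
strong causal chain legitimately leaves residual variances far below 0.02,
and the 0.02 floor exists to stabilise the *latent-factor* covariance
structures, which a diagonal Ψ₀ does not have. The reduced form
`G₀ = (I−Λ)⁻¹G₀*(I−Λ)⁻ᵀ`, `R₀ = (I−Λ)⁻¹Ψ₀(I−Λ)⁻ᵀ` links SEM and
multi-trait parameters; fitting the multi-trait model to SEM-generated data
recovers these reduced-form covariances.

DIC uses a deviance conditional on the fixed and genetic effects but
**marginal over the residual covariance structure**: for the multi-trait
model, `D = −2 log N(y | Xβ + u, R₀ ⊗ I)`; for the SEM (which has no
residual latent vectors) the analogous quantity is the per-equation
residual likelihood under Ψ₀. This focus is the one under which the two
covariance models actually compete: the multi-trait model's floored R₀
cannot exploit a nearly deterministic chain, while the SEM's unfloored
diagonal Ψ₀ can, and the SEM is additionally more parsimonious. A fully
conditional focus (conditioning also on the residual latent vectors) is
available via `deviance_focus="conditional"`, but under it the latent
vectors absorb the residual covariance and the comparison degenerates into
one of per-record overfit. `pD = D̄ − D(θ̄)` uses the posterior mean of the
location fit and of the covariance parameters.

Because fitting standardizes each trait by its sample SD, a generating
coefficient λ appears in the fit as `λ · SD(parent)/SD(child)` on the
latent scale; recovery tests and the acceptance script apply this exact
algebraic conversion rather than a tolerance.

## Pipeline, prior knowledge, reporting

The pipeline (config-driven, YAML) runs simulate → standardize/design →
multi-trait fit → IC at a decreasing ladder of HPD contents (default 95,
90, 85, 80%) → prior-knowledge orientation → SEM fit → DIC comparison,
writing every artifact as plain text with a manifest keyed by a config
hash, so identical (config, seed) runs produce byte-identical artifacts.
Prior-knowledge orientation is declarative: an ordered trait chain whose
consecutive edges must exist in the graph and whose orientation must not
create cycles or unsupported colliders — both checked, with errors naming
the offending edge. The molar-mass utility for saturated fatty acids
(CnH2nO2, standard atomic weights) supports interpreting chain coefficients
per unit mass; M(C6:0)/M(C4:0) = 1.32.

## Problem sizes in tests and the acceptance script

The package's own desk-scale defaults are 4 chains × 20 000 iterations
(burn-in 5 000, thinning 10); production-scale settings remain plain config
values. The test suite and acceptance script use smaller sizes chosen so
posteriors stay tight enough for 3-SD recovery checks: the shared recovery
study uses 1200 cows on 12 herds over three generations with 2 chains ×
4000 iterations; the DIC replication uses 5 seeds at 350 cows; skeleton
recovery uses 24 runs at n = 5000 with 600 conjugate posterior draws; the
dual-route sampler validation compares the Gibbs fit against an
affine-invariant ensemble sampler on the analytically marginalized
posterior of a two-trait instance (n = 500).

Statistical acceptance thresholds are treated statistically: per-seed
skeleton recovery at 95% HPD content is itself a ~95%-probability event
(each credible interval excludes a true zero with ~5% probability), so the
"≥ 95% of seeds" claim is tested as a one-sided binomial consistency check
(reject only when the observed count is below the 5th percentile of
Binomial(24, 0.95)).

## Known limitations

- **Floor-induced distortion under near-determinism.** When true
  conditional residual variances lie below the 0.02 floor (as in the
  default chain truth), the floored factor-structured R₀ cannot represent
  the chain's conditional independencies exactly. With large samples the
  posterior becomes tight enough that the IC step connects the chain traits
  densely; sparse recovery of the skeleton is a property of moderate-noise
  structures (all conditional variances above the floor) or of posteriors
  with more spread. The IC machinery itself is validated on such
  structures; the near-deterministic default instead drives the SEM/DIC
  results.
- Loadings are unidentified; anything reported about covariance structures
  goes through the reconstructed matrices.
- The conditional-independence test is Gaussian partial correlation; cyclic
  structures, latent confounders within the trait set, and non-linear
  links are out of scope.
- At short chain lengths the covariance entries can have small effective
  sample sizes (the trait panel is nearly collinear by design); script 02
  prints ESS so users can judge chain-length adequacy.
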