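"""Synthetic pedigreed populations with phenotypes from a known causal model.

The generator emulates a field study of first-lactation dairy cows spread
over commercial herds: a multi-generation pedigree, herd/season/lactation
covariates, additive genetic effects correlated through the pedigree, and
multi-trait phenotypes produced by a *recursive* structural model

.. math::

    y = (I - \\Lambda)^{-1} (X\\beta^* + u^* + e^*),

with acyclic structural coefficients ``Λ``, direct genetic effects
``u* ~ N(0, G0* ⊗ A)`` and independent residuals ``e* ~ N(0, Ψ0 ⊗ I)``.
Because the generating model is the reduced form of a structural equation
model, downstream network search and SEM fitting are well-specified
recovery problems with a known answer.

Default trait names, means and phenotypic standard deviations follow the
bovine milk fatty-acid panel (g/kg milk) that motivates the package; the
default causal structure is the de-novo-synthesis chain
C4:0 → C6:0 → C8:0 → C10:0 → C12:0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from milknet.relationships import Pedigree, inbreeding_coefficients

__all__ = [
    "FATTY_ACID_TRAITS",
    "CHAIN_TRAITS",
    "StudyDesign",
    "FixedEffectTruth",
    "SimulationTruth",
    "default_truth",
    "simulate_population",
    "simulate_genetic_effects",
    "simulate_phenotypes_from_sem",
    "simulate_study",
    "write_truth",
    "read_truth",
]

#: Milk fatty-acid panel: trait -> (mean, phenotypic SD), both in g/kg milk.
FATTY_ACID_TRAITS: dict[str, tuple[float, float]] = {
    "C4:0": (1.53, 0.26),
    "C6:0": (0.97, 0.17),
    "C8:0": (0.60, 0.11),
    "C10:0": (1.32, 0.28),
    "C12:0": (1.79, 0.37),
    "C14:0": (5.05, 0.77),
    "C16:0": (14.27, 2.84),
    "C18:0": (3.80, 0.84),
    "C10:1": (0.16, 0.04),
    "C12:1": (0.05, 0.01),
    "C14:1": (0.59, 0.13),
    "C16:1": (0.63, 0.19),
    "C18:1": (7.87, 1.20),
    "CLA": (0.17, 0.04),
}

#: The de novo synthesis chain used as the default causal structure.
CHAIN_TRAITS: tuple[str, ...] = ("C4:0", "C6:0", "C8:0", "C10:0", "C12:0")

#: Default structural coefficients along the chain (parent -> child order).
DEFAULT_CHAIN_COEFFICIENTS: tuple[float, ...] = (1.05, 0.90, 0.85, 0.95)


class DesignError(ValueError):
    """Raised when a study design is internally infeasible."""


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the emulated field study.

    Defaults describe winter milk sampling of first-lactation cows: 1902
    cows on 397 herds with at least three cows per herd, days in milk
    between 63 and 282, and a pedigree reaching four generations back.
    """

    n_cows: int = 1902
    n_herds: int = 397
    min_cows_per_herd: int = 3
    dim_range: tuple[int, int] = (63, 282)
    n_generations: int = 4
    n_seasons: int = 3
    n_sire_codes: int = 2
    afc_mean: float = 24.0  # age at first calving, months
    afc_sd: float = 2.0

    def validate(self) -> None:
        if self.n_cows < self.n_herds * self.min_cows_per_herd:
            raise DesignError(
                f"infeasible design: {self.n_cows} cows cannot fill "
                f"{self.n_herds} herds with >= {self.min_cows_per_herd} cows each"
            )
        lo, hi = self.dim_range
        if not (1 <= lo <= hi <= 500):
            raise DesignError(f"dim_range {self.dim_range} outside [1, 500]")
        if self.n_generations < 1:
            raise DesignError("n_generations must be >= 1")


@dataclass(frozen=True)
class FixedEffectTruth:
    """Generating fixed-effect values, on the standardized latent scale.

    The lactation-stage effect uses the Wilmink parameterisation
    ``dim_slope * DIM + wilmink * exp(-0.05 * DIM)``; age at first calving
    enters centred at its design mean.
    """

    dim_slope: float = -0.0015
    wilmink: float = 0.40
    afc: float = 0.03
    afc2: float = -0.010
    season: tuple[float, ...] = (0.0, 0.10, -0.10)
    sire_code: tuple[float, ...] = (0.0, 0.15)
    herd_sd: float = 0.30


@dataclass(frozen=True)
class SimulationTruth:
    """The generating parameters of the recursive multi-trait model."""

    traits: tuple[str, ...]
    lambda_true: np.ndarray  # t x t, acyclic pattern, zero diagonal
    g0_star: np.ndarray  # t x t direct-genetic covariance, PSD
    psi0: np.ndarray  # t residual variances (diagonal of Psi0)
    fixed: FixedEffectTruth = field(default_factory=FixedEffectTruth)
    trait_means: np.ndarray | None = None  # g/kg output location
    trait_sds: np.ndarray | None = None  # g/kg output scale

    def __post_init__(self) -> None:
        t = len(self.traits)
        lam = np.asarray(self.lambda_true, dtype=float)
        g0 = np.asarray(self.g0_star, dtype=float)
        psi = np.asarray(self.psi0, dtype=float).ravel()
        if lam.shape != (t, t) or g0.shape != (t, t) or psi.shape != (t,):
            raise ValueError("truth parameter dimensions inconsistent with traits")
        if np.any(np.diag(lam) != 0):
            raise ValueError("lambda_true must have a zero diagonal")
        if not _is_acyclic(lam):
            raise ValueError("lambda_true pattern contains a cycle")
        if np.any(psi < 0):
            raise ValueError("psi0 must be non-negative")
        eigmin = np.linalg.eigvalsh((g0 + g0.T) / 2).min()
        if eigmin < -1e-8:
            raise ValueError("g0_star must be positive semi-definite")
        object.__setattr__(self, "lambda_true", lam)
        object.__setattr__(self, "g0_star", g0)
        object.__setattr__(self, "psi0", psi)
        means, sds = self.trait_means, self.trait_sds
        if means is None:
            means = np.array([FATTY_ACID_TRAITS.get(tr, (0.0, 1.0))[0] for tr in self.traits])
        if sds is None:
            sds = np.array([FATTY_ACID_TRAITS.get(tr, (0.0, 1.0))[1] for tr in self.traits])
        object.__setattr__(self, "trait_means", np.asarray(means, dtype=float))
        object.__setattr__(self, "trait_sds", np.asarray(sds, dtype=float))

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def reduced_residual_covariance(self) -> np.ndarray:
        """Residual covariance of the reduced form, (I-Λ)⁻¹ Ψ0 (I-Λ)⁻ᵀ."""
        t = self.n_traits
        m = np.linalg.inv(np.eye(t) - self.lambda_true)
        return m @ np.diag(self.psi0) @ m.T

    def reduced_genetic_covariance(self) -> np.ndarray:
        """Genetic covariance of the reduced form, (I-Λ)⁻¹ G0* (I-Λ)⁻ᵀ."""
        t = self.n_traits
        m = np.linalg.inv(np.eye(t) - self.lambda_true)
        return m @ self.g0_star @ m.T


def _is_acyclic(lam: np.ndarray) -> bool:
    g = nx.DiGraph()
    g.add_nodes_from(range(lam.shape[0]))
    # lambda[child, parent] != 0 encodes the edge parent -> child
    child, parent = np.nonzero(lam)
    g.add_edges_from(zip(parent, child))
    return nx.is_directed_acyclic_graph(g)


#: Direct-genetic variances of the chain traits on the standardized scale.
_CHAIN_G_VAR = (0.460, 0.114, 0.073, 0.066, 0.026)
#: Correlations between the chain traits' direct genetic effects.
_CHAIN_G_CORR = {
    (0, 1): -0.440, (0, 2): -0.417, (0, 3): -0.400, (0, 4): -0.084,
    (1, 2): 0.761, (1, 3): 0.730, (1, 4): 0.160,
    (2, 3): 0.692, (2, 4): 0.152,
    (3, 4): 0.148,
}
#: Direct residual variances of the chain traits: the causal chain is nearly
#: deterministic once upstream traits are known, so downstream variances are
#: one to two orders of magnitude below the first trait's.
_CHAIN_PSI = (0.455, 0.003, 0.002, 0.006, 0.059)


def default_truth(
    traits: tuple[str, ...] | list[str] | None = None,
    chain: tuple[str, ...] = CHAIN_TRAITS,
    chain_coefficients: tuple[float, ...] = DEFAULT_CHAIN_COEFFICIENTS,
    extra_genetic_variance: float = 0.30,
    extra_genetic_correlation: float = 0.50,
) -> SimulationTruth:
    """Build the default generating truth.

    The causal structure is a single directed chain over ``chain`` (the
    de novo synthesis pathway by default), with structural coefficients in
    the 0.85–1.05 range and the chain traits' direct genetic and residual
    variance components matching the magnitudes a SEM fit of such a panel
    reports on standardized data — in particular, tiny direct residual
    variances for downstream chain traits, so most of each trait's variation
    is explained by its causal parent.  Any further traits are causally
    unlinked but genetically correlated (``extra_genetic_*`` parameters,
    with a weak 0.2 genetic correlation to the chain traits' direct
    effects).
    """
    traits = tuple(traits) if traits is not None else chain
    t = len(traits)
    lam = np.zeros((t, t))
    for coef, (parent, kid) in zip(chain_coefficients, zip(chain[:-1], chain[1:])):
        if parent in traits and kid in traits:
            lam[traits.index(kid), traits.index(parent)] = coef

    chain_pos = {tr: c for c, tr in enumerate(chain)}
    gvar = np.array(
        [
            _CHAIN_G_VAR[chain_pos[tr]] if tr in chain_pos else extra_genetic_variance
            for tr in traits
        ]
    )
    corr = np.eye(t)
    for i in range(t):
        for j in range(i + 1, t):
            a, b = traits[i], traits[j]
            if a in chain_pos and b in chain_pos:
                key = tuple(sorted((chain_pos[a], chain_pos[b])))
                corr[i, j] = corr[j, i] = _CHAIN_G_CORR[key]
            elif a in chain_pos or b in chain_pos:
                corr[i, j] = corr[j, i] = 0.20
            else:
                corr[i, j] = corr[j, i] = extra_genetic_correlation
    g0 = corr * np.sqrt(np.outer(gvar, gvar))
    evals, evecs = np.linalg.eigh(g0)
    if evals.min() < 1e-8:  # eigenvalue clip keeps mixed blocks PSD
        g0 = (evecs * np.clip(evals, 1e-6, None)) @ evecs.T
        g0 = (g0 + g0.T) / 2
    psi = np.array(
        [_CHAIN_PSI[chain_pos[tr]] if tr in chain_pos else 0.55 for tr in traits]
    )
    return SimulationTruth(traits=traits, lambda_true=lam, g0_star=g0, psi0=psi)


# ---------------------------------------------------------------------------
# population structure
# ---------------------------------------------------------------------------

def simulate_population(
    design: StudyDesign, seed: int | np.random.Generator = 0
) -> tuple[Pedigree, pd.DataFrame]:
    """Simulate a pedigree and the covariate table of the phenotyped cows.

    The pedigree has ``n_generations`` layers; the phenotyped cows form the
    last one and earlier layers halve in size, with a small fraction of
    males acting as sires (mimicking artificial insemination, so paternal
    half-sib families arise).  With ``n_generations=1`` all cows are
    founders.  Herd assignment guarantees the design minimum per herd and
    distributes the remaining cows multinomially.

    Returns
    -------
    (Pedigree, DataFrame)
        Covariate columns: ``animal, herd, dim, afc, season, sire_code``.
    """
    design.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sizes = [design.n_cows]
    for _ in range(design.n_generations - 1):
        sizes.append(max(4, int(np.ceil(sizes[-1] / 2))))
    sizes = sizes[::-1]  # oldest generation first

    records: list[tuple[str, str | None, str | None]] = []
    males_prev: list[str] = []
    females_prev: list[str] = []
    male_code: dict[str, int] = {}
    last_gen: list[str] = []
    for g, size in enumerate(sizes, start=1):
        is_last = g == len(sizes)
        ids = [
            (f"COW{i + 1:05d}" if is_last else f"G{g}A{i + 1:05d}")
            for i in range(size)
        ]
        if males_prev:
            sires = rng.choice(males_prev, size=size)
            dams = rng.choice(females_prev, size=size)
            records.extend(zip(ids, sires, dams))
        else:
            records.extend((a, None, None) for a in ids)
        if not is_last:
            n_males = max(1, int(round(0.10 * size)))
            males_prev = ids[:n_males]
            females_prev = ids[n_males:]
            for m in males_prev:
                male_code[m] = int(rng.integers(design.n_sire_codes))
        last_gen = ids
    ped = Pedigree(tuple(records))

    n = design.n_cows
    herds = np.repeat(np.arange(design.n_herds), design.min_cows_per_herd)
    extra = n - herds.size
    if extra > 0:
        herds = np.concatenate([herds, rng.integers(design.n_herds, size=extra)])
    rng.shuffle(herds)

    sire_of = {a: s for a, s, _ in records}
    sire_codes = np.array(
        [
            male_code.get(sire_of[a], int(rng.integers(design.n_sire_codes)))
            if sire_of[a] is not None
            else int(rng.integers(design.n_sire_codes))
            for a in last_gen
        ]
    )
    lo, hi = design.dim_range
    covariates = pd.DataFrame(
        {
            "animal": last_gen,
            "herd": [f"H{h + 1:04d}" for h in herds],
            "dim": rng.integers(lo, hi + 1, size=n),
            "afc": np.round(rng.normal(design.afc_mean, design.afc_sd, size=n), 2),
            "season": [f"S{s + 1}" for s in rng.integers(design.n_seasons, size=n)],
            "sire_code": [f"K{c + 1}" for c in sire_codes],
        }
    )
    return ped, covariates


# ---------------------------------------------------------------------------
# genetic effects: gene dropping
# ---------------------------------------------------------------------------

def simulate_genetic_effects(
    ped: Pedigree,
    g0_star: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Drop multivariate breeding values down the pedigree.

    Founders draw ``u ~ N(0, G0*)``; an offspring receives the parental
    average plus a Mendelian-sampling deviation with covariance
    ``G0* * (0.5 - 0.25 (F_s + F_d))`` (the term for an unknown parent is
    replaced by a half-founder contribution), so that exactly
    ``Var(vec(u)) = G0* ⊗ A``.

    Raises
    ------
    ValueError
        If ``g0_star`` is not positive semi-definite.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g0 = np.asarray(g0_star, dtype=float)
    t = g0.shape[0]
    evals, evecs = np.linalg.eigh((g0 + g0.T) / 2)
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ValueError("g0_star must be positive semi-definite")
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))  # G0* = root rootᵀ

    F = inbreeding_coefficients(ped)

    u: dict[str, np.ndarray] = {}
    for animal, sire, dam in ped.records:
        mean = np.zeros(t)
        var_scale = 1.0
        for p in (sire, dam):
            if p is not None:
                mean += 0.5 * u[p]
                var_scale -= 0.25 * (1.0 + F[p])
        u[animal] = mean + np.sqrt(var_scale) * (root @ rng.standard_normal(t))
    return pd.DataFrame.from_dict(u, orient="index").loc[list(ped.animals)]


# ---------------------------------------------------------------------------
# phenotypes from the recursive model
# ---------------------------------------------------------------------------

def _fixed_effect_part(
    truth: SimulationTruth, covariates: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Per-animal fixed-effect contribution, identical across traits.

    Herd effects are drawn once per herd from ``N(0, herd_sd^2)``; they act
    as fixed herd levels in the analysis model.
    """
    fx = truth.fixed
    dim = covariates["dim"].to_numpy(dtype=float)
    afc_c = covariates["afc"].to_numpy(dtype=float) - np.mean(covariates["afc"])
    season_idx = covariates["season"].str.removeprefix("S").astype(int) - 1
    code_idx = covariates["sire_code"].str.removeprefix("K").astype(int) - 1
    herds = covariates["herd"].unique()
    herd_effect = dict(zip(herds, rng.normal(0.0, fx.herd_sd, size=herds.size)))
    part = (
        fx.dim_slope * dim
        + fx.wilmink * np.exp(-0.05 * dim)
        + fx.afc * afc_c
        + fx.afc2 * afc_c**2
        + np.asarray(fx.season)[season_idx]
        + np.asarray(fx.sire_code)[code_idx]
        + covariates["herd"].map(herd_effect).to_numpy()
    )
    return part


def simulate_phenotypes_from_sem(
    truth: SimulationTruth,
    ped: Pedigree,
    covariates: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate phenotypes through the reduced form of the recursive model.

    Per phenotyped animal, ``y = (I - Λ)⁻¹ (Xβ* + u* + e*)`` on the latent
    standardized scale, then shifted/scaled to the output units with the
    per-trait means and SDs of the truth.  Returns the covariate table with
    one additional column per trait.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = truth.n_traits
    animals = covariates["animal"].tolist()
    n = len(animals)

    u_all = simulate_genetic_effects(ped, truth.g0_star, rng)
    u = u_all.loc[animals].to_numpy()
    e = rng.standard_normal((n, t)) * np.sqrt(truth.psi0)
    fixed = _fixed_effect_part(truth, covariates, rng)[:, None]

    b = fixed + u + e
    latent = np.linalg.solve(np.eye(t) - truth.lambda_true, b.T).T
    out = covariates.copy()
    scaled = truth.trait_means + truth.trait_sds * latent
    for j, tr in enumerate(truth.traits):
        out[tr] = scaled[:, j]
    return out


def simulate_study(
    truth: SimulationTruth,
    design: StudyDesign | None = None,
    seed: int = 0,
) -> tuple[Pedigree, pd.DataFrame]:
    """Convenience wrapper: population + genetics + phenotypes, one seed."""
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    ped, covariates = simulate_population(design, rng)
    phenotypes = simulate_phenotypes_from_sem(truth, ped, covariates, rng)
    return ped, phenotypes


# ---------------------------------------------------------------------------
# truth round trip (YAML)
# ---------------------------------------------------------------------------

def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    payload = {
        "traits": list(truth.traits),
        "lambda_true": truth.lambda_true.tolist(),
        "g0_star": truth.g0_star.tolist(),
        "psi0": truth.psi0.tolist(),
        "trait_means": truth.trait_means.tolist(),
        "trait_sds": truth.trait_sds.tolist(),
        "fixed": {
            "dim_slope": truth.fixed.dim_slope,
            "wilmink": truth.fixed.wilmink,
            "afc": truth.fixed.afc,
            "afc2": truth.fixed.afc2,
            "season": list(truth.fixed.season),
            "sire_code": list(truth.fixed.sire_code),
            "herd_sd": truth.fixed.herd_sd,
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_truth(path: str | Path) -> SimulationTruth:
    payload = yaml.safe_load(Path(path).read_text())
    fx = payload["fixed"]
    return SimulationTruth(
        traits=tuple(payload["traits"]),
        lambda_true=np.array(payload["lambda_true"]),
        g0_star=np.array(payload["g0_star"]),
        psi0=np.array(payload["psi0"]),
        trait_means=np.array(payload["trait_means"]),
        trait_sds=np.array(payload["trait_sds"]),
        fixed=FixedEffectTruth(
            dim_slope=fx["dim_slope"],
            wilmink=fx["wilmink"],
            afc=fx["afc"],
            afc2=fx["afc2"],
            season=tuple(fx["season"]),
            sire_code=tuple(fx["sire_code"]),
            herd_sd=fx["herd_sd"],
        ),
    )
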