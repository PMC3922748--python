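"""Structural equation models for a fixed acyclic causal structure.

Given an acyclic structure ``Λ`` (zeros on the diagonal, a structural
coefficient ``λ_{child,parent}`` wherever the network has ``parent →
child``), the model is

.. math::

    y = (Λ \\otimes I) y + X β^* + Z u^* + e^*,

with direct genetic effects ``u* ~ N(0, G0* ⊗ A)`` and a *diagonal*
residual covariance ``Ψ0`` — the assumption that confers likelihood
identifiability on the structural coefficients.  Fitting reduces to a
multi-trait mixed model where each trait's causal parents enter that
trait's equation as covariates; ``G0*`` carries the same latent-factor
structure and variance floor as the multi-trait model, and the ``λ`` get
flat priors (conditionally normal draws).

The reduced form links SEM and multi-trait parameters:
``G0 = (I-Λ)⁻¹ G0* (I-Λ)⁻ᵀ`` and ``R0 = (I-Λ)⁻¹ Ψ0 (I-Λ)⁻ᵀ``.

Model comparison uses the deviance information criterion with a
*conditional* deviance focus: the deviance is −2 × the log-likelihood of
the phenotypes given all sampled location effects (fixed effects, latent
vectors, remaining genetic effects, and — for the SEM — the parent-trait
regressions), with the model's diagonal residual variances.  The penalty
``pD = mean(D) − D(posterior mean)`` then counts effective location
parameters, so the more parsimonious SEM (no residual latent vectors) is
rewarded exactly where its parsimony lies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from milknet.mixed_model import (
    MCMCResult,
    _deviance_at,
    _factor_gibbs_chain,
    _prepare_rotation,
)

__all__ = [
    "LambdaStructure",
    "SEMPosterior",
    "ModelComparison",
    "fit_sem",
    "reduced_form_covariances",
    "compute_dic",
    "compare_models",
]


@dataclass(frozen=True)
class LambdaStructure:
    """Pattern of free structural coefficients: directed edges parent → child."""

    traits: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # (parent, child)

    def __post_init__(self) -> None:
        known = set(self.traits)
        for parent, child in self.edges:
            for v in (parent, child):
                if v not in known:
                    raise ValueError(f"structure references unknown trait {v!r}")
            if parent == child:
                raise ValueError(f"self loop on trait {parent!r}")
        g = nx.DiGraph()
        g.add_nodes_from(self.traits)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structural-coefficient pattern contains a cycle")

    @classmethod
    def from_chain(cls, traits, chain=None) -> "LambdaStructure":
        """Chain structure ``traits[0] → traits[1] → ...`` (or over ``chain``)."""
        seq = tuple(chain) if chain is not None else tuple(traits)
        return cls(tuple(traits), tuple(zip(seq[:-1], seq[1:])))

    def parents_of(self, child: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.edges if c == child)

    @property
    def n_free(self) -> int:
        return len(self.edges)

    def lambda_matrix(self, values: np.ndarray | dict) -> np.ndarray:
        """Assemble the t×t ``Λ`` with ``Λ[child, parent] = λ``."""
        t = len(self.traits)
        idx = {v: i for i, v in enumerate(self.traits)}
        lam = np.zeros((t, t))
        for e, (parent, child) in enumerate(self.edges):
            val = values[(parent, child)] if isinstance(values, dict) else values[e]
            lam[idx[child], idx[parent]] = val
        return lam

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.edges, columns=["parent", "child"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, traits) -> "LambdaStructure":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(tuple(traits), tuple(df[["parent", "child"]].itertuples(index=False, name=None)))


@dataclass
class SEMPosterior:
    """Posterior samples from a structural-equation-model fit."""

    structure: LambdaStructure
    lambda_samples: np.ndarray  # (m, n_free), ordered as structure.edges
    psi: np.ndarray  # (m, t) residual variances
    g0_star: np.ndarray  # (m, t, t) direct-genetic covariance draws
    deviance: np.ndarray  # (m,)
    deviance_at_mean: float
    chain: np.ndarray
    iteration: np.ndarray
    n_records: int

    @property
    def traits(self) -> tuple[str, ...]:
        return self.structure.traits

    def lambda_mean(self) -> dict[tuple[str, str], float]:
        means = self.lambda_samples.mean(axis=0)
        return dict(zip(self.structure.edges, means))

    def lambda_sd(self) -> dict[tuple[str, str], float]:
        sds = self.lambda_samples.std(axis=0, ddof=1)
        return dict(zip(self.structure.edges, sds))


def fit_sem(
    phenotypes: pd.DataFrame,
    X: np.ndarray,
    A: np.ndarray | pd.DataFrame,
    structure: LambdaStructure,
    k: int = 2,
    variance_floor: float = 0.02,
    psi_floor: float = 1e-6,
    chains: int = 4,
    iterations: int = 20_000,
    burn_in: int = 5_000,
    thin: int = 10,
    seed: int = 0,
) -> SEMPosterior:
    """Fit the SEM by Gibbs sampling, for a fixed acyclic ``Λ`` pattern.

    Each trait's equation regresses on the shared fixed effects plus the
    observed phenotypes of its causal parents; residuals are independent
    across traits (diagonal ``Ψ0``), and ``G0*`` is modelled with ``k``
    latent genetic factors under the same variance floor as the multi-trait
    model.  ``psi_floor`` keeps the residual variances positive without
    constraining them away from the very small values a strong causal chain
    produces.
    """
    traits = structure.traits
    t = len(traits)
    Y = phenotypes[list(traits)].to_numpy(dtype=float)
    n = Y.shape[0]
    if iterations <= burn_in:
        raise ValueError("need at least one post-burn-in iteration")
    for parent, child in structure.edges:
        if np.std(Y[:, traits.index(parent)]) == 0:
            raise ValueError(f"parent trait {parent!r} has zero variance")

    Q, d = _prepare_rotation(A)
    ytil = Q.T @ Y
    xtil = Q.T @ np.asarray(X, dtype=float)
    p_base = xtil.shape[1]

    designs, lam_cols = [], []
    for i, tr in enumerate(traits):
        parents = structure.parents_of(tr)
        cols = [ytil[:, traits.index(p)] for p in parents]
        designs.append(np.column_stack([xtil] + cols) if cols else xtil)
        lam_cols.append({p: p_base + c for c, p in enumerate(parents)})

    seeds = np.random.SeedSequence(seed).spawn(chains)
    lam_list, psi_list, g0_list = [], [], []
    dev_list, chain_ids, iters = [], [], []
    fitted_sum = np.zeros((n, t))
    psi_sum = np.zeros(t)
    m_total = 0
    for c, ss in enumerate(seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        res = _factor_gibbs_chain(
            ytil,
            designs,
            d,
            k=k,
            floor_u=variance_floor,
            floor_e=np.full(t, psi_floor),
            n_resid_factors=0,
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            rng=rng,
        )
        m = res["m"]
        lam = np.empty((m, structure.n_free))
        for e, (parent, child) in enumerate(structure.edges):
            i = traits.index(child)
            lam[:, e] = res["beta"][i][:, lam_cols[i][parent]]
        g0 = np.einsum("mki,mkj->mij", res["s"], res["s"])
        g0[:, np.arange(t), np.arange(t)] += res["tau_u"]
        lam_list.append(lam)
        psi_list.append(res["tau_e"])
        g0_list.append(g0)
        dev_list.append(res["deviance"])
        chain_ids.append(np.full(m, c))
        iters.append(res["iteration"])
        fitted_sum += res["fitted_sum"]
        psi_sum += res["tau_e_sum"]
        m_total += m

    dev_at_mean = _deviance_at(ytil, fitted_sum / m_total, psi_sum / m_total)
    return SEMPosterior(
        structure=structure,
        lambda_samples=np.concatenate(lam_list),
        psi=np.concatenate(psi_list),
        g0_star=np.concatenate(g0_list),
        deviance=np.concatenate(dev_list),
        deviance_at_mean=dev_at_mean,
        chain=np.concatenate(chain_ids),
        iteration=np.concatenate(iters),
        n_records=n,
    )


def reduced_form_covariances(
    lam: np.ndarray, g0_star: np.ndarray, psi0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map SEM parameters to multi-trait (reduced-form) covariances.

    ``G0 = (I-Λ)⁻¹ G0* (I-Λ)⁻ᵀ`` and ``R0 = (I-Λ)⁻¹ Ψ0 (I-Λ)⁻ᵀ``; for an
    acyclic pattern ``I - Λ`` is always invertible, so a singular matrix
    here flags numerical misuse.
    """
    lam = np.asarray(lam, dtype=float)
    t = lam.shape[0]
    psi = np.asarray(psi0, dtype=float)
    if psi.ndim == 1:
        psi = np.diag(psi)
    ident = np.eye(t)
    if abs(np.linalg.det(ident - lam)) < 1e-12:
        raise ValueError("I - Lambda is singular")
    m = np.linalg.inv(ident - lam)
    g0 = m @ np.asarray(g0_star, dtype=float) @ m.T
    r0 = m @ psi @ m.T
    return (g0 + g0.T) / 2, (r0 + r0.T) / 2


def compute_dic(
    deviance: np.ndarray, deviance_at_mean: float
) -> tuple[float, float]:
    """Deviance information criterion and effective number of parameters.

    ``pD = mean(D) − D(θ̄)`` and ``DIC = mean(D) + pD``, over the post-
    burn-in conditional deviance trace.
    """
    dev = np.asarray(deviance, dtype=float).ravel()
    bad = int(np.sum(~np.isfinite(dev)))
    if bad:
        raise ValueError(f"{bad} non-finite deviance draws")
    if dev.size < 30:
        raise ValueError(f"need at least 30 deviance evaluations, got {dev.size}")
    mean_dev = float(dev.mean())
    p_d = mean_dev - float(deviance_at_mean)
    return mean_dev + p_d, p_d


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Side-by-side variance components and DIC of two fitted models."""

    table: pd.DataFrame
    dic_a: float
    pd_a: float
    dic_b: float
    pd_b: float

    @property
    def delta_dic(self) -> float:
        """DIC(second model) − DIC(first model); negative favours the second."""
        return self.dic_b - self.dic_a

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _component_stats(fit: MCMCResult | SEMPosterior) -> dict[str, tuple[float, float]]:
    """Posterior mean and SD of σ²_e, σ²_g, r_e, r_g for either model."""
    out: dict[str, tuple[float, float]] = {}
    if isinstance(fit, MCMCResult):
        traits = fit.spec.traits
        r0, g0 = fit.samples.r0, fit.samples.g0
        resid_var = np.diagonal(r0, axis1=1, axis2=2)
        resid_corr = _corr_draws(r0)
    else:
        traits = fit.traits
        g0 = fit.g0_star
        resid_var = fit.psi
        resid_corr = None  # structurally zero residual correlations
    t = len(traits)
    gen_var = np.diagonal(g0, axis1=1, axis2=2)
    gen_corr = _corr_draws(g0)

    def put(name, draws):
        out[name] = (float(np.mean(draws)), float(np.std(draws, ddof=1)))

    for i, tr in enumerate(traits):
        put(f"sigma2_e {tr}", resid_var[:, i])
    for i in range(t):
        for j in range(i + 1, t):
            name = f"r_e {traits[i]},{traits[j]}"
            if resid_corr is None:
                out[name] = (np.nan, np.nan)
            else:
                put(name, resid_corr[:, i, j])
    for i, tr in enumerate(traits):
        put(f"sigma2_g {tr}", gen_var[:, i])
    for i in range(t):
        for j in range(i + 1, t):
            put(f"r_g {traits[i]},{traits[j]}", gen_corr[:, i, j])
    return out


def _corr_draws(mats: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diagonal(mats, axis1=1, axis2=2))
    return mats / (sd[:, :, None] * sd[:, None, :])


def _traits_of(fit) -> tuple[str, ...]:
    return fit.spec.traits if isinstance(fit, MCMCResult) else fit.traits


def compare_models(
    fit_a: MCMCResult | SEMPosterior, fit_b: MCMCResult | SEMPosterior
) -> ModelComparison:
    """Compare two fits of the same traits on the same standardized data.

    The table holds posterior means and SDs of every residual/genetic
    variance and correlation for both models (``2t + t(t-1)`` rows);
    ``delta_dic`` is ``DIC(b) − DIC(a)``.  Residual correlations of a SEM
    are structurally zero and reported as missing.
    """
    ta, tb = _traits_of(fit_a), _traits_of(fit_b)
    if ta != tb:
        raise ValueError(f"trait sets differ: {ta} vs {tb}")
    stats_a = _component_stats(fit_a)
    stats_b = _component_stats(fit_b)
    rows = [
        (name, *stats_a[name], *stats_b[name])
        for name in stats_a
    ]
    table = pd.DataFrame(
        rows, columns=["component", "mean_a", "sd_a", "mean_b", "sd_b"]
    )
    dic_a, pd_a = compute_dic(fit_a.deviance, fit_a.deviance_at_mean)
    dic_b, pd_b = compute_dic(fit_b.deviance, fit_b.deviance_at_mean)
    return ModelComparison(table=table, dic_a=dic_a, pd_a=pd_a, dic_b=dic_b, pd_b=pd_b)
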