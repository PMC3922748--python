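"""Shared fixtures: simulated study data and fitted models.

The heavier fixtures are session-scoped so that several tests can share one
simulation and one pair of model fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from milknet.mixed_model import (
    MCMCResult,
    ModelSpec,
    build_design_matrices,
    run_mcmc,
    standardize_phenotypes,
)
from milknet.relationships import build_numerator_relationship_matrix
from milknet.sem import LambdaStructure, SEMPosterior, fit_sem
from milknet.synthetic_data import (
    SimulationTruth,
    StudyDesign,
    default_truth,
    simulate_phenotypes_from_sem,
    simulate_population,
)


@dataclass
class CovarianceDraws:
    """Minimal stand-in for posterior covariance samples (synthetic).

    Wraps a stack of residual-covariance draws so network-search code can be
    exercised in isolation from the mixed-model sampler.
    """

    traits: tuple[str, ...]
    r0: np.ndarray


def conjugate_covariance_posterior(
    data: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-Wishart posterior draws of a covariance under a Jeffreys prior.

    For centred Gaussian rows ``data`` (n × t) the posterior of the
    covariance is InvWishart(n, SS); used as an independent, conjugate
    source of posterior covariance samples for isolation tests.
    """
    n = data.shape[0]
    ss = data.T @ data
    return stats.invwishart.rvs(df=n, scale=ss, size=n_draws, random_state=rng)


def simulate_dag_residuals(
    lam: np.ndarray, psi: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n rows from the reduced form y = (I-Λ)⁻¹ e, e ~ N(0, diag(psi))."""
    t = lam.shape[0]
    e = rng.standard_normal((n, t)) * np.sqrt(psi)
    return np.linalg.solve(np.eye(t) - lam, e.T).T


@dataclass
class ChainStudy:
    """A simulated five-trait causal-chain study plus fitted models."""

    truth: SimulationTruth
    phenotypes: pd.DataFrame
    standardized: pd.DataFrame
    scale: pd.DataFrame
    X: np.ndarray
    A_obs: pd.DataFrame
    mtm: MCMCResult
    sem: SEMPosterior
    structure: LambdaStructure

    def expected_lambda_std(self) -> dict[tuple[str, str], float]:
        """Generating structural coefficients on the standardized scale.

        Standardizing each trait by its sample SD rescales a coefficient by
        SD(parent)/SD(child) on the latent scale (sample SD divided by the
        configured output SD); exact algebra, no tolerance involved.
        """
        sd_lat = self.scale["sd"].to_numpy() / self.truth.trait_sds
        traits = self.truth.traits
        out = {}
        for parent, child in self.structure.edges:
            i, j = traits.index(child), traits.index(parent)
            out[(parent, child)] = self.truth.lambda_true[i, j] * sd_lat[j] / sd_lat[i]
        return out


@pytest.fixture(scope="session")
def chain_study() -> ChainStudy:
    """Simulate the default causal-chain study and fit both models.

    Sizes (1200 cows, 12 herds, 3 generations; 2 chains × 4000 iterations,
    burn-in 1000, thinning 5) keep the whole fixture under a minute while
    leaving posteriors tight enough for 3-SD recovery checks.
    """
    truth = default_truth()
    design = StudyDesign(n_cows=1200, n_herds=12, n_generations=3)
    rng = np.random.default_rng(5)
    ped, cov = simulate_population(design, rng)
    phenotypes = simulate_phenotypes_from_sem(truth, ped, cov, rng)
    std, scale = standardize_phenotypes(phenotypes, truth.traits)
    X, _ = build_design_matrices(phenotypes)
    A = build_numerator_relationship_matrix(ped)
    animals = phenotypes["animal"].tolist()
    A_obs = A.loc[animals, animals]

    mcmc = dict(chains=2, iterations=4000, burn_in=1000, thin=5)
    spec = ModelSpec(traits=truth.traits, k=2)
    mtm = run_mcmc(std, X, A_obs, spec, seed=10, **mcmc)
    structure = LambdaStructure.from_chain(truth.traits)
    sem = fit_sem(std, X, A_obs, structure, k=2, seed=9, **mcmc)
    return ChainStudy(
        truth=truth,
        phenotypes=phenotypes,
        standardized=std,
        scale=scale,
        X=X,
        A_obs=A_obs,
        mtm=mtm,
        sem=sem,
        structure=structure,
    )
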