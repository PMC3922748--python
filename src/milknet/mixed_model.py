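"""Bayesian multi-trait animal model with latent-factor covariance structures.

The model for standardized phenotypes ``y`` (n animals × t traits) is

.. math::

    y = X\\beta + Zu + e, \\qquad
    \\begin{pmatrix} u \\\\ e \\end{pmatrix}
    \\sim N\\left(0, \\begin{pmatrix} G_0 \\otimes A & 0 \\\\
                                      0 & R_0 \\otimes I \\end{pmatrix}\\right),

with both covariance matrices given a latent-factor structure: trait ``i``'s
residual is ``e_i = Σ_k r_{k,i} v_k + ε_i`` with ``v_k ~ N(0, I)`` and
``ε_i ~ N(0, τ²_{e,i} I)``, and the genetic effect is
``u_i = Σ_k s_{k,i} w_k + δ_i`` with ``w_k ~ N(0, A)`` and
``δ_i ~ N(0, τ²_{u,i} A)``.  Hence the reconstructed covariances are

.. math::

    R_0[i,j] = \\sum_k r_{k,i} r_{k,j} + \\delta_{ij} τ^2_{e,i}, \\qquad
    G_0[i,j] = \\sum_k s_{k,i} s_{k,j} + \\delta_{ij} τ^2_{u,i}.

Loadings get flat priors; the remaining variances get uniform priors on
``[floor, ∞)`` (default floor 0.02 on standardized traits, i.e. at least 2%
of each trait's residual and genetic variance is trait-specific), which
keeps the sampler mixing when traits are very highly correlated.

All conditionals are conjugate (normals for location parameters and
loadings, scaled inverse chi-square for variances), so the sampler is a
pure Gibbs scheme.  Computationally the model is rotated into the
eigenbasis of ``A`` (``A = Q D Qᵀ``); in those coordinates every latent
vector has an independent-component prior and all updates vectorise, which
is what makes desk-scale chains cheap.  Only the reconstructed covariance
matrices are identified (loadings are sign/rotation invariant) and only
those are monitored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import gammainc, gammaincinv

__all__ = [
    "ModelSpec",
    "DesignInfo",
    "PosteriorCovarianceSamples",
    "MCMCResult",
    "standardize_phenotypes",
    "build_design_matrices",
    "latent_covariance_parameters",
    "full_covariance_parameters",
    "choose_num_factors",
    "reconstruct_covariance",
    "run_mcmc",
    "effective_sample_size",
]


# ---------------------------------------------------------------------------
# specification & small operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Specification of the multi-trait latent-factor model.

    Parameters
    ----------
    traits:
        Ordered trait names.
    k:
        Number of latent factors per covariance structure (``1 <= k < t``).
    variance_floor:
        Lower bound of the uniform prior on the remaining variances.
    wilmink_exponent:
        Rate of the exponential lactation-curve covariate
        ``exp(-wilmink_exponent * DIM)``.
    """

    traits: tuple[str, ...]
    k: int
    variance_floor: float = 0.02
    wilmink_exponent: float = 0.05

    def __post_init__(self) -> None:
        t = len(self.traits)
        if not 1 <= self.k < t:
            raise ValueError(f"k must satisfy 1 <= k < t, got k={self.k}, t={t}")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


def latent_covariance_parameters(t: int, k: int) -> int:
    """Parameters of one latent-factor covariance structure: (k+1)·t.

    ``k`` loadings plus one remaining variance per trait.  Compare with
    :func:`full_covariance_parameters` to see when the factor model
    restricts the covariance (fewer parameters) or matches its parameter
    count exactly.
    """
    return (k + 1) * t


def full_covariance_parameters(t: int) -> int:
    """Free parameters of an unstructured t×t covariance: t(t+1)/2."""
    return t * (t + 1) // 2


def standardize_phenotypes(
    phenotypes: pd.DataFrame, traits: list[str] | tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center and scale each trait to mean 0 and (sample) SD 1.

    Returns the table with trait columns replaced by their standardized
    values, plus a ``(trait, mean, sd)`` scale frame for back-transforming.

    Raises
    ------
    ValueError
        If a trait has zero variance (named in the message).
    """
    out = phenotypes.copy()
    rows = []
    for tr in traits:
        x = phenotypes[tr].to_numpy(dtype=float)
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"trait {tr!r} has zero variance; cannot standardize")
        out[tr] = (x - mu) / sd
        rows.append((tr, mu, sd))
    scale = pd.DataFrame(rows, columns=["trait", "mean", "sd"]).set_index("trait")
    return out, scale


@dataclass(frozen=True)
class DesignInfo:
    """Frozen coding of the fixed-effect design (levels seen at build time)."""

    season_levels: tuple[str, ...]
    sire_code_levels: tuple[str, ...]
    herd_levels: tuple[str, ...]
    wilmink_exponent: float
    column_names: tuple[str, ...]


def build_design_matrices(
    covariates: pd.DataFrame,
    wilmink_exponent: float = 0.05,
    info: DesignInfo | None = None,
) -> tuple[np.ndarray, DesignInfo]:
    """Build the fixed-effect design matrix shared by all traits.

    Columns: intercept; days in milk and ``exp(-c·DIM)`` (the Wilmink
    lactation-curve pair); age at first calving and its square; season,
    sire-code and herd dummies (reference-coded on the first sorted level).

    Passing a previously returned ``info`` re-applies the same coding;
    categories unseen at build time then raise.

    Raises
    ------
    ValueError
        On unseen categories (with ``info``) or a rank-deficient design
        (naming the collinear columns).
    """
    def levels(col: str) -> tuple[str, ...]:
        if info is not None:
            known = getattr(info, f"{col}_levels")
            unseen = set(covariates[col].astype(str)) - set(known)
            if unseen:
                raise ValueError(f"unseen {col} categories: {sorted(unseen)}")
            return known
        return tuple(sorted(covariates[col].astype(str).unique()))

    season_levels = levels("season")
    sire_levels = levels("sire_code")
    herd_levels = levels("herd")
    if info is not None:
        wilmink_exponent = info.wilmink_exponent

    herd_counts = covariates["herd"].value_counts()
    small = herd_counts[herd_counts < 2]
    if len(small):
        warnings.warn(
            f"{len(small)} herd(s) have fewer than 2 phenotyped cows", stacklevel=2
        )

    dim = covariates["dim"].to_numpy(dtype=float)
    afc = covariates["afc"].to_numpy(dtype=float)
    cols: list[np.ndarray] = [
        np.ones_like(dim),
        dim,
        np.exp(-wilmink_exponent * dim),
        afc,
        afc**2,
    ]
    names = ["intercept", "dim", "wilmink_exp", "afc", "afc2"]

    def dummies(col: str, lv: tuple[str, ...]) -> None:
        x = covariates[col].astype(str).to_numpy()
        for level in lv[1:]:
            cols.append((x == level).astype(float))
            names.append(f"{col}[{level}]")

    dummies("season", season_levels)
    dummies("sire_code", sire_levels)
    dummies("herd", herd_levels)

    X = np.column_stack(cols)
    # rank check via pivoted QR diagonal
    _, R, piv = _qr_pivot(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    bad += [names[p] for p in piv[len(diag):]]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    built = DesignInfo(
        season_levels=season_levels,
        sire_code_levels=sire_levels,
        herd_levels=herd_levels,
        wilmink_exponent=wilmink_exponent,
        column_names=tuple(names),
    )
    return X, built


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def choose_num_factors(
    phenotypes: pd.DataFrame | np.ndarray,
    threshold: float = 0.90,
    traits: list[str] | None = None,
) -> int:
    """Pick the latent-factor dimension by PCA of the trait correlations.

    Returns the smallest ``k`` such that the top-``k`` eigenvalues of the
    trait correlation matrix explain at least ``threshold`` of the total
    variance.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if isinstance(phenotypes, pd.DataFrame):
        data = phenotypes[traits] if traits else phenotypes
        data = data.to_numpy(dtype=float)
    else:
        data = np.asarray(phenotypes, dtype=float)
    if data.shape[1] < 2:
        raise ValueError("need at least two traits")
    corr = np.corrcoef(data, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    frac = np.cumsum(evals) / evals.sum()
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def reconstruct_covariance(loadings: np.ndarray, remaining: np.ndarray) -> np.ndarray:
    """Covariance implied by factor loadings plus trait-specific variances.

    ``Σ[i,j] = Σ_k load[k,i]·load[k,j] + δ_ij·remaining[i]`` — positive
    definite whenever all remaining variances are positive.
    """
    load = np.atleast_2d(np.asarray(loadings, dtype=float))
    rem = np.asarray(remaining, dtype=float).ravel()
    if np.any(rem <= 0):
        raise ValueError("remaining variances must be strictly positive")
    if load.shape[1] != rem.size:
        raise ValueError("loadings and remaining variances disagree on trait count")
    return load.T @ load + np.diag(rem)


# ---------------------------------------------------------------------------
# posterior containers
# ---------------------------------------------------------------------------

@dataclass
class PosteriorCovarianceSamples:
    """Thinned post-burn-in draws of the genetic and residual covariances."""

    traits: tuple[str, ...]
    g0: np.ndarray  # (m, t, t)
    r0: np.ndarray  # (m, t, t)
    chain: np.ndarray  # (m,)
    iteration: np.ndarray  # (m,)

    def __len__(self) -> int:
        return self.g0.shape[0]

    def validate(self, floor: float = 0.0) -> None:
        """Assert every draw is symmetric PD with diagonal >= floor."""
        for name, mats in (("G0", self.g0), ("R0", self.r0)):
            if not np.allclose(mats, np.swapaxes(mats, 1, 2)):
                raise AssertionError(f"{name} samples not symmetric")
            if np.any(np.diagonal(mats, axis1=1, axis2=2) < floor - 1e-12):
                raise AssertionError(f"{name} diagonal below floor")
            np.linalg.cholesky(mats)  # raises if any draw is not PD

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorCovarianceSamples":
        """Rebuild samples from the flat (chain, iter, param, value) layout."""
        params = df["param"].str.extract(r"^(G0|R0)\[(.+),(.+)\]$")
        traits = tuple(dict.fromkeys(params[1]))
        tidx = {tr: i for i, tr in enumerate(traits)}
        t = len(traits)
        keys = df[["chain", "iter"]].drop_duplicates().to_numpy()
        kidx = {(c, i): m for m, (c, i) in enumerate(map(tuple, keys))}
        g0 = np.zeros((len(kidx), t, t))
        r0 = np.zeros((len(kidx), t, t))
        for (c, it, val), (tag, a, b) in zip(
            df[["chain", "iter", "value"]].itertuples(index=False),
            params.itertuples(index=False),
        ):
            m, i, j = kidx[(c, it)], tidx[a], tidx[b]
            target = g0 if tag == "G0" else r0
            target[m, i, j] = target[m, j, i] = val
        return cls(
            traits=traits,
            g0=g0,
            r0=r0,
            chain=keys[:, 0],
            iteration=keys[:, 1],
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat (chain, iter, param, value) layout for CSV export."""
        t = len(self.traits)
        rows = []
        iu = [(i, j) for i in range(t) for j in range(i, t)]
        for m in range(len(self)):
            for mat, tag in ((self.g0[m], "G0"), (self.r0[m], "R0")):
                for i, j in iu:
                    rows.append(
                        (
                            int(self.chain[m]),
                            int(self.iteration[m]),
                            f"{tag}[{self.traits[i]},{self.traits[j]}]",
                            mat[i, j],
                        )
                    )
        return pd.DataFrame(rows, columns=["chain", "iter", "param", "value"])


@dataclass
class MCMCResult:
    """Everything the downstream stages need from a multi-trait fit."""

    spec: ModelSpec
    samples: PosteriorCovarianceSamples
    deviance: np.ndarray  # (m,) conditional deviance trace
    deviance_at_mean: float
    beta_mean: np.ndarray  # (p,) posterior mean fixed effects per trait (p, t)
    log_posterior: np.ndarray  # (m,) up to a constant; per-sample diagnostics
    n_records: int


# ---------------------------------------------------------------------------
# Gibbs engine (shared with the SEM module)
# ---------------------------------------------------------------------------

def _sample_truncated_variance(
    ss: np.ndarray, n: int, floor: np.ndarray | float, rng: np.random.Generator
) -> np.ndarray:
    """Draw variances from p(τ²) ∝ (τ²)^(-n/2) exp(-ss/2τ²) on [floor, ∞).

    This is the conditional scaled inverse chi-square under a flat prior on
    the variance, truncated below; sampled by inverse CDF of the precision
    (a truncated gamma), never by clamping.
    """
    a = n / 2.0 - 1.0
    b = np.maximum(np.asarray(ss, dtype=float) / 2.0, 1e-300)
    floor = np.broadcast_to(np.asarray(floor, dtype=float), b.shape)
    cdf_max = gammainc(a, b / floor)  # P(precision <= 1/floor)
    u = rng.uniform(size=b.shape) * cdf_max
    with np.errstate(divide="ignore"):
        prec = gammaincinv(a, u) / b
    out = np.where(prec > 0, 1.0 / np.maximum(prec, 1e-300), np.inf)
    # numerically degenerate posteriors (cdf_max ~ 0) sit at the floor
    return np.where((cdf_max < 1e-12) | ~np.isfinite(out), floor, out)


def _factor_gibbs_chain(
    ytil: np.ndarray,
    designs: list[np.ndarray],
    d_eig: np.ndarray,
    k: int,
    floor_u: float,
    floor_e: np.ndarray,
    n_resid_factors: int,
    iterations: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
) -> dict:
    """One Gibbs chain in the eigenbasis of A.

    ``ytil = Qᵀy`` and ``designs[i] = QᵀX_i`` are pre-rotated; ``d_eig``
    holds the eigenvalues of A.  ``n_resid_factors`` is the number of
    residual latent vectors (0 turns the residual structure diagonal, which
    is how the SEM module reuses this engine).
    """
    n, t = ytil.shape
    ke, ku = n_resid_factors, k
    chols = []
    for i, X in enumerate(designs):
        xtx = X.T @ X
        try:
            chols.append(np.linalg.cholesky(xtx))
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"singular fixed-effect crossproduct for trait index {i}; "
                "a covariate (or parent trait) may be constant"
            ) from err

    beta = [
        cho_solve((L, True), X.T @ ytil[:, i])
        for i, (X, L) in enumerate(zip(designs, chols))
    ]
    V = np.zeros((n, ke))
    r = 0.1 * rng.standard_normal((ke, t))
    W = np.zeros((n, ku))
    s = 0.1 * rng.standard_normal((ku, t))
    Delta = np.zeros((n, t))
    tau_e = np.maximum(0.5, np.asarray(floor_e, dtype=float) * np.ones(t))
    tau_u = np.maximum(0.5, floor_u) * np.ones(t)

    E = ytil - V @ r - W @ s - Delta
    for i, X in enumerate(designs):
        E[:, i] -= X @ beta[i]

    m_keep = len(range(burn_in, iterations, thin))
    store = {
        "r": np.empty((m_keep, ke, t)),
        "s": np.empty((m_keep, ku, t)),
        "tau_e": np.empty((m_keep, t)),
        "tau_u": np.empty((m_keep, t)),
        "beta": [np.empty((m_keep, X.shape[1])) for X in designs],
        "deviance": np.empty(m_keep),
        "deviance_conditional": np.empty(m_keep),
        "log_posterior": np.empty(m_keep),
        "iteration": np.empty(m_keep, dtype=int),
    }
    fitted_sum = np.zeros((n, t))  # fixed + genetic fit (residual factors out)
    fitted_cond_sum = np.zeros((n, t))  # including residual latent vectors
    r0_sum = np.zeros((t, t))
    tau_e_sum = np.zeros(t)
    kept = 0
    inv_d = 1.0 / d_eig
    log2pi = np.log(2 * np.pi)

    for it in range(iterations):
        # --- fixed effects (and, for the SEM, structural coefficients)
        for i, (X, L) in enumerate(zip(designs, chols)):
            p = E[:, i] + X @ beta[i]
            bhat = cho_solve((L, True), X.T @ p)
            z = rng.standard_normal(X.shape[1])
            beta[i] = bhat + np.sqrt(tau_e[i]) * solve_triangular(
                L.T, z, lower=False
            )
            E[:, i] = p - X @ beta[i]

        inv_tau_e = 1.0 / tau_e
        # --- residual latent vectors and their loadings
        for kk in range(ke):
            p = E + np.outer(V[:, kk], r[kk])
            prec = 1.0 + float(np.sum(r[kk] ** 2 * inv_tau_e))
            mean = (p @ (r[kk] * inv_tau_e)) / prec
            V[:, kk] = mean + rng.standard_normal(n) / np.sqrt(prec)
            denom = float(V[:, kk] @ V[:, kk])
            rhat = (V[:, kk] @ p) / denom
            r[kk] = rhat + rng.standard_normal(t) * np.sqrt(tau_e / denom)
            E = p - np.outer(V[:, kk], r[kk])

        # --- genetic latent vectors (A-correlated prior) and loadings
        for kk in range(ku):
            p = E + np.outer(W[:, kk], s[kk])
            prec = inv_d + float(np.sum(s[kk] ** 2 * inv_tau_e))
            mean = (p @ (s[kk] * inv_tau_e)) / prec
            W[:, kk] = mean + rng.standard_normal(n) / np.sqrt(prec)
            denom = float(W[:, kk] @ W[:, kk])
            shat = (W[:, kk] @ p) / denom
            s[kk] = shat + rng.standard_normal(t) * np.sqrt(tau_e / denom)
            E = p - np.outer(W[:, kk], s[kk])

        # --- remaining per-trait genetic effects
        p = E + Delta
        prec = inv_d[:, None] / tau_u[None, :] + inv_tau_e[None, :]
        mean = (p * inv_tau_e[None, :]) / prec
        Delta = mean + rng.standard_normal((n, t)) / np.sqrt(prec)
        E = p - Delta

        # --- variances (truncated scaled inverse chi-square)
        ss_e = np.sum(E**2, axis=0)
        tau_e = _sample_truncated_variance(ss_e, n, floor_e, rng)
        ss_u = np.sum(Delta**2 * inv_d[:, None], axis=0)
        tau_u = _sample_truncated_variance(ss_u, n, floor_u, rng)

        if it >= burn_in and (it - burn_in) % thin == 0:
            store["r"][kept] = r
            store["s"][kept] = s
            store["tau_e"][kept] = tau_e
            store["tau_u"][kept] = tau_u
            for i in range(t):
                store["beta"][i][kept] = beta[i]
            # deviance, marginal over the residual covariance structure:
            # residual of the fixed+genetic fit has covariance R0 per record
            resid = E + V @ r if ke else E
            r0_cur = r.T @ r + np.diag(tau_e)
            _, logdet = np.linalg.slogdet(r0_cur)
            dev_marg = n * (t * log2pi + logdet) + float(
                np.trace(np.linalg.solve(r0_cur, resid.T @ resid))
            )
            store["deviance"][kept] = dev_marg
            dev_cond = float(np.sum(n * np.log(2 * np.pi * tau_e) + ss_e / tau_e))
            store["deviance_conditional"][kept] = dev_cond
            # log posterior kernel: conditional loglik + latent/remaining priors
            lp = -0.5 * dev_cond
            lp -= 0.5 * float(np.sum(V**2))
            lp -= 0.5 * float(np.sum(W**2 * inv_d[:, None]) + ku * np.sum(np.log(d_eig)))
            lp -= 0.5 * float(
                np.sum(Delta**2 * inv_d[:, None], axis=0) @ (1.0 / tau_u)
                + n * np.sum(np.log(tau_u))
                + np.sum(np.log(d_eig)) * t
            )
            store["log_posterior"][kept] = lp
            store["iteration"][kept] = it
            fitted_sum += ytil - resid
            fitted_cond_sum += ytil - E
            r0_sum += r0_cur
            tau_e_sum += tau_e
            kept += 1

    store["fitted_sum"] = fitted_sum
    store["fitted_cond_sum"] = fitted_cond_sum
    store["r0_sum"] = r0_sum
    store["tau_e_sum"] = tau_e_sum
    store["m"] = kept
    return store


def _prepare_rotation(A: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    Amat = A.to_numpy() if isinstance(A, pd.DataFrame) else np.asarray(A, dtype=float)
    d, Q = np.linalg.eigh((Amat + Amat.T) / 2)
    if d.min() <= 1e-10:
        raise ValueError("relationship matrix is not positive definite")
    return Q, d


def _deviance_at(ytil: np.ndarray, fitted: np.ndarray, r0: np.ndarray) -> float:
    """-2 log N(y | fitted, R0 ⊗ I); ``r0`` may be a full matrix or a diagonal."""
    n, t = ytil.shape
    resid = ytil - fitted
    r0 = np.asarray(r0, dtype=float)
    if r0.ndim == 1:
        r0 = np.diag(r0)
    _, logdet = np.linalg.slogdet(r0)
    return float(
        n * (t * np.log(2 * np.pi) + logdet)
        + np.trace(np.linalg.solve(r0, resid.T @ resid))
    )


def run_mcmc(
    phenotypes: pd.DataFrame | np.ndarray,
    X: np.ndarray,
    A: np.ndarray | pd.DataFrame,
    spec: ModelSpec,
    chains: int = 4,
    iterations: int = 20_000,
    burn_in: int = 5_000,
    thin: int = 10,
    seed: int = 0,
    deviance_focus: str = "marginal",
) -> MCMCResult:
    """Fit the multi-trait latent-factor animal model by Gibbs sampling.

    Parameters
    ----------
    phenotypes:
        Standardized trait values, one row per phenotyped animal (columns
        ordered as ``spec.traits`` when a DataFrame is passed).
    X:
        Fixed-effect design matrix (shared across traits).
    A:
        Numerator relationship matrix restricted to (and aligned with) the
        phenotyped animals; must be positive definite.
    chains, iterations, burn_in, thin:
        ``iterations`` counts total iterations per chain including burn-in;
        thinned post-burn-in samples are retained.
    seed:
        Chains receive independent streams spawned from this seed, so runs
        are reproducible and chains independent.
    deviance_focus:
        ``"marginal"`` (default) evaluates the deviance conditional on fixed
        and genetic effects but marginal over the residual covariance
        structure (residual covariance ``R0`` per record), which is the
        focus under which DIC compares covariance models; ``"conditional"``
        additionally conditions on the residual latent vectors.

    Returns
    -------
    MCMCResult
        With :class:`PosteriorCovarianceSamples` of (G0, R0) and a
        conditional deviance trace (see :func:`milknet.sem.compute_dic`).
    """
    Y = (
        phenotypes[list(spec.traits)].to_numpy(dtype=float)
        if isinstance(phenotypes, pd.DataFrame)
        else np.asarray(phenotypes, dtype=float)
    )
    n, t = Y.shape
    if t != len(spec.traits):
        raise ValueError("phenotype columns disagree with spec.traits")
    if iterations <= burn_in:
        raise ValueError("need at least one post-burn-in iteration")
    if X.shape[0] != n or (hasattr(A, "shape") and A.shape[0] != n):
        raise ValueError("phenotypes, X and A must agree on the number of records")

    Q, d = _prepare_rotation(A)
    ytil = Q.T @ Y
    xtil = Q.T @ np.asarray(X, dtype=float)
    floor = spec.variance_floor

    if deviance_focus not in ("marginal", "conditional"):
        raise ValueError(f"unknown deviance focus {deviance_focus!r}")
    seeds = np.random.SeedSequence(seed).spawn(chains)
    g0_list, r0_list, chain_ids, iters = [], [], [], []
    dev_list, lp_list = [], []
    fitted_sum = np.zeros((n, t))
    r0_sum = np.zeros((t, t))
    tau_e_sum = np.zeros(t)
    beta_sum = None
    m_total = 0
    for c, ss in enumerate(seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        res = _factor_gibbs_chain(
            ytil,
            [xtil] * t,
            d,
            k=spec.k,
            floor_u=floor,
            floor_e=np.full(t, floor),
            n_resid_factors=spec.k,
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            rng=rng,
        )
        m = res["m"]
        g0 = np.einsum("mki,mkj->mij", res["s"], res["s"])
        g0[:, np.arange(t), np.arange(t)] += res["tau_u"]
        r0 = np.einsum("mki,mkj->mij", res["r"], res["r"])
        r0[:, np.arange(t), np.arange(t)] += res["tau_e"]
        g0_list.append(g0)
        r0_list.append(r0)
        chain_ids.append(np.full(m, c))
        iters.append(res["iteration"])
        dev_list.append(
            res["deviance"] if deviance_focus == "marginal" else res["deviance_conditional"]
        )
        lp_list.append(res["log_posterior"])
        fitted_sum += (
            res["fitted_sum"] if deviance_focus == "marginal" else res["fitted_cond_sum"]
        )
        r0_sum += res["r0_sum"]
        tau_e_sum += res["tau_e_sum"]
        bmean = np.column_stack([b.mean(axis=0) for b in res["beta"]])
        beta_sum = bmean * m if beta_sum is None else beta_sum + bmean * m
        m_total += m

    samples = PosteriorCovarianceSamples(
        traits=spec.traits,
        g0=np.concatenate(g0_list),
        r0=np.concatenate(r0_list),
        chain=np.concatenate(chain_ids),
        iteration=np.concatenate(iters),
    )
    dev_at_mean = _deviance_at(
        ytil,
        fitted_sum / m_total,
        r0_sum / m_total if deviance_focus == "marginal" else tau_e_sum / m_total,
    )
    return MCMCResult(
        spec=spec,
        samples=samples,
        deviance=np.concatenate(dev_list),
        deviance_at_mean=dev_at_mean,
        beta_mean=beta_sum / m_total,
        log_posterior=np.concatenate(lp_list),
        n_records=n,
    )


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def effective_sample_size(trace: np.ndarray | list) -> float:
    """Effective sample size via Geyer's initial positive sequence.

    ``ESS = N / (1 + 2 Σ ρ̂)`` per chain, with the autocorrelation sum
    truncated where consecutive pairs of autocorrelations stop being
    positive; multi-chain input (2-D, chains × draws) sums per-chain ESS.
    A constant chain carries no information and reports 0 with a warning.
    """
    arr = np.atleast_2d(np.asarray(trace, dtype=float))
    total = 0.0
    for x in arr:
        n = x.size
        if n < 10:
            raise ValueError("need at least 10 samples per chain")
        x = x - x.mean()
        var = float(x @ x) / n
        if var == 0:
            warnings.warn("constant chain: effective sample size is 0", stacklevel=2)
            continue
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(x, nfft)
        acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
        rho = acov / acov[0]
        # Geyer initial positive sequence on pair sums
        tau = -1.0
        mmax = n // 2
        for mpair in range(mmax):
            gamma = rho[2 * mpair] + (rho[2 * mpair + 1] if 2 * mpair + 1 < n else 0.0)
            if gamma <= 0:
                break
            tau += 2.0 * gamma
        tau = max(tau, 1.0)
        total += n / tau
    return float(total)
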