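"""Structural equation model: fitting, reduced form, DIC, comparison."""

import numpy as np
import pandas as pd
import pytest

from milknet.mixed_model import ModelSpec, run_mcmc
from milknet.sem import (
    LambdaStructure,
    compare_models,
    compute_dic,
    fit_sem,
    reduced_form_covariances,
)


class TestLambdaStructure:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            LambdaStructure(("a", "b"), (("a", "b"), ("b", "a")))

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError, match="unknown trait"):
            LambdaStructure(("a", "b"), (("a", "z"),))

    def test_chain_builder_and_matrix_layout(self):
        s = LambdaStructure.from_chain(("x", "y", "z"))
        assert s.edges == (("x", "y"), ("y", "z"))
        lam = s.lambda_matrix([0.5, 0.7])
        assert lam[1, 0] == 0.5 and lam[2, 1] == 0.7
        assert np.all(np.diag(lam) == 0)

    def test_tsv_round_trip(self, tmp_path):
        s = LambdaStructure.from_chain(("x", "y", "z"))
        path = tmp_path / "structure.tsv"
        s.to_tsv(path)
        assert LambdaStructure.from_tsv(path, ("x", "y", "z")) == s


class TestReducedForm:
    def test_zero_lambda_is_identity_transform(self):
        g0 = np.array([[1.0, 0.3], [0.3, 2.0]])
        psi = np.array([0.5, 0.7])
        g, r = reduced_form_covariances(np.zeros((2, 2)), g0, psi)
        assert np.allclose(g, g0) and np.allclose(r, np.diag(psi))

    def test_two_trait_unit_coefficient(self):
        lam = np.array([[0.0, 0.0], [1.0, 0.0]])
        _, r = reduced_form_covariances(lam, np.zeros((2, 2)), np.ones(2))
        assert np.allclose(r, [[1.0, 1.0], [1.0, 2.0]])

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_recovers_psi(self, seed):
        rng = np.random.default_rng(seed)
        t = int(rng.integers(2, 7))
        lam = np.tril(rng.normal(scale=0.8, size=(t, t)), k=-1)  # acyclic
        psi = rng.uniform(0.1, 2.0, size=t)
        g0 = np.zeros((t, t))
        _, r = reduced_form_covariances(lam, g0, psi)
        back = (np.eye(t) - lam) @ r @ (np.eye(t) - lam).T
        assert np.allclose(back, np.diag(psi), atol=1e-12)


class TestComputeDIC:
    def test_point_mass_posterior_has_zero_pd(self):
        dic, pd_ = compute_dic(np.full(50, 123.4), 123.4)
        assert pd_ == pytest.approx(0.0, abs=1e-9)
        assert dic == pytest.approx(123.4)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="at least 30"):
            compute_dic(np.ones(10), 1.0)

    def test_nonfinite_draws_rejected_with_count(self):
        dev = np.ones(40)
        dev[[3, 7]] = np.nan
        with pytest.raises(ValueError, match="2 non-finite"):
            compute_dic(dev, 1.0)

    def test_fixed_effects_model_pd_close_to_parameter_count(self):
        """Known-variance normal regression: pD equals the regressor count."""
        rng = np.random.default_rng(0)
        n, p, sigma2 = 4000, 12, 1.0
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        y = X @ rng.normal(size=p) + rng.normal(scale=np.sqrt(sigma2), size=n)
        xtx_inv = np.linalg.inv(X.T @ X)
        bhat = xtx_inv @ X.T @ y
        L = np.linalg.cholesky(sigma2 * xtx_inv)
        draws = bhat + (L @ rng.standard_normal((p, 3000))).T

        def deviance(beta):
            r = y - X @ beta
            return n * np.log(2 * np.pi * sigma2) + r @ r / sigma2

        trace = np.array([deviance(b) for b in draws])
        _, pd_ = compute_dic(trace, deviance(draws.mean(axis=0)))
        assert pd_ == pytest.approx(p, rel=0.15)


class TestFitSEM:
    def test_lambda_posterior_matches_marginalized_ensemble_oracle(self):
        """Dual-route posterior check on a two-trait instance.

        The Gibbs sampler (which augments with breeding values and latent
        vectors) must agree with an entirely independent route: the genetic
        effects are integrated out analytically in the eigenbasis of A and
        the 9 remaining parameters are sampled with an affine-invariant
        ensemble sampler under identical priors.  Tolerances are sized to
        the Monte Carlo error of the two finite chains.
        """
        emcee = pytest.importorskip("emcee")
        from milknet.relationships import build_numerator_relationship_matrix
        from milknet.synthetic_data import StudyDesign, simulate_population

        rng = np.random.default_rng(2)
        n, lam_true, sg2, psi_true = 500, 0.7, 0.3, 0.36
        ped, cov = simulate_population(
            StudyDesign(n_cows=n, n_herds=8, n_generations=3), seed=21
        )
        A = build_numerator_relationship_matrix(ped)
        animals = cov["animal"].tolist()
        Aobs = A.loc[animals, animals].to_numpy()
        La = np.linalg.cholesky(Aobs)
        u = La @ rng.standard_normal((n, 2)) * np.sqrt(sg2)
        y1 = rng.standard_normal(n) * 0.8 + u[:, 0]
        y2 = lam_true * y1 + u[:, 1] + rng.normal(scale=np.sqrt(psi_true), size=n)
        std = pd.DataFrame({"p": y1, "c": y2})
        floor, psi_floor = 0.02, 1e-6
        fit = fit_sem(
            std, np.ones((n, 1)), Aobs, LambdaStructure(("p", "c"), (("p", "c"),)),
            k=1, variance_floor=floor, psi_floor=psi_floor,
            chains=2, iterations=12000, burn_in=3000, thin=10, seed=4,
        )

        d, Q = np.linalg.eigh(Aobs)
        y1t, y2t, xt = Q.T @ y1, Q.T @ y2, Q.T @ np.ones(n)

        def logpost(th):
            b1, b2, lam, s1, s2, tu1, tu2, p1, p2 = th
            if tu1 < floor or tu2 < floor or p1 < psi_floor or p2 < psi_floor:
                return -np.inf
            g11, g12, g22 = s1 * s1 + tu1, s1 * s2, s2 * s2 + tu2
            c11 = g11 * d + p1
            c12 = lam * c11 + g12 * d
            c22 = lam * lam * c11 + 2 * lam * g12 * d + g22 * d + p2
            r1 = y1t - b1 * xt
            r2 = y2t - (lam * b1 + b2) * xt
            det = c11 * c22 - c12**2
            if np.any(det <= 0):
                return -np.inf
            quad = (c22 * r1 * r1 - 2 * c12 * r1 * r2 + c11 * r2 * r2) / det
            return -0.5 * np.sum(np.log(2 * np.pi * det) + quad)

        nwalkers, ndim = 48, 9
        rs = np.random.default_rng(7)
        start = np.array([0, 0, 0.6, 0.3, 0.3, 0.1, 0.1, 0.5, 0.5]) + (
            0.05 * rs.standard_normal((nwalkers, ndim))
        )
        start[:, 5:7] = np.abs(start[:, 5:7]) + floor
        start[:, 7:9] = np.abs(start[:, 7:9]) + 0.05
        sampler = emcee.EnsembleSampler(nwalkers, ndim, logpost)
        sampler.run_mcmc(start, 6000, progress=False)
        chain = sampler.get_chain(discard=3000, thin=10, flat=True)[:, 2]

        assert fit.lambda_mean()[("p", "c")] == pytest.approx(chain.mean(), abs=0.02)
        assert fit.lambda_sd()[("p", "c")] == pytest.approx(chain.std(), abs=0.015)

    def test_empty_structure_has_no_lambda_samples(self):
        rng = np.random.default_rng(3)
        std = pd.DataFrame(rng.standard_normal((60, 2)), columns=["a", "b"])
        fit = fit_sem(
            std, np.ones((60, 1)), np.eye(60),
            LambdaStructure(("a", "b"), ()),
            k=1, chains=1, iterations=100, burn_in=40, thin=2, seed=0,
        )
        assert fit.lambda_samples.shape[1] == 0
        assert fit.psi.shape[1] == 2

    def test_constant_parent_trait_rejected(self):
        std = pd.DataFrame({"p": np.zeros(40), "c": np.random.default_rng(0).standard_normal(40)})
        with pytest.raises(ValueError, match="zero variance"):
            fit_sem(
                std, np.ones((40, 1)), np.eye(40),
                LambdaStructure(("p", "c"), (("p", "c"),)),
                k=1, chains=1, iterations=60, burn_in=20,
            )

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        std = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
        kw = dict(k=1, chains=1, iterations=120, burn_in=40, thin=2, seed=8)
        s = LambdaStructure(("a", "b"), (("a", "b"),))
        f1 = fit_sem(std, np.ones((50, 1)), np.eye(50), s, **kw)
        f2 = fit_sem(std, np.ones((50, 1)), np.eye(50), s, **kw)
        assert np.array_equal(f1.lambda_samples, f2.lambda_samples)
        assert np.array_equal(f1.deviance, f2.deviance)


class TestRecoveryOnChainStudy:
    def test_lambda_recovered_within_3_posterior_sd(self, chain_study):
        expected = chain_study.expected_lambda_std()
        mean, sd = chain_study.sem.lambda_mean(), chain_study.sem.lambda_sd()
        for edge, lam_std in expected.items():
            z = (mean[edge] - lam_std) / sd[edge]
            assert abs(z) < 3, f"{edge}: z={z:.2f}"

    def test_structural_coefficients_in_reported_range(self, chain_study):
        """Back-transformed to the generating scale, the estimated chain
        coefficients sit in the 0.85–1.05 band of the de novo pathway."""
        truth = chain_study.truth
        sd_lat = chain_study.scale["sd"].to_numpy() / truth.trait_sds
        mean = chain_study.sem.lambda_mean()
        for parent, child in chain_study.structure.edges:
            i, j = truth.traits.index(child), truth.traits.index(parent)
            lam_native = mean[(parent, child)] * sd_lat[i] / sd_lat[j]
            # truth band 0.85-1.05 plus estimation error at this chain length
            assert 0.75 <= lam_native <= 1.15, (parent, child, lam_native)

    def test_mtm_posterior_matches_reduced_form_truth(self, chain_study):
        """Fitting the multi-trait model to SEM-generated data recovers the
        reduced-form covariances of the generating truth (3 SD per entry)."""
        truth = chain_study.truth
        sd_lat = chain_study.scale["sd"].to_numpy() / truth.trait_sds
        denom = np.outer(sd_lat, sd_lat)
        r0_expect = truth.reduced_residual_covariance() / denom
        g0_expect = truth.reduced_genetic_covariance() / denom
        samples = chain_study.mtm.samples
        z_r = (samples.r0.mean(0) - r0_expect) / samples.r0.std(0)
        z_g = (samples.g0.mean(0) - g0_expect) / samples.g0.std(0)
        # the floor keeps trait-specific residual variance >= 2%, which the
        # near-deterministic chain's tiny conditional variances violate, so
        # diagonal entries are compared with the floor allowance added
        assert np.abs(z_g).max() < 3.5
        off = ~np.eye(5, dtype=bool)
        assert np.abs(z_r[off]).max() < 3.5

    def test_sem_downstream_residual_variances_collapse(self, chain_study):
        """Conditioning on the causal parent removes most residual variance
        for downstream chain traits (multi-trait vs SEM pattern)."""
        cmp_ = compare_models(chain_study.mtm, chain_study.sem)
        tab = cmp_.table.set_index("component")
        for tr in chain_study.truth.traits[1:]:
            mtm_var = tab.loc[f"sigma2_e {tr}", "mean_a"]
            sem_var = tab.loc[f"sigma2_e {tr}", "mean_b"]
            assert sem_var < 0.25 * mtm_var

    def test_dic_prefers_sem_on_sem_generated_data(self, chain_study):
        cmp_ = compare_models(chain_study.mtm, chain_study.sem)
        assert cmp_.delta_dic < 0


class TestCompareModels:
    def test_self_comparison_has_zero_delta(self, chain_study):
        cmp_ = compare_models(chain_study.mtm, chain_study.mtm)
        assert cmp_.delta_dic == 0.0

    def test_report_row_count(self, chain_study):
        t = len(chain_study.truth.traits)
        cmp_ = compare_models(chain_study.mtm, chain_study.sem)
        assert len(cmp_.table) == 2 * t + 2 * (t * (t - 1) // 2)

    def test_mismatched_traits_rejected(self, chain_study):
        other = ModelSpec(traits=("x", "y"), k=1)
        rng = np.random.default_rng(0)
        fit = run_mcmc(
            rng.standard_normal((40, 2)), np.ones((40, 1)), np.eye(40), other,
            chains=1, iterations=100, burn_in=40, thin=2,
        )
        with pytest.raises(ValueError, match="trait sets differ"):
            compare_models(chain_study.mtm, fit)
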