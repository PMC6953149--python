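"""Density components: mean structure, CAR likelihood, shrinkage layer,
AR(1) effects and the conditional posterior-mean identity."""

import numpy as np
import pytest
from scipy import integrate, stats

from icarh import (
    LatentState,
    ModelSpec,
    ar1_logprior,
    beta_posterior_mean_oracle,
    expected_kappa,
    horseshoe_logprior,
    kappa_pdf,
    log_joint,
    loglik_observation,
    mean_structure,
)
from icarh.pathways import build_design_matrices


def make_state(rng, N, T, M, K, P):
    return LatentState(
        alpha=rng.normal(size=M),
        gamma=rng.normal(size=(N, M)),
        nu=rng.normal(size=(N, T, M)),
        theta=rng.uniform(-0.8, 0.8, size=M),
        beta=rng.normal(size=(M, K)),
        lam=np.abs(rng.standard_t(2, size=(M, K))) + 0.1,
        sigma2=1.3,
        sigma2_beta=rng.uniform(0.5, 2, size=M),
        sigma2_gamma=rng.uniform(0.05, 0.3, size=M),
        sigma2_nu=rng.uniform(0.1, 0.5, size=M),
        phi_cases=np.zeros(P),
        phi_controls=np.zeros(P),
    )


class TestMeanStructure:
    def test_all_zero_state(self):
        rng = np.random.default_rng(0)
        state = make_state(rng, 3, 4, 2, 1, 1)
        state.alpha[:] = 0
        state.gamma[:] = 0
        state.nu[:] = 0
        state.beta[:] = 0
        Y = rng.normal(size=(3, 4, 1))
        np.testing.assert_allclose(mean_structure(state, Y, 1, 2), 0.0)

    def test_treatment_only_constant_over_units(self):
        rng = np.random.default_rng(1)
        state = make_state(rng, 3, 4, 2, 1, 1)
        state.gamma[:] = 0
        state.nu[:] = 0
        state.beta[:] = 0
        Y = rng.normal(size=(3, 4, 1))
        for i in range(3):
            for t in range(4):
                np.testing.assert_allclose(
                    mean_structure(state, Y, i, t), state.alpha
                )

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(2)
        N, T, M, K = 3, 4, 2, 1
        state = make_state(rng, N, T, M, K, 1)
        Y = rng.normal(size=(N, T, K))
        i, t = 2, 1
        for m in range(M):
            expected = (state.alpha[m] + state.gamma[i, m]
                        + state.beta[m] @ Y[i, t] + state.nu[i, t, m])
            assert mean_structure(state, Y, i, t)[m] == pytest.approx(expected)

    def test_continuous_treatment_mode(self):
        rng = np.random.default_rng(3)
        state = make_state(rng, 2, 3, 2, 1, 1)
        state.gamma[:] = 0
        state.nu[:] = 0
        state.beta[:] = 0
        Y = np.zeros((2, 3, 1))
        y_drug = rng.normal(size=(2, 3))
        mu = mean_structure(state, Y, 1, 2, y_drug=y_drug)
        np.testing.assert_allclose(mu, state.alpha * y_drug[1, 2])

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        state = make_state(rng, 2, 3, 2, 2, 1)
        Y = rng.normal(size=(2, 3, 3))
        with pytest.raises(ValueError, match="columns"):
            mean_structure(state, Y, 0, 0)


class TestLoglikObservation:
    def test_independent_case(self):
        Z = np.zeros((4, 1), dtype=int)
        Z[0, 0] = 1
        pm = build_design_matrices(Z)
        mu = np.zeros(4)
        val = loglik_observation(mu, mu, pm, np.zeros(1), 2.0)
        assert val == pytest.approx(-2 * np.log(2 * np.pi * 2.0))

    def test_two_metabolite_pathway_matches_bivariate_normal(self):
        Z = np.array([[1], [1]])
        pm = build_design_matrices(Z)
        phi, s2 = np.array([0.3]), 1.5
        # closed-form 2x2: I - C = [[1, -phi], [-phi, 1]]
        Q = np.array([[1, -0.3], [-0.3, 1]])
        cov = s2 * np.linalg.inv(Q)
        x = np.array([0.4, -1.1])
        mu = np.array([0.1, 0.2])
        expected = stats.multivariate_normal.logpdf(x, mu, cov)
        assert loglik_observation(x, mu, pm, phi, s2) == pytest.approx(expected)

    def test_likelihood_prefers_generating_mean(self, small_sim):
        _, dataset, truth = small_sim
        pm = build_design_matrices(truth.Z)
        rng = np.random.default_rng(0)
        mu = (truth.alpha[None, None, :] + truth.gamma[:, None, :]
              + np.einsum("ntk,mk->ntm", dataset.Y, truth.beta) + truth.nu)
        perm = rng.permutation(dataset.X.shape[2])
        total_true = total_shuffled = 0.0
        for e, idx in (("c", dataset.control_indices),
                       ("t", dataset.case_indices)):
            phi = truth.phi_controls if e == "c" else truth.phi_cases
            for i in idx:
                for t in range(dataset.X.shape[1]):
                    total_true += loglik_observation(
                        dataset.X[i, t], mu[i, t], pm, phi, truth.sigma2)
                    total_shuffled += loglik_observation(
                        dataset.X[i, t], mu[i, t][perm], pm, phi, truth.sigma2)
        assert np.isfinite(total_true)
        assert total_true > total_shuffled


class TestHorseshoe:
    def test_matches_reference_densities(self):
        beta, lam, s2b, tau = np.array([[0.4]]), np.array([[0.7]]), \
            np.array([2.0]), 1.5
        expected = (
            stats.norm.logpdf(0.4, 0, 0.7 * np.sqrt(2.0))
            + stats.t.logpdf(0.7, 1.5) + np.log(2.0)
        )
        assert horseshoe_logprior(beta, lam, s2b, tau) == pytest.approx(expected)

    def test_tau_one_is_half_cauchy_on_lambda(self):
        # the original horseshoe: lambda ~ half-Cauchy(0, 1)
        lam = np.array([[0.9]])
        val = horseshoe_logprior(np.array([[0.0]]), lam, np.array([1.0]), 1.0)
        expected = (stats.norm.logpdf(0.0, 0, 0.9)
                    + stats.halfcauchy.logpdf(0.9))
        assert val == pytest.approx(expected)

    def test_shrinkage_limit(self):
        vals = [
            horseshoe_logprior(np.array([[0.5]]), np.array([[lam]]),
                               np.array([1.0]), 1.0)
            for lam in (1e-2, 1e-4, 1e-6)
        ]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < -1e6

    def test_rejects_bad_tau(self):
        with pytest.raises(ValueError):
            horseshoe_logprior(np.zeros((1, 1)), np.ones((1, 1)),
                               np.ones(1), 0.0)


class TestKappa:
    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 5.0])
    @pytest.mark.parametrize("sigma_beta", [0.25, 1.0, 4.0])
    def test_normalization(self, tau, sigma_beta):
        mass, _ = integrate.quad(
            lambda k: kappa_pdf(k, tau, sigma_beta), 0, 1, limit=200
        )
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_reduces_to_beta_at_unit_scale(self):
        grid = np.linspace(0.01, 0.99, 25)
        for tau in (1.0, 2.0, 3.7):
            np.testing.assert_allclose(
                kappa_pdf(grid, tau, 1.0),
                stats.beta(tau / 2, 0.5).pdf(grid),
                rtol=1e-10,
            )

    def test_horseshoe_shape_at_tau_one(self):
        grid = np.linspace(0.02, 0.98, 20)
        np.testing.assert_allclose(
            kappa_pdf(grid, 1.0, 1.0), stats.beta(0.5, 0.5).pdf(grid),
            rtol=1e-10,
        )

    def test_zero_outside_unit_interval(self):
        assert kappa_pdf(np.array([-0.1, 0.0, 1.0, 1.5]), 1.0, 1.0).tolist() \
            == [0, 0, 0, 0]

    def test_matches_monte_carlo_transform(self):
        # kappa = 1/(1 + lam^2 s^2 / tau) with lam ~ St+(tau)
        rng = np.random.default_rng(1)
        tau, s = 2.0, 0.5
        lam = np.abs(rng.standard_t(tau, size=400_000))
        kappa = 1 / (1 + lam ** 2 * s ** 2 / tau)
        hist, edges = np.histogram(kappa, bins=20, range=(0, 1), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        density = kappa_pdf(centers, tau, s)
        # integrable singularity at 1 makes the last bin noisy; compare bulk
        np.testing.assert_allclose(hist[:-1], density[:-1], rtol=0.1)


class TestExpectedKappa:
    def test_symmetric_beta_mean(self):
        assert expected_kappa(1.0, sigma_beta=1.0) == pytest.approx(0.5, abs=1e-8)

    def test_beta_mean_formula(self):
        # Beta(2, 1/2) mean = 2 / 2.5 = 0.8
        assert expected_kappa(4.0, sigma_beta=1.0) == pytest.approx(0.8, abs=1e-8)

    def test_monotone_in_tau(self):
        vals = [expected_kappa(t, sigma_beta=1.0) for t in (0.5, 1, 2, 4, 8)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_improper_marginalization_monotone(self):
        vals = [expected_kappa(t, sigma_beta=None, improper_truncation=(0.1, 10))
                for t in (0.5, 1.0, 4.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)


class TestAR1:
    def test_theta_zero_independent(self):
        rng = np.random.default_rng(0)
        nu = rng.normal(size=(2, 4, 3))
        s2 = np.array([0.5, 1.0, 2.0])
        val = ar1_logprior(nu, np.zeros(3), s2)
        expected = stats.norm.logpdf(nu, 0, np.sqrt(s2)).sum()
        assert val == pytest.approx(expected)

    def test_zero_nu_maximal(self):
        rng = np.random.default_rng(1)
        zero = np.zeros((2, 3, 1))
        for theta in (-0.5, 0.0, 0.7):
            base = ar1_logprior(zero, [theta], [0.4])
            for _ in range(10):
                other = rng.normal(size=(2, 3, 1), scale=0.5)
                assert base >= ar1_logprior(other, [theta], [0.4])

    def test_hand_computed_sum(self):
        # N=1, T=3, M=1 with fixed numbers
        nu = np.array([0.5, -0.2, 0.9]).reshape(1, 3, 1)
        theta, s2 = 0.6, 0.3
        expected = (
            stats.norm.logpdf(0.5, 0, np.sqrt(s2 / (1 - theta ** 2)))
            + stats.norm.logpdf(-0.2, 0.6 * 0.5, np.sqrt(s2))
            + stats.norm.logpdf(0.9, 0.6 * -0.2, np.sqrt(s2))
        )
        assert ar1_logprior(nu, [theta], [s2]) == pytest.approx(expected)

    def test_needs_two_time_points(self):
        with pytest.raises(ValueError, match="T >= 2"):
            ar1_logprior(np.zeros((1, 1, 1)), [0.0], [1.0])


class TestBetaPosteriorMeanOracle:
    def test_full_shrinkage_gives_zero(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(3, 4, 2))
        mu = rng.normal(size=(3, 4))
        beta = beta_posterior_mean_oracle(Y, np.ones(2), 1.0, mu, 0.3, 0.2, 0.1)
        np.testing.assert_array_equal(beta, 0.0)

    def test_ridge_special_case(self):
        # kappa arranged so tau * Upsilon = tau * I reduces to ridge
        rng = np.random.default_rng(1)
        T, N, K = 3, 5, 2
        Y = rng.normal(size=(T, N, K))
        mu = rng.normal(size=(T, N))
        tau, theta, s2n, s2g = 2.0, 0.4, 0.3, 0.1
        kappa = np.full(K, 0.5)  # 1/kappa - 1 = 1
        s2 = s2n / (1 - theta ** 2) + s2g
        gram = sum(Y[t].T @ Y[t] for t in range(T)) / s2
        rhs = sum(Y[t].T @ mu[t] for t in range(T)) / s2
        ridge = np.linalg.solve(gram + tau * np.eye(K), rhs)
        np.testing.assert_allclose(
            beta_posterior_mean_oracle(Y, kappa, tau, mu, theta, s2n, s2g),
            ridge,
        )

    def test_matches_penalized_least_squares(self):
        rng = np.random.default_rng(2)
        T, N, K = 3, 6, 2
        Y = rng.normal(size=(T, N, K))
        mu = rng.normal(size=(T, N))
        tau, theta, s2n, s2g = 1.2, -0.3, 0.25, 0.15
        kappa = np.array([0.2, 0.7])
        s2 = s2n / (1 - theta ** 2) + s2g
        ups = np.diag(1 / kappa - 1)
        gram = sum(Y[t].T @ Y[t] for t in range(T)) / s2
        rhs = sum(Y[t].T @ mu[t] for t in range(T)) / s2
        expected = np.linalg.solve(gram + tau * ups, rhs)
        np.testing.assert_allclose(
            beta_posterior_mean_oracle(Y, kappa, tau, mu, theta, s2n, s2g),
            expected,
        )

    def test_mixed_exact_zero_and_free(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(3, 5, 2))
        mu = rng.normal(size=(3, 5))
        beta = beta_posterior_mean_oracle(
            Y, np.array([1.0, 0.5]), 1.0, mu, 0.0, 0.2, 0.1
        )
        assert beta[0] == 0.0
        assert beta[1] != 0.0


class TestModelSpecConfig:
    def test_yaml_round_trip(self, tmp_path):
        spec = ModelSpec(tau=2.5, psi=10.0, gamma_prior=(2.0, 0.5),
                         phi_prior="uniform", treatment_mode="continuous")
        spec.sampler.iterations = 800
        spec.sampler.warmup = 300
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = ModelSpec.from_yaml(path)
        assert back == spec

    def test_invalid_values_rejected(self):
        import pytest as _pt

        with _pt.raises(ValueError):
            ModelSpec(tau=-1.0)
        with _pt.raises(ValueError):
            ModelSpec(phi_prior="flat")
        with _pt.raises(ValueError):
            ModelSpec().sampler.__class__(iterations=100, warmup=200)


class TestJointDecomposition:
    def test_total_is_sum_of_parts(self, small_sim):
        _, dataset, truth = small_sim
        rng = np.random.default_rng(9)
        pm = build_design_matrices(truth.Z)
        N, T, M = dataset.X.shape
        K = dataset.Y.shape[2]
        state = make_state(rng, N, T, M, K, pm.n_pathways)
        act = pm.active
        width = pm.phi_upper[act] - pm.phi_lower[act]
        state.phi_controls[act] = pm.phi_lower[act] + 0.3 * width
        state.phi_cases[act] = pm.phi_lower[act] + 0.6 * width
        spec = ModelSpec(tau=1.2)
        total, parts = log_joint(state, dataset, pm, spec)
        assert np.isfinite(total)
        assert total == pytest.approx(sum(parts.values()), abs=1e-10)
        assert set(parts) >= {"likelihood", "shrinkage", "temporal",
                              "individual", "phi_prior", "variance_priors"}
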