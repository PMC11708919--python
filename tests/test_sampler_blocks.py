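"""Each Gibbs block against independently derived conditional distributions.

The closed forms here are worked out from conjugate normal/Gamma algebra in
the test itself (never by calling the sampler's internals), and the blocks
are exercised repeatedly on tiny fixed instances so Monte-Carlo moments can
be compared within 3 MC standard errors.
"""

import numpy as np
import pandas as pd
import pytest

from metfactor.data import (ECDesignSet, Kinship, ModelInputs, TraitMatrix)
from metfactor.sampler import (SamplerConfig, SamplerError, _delta_update,
                               _precompute, initialize_state,
                               impute_missing_values, observed_loglik,
                               sample_factor_scores, sample_genetic_effects,
                               sample_loading_regression, sample_loadings)

N_MC = 10_000


def _inputs(values, kinship=None):
    """Tiny ModelInputs with no fixed effects (zero-column design) so the
    conditional oracles below stay closed-form."""
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    rows = [f"g{i}" for i in range(n)]
    cols = [f"e{j}" for j in range(t)]
    meta = pd.DataFrame({"location": cols, "year": 2000, "state": "S",
                         "tester": "T"}, index=cols)
    tm = TraitMatrix.from_values(values, rows, cols, meta)
    kin = kinship if kinship is not None else Kinship(np.eye(n), rows)
    return ModelInputs(tm, kin, ECDesignSet.build(t),
                       fixed_design=np.zeros((n, 0)))


def _setup(values, k=1, seed=0, config=None):
    inputs = _inputs(values)
    cfg = config or SamplerConfig(k_max=k, n_iter=10, burn_in=5, thin=1, seed=seed)
    pre = _precompute(inputs, cfg, None)
    state = initialize_state(inputs, cfg, None)
    return inputs, cfg, pre, state


class TestInitialization:
    def test_deterministic_given_seed(self):
        _, _, _, s1 = _setup(np.arange(12.0).reshape(4, 3), k=2, seed=5)
        _, _, _, s2 = _setup(np.arange(12.0).reshape(4, 3), k=2, seed=5)
        for name in ("F", "Lambda", "delta", "Y", "sigma2_R"):
            np.testing.assert_array_equal(getattr(s1, name), getattr(s2, name))

    def test_rank1_noiseless_concentrates_first_factor(self):
        u = np.array([1.0, -1.0, 2.0, 0.5])
        v = np.array([1.0, 2.0, -1.0])
        _, _, _, state = _setup(np.outer(u, v), k=2)
        lam2 = (state.Lambda ** 2).sum(axis=1)
        assert lam2[0] / lam2.sum() > 0.99

    def test_all_missing_column_initializes_finite(self):
        vals = np.arange(12.0).reshape(4, 3)
        vals[:, 1] = np.nan
        _, _, _, state = _setup(vals, k=2)
        assert np.isfinite(state.Lambda).all() and np.isfinite(state.Y).all()

    def test_k_max_exceeding_dims_errors(self):
        with pytest.raises(SamplerError, match="k_max"):
            _setup(np.arange(12.0).reshape(4, 3), k=5)


class TestFactorScoreConditional:
    def test_conjugate_normal_oracle(self):
        """k=1, t=1, λ=1, residual var 1, prior N(0,1), y=2 → N(1, 0.5).

        Oracle: precision = 1/priorvar + λ²/d = 2, mean = (y λ/d)/2 = 1.
        """
        inputs, cfg, pre, state = _setup([[2.0]], k=1)
        state.Lambda[:] = 1.0
        state.U_F[:] = 0.0
        state.U_R[:] = 0.0
        state.B[:] = 0.0
        state.h2_F[:] = 0.0          # prior variance 1 (total fixed at 1)
        state.sigma2_R[:] = 1.0
        state.h2_R[:] = 0.0
        rng = np.random.default_rng(1)
        draws = np.empty(N_MC)
        for i in range(N_MC):
            sample_factor_scores(state, inputs, pre, cfg, rng)
            draws[i] = state.F[0, 0]
        se_mean = draws.std() / np.sqrt(N_MC)
        assert abs(draws.mean() - 1.0) < 3 * se_mean
        assert abs(draws.var() - 0.5) < 3 * 0.5 * np.sqrt(2 / N_MC) * 3

    def test_zero_loadings_fall_back_to_prior(self):
        inputs, cfg, pre, state = _setup([[2.0, 1.0]], k=1)
        state.Lambda[:] = 0.0
        state.U_F[:] = 0.7
        state.h2_F[:] = 0.5
        state.sigma2_R[:] = 1.0
        state.h2_R[:] = 0.0
        rng = np.random.default_rng(2)
        draws = np.array([
            (sample_factor_scores(state, inputs, pre, cfg, rng),
             state.F[0, 0])[1] for _ in range(N_MC)])
        # prior: N(U_F, 1 - h2) = N(0.7, 0.5)
        assert abs(draws.mean() - 0.7) < 3 * draws.std() / np.sqrt(N_MC)
        assert abs(draws.var() - 0.5) < 0.05


class TestLoadingConditional:
    def test_conjugate_normal_oracle(self):
        """n=2, f=(1,1), adjusted y=(1,1), d=1, prior N(0, prec 1):
        posterior precision 3, mean 2/3."""
        inputs, cfg, pre, state = _setup([[1.0], [1.0]], k=1)
        state.F[:] = 1.0
        state.U_R[:] = 0.0
        state.B[:] = 0.0
        state.A[:] = 0.0
        state.psi[:] = 1.0
        state.tau[:] = 1.0
        state.sigma2_R[:] = 1.0
        state.h2_R[:] = 0.0
        rng = np.random.default_rng(3)
        draws = np.empty(N_MC)
        for i in range(N_MC):
            sample_loadings(state, inputs, pre, cfg, rng)
            draws[i] = state.Lambda[0, 0]
        se = draws.std() / np.sqrt(N_MC)
        assert abs(draws.mean() - 2.0 / 3.0) < 3 * se
        assert abs(draws.var() - 1.0 / 3.0) < 0.02

    def test_no_data_limit_returns_ec_prior(self):
        inputs, cfg, pre, state = _setup([[1.0], [1.0]], k=1)
        state.F[:] = 0.0
        state.U_R[:] = 0.0
        state.B[:] = 0.0
        state.A[:] = 0.4          # intercept-only prior mean 0.4
        state.psi[:] = 2.0
        state.tau[:] = 1.0
        state.sigma2_R[:] = 1.0
        state.h2_R[:] = 0.0
        rng = np.random.default_rng(4)
        draws = np.empty(N_MC)
        for i in range(N_MC):
            sample_loadings(state, inputs, pre, cfg, rng)
            draws[i] = state.Lambda[0, 0]
        assert abs(draws.mean() - 0.4) < 3 * draws.std() / np.sqrt(N_MC)
        assert abs(draws.var() - 0.5) < 0.03


class TestLoadingRegressionConditionals:
    def test_coefficient_conjugate_oracle(self):
        """Intercept-only, λ=(1,1), ψ=τ=σ²=1 → coefficient N(2/3, 1/3)."""
        inputs, cfg, pre, state = _setup([[1.0, 1.0]], k=1)
        rng = np.random.default_rng(5)
        a_draws = np.empty(N_MC)
        for i in range(N_MC):
            state.Lambda[:] = 1.0
            state.psi[:] = 1.0
            state.tau[:] = 1.0
            state.delta[:] = 1.0
            state.sigma2_l[:] = 1.0
            sample_loading_regression(state, inputs, pre, cfg, rng)
            a_draws[i] = state.A[0, 0]
        se = a_draws.std() / np.sqrt(N_MC)
        assert abs(a_draws.mean() - 2.0 / 3.0) < 3 * se
        assert abs(a_draws.var() - 1.0 / 3.0) < 0.02

    def test_psi_matches_its_gamma_conditional(self):
        """ψ_jk | ε, τ ~ Gamma((ν+1)/2, (ν + τ ε²)/2): the draw minus its
        conditional mean (ν+1)/(ν+τε²) averages to zero; at ε=0, τ=1, ν=3
        the conditional mean is 4/3."""
        inputs, cfg, pre, state = _setup([[1.0, 1.0]], k=1)
        rng = np.random.default_rng(6)
        nu = cfg.nu
        W = pre.W
        resid = np.empty((N_MC // 10, 2))
        for i in range(len(resid)):
            tau_before = state.tau.copy()
            sample_loading_regression(state, inputs, pre, cfg, rng)
            eps = state.Lambda - (W @ state.A).T
            cond_mean = (nu + 1.0) / (nu + tau_before[:, None] * eps ** 2)
            resid[i] = (state.psi - cond_mean)[0]
        se = resid.std() / np.sqrt(resid.size)
        assert abs(resid.mean()) < 3 * se
        # at ε=0, τ=1, ν=3 the conditional is Gamma(2, rate 1.5): mean 4/3
        assert (nu + 1.0) / (nu + 1.0 * 0.0 ** 2) == pytest.approx(4.0 / 3.0)

    def test_delta_prior_recovery_with_no_elements(self):
        """With zero-dimensional data the δ1 conditional is its prior."""
        cfg = SamplerConfig(k_max=3, n_iter=10, burn_in=5)
        rng = np.random.default_rng(8)
        draws = np.empty(N_MC)
        for i in range(N_MC):
            delta = np.ones(3)
            delta, tau = _delta_update(delta, np.array([]), 0, cfg, rng)
            draws[i] = delta[0]
        # prior Ga(alpha1, beta1): mean α/β, var α/β²
        assert abs(draws.mean() - cfg.alpha1 / cfg.beta1) \
            < 3 * draws.std() / np.sqrt(N_MC)
        assert abs(draws.var() - cfg.alpha1 / cfg.beta1 ** 2) < 0.1

    def test_tau_is_cumprod_of_delta(self):
        inputs, cfg, pre, state = _setup(np.ones((3, 3)), k=2)
        rng = np.random.default_rng(9)
        for _ in range(10):
            sample_loading_regression(state, inputs, pre, cfg, rng)
            np.testing.assert_allclose(state.tau, np.cumprod(state.delta))
            assert (state.psi > 0).all() and (state.sigma2_l > 0).all()


class TestGeneticEffectConditionals:
    def test_identity_kinship_blup_shrinks_by_half(self):
        """K=I, σ²g=σ²e: E[u|y] = y/2.  Fix h² by using a 2-point grid."""
        y = np.array([[2.0], [-2.0], [1.0], [-1.0]])
        cfg = SamplerConfig(k_max=1, n_iter=10, burn_in=5, h2_grid_size=2,
                            resid_a=200.0, resid_b=100.0)  # σ²_R pinned near 1
        inputs, cfg, pre, state = _setup(y, k=1, config=cfg)
        rng = np.random.default_rng(10)
        draws = np.empty((N_MC // 10, 4))
        for i in range(len(draws)):
            state.F[:] = 0.0
            state.Lambda[:] = 0.0
            state.B[:] = 0.0
            sample_genetic_effects(state, inputs, pre, cfg, rng)
            draws[i] = state.U_R[:, 0]
        # h² grid {0, 0.5}: conditional on h²=0.5 (dominant for this y),
        # E[u|y] = y/2; mixture with h²=0 pulls towards 0 slightly.
        kept = draws[np.abs(draws).sum(axis=1) > 1e-9]
        ratio = kept.mean(axis=0) / y[:, 0]
        assert np.all(np.abs(ratio - 0.5) < 0.1)

    def test_h2_grid_probabilities_detect_zero_heritability(self):
        """Pure-noise data under an informative kinship: posterior mass on
        grid points ≤ 0.1 should exceed 0.9."""
        from metfactor.simulate import simulate_kinship
        rng = np.random.default_rng(11)
        n = 500
        kin = simulate_kinship(n, 50, rng)
        kin = Kinship(kin.matrix, [f"g{i}" for i in range(n)])
        y = rng.standard_normal((n, 1))  # h² = 0 truth
        inputs = _inputs(y, kinship=kin)
        cfg = SamplerConfig(k_max=1, n_iter=10, burn_in=5, h2_grid_size=10)
        pre = _precompute(inputs, cfg, None)
        state = initialize_state(inputs, cfg, None)
        state.F[:] = 0.0
        state.Lambda[:] = 0.0
        h2s = []
        for _ in range(100):
            sample_genetic_effects(state, inputs, pre, cfg, rng)
            h2s.append(state.h2_R[0])
        assert np.mean(np.array(h2s) <= 0.1) > 0.9

    def test_h2_sampler_frequencies_match_exact_conditional(self):
        """Sampled grid frequencies agree with the analytic conditional
        probabilities (independent normal-likelihood computation)."""
        from scipy.stats import norm
        from metfactor.sampler import _sample_h2_column
        rng = np.random.default_rng(20)
        s = np.abs(rng.standard_normal(6)) + 0.1
        y = rng.standard_normal(6) * np.sqrt(0.5 * s + 0.5)
        grid = np.arange(4) / 4
        # oracle: p(h2) ∝ Π_i N(y_i; 0, h2 s_i + 1 − h2)
        logp = np.array([norm.logpdf(y, scale=np.sqrt(g * s + 1 - g)).sum()
                         for g in grid])
        p = np.exp(logp - logp.max())
        p /= p.sum()
        draws = np.array([_sample_h2_column(y, s, grid, 1.0,
                                            np.random.default_rng(i))
                          for i in range(4000)])
        freq = np.array([(draws == g).mean() for g in grid])
        np.testing.assert_allclose(freq, p, atol=4 * np.sqrt(0.25 / 4000) + 0.02)


class TestImputationAndInvariants:
    def test_imputation_mean_matches_linear_predictor(self):
        vals = np.array([[1.0, np.nan], [0.5, 2.0]])
        inputs, cfg, pre, state = _setup(vals, k=1)
        state.B[:] = 0.0
        state.F[:] = np.array([[1.0], [2.0]])
        state.Lambda[:] = np.array([[0.3, 0.7]])
        state.U_R[:] = 0.1
        state.sigma2_R[:] = 0.5
        state.h2_R[:] = 0.0
        rng = np.random.default_rng(12)
        target = 1.0 * 0.7 + 0.1
        draws = np.empty(N_MC)
        for i in range(N_MC):
            impute_missing_values(state, inputs, pre, cfg, rng)
            draws[i] = state.Y[0, 1]
        assert abs(draws.mean() - target) < 3 * draws.std() / np.sqrt(N_MC)
        assert abs(draws.var() - 0.5) < 0.03

    def test_observed_cells_never_touched(self):
        vals = np.array([[1.0, np.nan], [0.5, 2.0]])
        inputs, cfg, pre, state = _setup(vals, k=1)
        rng = np.random.default_rng(13)
        obs_before = state.Y[pre.obs_mask].copy()
        for _ in range(20):
            for block in (sample_genetic_effects, sample_factor_scores,
                          sample_loadings, sample_loading_regression,
                          impute_missing_values):
                block(state, inputs, pre, cfg, rng)
        np.testing.assert_array_equal(state.Y[pre.obs_mask], obs_before)

    def test_sign_flip_invariance_of_loglik(self):
        inputs, cfg, pre, state = _setup(np.arange(6.0).reshape(3, 2), k=2)
        rng = np.random.default_rng(14)
        sample_genetic_effects(state, inputs, pre, cfg, rng)
        base = observed_loglik(state, inputs, pre)
        h = 1
        state.F[:, h] *= -1
        state.Lambda[h, :] *= -1
        state.U_F[:, h] *= -1
        state.A[:, h] *= -1
        assert observed_loglik(state, inputs, pre) == pytest.approx(base, abs=1e-10)
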