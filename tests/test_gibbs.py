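"""Gibbs engine: initialization admissibility, bookkeeping, monotonicity
invariants, data-augmentation consistency, label-marginal enumeration oracle
and seeded reproducibility."""

import numpy as np
import pytest

from psbart.data import G00, G10, G11, ObservationPattern, TrialDataset
from psbart.gibbs import (PosteriorDraws, SamplerConfig, compute_csace_draw,
                          initialize_chain, run_mcmc)
from psbart.gibbs import _prepare
from psbart.simulate import DgpConfig, generate_dataset


class TestSamplerConfig:
    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iter=10, n_burn=10)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            SamplerConfig(always_survivor_threshold=1.0)


class TestInitialization:
    def _config(self):
        return SamplerConfig(n_iter=10, n_burn=5, seed=0, K_outcome=10,
                             K_membership=5)

    def test_identified_cells_deterministic(self, small_sim):
        data, _ = small_sim
        rng = np.random.default_rng(0)
        state = initialize_chain(data, self._config(), rng)
        obs_dead_treated = (data.r_s == 1) & (data.s_obs == 0) & (data.z == 1)
        obs_alive_control = (data.r_s == 1) & (data.s_obs == 1) & (data.z == 0)
        assert (state.G[obs_dead_treated] == G00).all()
        assert (state.G[obs_alive_control] == G11).all()

    def test_initial_labels_admissible_everywhere(self, small_sim):
        data, _ = small_sim
        state = initialize_chain(data, self._config(),
                                 np.random.default_rng(1))
        z, G, s = data.z, state.G, state.s_cur
        # monotonicity-admissibility given (z, current survival)
        assert not ((z == 1) & (s == 0) & (G != G00)).any()
        assert not ((z == 0) & (s == 1) & (G != G11)).any()
        assert not ((z == 1) & (s == 1) & (G == G00)).any()
        assert not ((z == 0) & (s == 0) & (G == G11)).any()

    def test_same_seed_same_state(self, small_sim):
        data, _ = small_sim
        a = initialize_chain(data, self._config(), np.random.default_rng(7))
        b = initialize_chain(data, self._config(), np.random.default_rng(7))
        np.testing.assert_array_equal(a.G, b.G)
        np.testing.assert_allclose(a.membership.Q, b.membership.Q)
        np.testing.assert_allclose(a.y_cur, b.y_cur, equal_nan=True)

    def test_all_control_survivors_forced_always(self):
        n = 12
        data = TrialDataset(
            cluster=np.repeat([0, 1], 6), z=np.repeat([0, 1], 6),
            x=np.random.default_rng(0).standard_normal((n, 2)),
            covariate_names=["a", "b"],
            s_obs=np.ones(n), r_s=np.ones(n, int), r_y=np.ones(n, int),
            y_obs=np.random.default_rng(1).standard_normal(n),
            truncated=np.zeros(n, bool))
        state = initialize_chain(data, self._config(),
                                 np.random.default_rng(2))
        assert (state.G[data.z == 0] == G11).all()


class TestBookkeeping:
    def test_retained_draw_count_and_thinning(self, small_sim):
        data, _ = small_sim
        cfg = SamplerConfig(n_iter=20, n_burn=10, thin=1, seed=1,
                            K_outcome=10, K_membership=5)
        draws = run_mcmc(data, cfg, "lmm", "lmm")
        assert draws.n_draws == 10
        cfg = SamplerConfig(n_iter=20, n_burn=10, thin=3, seed=1,
                            K_outcome=10, K_membership=5)
        draws = run_mcmc(data, cfg, "lmm", "lmm")
        assert draws.n_draws == 4  # iterations 10, 13, 16, 19

    def test_proportions_are_simplex_points(self, small_sim):
        data, _ = small_sim
        cfg = SamplerConfig(n_iter=16, n_burn=8, seed=2, K_outcome=10,
                            K_membership=5)
        draws = run_mcmc(data, cfg, "lmm", "lmm")
        np.testing.assert_allclose(draws.pi.sum(axis=1), 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def short_run():
    data, truth = generate_dataset(
        DgpConfig(n_clusters=30, cluster_size=5, seed=21))
    cfg = SamplerConfig(n_iter=60, n_burn=30, seed=4, K_outcome=15,
                        K_membership=8)
    return data, run_mcmc(data, cfg, "bart", "bart")


class TestInvariants:
    def test_monotonicity_never_violated(self, short_run):
        data, draws = short_run
        z = data.z
        obs_dead = (data.r_s == 1) & (data.s_obs == 0)
        obs_alive = (data.r_s == 1) & (data.s_obs == 1)
        for G in draws.G:
            assert not ((z == 1) & obs_dead & (G != G00)).any()
            assert not ((z == 0) & obs_alive & (G != G11)).any()
            assert not ((z == 1) & obs_alive & (G == G00)).any()
            assert not ((z == 0) & obs_dead & (G == G11)).any()

    def test_sace_equals_mean_of_stratum_taus(self, short_run):
        """Each draw's SACE is the arithmetic mean of that draw's effect
        surface over its current always-survivors."""
        _, draws = short_run
        for i in range(draws.n_draws):
            mask = draws.G[i] == G11
            if np.isnan(draws.sace[i]):
                assert not mask.any()
            else:
                assert draws.sace[i] == pytest.approx(
                    float(draws.tau[i][mask].mean()), abs=1e-5)

    def test_tau_surface_finite_everywhere(self, short_run):
        _, draws = short_run
        assert np.isfinite(draws.tau).all()


class TestDataAugmentation:
    def test_imputed_survival_follows_label_map(self, small_sim):
        """S = 1 iff G = 11, or G = 10 under treatment, for unrecorded
        rows — checked across several Gibbs steps."""
        from psbart.gibbs import gibbs_step
        data, _ = small_sim
        prep = _prepare(data)
        cfg = SamplerConfig(n_iter=10, n_burn=5, seed=3, K_outcome=10,
                            K_membership=5)
        rng = np.random.default_rng(5)
        state = initialize_chain(data, cfg, rng, prep=prep)
        unrec = data.r_s == 0
        for _ in range(5):
            gibbs_step(state, prep, cfg, rng)
            expected = ((state.G == G11)
                        | ((state.G == G10) & (data.z == 1))).astype(int)
            np.testing.assert_array_equal(state.s_cur[unrec],
                                          expected[unrec])
            # never-survivors and untreated protected carry no outcome
            assert np.isnan(state.y_cur[state.s_cur == 0]).all()
            assert not np.isnan(state.y_cur[state.s_cur == 1]).any()

    def test_observed_cells_never_overwritten(self, small_sim):
        from psbart.gibbs import gibbs_step
        data, _ = small_sim
        prep = _prepare(data)
        cfg = SamplerConfig(n_iter=10, n_burn=5, seed=3, K_outcome=10,
                            K_membership=5)
        rng = np.random.default_rng(6)
        state = initialize_chain(data, cfg, rng, prep=prep)
        obs = ~np.isnan(data.y_obs)
        for _ in range(3):
            gibbs_step(state, prep, cfg, rng)
            np.testing.assert_array_equal(state.y_cur[obs], data.y_obs[obs])
            rec = data.r_s == 1
            np.testing.assert_array_equal(state.s_cur[rec],
                                          data.s_obs[rec].astype(int))


class TestCsaceDraw:
    def test_identical_ensembles_give_zero_effect(self, small_sim):
        data, _ = small_sim
        cfg = SamplerConfig(n_iter=10, n_burn=5, seed=0, K_outcome=10,
                            K_membership=5)
        rng = np.random.default_rng(0)
        prep = _prepare(data)
        state = initialize_chain(data, cfg, rng, prep=prep)
        state.models[(G11, 0)] = state.models[(G11, 1)]
        state.outcome_set.models[(G11, 0)] = state.models[(G11, 1)]
        tau, sace = compute_csace_draw(state, prep)
        assert sace == pytest.approx(0.0, abs=1e-12)
        assert np.nanmax(np.abs(tau)) == pytest.approx(0.0, abs=1e-12)

    def test_sace_is_mean_of_taus(self, small_sim):
        data, _ = small_sim
        cfg = SamplerConfig(n_iter=10, n_burn=5, seed=0, K_outcome=10,
                            K_membership=5)
        rng = np.random.default_rng(1)
        prep = _prepare(data)
        state = initialize_chain(data, cfg, rng, prep=prep)
        tau, sace = compute_csace_draw(state, prep)
        assert sace == pytest.approx(float(tau[state.G == G11].mean()))


class TestLabelMarginalOracle:
    def test_gibbs_label_marginals_match_enumeration(self, rng):
        """Six individuals, frozen membership probabilities and outcome
        densities: sampler label frequencies must match exhaustive
        enumeration of all admissible label vectors weighted by the
        observed-data likelihood."""
        from psbart.strata import label_full_conditional
        P = ObservationPattern
        # one individual per pattern/arm situation
        cases = [
            (P.COMPLETE_SURVIVOR, 1, (0.2, 0.3, 0.5), 0.35, 0.6),
            (P.COMPLETE_SURVIVOR, 0, (0.3, 0.3, 0.4), None, None),
            (P.DEATH_TRUNCATION, 1, (0.25, 0.35, 0.4), None, None),
            (P.DEATH_TRUNCATION, 0, (0.5, 0.3, 0.2), None, None),
            (P.SURVIVOR_OUTCOME_MISSING, 1, (0.15, 0.45, 0.4), None, None),
            (P.STATUS_OUTCOME_MISSING, 0, (0.3, 0.4, 0.3), None, None),
        ]
        conditionals = [
            label_full_conditional(pat, z, pr, dens11=d11, dens10=d10)
            for pat, z, pr, d11, d10 in cases]

        # enumeration oracle: joint over admissible vectors factorizes, so
        # accumulate marginals explicitly from the product weights
        marg = np.zeros((6, 3))
        idx = np.indices((3,) * 6).reshape(6, -1).T
        for vec in idx:
            wgt = 1.0
            for i, g in enumerate(vec):
                wgt *= conditionals[i][g]
            if wgt == 0:
                continue
            for i, g in enumerate(vec):
                marg[i, g] += wgt
        marg /= marg.sum(axis=1, keepdims=True)

        draws = np.empty((50_000, 6), dtype=int)
        u = rng.random((50_000, 6))
        for i, cond in enumerate(conditionals):
            cum = np.cumsum(cond)
            draws[:, i] = np.searchsorted(cum, u[:, i])
        freq = np.stack([(draws == g).mean(axis=0) for g in range(3)], axis=1)
        np.testing.assert_allclose(freq, marg, atol=0.02)


class TestReproducibility:
    def test_bitwise_identical_retained_draws(self):
        data, _ = generate_dataset(
            DgpConfig(n_clusters=20, cluster_size=4, seed=33))
        cfg = SamplerConfig(n_iter=30, n_burn=15, seed=17, K_outcome=10,
                            K_membership=5)
        a = run_mcmc(data, cfg, "bart", "bart")
        b = run_mcmc(data, cfg, "bart", "bart")
        np.testing.assert_array_equal(a.G, b.G)
        np.testing.assert_array_equal(a.tau, b.tau)
        np.testing.assert_array_equal(a.sace, b.sace)
        np.testing.assert_array_equal(a.pi, b.pi)

    def test_posterior_pi11_tracks_truth(self):
        """On simulated data the posterior mean always-survivor proportion
        lands near the generating fraction."""
        data, truth = generate_dataset(
            DgpConfig(n_clusters=60, cluster_size=6, seed=44))
        cfg = SamplerConfig(n_iter=300, n_burn=150, seed=5, K_outcome=25,
                            K_membership=12)
        draws = run_mcmc(data, cfg, "bart", "bart")
        pi11 = draws.stratum_proportions()[2]
        assert abs(pi11 - (truth.g == G11).mean()) < 0.05
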