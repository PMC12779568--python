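import numpy as np
import pytest

from dihsmm.gibbs import (
    ChainConfig,
    emission_loglik,
    gibbs_sweep,
    init_model,
    log_joint,
    resample_concentrations,
    resample_duration_params,
    resample_state_sequence,
    resample_transition_params,
    resample_weights,
    run_gibbs_chain,
    run_chains,
)
from dihsmm.model import (
    HyperParams,
    ModelSample,
    check_model,
    sample_duration,
    zero_diag_renorm,
)
from dihsmm.trial_features import build_design

import pandas as pd


def _two_state_model(n_sessions, w0, w1, r=3, p=0.5):
    w = np.stack(
        [np.tile(np.asarray(w0, float), (n_sessions, 1)),
         np.tile(np.asarray(w1, float), (n_sessions, 1))]
    )
    return ModelSample(
        beta=np.array([0.5, 0.5]),
        pi0=np.array([0.5, 0.5]),
        pi=np.array([[0.5, 0.5], [0.5, 0.5]]),
        alpha=1.0,
        gamma=1.0,
        r=np.array([r, r]),
        p=np.array([p, p]),
        w=w,
    )


def _design_all_left(T=30):
    table = pd.DataFrame(
        {
            "session": np.ones(T, int),
            "trial": np.arange(1, T + 1),
            "contrast_left": np.ones(T),
            "contrast_right": np.zeros(T),
            "choice": ["L"] * T,
        }
    )
    return build_design(table)


class TestStateSequence:
    def test_zero_likelihood_state_excluded(self, rng):
        design = _design_all_left()
        # state 0 insists on rightward choices; every observed choice is L
        model = _two_state_model(1, [0, 0, 0, 50.0], [0, 0, 0, 0.0])
        resample_state_sequence(model, design, rng)
        assert np.all(model.x == 1)

    def test_duration_law_forcing_single_segment(self, rng):
        design = _design_all_left(T=25)
        # durations overwhelmingly exceed the session length
        model = _two_state_model(1, [0, 0, 0, 0.0], [0, 0, 0, 0.0], r=400, p=0.01)
        for _ in range(10):
            resample_state_sequence(model, design, rng)
            assert len(model.z[0]) == 1

    def test_invariants_preserved(self, planted_fit):
        _, design, _ = planted_fit
        rng = np.random.default_rng(3)
        hp = HyperParams(L=6)
        model = init_model(design, hp, rng)
        resample_state_sequence(model, design, rng)
        check_model(model, design.session_lengths)


class TestDurationParams:
    def test_parameter_recovery(self, rng):
        # 200 completed segments from (r=20, p=0.3) assigned to state 0,
        # interleaved with dummy state-1 segments so no segment is censored
        hp = HyperParams(L=2)
        durs = sample_duration(20, 0.3, rng, size=200)
        z, d = [], []
        for dur in durs:
            z.extend([0, 1])
            d.extend([dur, 1])
        model = _two_state_model(1, [0] * 4, [0] * 4)
        model.z = [np.array(z)]
        model.d = [np.array(d)]
        model.censored = np.array([True])
        r_draws, mean_durs = [], []
        for _ in range(50):
            resample_duration_params(model, hp, rng)
            r_draws.append(model.r[0])
            mean_durs.append(1 + model.r[0] * (1 - model.p[0]) / model.p[0])
        assert 10 <= np.median(r_draws) <= 40
        true_mean = 1 + 20 * 0.7 / 0.3
        assert np.mean(mean_durs) == pytest.approx(true_mean, rel=0.10)

    def test_all_unit_durations_push_p_to_one(self, rng):
        hp = HyperParams(L=2)
        model = _two_state_model(1, [0] * 4, [0] * 4)
        z = np.array([0, 1] * 150)
        model.z = [z]
        model.d = [np.ones_like(z)]
        model.censored = np.array([True])
        ps = []
        for _ in range(30):
            resample_duration_params(model, hp, rng)
            ps.append(model.p[0])
        assert np.mean(ps) > 0.95

    def test_single_segment_keeps_r_diffuse(self, rng):
        hp = HyperParams(L=2)
        model = _two_state_model(1, [0] * 4, [0] * 4)
        model.z = [np.array([0, 1])]
        model.d = [np.array([4, 1])]
        model.censored = np.array([True])
        support = hp.r_support
        draws = []
        for _ in range(800):
            resample_duration_params(model, hp, rng)
            draws.append(model.r[0])

        def empirical_entropy(values):
            counts = np.bincount(values, minlength=support.max() + 1)[support.min():]
            probs = counts / counts.sum()
            probs = probs[probs > 0]
            return -(probs * np.log(probs)).sum()

        # compare against the entropy of a genuinely uniform sample of the
        # same size (the finite-sample ceiling)
        reference = empirical_entropy(rng.choice(support, size=len(draws)))
        assert empirical_entropy(draws) > 0.90 * reference


class TestTransitionParams:
    def _model_with_sessions(self, z_sessions, L=4):
        model = ModelSample(
            beta=np.full(L, 1 / L),
            pi0=np.full(L, 1 / L),
            pi=np.full((L, L), 1 / L),
            alpha=1.0,
            gamma=1.0,
            r=np.full(L, 10),
            p=np.full(L, 0.5),
            w=np.zeros((L, 1, 4)),
        )
        model.z = [np.asarray(z) for z in z_sessions]
        model.d = [np.ones(len(z), int) for z in z_sessions]
        model.censored = np.ones(len(z_sessions), bool)
        return model

    def test_prior_reproduction_with_no_counts(self, rng):
        # with zero transition counts each pi row is Dir(alpha*beta) given
        # the beta of the same draw: the row-minus-beta residuals average out
        hp = HyperParams(L=4)
        model = self._model_with_sessions([])
        model.alpha = 5.0
        diffs = []
        for _ in range(600):
            resample_transition_params(model, hp, rng)
            diffs.append(model.pi[0] - model.beta)
        np.testing.assert_allclose(np.mean(diffs, axis=0), 0.0, atol=0.03)

    def test_repeated_transition_dominates_effective_row(self, rng):
        hp = HyperParams(L=4)
        model = self._model_with_sessions([[0, 1]] * 1000)
        vals = []
        for _ in range(100):
            resample_transition_params(model, hp, rng)
            vals.append(zero_diag_renorm(model.pi)[0, 1])
        assert np.mean(vals) > 0.95

    def test_pi0_posterior_mean(self, rng):
        hp = HyperParams(L=4)
        model = self._model_with_sessions([[1, 0]] * 100)
        vals = []
        for _ in range(300):
            resample_transition_params(model, hp, rng)
            vals.append(model.pi0[1])
        expected = (100 + 3 / 4) / (100 + 3)
        assert np.mean(vals) == pytest.approx(expected, abs=0.02)


class TestConcentrations:
    def test_more_states_pull_gamma_up(self, rng):
        hp = HyperParams(L=8)
        few = ModelSample(
            beta=np.array([0.93] + [0.01] * 7),
            pi0=np.full(8, 1 / 8), pi=np.full((8, 8), 1 / 8),
            alpha=1.0, gamma=1.0, r=np.full(8, 10), p=np.full(8, 0.5),
            w=np.zeros((8, 1, 4)),
        )
        many = few.copy()
        many.beta = np.full(8, 1 / 8)
        g_few, g_many = [], []
        for _ in range(120):
            resample_concentrations(few, hp, rng)
            resample_concentrations(many, hp, rng)
            g_few.append(few.gamma)
            g_many.append(many.gamma)
        from scipy.stats import mannwhitneyu

        assert np.median(g_many) > np.median(g_few)
        assert mannwhitneyu(g_many, g_few, alternative="greater").pvalue < 0.01

    def test_draws_finite_positive(self, rng):
        hp = HyperParams(L=4)
        model = ModelSample(
            beta=np.full(4, 0.25), pi0=np.full(4, 0.25),
            pi=np.full((4, 4), 0.25), alpha=1.0, gamma=1.0,
            r=np.full(4, 10), p=np.full(4, 0.5), w=np.zeros((4, 1, 4)),
        )
        for _ in range(50):
            resample_concentrations(model, hp, rng)
            assert 0 < model.alpha < np.inf
            assert 0 < model.gamma < np.inf


class TestWeights:
    def test_zero_drift_locks_sessions_together(self, rng):
        hp = HyperParams(L=2, sigma_drift=0.0)
        table = pd.DataFrame(
            {
                "session": [1, 1, 2, 2],
                "trial": [1, 2, 1, 2],
                "contrast_left": [1.0, 0.0, 1.0, 0.0],
                "contrast_right": [0.0, 1.0, 0.0, 1.0],
                "choice": ["L", "R", "L", "R"],
            }
        )
        design = build_design(table)
        model = _two_state_model(2, [0] * 4, [0] * 4)
        model.x = np.array([0, 0, 0, 0])
        model.z = [np.array([0]), np.array([0])]
        model.d = [np.array([2]), np.array([2])]
        model.censored = np.array([True, True])
        for _ in range(5):
            resample_weights(model, design, hp, rng)
            np.testing.assert_array_equal(model.w[0, 0], model.w[0, 1])

    def test_no_data_reproduces_diffuse_prior(self, rng):
        hp = HyperParams(L=2, sigma_drift=0.04)
        design = _design_all_left(T=10)
        model = _two_state_model(1, [0] * 4, [0] * 4)
        model.x = np.zeros(10, int)
        model.z = [np.array([0])]
        model.d = [np.array([10])]
        model.censored = np.array([True])
        draws = []
        for _ in range(3000):
            resample_weights(model, design, hp, rng)
            draws.append(model.w[1, 0].copy())  # state 1 owns no trials
        draws = np.array(draws)
        assert np.allclose(draws.mean(axis=0), 0.0, atol=0.25)
        assert np.allclose(draws.var(axis=0), 8.0, rtol=0.15)


class TestSweepAndChains:
    def test_sweep_preserves_invariants_and_is_deterministic(self, planted_fit):
        _, design, _ = planted_fit
        hp = HyperParams(L=5)
        models = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            model = init_model(design, hp, rng)
            for _ in range(3):
                gibbs_sweep(model, design, hp, rng)
            models.append(model)
        check_model(models[0], design.session_lengths)
        np.testing.assert_array_equal(models[0].x, models[1].x)
        np.testing.assert_allclose(models[0].w, models[1].w)
        assert models[0].alpha == models[1].alpha

    def test_log_joint_improves_from_random_init(self, planted_fit):
        _, design, _ = planted_fit
        rng = np.random.default_rng(2)
        hp = HyperParams(L=5)
        model = init_model(design, hp, rng)
        lps = []
        for _ in range(40):
            gibbs_sweep(model, design, hp, rng)
            lps.append(log_joint(model, design, hp))
        assert np.median(lps[-10:]) > np.median(lps[:3])

    def test_chain_continuation_is_bit_exact(self, planted_fit):
        _, design, _ = planted_fit
        hp = HyperParams(L=4)
        rng1 = np.random.default_rng(11)
        _, _, final_once = run_gibbs_chain(design, hp, 20, 5, 2, rng1)
        rng2 = np.random.default_rng(11)
        _, _, mid = run_gibbs_chain(design, hp, 10, 5, 2, rng2)
        _, _, final_twice = run_gibbs_chain(
            design, hp, 10, 0, 2, rng2, init=mid
        )
        np.testing.assert_array_equal(final_once.x, final_twice.x)
        np.testing.assert_allclose(final_once.w, final_twice.w)

    def test_run_chains_summaries_schema(self, planted_fit):
        _, design, _ = planted_fit
        hp = HyperParams(L=4)
        config = ChainConfig(n_chains=2, n_samples=12, burn_in=4, thin=2, seed=9)
        chainset = run_chains(design, hp, config)
        assert chainset.n_chains == 2
        assert all(len(c) == config.n_stored for c in chainset.chains)
        expected_cols = {"chain", "sample", "alpha", "gamma", "top1_trials",
                         "top2_trials", "n_states_20", "n_states_10"}
        assert expected_cols <= set(chainset.summaries.columns)
        assert len(chainset.summaries) == 2 * config.n_stored

    def test_chainset_round_trip(self, planted_fit, tmp_path):
        _, design, _ = planted_fit
        hp = HyperParams(L=4)
        config = ChainConfig(n_chains=2, n_samples=8, burn_in=2, thin=2, seed=1)
        chainset = run_chains(design, hp, config)
        path = tmp_path / "chains.h5"
        chainset.save(path)
        from dihsmm.gibbs import ChainSet

        back = ChainSet.load(path)
        assert back.n_chains == chainset.n_chains
        np.testing.assert_array_equal(back.chains[0][0].x, chainset.chains[0][0].x)
        np.testing.assert_allclose(back.chains[1][-1].w, chainset.chains[1][-1].w)
        assert back.config.thin == 2
        assert back.hyper.L == 4


def test_default_chain_config_thinning_arithmetic():
    config = ChainConfig()
    assert config.n_chains == 16
    assert config.n_stored == (48_000 - 4_000) // 25 == 1_760


def test_emission_loglik_matches_direct_formula(planted_fit):
    _, design, model = planted_fit
    hp = HyperParams(L=3)
    ll = emission_loglik(design, model)
    t = np.flatnonzero(~design.is_timeout)[5]
    n = design.session[t] - 1
    for i in range(3):
        psi = design.F[t] @ model.w[i, n]
        p = 1 / (1 + np.exp(-psi))
        expected = np.log(p if design.y[t] == 1 else 1 - p)
        assert ll[t, i] == pytest.approx(expected, abs=1e-10)
    assert np.all(ll[design.is_timeout] == 0)
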