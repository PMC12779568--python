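import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from dihsmm.aggregation import (
    binned_similarity,
    cluster_trials,
    co_occupancy,
    compute_rhat,
    embed_and_find_modes,
    mean_co_occupancy,
    select_chains,
    state_pmfs,
    trial_connectedness,
)
from dihsmm.gibbs import SampleRecord
from dihsmm.trial_features import build_design


def reference_rhat(chains):
    """Independent textbook implementation of the potential scale reduction."""
    x = np.asarray(chains, float)
    m, n = x.shape
    chain_means = x.mean(axis=1)
    W = np.mean([np.var(c, ddof=1) for c in x])
    B = n * np.var(chain_means, ddof=1)
    return np.sqrt(((n - 1) / n * W + B / n) / W)


class TestRhat:
    def test_identical_chains_give_one(self):
        series = np.sin(np.arange(500))
        chains = np.vstack([series, series, series])
        for variant in ("plain", "folded", "rank_normalized"):
            assert compute_rhat(chains, variant) == pytest.approx(1.0)

    def test_constant_offset_chains_diverge(self):
        chains = np.vstack([np.zeros(200), np.ones(200)])
        assert compute_rhat(chains) > 1.05
        assert compute_rhat(chains) == np.inf  # zero within-chain variance

    def test_agrees_with_reference_formula(self, rng):
        chains = rng.normal(size=(4, 300)) + rng.normal(size=(4, 1)) * 0.3
        assert compute_rhat(chains, "plain") == pytest.approx(
            reference_rhat(chains), abs=1e-12
        )

    def test_iid_chains_converge(self, rng):
        chains = rng.normal(size=(4, 10_000))
        assert compute_rhat(chains) < 1.01
        assert compute_rhat(chains, "folded") < 1.01
        assert compute_rhat(chains, "rank_normalized") < 1.01

    def test_folded_detects_variance_mismatch(self, rng):
        a = rng.normal(0, 1, size=2000)
        b = rng.normal(0, 3, size=2000)
        chains = np.vstack([a, b])
        assert compute_rhat(chains, "folded") > compute_rhat(chains, "plain")

    def test_constant_everywhere_convention(self):
        chains = np.full((3, 50), 2.5)
        assert compute_rhat(chains) == 1.0


class TestSelectChains:
    def _summaries(self, series_by_chain):
        rows = []
        for c, series in enumerate(series_by_chain):
            for k, v in enumerate(series):
                rows.append({"chain": c, "sample": k, "alpha": v, "gamma": v * 0.5})
        return pd.DataFrame(rows)

    def test_identical_chains_keep_everything(self, rng):
        base = rng.normal(size=200)
        summaries = self._summaries([base] * 6)
        report = select_chains(summaries, min_keep=4)
        assert report.selected_chains == [0, 1, 2, 3, 4, 5]
        assert report.converged

    def test_adversarial_chain_removed_first(self, rng):
        good = [rng.normal(size=300) for _ in range(7)]
        bad = rng.normal(size=300) + 10.0
        summaries = self._summaries(good[:3] + [bad] + good[3:])
        report = select_chains(summaries, min_keep=4)
        assert 3 not in report.selected_chains
        # exhaustive one-removal check: no other single removal does better
        best_single = None
        best_val = np.inf
        for drop in range(8):
            kept = [c for c in range(8) if c != drop]
            sub = summaries[summaries["chain"].isin(kept)]
            val = select_chains(sub, min_keep=len(kept)).max_rhat
            if val < best_val:
                best_val, best_single = val, drop
        assert best_single == 3

    def test_min_keep_respected_on_failure(self, rng):
        chains = [rng.normal(size=100) + 5 * c for c in range(10)]
        report = select_chains(self._summaries(chains), min_keep=8)
        assert len(report.selected_chains) == 8
        assert not report.converged


class TestCoOccupancy:
    def test_single_state_all_ones(self):
        C = co_occupancy(np.zeros(4, int))
        assert np.all(C)

    def test_direct_definition(self):
        C = co_occupancy(np.array([1, 1, 2]))
        np.testing.assert_array_equal(
            C, [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
        )

    def test_symmetric_unit_diagonal(self, rng):
        x = rng.integers(0, 4, size=30)
        C = co_occupancy(x)
        assert np.array_equal(C, C.T)
        assert np.all(np.diag(C))


class TestBinnedSimilarity:
    def test_identical_proportions_attain_L(self):
        x = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        M = binned_similarity(x, L=3, n_bins=2)
        assert M[0, 1] == pytest.approx(3.0)

    def test_one_hot_bins_differ_by_two(self):
        x = np.array([0, 0, 0, 2, 2, 2])
        M = binned_similarity(x, L=4, n_bins=2)
        # |1-0| + |0-1| = 2 total absolute difference
        assert M[0, 1] == pytest.approx(4 - 2)

    def test_maximal_iff_equal(self, rng):
        x = rng.integers(0, 3, size=60)
        M = binned_similarity(x, L=3, n_bins=6)
        assert np.all(M <= 3 + 1e-12)
        np.testing.assert_allclose(np.diag(M), 3.0)

    def test_single_trial_bins_order_matches_co_occupancy(self, rng):
        """With one trial per bin the similarity is an affine rescaling of the
        binary co-occupancy, so pair orderings agree."""
        x = rng.integers(0, 3, size=12)
        M = binned_similarity(x, L=5, n_bins=12)
        C = co_occupancy(x)
        iu = np.triu_indices(12, 1)
        np.testing.assert_allclose(M[iu], 5 - 2 * (1 - C[iu].astype(float)))


class TestModes:
    def test_identical_samples_single_mode(self):
        mats = np.ones((30, 5, 5))
        modes = embed_and_find_modes(mats, min_mode_samples=10)
        assert len(modes) == 1
        assert len(modes[0]) == 30

    def test_planted_partition_recovered(self, rng):
        a = np.zeros((4, 4))
        a[:2, :2] = 4
        b = np.zeros((4, 4))
        b[2:, 2:] = 4
        mats = np.array(
            [a + rng.normal(0, 0.05, (4, 4)) for _ in range(120)]
            + [b + rng.normal(0, 0.05, (4, 4)) for _ in range(80)]
        )
        modes = embed_and_find_modes(mats, min_mode_samples=40, seed=0)
        assert len(modes) == 2
        labels = np.zeros(200, int)
        labels[modes[1]] = 1
        truth = np.array([0] * 120 + [1] * 80)
        assert adjusted_rand_score(truth, labels) >= 0.95
        assert sum(len(m) for m in modes) <= 200

    def test_too_few_samples_single_mode(self, rng):
        mats = rng.normal(size=(12, 3, 3))
        modes = embed_and_find_modes(mats, min_mode_samples=400)
        assert len(modes) == 1 and len(modes[0]) == 12


class TestClusterTrials:
    def test_identical_samples_two_states_full_coverage(self):
        x = np.array([0, 0, 0, 1, 1, 1, 1])
        clustering = cluster_trials([x] * 20, cut=0.95, min_cluster_frac=0.0)
        assert clustering.n_states == 2
        assert clustering.coverage == 1.0
        # numbered by first appearance
        assert clustering.labels[0] == 1
        assert clustering.labels[-1] == 2
        np.testing.assert_allclose(clustering.connectedness, 1.0)

    def test_zero_cut_requires_perfect_coassignment(self, rng):
        xs = [rng.integers(0, 3, size=10) for _ in range(25)]
        xs.append(xs[0])
        clustering = cluster_trials(xs, cut=0.0, min_cluster_frac=0.0)
        C = mean_co_occupancy(xs)
        for s in range(1, clustering.n_states + 1):
            idx = clustering.trials_of(s)
            assert np.all(C[np.ix_(idx, idx)] >= 1.0 - 1e-12)

    def test_cut_monotonicity(self, rng):
        xs = [rng.integers(0, 3, size=40) for _ in range(30)]
        counts = []
        for cut in (0.2, 0.5, 0.8, 0.95):
            clustering = cluster_trials(xs, cut=cut, min_cluster_frac=0.0)
            counts.append(clustering.n_states)
        assert counts == sorted(counts, reverse=True)

    def test_pair_guarantee_at_cut(self, rng):
        xs = [rng.integers(0, 2, size=25) for _ in range(40)]
        cut = 0.6
        clustering = cluster_trials(xs, cut=cut, min_cluster_frac=0.0)
        C = mean_co_occupancy(xs)
        for s in range(1, clustering.n_states + 1):
            idx = clustering.trials_of(s)
            sub = C[np.ix_(idx, idx)]
            assert sub.min() >= 1 - cut - 1e-6


class TestConnectedness:
    def test_half_coassigned(self):
        x1 = np.array([0, 0, 0])
        x2 = np.array([0, 1, 0])
        C = mean_co_occupancy([x1, x2])
        labels = np.array([1, 1, 1])
        conn = trial_connectedness(labels, C)
        # trial 1 shares a state with trials 0 and 2 in half the samples
        assert conn[1] == pytest.approx(0.5)
        assert np.all(conn <= 1.0 + 1e-12)

    def test_singleton_convention(self):
        C = np.eye(3, dtype=np.float32)
        conn = trial_connectedness(np.array([1, 2, 0]), C)
        assert conn[0] == 1.0 and conn[1] == 1.0
        assert np.isnan(conn[2])


def _records_for(x, w_by_state, n_sessions):
    L = len(w_by_state)
    w = np.repeat(np.asarray(w_by_state, np.float32)[:, None, :], n_sessions, axis=1)
    return SampleRecord(
        x=np.asarray(x, np.int8), w=w,
        beta=np.full(L, 1 / L, np.float32), pi=np.full((L, L), 1 / L, np.float32),
        pi0=np.full(L, 1 / L, np.float32), r=np.full(L, 10, np.int32),
        p=np.full(L, 0.5, np.float32), alpha=1.0, gamma=1.0,
    )


@pytest.fixture
def flat_design():
    T = 12
    table = pd.DataFrame(
        {
            "session": np.ones(T, int),
            "trial": np.arange(1, T + 1),
            "contrast_left": [1.0, 0.0] * (T // 2),
            "contrast_right": [0.0, 1.0] * (T // 2),
            "choice": ["L", "R"] * (T // 2),
        }
    )
    return build_design(table)


class TestStatePMFs:
    def test_zero_weights_give_chance(self, flat_design):
        rec = _records_for(np.zeros(12), [[0.0, 0.0, 0.0, 0.0]], 1)
        from dihsmm.aggregation import StateClustering

        clustering = StateClustering(
            labels=np.ones(12, int), connectedness=np.ones(12),
            coverage=1.0, cut=0.95, n_states=1,
        )
        pmfs = state_pmfs(clustering, [rec], flat_design)
        np.testing.assert_allclose(pmfs["p_right"], 0.5)

    def test_tuned_weights_match_sigmoid(self, flat_design):
        rec = _records_for(np.zeros(12), [[-8.0, 8.0, 0.0, 0.0]], 1)
        from dihsmm.aggregation import StateClustering

        clustering = StateClustering(
            labels=np.ones(12, int), connectedness=np.ones(12),
            coverage=1.0, cut=0.95, n_states=1,
        )
        pmfs = state_pmfs(clustering, [rec], flat_design)
        s = pmfs.set_index("signed_contrast")["p_right"]
        sig8 = 1 / (1 + np.exp(-8))
        assert s[1.0] == pytest.approx(sig8, abs=1e-6)
        assert s[-1.0] == pytest.approx(1 - sig8, abs=1e-6)
        assert s[0.0] == pytest.approx(0.5)

    def test_averaging_identical_samples_is_idempotent(self, flat_design):
        rec = _records_for(np.zeros(12), [[-2.0, 2.0, 0.5, 0.3]], 1)
        from dihsmm.aggregation import StateClustering

        clustering = StateClustering(
            labels=np.ones(12, int), connectedness=np.ones(12),
            coverage=1.0, cut=0.95, n_states=1,
        )
        one = state_pmfs(clustering, [rec], flat_design)
        many = state_pmfs(clustering, [rec] * 7, flat_design)
        pd.testing.assert_frame_equal(one, many)
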