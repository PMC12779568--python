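"""From raw MCMC chains to label-switching-free behavioral states.

State labels carry no meaning across (or even within) chains, so states are
defined through trial co-occupancy: two trials belong together to the extent
that posterior samples assign them to the same state.  The pipeline is:

1. screen chains with R-hat (plain, folded, rank-normalized; chains are not
   split) on label-independent summary scalars, greedily discarding the worst
   chains down to a minimum count;
2. bin trials and compute per-sample binned co-occupancy-similarity matrices;
3. embed the flattened matrices with PCA and find posterior modes by Gaussian
   mixture density estimation, keeping modes with enough samples;
4. within a mode, average full-resolution co-occupancy across samples and
   complete-linkage cluster trials on 1 - C, cutting the dendrogram at a
   threshold (0.95 by default: every pair in a cluster shares a state in at
   least 5% of samples);
5. report per-trial connectedness and per-state per-session psychometric
   functions (PMFs), averaged over states weighted by how often they occur in
   the cluster's trials, then evenly over samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from scipy.stats import norm
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .trial_features import DesignMatrix, signed_contrast_grid, transform_contrast

__all__ = [
    "ConvergenceReport",
    "StateClustering",
    "AggregationResult",
    "compute_rhat",
    "select_chains",
    "co_occupancy",
    "binned_similarity",
    "embed_and_find_modes",
    "cluster_trials",
    "trial_connectedness",
    "state_pmfs",
    "state_weights",
    "aggregate_chains",
]

RHAT_VARIANTS = ("plain", "folded", "rank_normalized")


def compute_rhat(chains, variant: str = "plain", split: bool = False) -> float:
    """Potential scale reduction over parallel chains of equal length.

    ``chains`` is (m, n): m chains of n draws.  ``folded`` applies
    ``|x - median|`` first (variance-sensitive), ``rank_normalized`` maps
    pooled ranks through normal quantiles (shape-sensitive).  Chains are not
    split unless ``split=True``.  A series that is constant everywhere is
    defined to have R-hat 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (m >= 2, n) array of chains")
    if variant == "folded":
        x = np.abs(x - np.median(x))
    elif variant == "rank_normalized":
        flat = x.ravel()
        # average ranks for ties so identical chains stay identical
        order = pd.Series(flat).rank(method="average").to_numpy()
        z = norm.ppf((order - 3.0 / 8.0) / (flat.size + 0.25))
        x = z.reshape(x.shape)
    elif variant != "plain":
        raise ValueError(f"unknown R-hat variant {variant!r}")
    if split:
        half = x.shape[1] // 2
        x = np.vstack([x[:, :half], x[:, half : 2 * half]])
    m, n = x.shape
    if n < 2:
        raise ValueError("chains too short")
    W = x.var(axis=1, ddof=1).mean()
    B = n * x.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    # floored at 1: the (n-1)/n finite-sample deflation is not evidence of
    # convergence problems, and identical chains should report exactly 1
    return float(max(1.0, np.sqrt(var_plus / W)))


@dataclass
class ConvergenceReport:
    """R-hat screening outcome: per-feature/variant values and chain choice."""

    rhat: pd.DataFrame          # columns: feature, variant, rhat (after selection)
    selected_chains: list
    max_rhat: float
    threshold: float
    converged: bool


def _max_rhat(series: dict, chain_ids) -> tuple[float, pd.DataFrame]:
    rows = []
    for feat, mat in series.items():
        for variant in RHAT_VARIANTS:
            rows.append(
                {
                    "feature": feat,
                    "variant": variant,
                    "rhat": compute_rhat(mat[list(chain_ids)], variant),
                }
            )
    df = pd.DataFrame(rows)
    return float(df["rhat"].max()), df


def select_chains(
    summaries: pd.DataFrame,
    features=None,
    min_keep: int = 8,
    threshold: float = 1.05,
) -> ConvergenceReport:
    """Greedy chain selection by the max R-hat over all features and variants.

    While the max R-hat is at or above the threshold and more than
    ``min_keep`` chains remain, remove the chain whose removal lowers the max
    the most.  Failure to reach the threshold is reported, not raised: what
    to do with a non-converged animal is the caller's decision.
    """
    if features is None:
        features = [
            c for c in summaries.columns if c not in ("chain", "sample")
        ]
    chain_ids = sorted(summaries["chain"].unique())
    n = min(summaries.groupby("chain").size())
    series = {
        feat: np.vstack(
            [
                summaries.loc[summaries["chain"] == c, feat].to_numpy()[:n]
                for c in chain_ids
            ]
        )
        for feat in features
    }
    index = {c: k for k, c in enumerate(chain_ids)}
    kept = list(chain_ids)
    current, df = _max_rhat(series, [index[c] for c in kept])
    while current >= threshold and len(kept) > min_keep:
        best_val, best_chain, best_df = np.inf, None, None
        for c in kept:
            trial = [index[k] for k in kept if k != c]
            val, trial_df = _max_rhat(series, trial)
            if val < best_val:
                best_val, best_chain, best_df = val, c, trial_df
        kept.remove(best_chain)
        current, df = best_val, best_df
    return ConvergenceReport(
        rhat=df,
        selected_chains=kept,
        max_rhat=current,
        threshold=threshold,
        converged=bool(current < threshold),
    )


def co_occupancy(x: np.ndarray) -> np.ndarray:
    """Binary trial-by-trial same-state indicator for one sample."""
    x = np.asarray(x)
    return (x[:, None] == x[None, :])


def binned_similarity(x: np.ndarray, L: int, n_bins: int = 200) -> np.ndarray:
    """Coarse co-occupancy similarity between contiguous trial bins.

    Trials are cut into ``n_bins`` near-equal contiguous bins across the whole
    animal (ignoring session boundaries); entry (t, m) is
    ``sum_i (1 - |p_{t,i} - p_{m,i}|)`` over the L states, where ``p`` are
    within-bin state proportions.  Identical proportion vectors attain the
    maximum value L.
    """
    x = np.asarray(x)
    n_bins = min(n_bins, x.size)
    edges = np.linspace(0, x.size, n_bins + 1).astype(int)
    props = np.zeros((n_bins, L))
    for b in range(n_bins):
        seg = x[edges[b] : edges[b + 1]]
        props[b] = np.bincount(seg, minlength=L) / max(len(seg), 1)
    return L - cdist(props, props, metric="cityblock")


def embed_and_find_modes(
    binned_mats,
    n_components: int = 3,
    min_mode_samples: int = 400,
    max_modes: int = 4,
    seed: int = 0,
):
    """Posterior modes among samples, via PCA + Gaussian mixture density.

    ``binned_mats`` is (J, B, B) or (J, B*B).  Samples are embedded in the
    top principal components; mixtures with 1..max_modes components are
    scored by BIC; components holding at least ``min_mode_samples`` samples
    become modes, largest first.  With too few samples overall (or no
    sufficiently large component), all samples form a single mode.
    """
    X = np.asarray(binned_mats, dtype=np.float32).reshape(len(binned_mats), -1)
    J = X.shape[0]
    if J < max(min_mode_samples, 2):
        return [np.arange(J)]
    k = min(n_components, J - 1, X.shape[1])
    emb = PCA(n_components=k, svd_solver="randomized", random_state=seed).fit_transform(X)
    if np.allclose(emb.std(axis=0), 0):
        return [np.arange(J)]
    best_labels, best_bic = None, np.inf
    for n_comp in range(1, max_modes + 1):
        gm = GaussianMixture(
            n_components=n_comp, covariance_type="full", random_state=seed,
            n_init=2, reg_covar=1e-4,
        ).fit(emb)
        bic = gm.bic(emb)
        if bic < best_bic:
            best_bic, best_labels = bic, gm.predict(emb)
    modes = []
    labels, counts = np.unique(best_labels, return_counts=True)
    for lab in labels[np.argsort(counts)[::-1]]:
        members = np.flatnonzero(best_labels == lab)
        if len(members) >= min_mode_samples:
            modes.append(members)
    if not modes:
        return [np.arange(J)]
    return modes


@dataclass
class StateClustering:
    """Label-switching-free output: trial -> state map and diagnostics.

    ``labels`` maps each trial to a cluster-state numbered 1.. in order of
    first appearance; 0 marks unassigned trials (clusters below the minimum
    size).  ``connectedness`` is the mean co-assignment of a trial with the
    other trials of its state (singleton states: 1 by convention).
    """

    labels: np.ndarray
    connectedness: np.ndarray
    coverage: float
    cut: float
    n_states: int

    def trials_of(self, state: int) -> np.ndarray:
        return np.flatnonzero(self.labels == state)


def mean_co_occupancy(x_samples) -> np.ndarray:
    """Mode-averaged co-occupancy, accumulated as a running single-precision
    mean (per-sample matrices are never all held at once)."""
    T = len(x_samples[0])
    C = np.zeros((T, T), dtype=np.float32)
    for j, x in enumerate(x_samples):
        C += (co_occupancy(x).astype(np.float32) - C) / (j + 1)
    return C


def cluster_trials(
    x_samples,
    cut: float = 0.95,
    min_cluster_frac: float = 0.01,
    C: np.ndarray | None = None,
) -> StateClustering:
    """Complete-linkage clustering of trials on the averaged co-occupancy.

    ``1 - C`` is treated as a distance; cutting the dendrogram at ``cut``
    guarantees that every pair of trials within a cluster shared a state in
    at least ``1 - cut`` of the samples.  Clusters holding fewer than
    ``min_cluster_frac`` of trials are left unassigned (label 0).
    """
    if C is None:
        C = mean_co_occupancy(x_samples)
    T = C.shape[0]
    D = 1.0 - C.astype(np.float64)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="complete")
    raw = fcluster(Z, t=cut, criterion="distance")
    min_size = max(1, int(np.ceil(min_cluster_frac * T)))
    labels = np.zeros(T, dtype=int)
    next_label = 1
    seen = set()
    for t in range(T):
        c = raw[t]
        if c in seen:
            continue
        seen.add(c)
        members = raw == c
        if members.sum() >= min_size:
            labels[members] = next_label
            next_label += 1
    connectedness = trial_connectedness(labels, C)
    coverage = float((labels > 0).mean())
    return StateClustering(
        labels=labels,
        connectedness=connectedness,
        coverage=coverage,
        cut=cut,
        n_states=next_label - 1,
    )


def trial_connectedness(labels: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Mean co-assignment of each trial with the rest of its cluster-state.

    Unassigned trials get NaN; a trial alone in its state gets 1.
    """
    T = len(labels)
    out = np.full(T, np.nan)
    for state in np.unique(labels[labels > 0]):
        idx = np.flatnonzero(labels == state)
        if len(idx) == 1:
            out[idx] = 1.0
            continue
        sub = C[np.ix_(idx, idx)].astype(np.float64)
        out[idx] = (sub.sum(axis=1) - 1.0) / (len(idx) - 1)
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _pmf_features(grid, steepness):
    """Design rows over the signed-contrast grid: perseveration 0, bias 1."""
    cl = np.where(grid < 0, -grid, 0.0)
    cr = np.where(grid > 0, grid, 0.0)
    return np.column_stack([
        transform_contrast(cl, steepness),
        transform_contrast(cr, steepness),
        np.zeros_like(grid),
        np.ones_like(grid),
    ])


def state_pmfs(
    clustering: StateClustering,
    samples,
    design: DesignMatrix,
    steepness: float = 5.0,
    grid=None,
) -> pd.DataFrame:
    """Per-cluster-state, per-session psychometric functions.

    For each mode sample and session, the PMFs of the sample's own states are
    averaged weighted by how many of the cluster's trials each state owns;
    the result is then averaged evenly across samples.  Sessions in which a
    cluster owns no trials are omitted (undefined there).

    Returns a tidy frame (state, session, signed_contrast, p_right).
    """
    if grid is None:
        grid = signed_contrast_grid()
    Fg = _pmf_features(np.asarray(grid, float), steepness)
    rows = []
    for state in range(1, clustering.n_states + 1):
        trials = clustering.trials_of(state)
        for n in range(1, design.n_sessions + 1):
            sl = design.session_slice(n)
            in_session = trials[(trials >= sl.start) & (trials < sl.stop)]
            if in_session.size == 0:
                continue
            acc = np.zeros(len(grid))
            for rec in samples:
                occ = np.bincount(rec.x[in_session], minlength=rec.w.shape[0])
                states = np.flatnonzero(occ)
                pmfs = _sigmoid(Fg @ rec.w[states, n - 1].T)  # (grid, k)
                acc += pmfs @ (occ[states] / occ[states].sum())
            acc /= len(samples)
            for g, val in zip(grid, acc):
                rows.append((state, n, float(g), float(val)))
    return pd.DataFrame(
        rows, columns=["state", "session", "signed_contrast", "p_right"]
    )


def state_weights(
    clustering: StateClustering, samples, design: DesignMatrix
) -> pd.DataFrame:
    """Per-cluster-state, per-session regression weights, averaged like PMFs."""
    K = samples[0].w.shape[2]
    rows = []
    for state in range(1, clustering.n_states + 1):
        trials = clustering.trials_of(state)
        for n in range(1, design.n_sessions + 1):
            sl = design.session_slice(n)
            in_session = trials[(trials >= sl.start) & (trials < sl.stop)]
            if in_session.size == 0:
                continue
            acc = np.zeros(K)
            for rec in samples:
                occ = np.bincount(rec.x[in_session], minlength=rec.w.shape[0])
                states = np.flatnonzero(occ)
                acc += (occ[states] / occ[states].sum()) @ rec.w[states, n - 1]
            acc /= len(samples)
            rows.append((state, n, *acc.tolist()))
    return pd.DataFrame(
        rows,
        columns=["state", "session"] + [f"w{k}" for k in range(K)],
    )


@dataclass
class AggregationResult:
    """Everything the downstream classification needs from one posterior mode."""

    report: ConvergenceReport
    mode_sample_ids: np.ndarray
    clustering: StateClustering
    pmfs: pd.DataFrame
    weights: pd.DataFrame
    n_modes: int


def aggregate_chains(
    chainset,
    design: DesignMatrix,
    cut: float = 0.95,
    n_bins: int = 200,
    min_mode_samples: int = 400,
    min_cluster_frac: float = 0.01,
    min_keep: int | None = None,
    rhat_threshold: float = 1.05,
    seed: int = 0,
    require_converged: bool = True,
) -> AggregationResult:
    """Full aggregation pipeline on a ChainSet; analyses the largest mode."""
    min_keep = min_keep if min_keep is not None else max(
        chainset.n_chains // 2, min(chainset.n_chains, 2)
    )
    report = select_chains(
        chainset.summaries, min_keep=min_keep, threshold=rhat_threshold
    )
    if require_converged and not report.converged:
        raise RuntimeError(
            f"chains failed convergence screening (max R-hat {report.max_rhat:.3f})"
        )
    samples = chainset.pooled_samples(report.selected_chains)
    L = chainset.hyper.L
    binned = np.stack(
        [binned_similarity(rec.x, L, n_bins).astype(np.float32) for rec in samples]
    )
    modes = embed_and_find_modes(
        binned, min_mode_samples=min_mode_samples, seed=seed
    )
    mode_ids = modes[0]
    mode_samples = [samples[j] for j in mode_ids]
    clustering = cluster_trials(
        [rec.x for rec in mode_samples], cut=cut, min_cluster_frac=min_cluster_frac
    )
    pmfs = state_pmfs(
        clustering, mode_samples, design, steepness=chainset.hyper.steepness
    )
    weights = state_weights(clustering, mode_samples, design)
    return AggregationResult(
        report=report,
        mode_sample_ids=mode_ids,
        clustering=clustering,
        pmfs=pmfs,
        weights=weights,
        n_modes=len(modes),
    )
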