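"""Psychometric types, learning stages, and slow-vs-fast weight changes.

State PMFs fall into three characteristic classes, separated by the reward
rate they imply on easy trials (100% and 50% contrast, perseveration
ignored): flat (type 1, rate below 0.60), one-sided (type 2, up to 0.78) and
fully tuned (type 3).  Because weights drift, a state's type is re-evaluated
per session.  Type 2 states are subtyped symmetric / left-biased /
right-biased.  The animal's stage on a session is the highest type it has so
far used for a strict majority of any session's trials — by construction a
monotone summary of progress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import StateClustering
from .trial_features import DesignMatrix

__all__ = [
    "TYPE_BOUNDARIES",
    "StageReport",
    "easy_reward_rate",
    "classify_type",
    "classify_type2_subtype",
    "typed_states",
    "state_session_counts",
    "assign_stages",
    "state_introductions",
    "nearest_previous_state",
    "pmf_distance",
    "weight_change_summary",
]

#: Reward-rate boundaries: below the first -> type 1, below the second ->
#: type 2, otherwise type 3.
TYPE_BOUNDARIES = (0.60, 0.78)

#: A PMF is symmetric if its 100%-contrast error rates differ by at most this.
SYMMETRY_BAND = 0.10

#: A PMF counts as biased if its average choice is more than this from 50%.
BIAS_BAND = 0.05


def _pmf_series(pmf) -> pd.Series:
    if isinstance(pmf, pd.Series):
        return pmf.sort_index()
    return pd.Series(dict(pmf)).sort_index()


def easy_reward_rate(pmf) -> float:
    """Mean implied reward rate on the four easy stimuli (signed contrasts
    -1, -0.5, +0.5, +1): P(correct) averaged over them."""
    s = _pmf_series(pmf)
    needed = [-1.0, -0.5, 0.5, 1.0]
    if not all(c in s.index for c in needed):
        raise ValueError("PMF must be defined at signed contrasts ±1 and ±0.5")
    p_correct = [1 - s[-1.0], 1 - s[-0.5], s[0.5], s[1.0]]
    return float(np.mean(p_correct))


def classify_type(rate: float, boundaries=TYPE_BOUNDARIES) -> int:
    """Map an easy-trial reward rate onto a state type 1/2/3."""
    if not 0 <= rate <= 1:
        raise ValueError("reward rate must lie in [0, 1]")
    if rate < boundaries[0]:
        return 1
    if rate < boundaries[1]:
        return 2
    return 3


def classify_type2_subtype(pmf) -> str:
    """Subtype of a half-tuned PMF: symmetric, left-biased, or right-biased.

    Symmetric if the error rates on the two 100% contrasts are within
    ``SYMMETRY_BAND`` of each other.  Otherwise the direction is read from
    the average choice over the contrast grid: more than ``BIAS_BAND`` below
    50% is left-biased, otherwise right-biased.
    """
    s = _pmf_series(pmf)
    err_left = float(s[-1.0])        # P(R | 100% left) is an error
    err_right = 1.0 - float(s[1.0])  # P(L | 100% right) is an error
    if abs(err_left - err_right) <= SYMMETRY_BAND:
        return "symmetric"
    return "left-biased" if float(s.mean()) < 0.5 else "right-biased"


def typed_states(pmfs: pd.DataFrame) -> pd.DataFrame:
    """Per-state, per-session classification of an aggregated PMF table.

    Expects the tidy (state, session, signed_contrast, p_right) frame from
    the aggregation step; sessions whose PMF lacks the easy contrasts
    (because those stimuli were not yet defined for that state) are skipped.

    Returns a frame (state, session, reward_rate, type, subtype).
    """
    rows = []
    for (state, session), grp in pmfs.groupby(["state", "session"]):
        s = grp.set_index("signed_contrast")["p_right"]
        try:
            rate = easy_reward_rate(s)
        except ValueError:
            continue
        t = classify_type(rate)
        subtype = classify_type2_subtype(s) if t == 2 else ""
        rows.append((state, session, rate, t, subtype))
    return pd.DataFrame(
        rows, columns=["state", "session", "reward_rate", "type", "subtype"]
    )


def state_session_counts(
    clustering: StateClustering, design: DesignMatrix
) -> pd.DataFrame:
    """Non-timeout trial counts per (state, session) for stage majorities."""
    rows = []
    ok = ~design.is_timeout
    for n in range(1, design.n_sessions + 1):
        sl = design.session_slice(n)
        labels = clustering.labels[sl][ok[sl]]
        for state in np.unique(labels):
            rows.append((int(state), n, int((labels == state).sum())))
    return pd.DataFrame(rows, columns=["state", "session", "n_trials"])


@dataclass
class StageReport:
    """Monotone per-session stages and per-type usage fractions."""

    stages: pd.DataFrame        # session, stage, frac_type1, frac_type2, frac_type3
    majority_types: np.ndarray  # per-session majority type (0 = none)


def assign_stages(
    counts: pd.DataFrame, typed: pd.DataFrame, n_sessions: int | None = None
) -> StageReport:
    """Stage per session: the highest type ever used for a strict majority.

    ``counts`` is the (state, session, n_trials) frame over non-timeout
    trials, ``typed`` the per-(state, session) type table.  A type must
    exceed 50% of a session's counted trials to take that session's majority;
    a 50/50 split advances nothing.  Sessions before any majority are stage 1.
    """
    if n_sessions is None:
        n_sessions = int(counts["session"].max())
    type_of = {
        (row.state, row.session): row.type for row in typed.itertuples()
    }
    frac = np.zeros((n_sessions, 3))
    majority = np.zeros(n_sessions, dtype=int)
    for n in range(1, n_sessions + 1):
        sess = counts[counts["session"] == n]
        total = sess["n_trials"].sum()
        if total == 0:
            continue
        for row in sess.itertuples():
            t = type_of.get((row.state, n))
            if t is not None:
                frac[n - 1, t - 1] += row.n_trials / total
        for t in (3, 2, 1):
            if frac[n - 1, t - 1] > 0.5:
                majority[n - 1] = t
                break
    stage = np.maximum.accumulate(np.maximum(majority, 1))
    stages = pd.DataFrame(
        {
            "session": np.arange(1, n_sessions + 1),
            "stage": stage,
            "frac_type1": frac[:, 0],
            "frac_type2": frac[:, 1],
            "frac_type3": frac[:, 2],
        }
    )
    return StageReport(stages=stages, majority_types=majority)


def stage_occupancy(stages: pd.DataFrame) -> pd.DataFrame:
    """Fraction of sessions spent in each stage — the animal's simplex
    coordinates for population stage-occupancy plots."""
    n = len(stages)
    fractions = [
        float((stages["stage"] == s).sum()) / n if n else np.nan
        for s in (1, 2, 3)
    ]
    return pd.DataFrame(
        [fractions + [n]],
        columns=["frac_stage1", "frac_stage2", "frac_stage3", "n_sessions"],
    )


def state_introductions(
    clustering: StateClustering,
    design: DesignMatrix,
    typed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """First-appearance events of every state except the animal's first.

    Positions are normalised as (index - 1) / (count - 1): 0 is the first
    trial of training (or session), 1 the last.
    """
    T = design.n_trials
    rows = []
    first_trials = {}
    for state in range(1, clustering.n_states + 1):
        trials = clustering.trials_of(state)
        if trials.size:
            first_trials[state] = int(trials.min())
    if not first_trials:
        return pd.DataFrame(
            columns=["state", "session", "trial", "training_pos", "session_pos",
                     "type_at_introduction"]
        )
    first_state = min(first_trials, key=first_trials.get)
    for state, t0 in sorted(first_trials.items(), key=lambda kv: kv[1]):
        if state == first_state:
            continue
        session = int(design.session[t0])
        trial = int(design.trial[t0])
        T_sess = int(design.session_lengths[session - 1])
        training_pos = t0 / (T - 1) if T > 1 else 0.0
        session_pos = (trial - 1) / (T_sess - 1) if T_sess > 1 else 0.0
        t_intro = 0
        if typed is not None:
            match = typed[(typed["state"] == state) & (typed["session"] == session)]
            t_intro = int(match["type"].iloc[0]) if len(match) else 0
        rows.append((state, session, trial, training_pos, session_pos, t_intro))
    return pd.DataFrame(
        rows,
        columns=["state", "session", "trial", "training_pos", "session_pos",
                 "type_at_introduction"],
    )


def bias_concordance_test(n_same: int, n_total: int) -> float:
    """Two-sided exact binomial test of bias-direction concordance.

    Used at the population level to ask whether the fraction of animals whose
    new state expresses a previously seen bias direction differs from chance
    (0.5).  Returns the p-value.
    """
    from scipy.stats import binomtest

    return float(binomtest(n_same, n_total, 0.5, alternative="two-sided").pvalue)


def pmf_distance(pmf_a, pmf_b) -> float:
    """Distance between two PMFs on a shared signed-contrast grid.

    The 1-Wasserstein distance between the P(R) curves viewed as functions on
    the grid: the mean absolute difference across grid points.
    """
    a, b = _pmf_series(pmf_a), _pmf_series(pmf_b)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("PMFs share no grid points")
    return float(np.mean(np.abs(a[common].to_numpy() - b[common].to_numpy())))


def nearest_previous_state(new_pmf, existing: dict) -> tuple:
    """Closest existing state to a new PMF (perseveration plays no role:
    PMFs are evaluated with that feature at zero).  Returns (state, distance)."""
    if not existing:
        raise ValueError("no existing states to compare against")
    dists = {s: pmf_distance(new_pmf, p) for s, p in existing.items()}
    best = min(dists, key=dists.get)
    return best, dists[best]


def weight_change_summary(
    typed: pd.DataFrame,
    weights: pd.DataFrame,
    pmfs: pd.DataFrame,
    min_sessions: int = 5,
    max_sessions: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slow (within-state) and fast (state-introduction) weight changes.

    Slow: per state present between ``min_sessions`` and ``max_sessions``
    sessions, the per-feature weight difference between its last and first
    appearance.  Fast: for each state except the first, the difference
    between its weights at introduction and those of the nearest previously
    existing state (by PMF distance) on the preceding session it was seen.
    Bias rows carry the sign group of the starting bias so left and right
    biases do not cancel when averaged.
    """
    wcols = [c for c in weights.columns if c.startswith("w")]
    slow_rows, fast_rows = [], []
    first_session = {
        s: int(g["session"].min()) for s, g in weights.groupby("state")
    }
    for state, grp in weights.groupby("state"):
        grp = grp.sort_values("session")
        n_present = len(grp)
        if min_sessions <= n_present <= max_sessions:
            delta = grp[wcols].iloc[-1].to_numpy() - grp[wcols].iloc[0].to_numpy()
            bias0 = grp[wcols[-1]].iloc[0]
            slow_rows.append(
                (state, n_present, *delta,
                 "left" if bias0 < 0 else "right")
            )
    order = sorted(first_session, key=first_session.get)
    for k, state in enumerate(order):
        if k == 0:
            continue
        intro = first_session[state]
        prev_states = {}
        for other in order[:k]:
            prev = pmfs[(pmfs["state"] == other) & (pmfs["session"] < intro)]
            if len(prev) == 0:
                continue
            last = prev["session"].max()
            prev_states[other] = prev[prev["session"] == last].set_index(
                "signed_contrast"
            )["p_right"]
        new_pmf = pmfs[(pmfs["state"] == state) & (pmfs["session"] == intro)]
        if not prev_states or len(new_pmf) == 0:
            continue
        nearest, dist = nearest_previous_state(
            new_pmf.set_index("signed_contrast")["p_right"], prev_states
        )
        w_new = weights[(weights["state"] == state)
                        & (weights["session"] == intro)][wcols].iloc[0].to_numpy()
        prev_sess = weights[(weights["state"] == nearest)
                            & (weights["session"] < intro)]["session"].max()
        w_old = weights[(weights["state"] == nearest)
                        & (weights["session"] == prev_sess)][wcols].iloc[0].to_numpy()
        delta = w_new - w_old
        fast_rows.append(
            (state, nearest, intro, dist, *delta,
             "left" if w_old[-1] < 0 else "right")
        )
    slow = pd.DataFrame(
        slow_rows,
        columns=["state", "n_sessions", *(f"d_{c}" for c in wcols), "bias_group"],
    )
    fast = pd.DataFrame(
        fast_rows,
        columns=["state", "nearest_state", "session", "pmf_distance",
                 *(f"d_{c}" for c in wcols), "bias_group"],
    )
    return slow, fast
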