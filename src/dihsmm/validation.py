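"""Cross-validation, posterior predictive checks, and model recovery.

Held-out trials are masked missing-at-random: during fitting their emission
likelihood is 1 (they keep their slot in the duration/transition structure),
and the fit is scored by the summed negative log-likelihood of the held-out
responses under the posterior-averaged per-trial predictive probability.

Posterior predictive checks free-run the fitted model: each posterior sample
seeds each session with that sample's actual first-trial state, then states,
durations and choices evolve on their own (the perseveration feature is
recomputed from the simulated choices), and empirical session accuracies and
per-contrast choice fractions are located as percentiles within the
simulated distribution.

The recovery harness simulates from known ground truth, fits with
scaled-down chains, aggregates, and compares the result to the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import percentileofscore
from sklearn.metrics import adjusted_rand_score

from .aggregation import AggregationResult, aggregate_chains, _sigmoid, _pmf_features
from .gibbs import ChainConfig, run_chains
from .model import (
    HyperParams,
    ModelSample,
    generate_task_schedule,
    sample_duration,
    simulate_dataset,
    zero_diag_renorm,
)
from .trial_features import DesignMatrix, build_design

__all__ = [
    "make_cv_masks",
    "heldout_negloglik",
    "PPCResult",
    "ppc_simulate",
    "RecoveryReport",
    "recovery_experiment",
    "DESK_SCALE_CHAINS",
]

#: Scaled-down chain settings used by the recovery harness and tests.
DESK_SCALE_CHAINS = dict(n_chains=2, n_samples=1000, burn_in=300, thin=2)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def make_cv_masks(
    design: DesignMatrix, n_folds: int = 10, rng: np.random.Generator | None = None
):
    """Per-session random partition of trials into folds.

    Returns a list of ``n_folds`` boolean held-out masks that partition the
    trials; each fold holds out ~1/n_folds of every session (at least one
    trial even in tiny sessions).
    """
    rng = rng if rng is not None else np.random.default_rng()
    fold_of = np.empty(design.n_trials, dtype=int)
    for n in range(1, design.n_sessions + 1):
        sl = design.session_slice(n)
        T = sl.stop - sl.start
        perm = rng.permutation(T)
        fold_of[sl] = perm % n_folds
    return [fold_of == k for k in range(n_folds)]


def heldout_negloglik(samples, design: DesignMatrix, heldout) -> float:
    """Summed negative log predictive likelihood of the held-out responses.

    For each evaluation sample, the predictive probability of a held-out
    trial comes from the state that sample assigns to the trial and that
    state's weights for the trial's session; probabilities are averaged
    across samples before the log.  Timeout trials are skipped.
    """
    heldout = np.asarray(heldout, dtype=bool)
    eval_idx = np.flatnonzero(heldout & ~design.is_timeout)
    if eval_idx.size == 0:
        return 0.0
    probs = np.zeros(eval_idx.size)
    sess = design.session[eval_idx] - 1
    F = design.F[eval_idx]
    y = design.y[eval_idx]
    for rec in samples:
        w = rec.w[rec.x[eval_idx], sess]  # (n_eval, K)
        p_right = _sigmoid(np.einsum("tk,tk->t", F, w.astype(float)))
        probs += np.where(y == 1, p_right, 1.0 - p_right)
    probs /= len(samples)
    return float(-np.log(np.clip(probs, 1e-300, 1.0)).sum())


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

@dataclass
class PPCResult:
    """Empirical metrics located within the free-run simulated distribution."""

    percent_correct: pd.DataFrame  # session, empirical, sim_mean, percentile
    percent_right: pd.DataFrame    # signed_contrast, empirical, sim_mean, percentile
    n_simulations: int


def _free_run_session(rec, first_state, cl, cr, rewarded, hp, rng):
    """Free-run one session under one posterior sample; returns choices."""
    T = len(cl)
    tl = np.tanh(hp.steepness * cl) / np.tanh(hp.steepness)
    tr = np.tanh(hp.steepness * cr) / np.tanh(hp.steepness)
    pi_bar = zero_diag_renorm(rec.pi.astype(float))
    lam = np.exp(-hp.decay)
    S = Z = 0.0
    state = first_state
    remaining = sample_duration(int(rec.r[state]), float(rec.p[state]), rng)
    y = np.zeros(T, dtype=int)
    for t in range(T):
        if remaining == 0:
            if pi_bar[state].sum() > 0:
                state = rng.choice(len(pi_bar), p=pi_bar[state])
            remaining = sample_duration(int(rec.r[state]), float(rec.p[state]), rng)
        pers = S / Z if Z > 0 else 0.0
        # session index for weights: the caller passes session-resolved w
        w = rec.w[state]
        psi = tl[t] * w[0] + tr[t] * w[1] + pers * w[2] + w[3]
        y[t] = int(rng.random() < _sigmoid(psi))
        enc = 1.0 if y[t] else -1.0
        S = lam * (enc + S)
        Z = lam * (1.0 + Z)
        remaining -= 1
    return y


@dataclass
class _SessionSample:
    """Session-sliced view of a posterior sample for free-running."""

    pi: np.ndarray
    r: np.ndarray
    p: np.ndarray
    w: np.ndarray  # (L, K) weights of one session


def ppc_simulate(
    samples,
    table: pd.DataFrame,
    design: DesignMatrix,
    hp: HyperParams,
    rng: np.random.Generator,
    reps_per_sample: int = 3,
) -> PPCResult:
    """Posterior predictive check by unguided simulation.

    Each posterior sample free-runs every session ``reps_per_sample`` times,
    initialised with that sample's state on the session's first trial (the
    initial distribution is static, so a random start would mix proficient
    and naive behavior).  Metrics: per-session percent correct and percent
    rightward per signed contrast; the empirical value's percentile is taken
    within the pooled simulated distribution.
    """
    n_sessions = design.n_sessions
    cl = table["contrast_left"].to_numpy(float)
    cr = table["contrast_right"].to_numpy(float)
    rewarded = table["rewarded_side"].to_numpy()
    signed = np.where(cl > 0, -cl, cr)
    emp_choice = design.y  # -1 timeout, 0 L, 1 R
    ok = emp_choice >= 0

    n_sim = len(samples) * reps_per_sample
    sim_correct = np.zeros((n_sim, n_sessions))
    grid = np.unique(signed)
    sim_right = np.zeros((n_sim, len(grid)))
    run = 0
    for rec in samples:
        for _ in range(reps_per_sample):
            right_acc = np.zeros(len(grid))
            right_cnt = np.zeros(len(grid))
            for n in range(1, n_sessions + 1):
                sl = design.session_slice(n)
                first_state = int(rec.x[sl.start])
                sess_rec = _SessionSample(
                    pi=rec.pi, r=rec.r, p=rec.p, w=rec.w[:, n - 1].astype(float)
                )
                y = _free_run_session(
                    sess_rec, first_state, cl[sl], cr[sl], rewarded[sl], hp, rng
                )
                correct = (np.where(y == 1, "R", "L") == rewarded[sl])
                sim_correct[run, n - 1] = 100.0 * correct.mean()
                for g_idx, g in enumerate(grid):
                    m = signed[sl] == g
                    right_acc[g_idx] += y[m].sum()
                    right_cnt[g_idx] += m.sum()
            sim_right[run] = 100.0 * right_acc / np.maximum(right_cnt, 1)
            run += 1

    pc_rows = []
    for n in range(1, n_sessions + 1):
        sl = design.session_slice(n)
        m = ok[sl]
        emp = 100.0 * (
            (np.where(emp_choice[sl][m] == 1, "R", "L") == rewarded[sl][m]).mean()
        ) if m.any() else np.nan
        dist = sim_correct[:, n - 1]
        pc_rows.append(
            (n, emp, dist.mean(), percentileofscore(dist, emp, kind="mean"))
        )
    pr_rows = []
    for g_idx, g in enumerate(grid):
        m = (signed == g) & ok
        emp = 100.0 * (emp_choice[m] == 1).mean() if m.any() else np.nan
        dist = sim_right[:, g_idx]
        pr_rows.append(
            (float(g), emp, dist.mean(), percentileofscore(dist, emp, kind="mean"))
        )
    return PPCResult(
        percent_correct=pd.DataFrame(
            pc_rows, columns=["session", "empirical", "sim_mean", "percentile"]
        ),
        percent_right=pd.DataFrame(
            pr_rows,
            columns=["signed_contrast", "empirical", "sim_mean", "percentile"],
        ),
        n_simulations=n_sim,
    )


# ---------------------------------------------------------------------------
# model recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Outcome of one simulate -> fit -> aggregate -> compare experiment."""

    scenario: str
    n_cluster_states: int
    dominant_frac: float
    ari: float
    pmf_max_abs_err: float
    coverage: float
    aggregation: AggregationResult = field(repr=False)
    table: pd.DataFrame = field(repr=False)
    true_model: ModelSample = field(repr=False)


def _one_state_model(n_sessions: int, w_per_session: np.ndarray) -> ModelSample:
    """Ground-truth model with a single always-active state."""
    model = ModelSample(
        beta=np.array([1.0]),
        pi0=np.array([1.0]),
        pi=np.array([[1.0]]),
        alpha=1.0,
        gamma=1.0,
        r=np.array([100]),
        p=np.array([0.5]),
        w=w_per_session[None, :, :],
    )
    return model


def _scenario_model(scenario: str, n_sessions: int, k: int, rng):
    K = 4
    if scenario == "static_1state":
        w = np.tile(np.array([-4.0, 4.0, 1.0, 0.0]), (n_sessions, 1))
        return _one_state_model(n_sessions, w), None
    if scenario in ("drifting_1state", "per_trial_drift"):
        # constant per-session steps whose magnitude corresponds to a
        # variance of 0.0311 (the fitted walk uses sigma = 0.03)
        step = np.sqrt(0.0311)
        w0 = np.array([-0.8, 0.8, 0.5, 0.7])
        drift = np.array([-step, step, 0.0, -0.05])
        w = np.vstack([w0 + n * drift for n in range(n_sessions)])
        return _one_state_model(n_sessions, w), drift
    if scenario == "k_states":
        presets = np.array(
            [
                [0.0, 0.0, 0.5, -1.5],   # flat, left-biased
                [-1.0, 5.0, 0.5, 1.0],   # right-sided
                [-5.0, 5.0, 0.5, 0.0],   # fully tuned
                [0.0, 0.0, 0.3, 1.5],    # flat, right-biased
                [5.0, -1.0, 0.5, -1.0],  # left-sided
                [-3.0, 3.0, 1.0, 0.5],
                [0.0, 2.0, 0.0, -0.5],
                [-2.0, 0.0, 0.0, 0.5],
                [-6.0, 6.0, 0.0, 0.0],
            ]
        )[:k]
        w = np.repeat(presets[:, None, :], n_sessions, axis=1)
        model = ModelSample(
            beta=np.full(k, 1.0 / k),
            pi0=np.full(k, 1.0 / k),
            pi=np.full((k, k), 1.0 / k),
            alpha=1.0,
            gamma=1.0,
            r=np.full(k, 60),
            p=np.full(k, 0.25),
            w=w,
        )
        return model, None
    if scenario == "implausible_pmfs":
        presets = np.array(
            [
                [4.0, -4.0, 0.0, 0.0],   # anti-tuned
                [0.0, 0.0, -2.0, 0.0],   # alternating
                [-3.0, -3.0, 0.0, 2.0],  # pushed right by any stimulus? no: left
                [2.0, 2.0, 1.0, -2.0],
            ])[:max(k, 4)]
        kk = len(presets)
        w = np.repeat(presets[:, None, :], n_sessions, axis=1)
        model = ModelSample(
            beta=np.full(kk, 1.0 / kk), pi0=np.full(kk, 1.0 / kk),
            pi=np.full((kk, kk), 1.0 / kk), alpha=1.0, gamma=1.0,
            r=np.full(kk, 20), p=np.full(kk, 0.2), w=w,
        )
        return model, None
    raise ValueError(f"unknown scenario {scenario!r}")


def _simulate_per_trial_drift(model, schedule, rng, hp, timeout_prob):
    """Single drifting state whose weights step every trial, not per session.

    The per-session weight trajectory of the model is linearly interpolated
    across trials (a generative process outside the model class); the model's
    stored per-session weights remain the session-start values for scoring.
    """
    session = schedule["session"].to_numpy(int)
    lengths = schedule.groupby("session").size().to_numpy()
    T = len(schedule)
    starts = np.concatenate([[0], np.cumsum(lengths)])
    w_sess = model.w[0]  # (N, K)
    w_trial = np.empty((T, w_sess.shape[1]))
    for n in range(len(lengths)):
        nxt = w_sess[min(n + 1, len(lengths) - 1)]
        frac = np.arange(lengths[n]) / max(lengths[n], 1)
        w_trial[starts[n] : starts[n + 1]] = (
            w_sess[n][None, :] * (1 - frac[:, None]) + nxt[None, :] * frac[:, None]
        )
    cl = schedule["contrast_left"].to_numpy(float)
    cr = schedule["contrast_right"].to_numpy(float)
    tl = np.tanh(hp.steepness * cl) / np.tanh(hp.steepness)
    tr = np.tanh(hp.steepness * cr) / np.tanh(hp.steepness)
    lam = np.exp(-hp.decay)
    S = Z = 0.0
    prev_session = None
    choice = np.empty(T, dtype=object)
    for t in range(T):
        if session[t] != prev_session:
            S = Z = 0.0
            prev_session = session[t]
        pers = S / Z if Z > 0 else 0.0
        if timeout_prob > 0 and rng.random() < timeout_prob:
            choice[t] = "timeout"
            enc = 0.0
        else:
            psi = tl[t] * w_trial[t, 0] + tr[t] * w_trial[t, 1] \
                + pers * w_trial[t, 2] + w_trial[t, 3]
            y = rng.random() < _sigmoid(psi)
            choice[t] = "R" if y else "L"
            enc = 1.0 if y else -1.0
        S = lam * (enc + S)
        Z = lam * (1.0 + Z)
    table = schedule.copy()
    table["choice"] = choice
    table["true_state"] = 0
    model = model.copy()
    model.x = np.zeros(T, dtype=int)
    model.z = [np.array([0]) for _ in lengths]
    model.d = [np.array([ln]) for ln in lengths]
    model.censored = np.ones(len(lengths), dtype=bool)
    return table, model


def _true_pmf_error(
    result: AggregationResult,
    true_model: ModelSample,
    table: pd.DataFrame,
    design: DesignMatrix,
    steepness: float,
) -> float:
    """Max-abs deviation of the dominant state's per-session PMF from truth.

    Evaluated per session on the signed contrasts actually presented by then
    (early PMFs are undefined on stimuli that have not been introduced).
    """
    labels = result.clustering.labels
    if result.clustering.n_states == 0:
        return np.nan
    dominant = np.argmax(
        [np.sum(labels == s) for s in range(1, result.clustering.n_states + 1)]
    ) + 1
    pmfs = result.pmfs[result.pmfs["state"] == dominant]
    cl = table["contrast_left"].to_numpy(float)
    cr = table["contrast_right"].to_numpy(float)
    signed = np.where(cl > 0, -cl, cr)
    session = table["session"].to_numpy(int)
    err = 0.0
    for n in np.unique(session):
        shown = np.unique(signed[session <= n])
        sub = pmfs[(pmfs["session"] == n) & pmfs["signed_contrast"].isin(shown)]
        if len(sub) == 0:
            continue
        grid = sub["signed_contrast"].to_numpy()
        Fg = _pmf_features(grid, steepness)
        # true state active in session n: majority ground-truth state
        sl = design.session_slice(int(n))
        states, counts = np.unique(true_model.x[sl], return_counts=True)
        true_w = true_model.w[states[np.argmax(counts)], int(n) - 1]
        truth = _sigmoid(Fg @ true_w)
        err = max(err, float(np.max(np.abs(sub["p_right"].to_numpy() - truth))))
    return err


def recovery_experiment(
    scenario: str,
    seed: int,
    n_sessions: int = 15,
    trials_per_session: int = 300,
    k: int = 3,
    hp: HyperParams | None = None,
    chain_kwargs: dict | None = None,
    n_bins: int = 200,
    cut: float = 0.95,
    min_mode_samples: int = 400,
    timeout_prob: float = 0.01,
) -> RecoveryReport:
    """Simulate from known ground truth, fit, aggregate, and compare.

    Scenarios: ``static_1state``, ``drifting_1state`` (constant steps of
    variance 0.0311, fitted with sigma = 0.03), ``per_trial_drift`` (the same
    drift applied in per-trial steps, outside the model class), ``k_states``
    (k = 2..9 well-separated states) and ``implausible_pmfs``.
    """
    rng = np.random.default_rng(seed)
    if hp is None:
        sigma = 0.03 if scenario in ("drifting_1state", "per_trial_drift") else 0.04
        hp = HyperParams(L=8, sigma_drift=sigma)
    true_model, drift = _scenario_model(scenario, n_sessions, k, rng)
    schedule = generate_task_schedule(n_sessions, trials_per_session, rng)
    if scenario == "per_trial_drift":
        table, true_model = _simulate_per_trial_drift(
            true_model, schedule, rng, hp, timeout_prob
        )
    else:
        table, true_model = simulate_dataset(
            true_model, schedule, rng, hp=hp, timeout_prob=timeout_prob
        )
    design = build_design(table, steepness=hp.steepness, decay=hp.decay)
    ck = dict(DESK_SCALE_CHAINS)
    if chain_kwargs:
        ck.update(chain_kwargs)
    config = ChainConfig(seed=int(rng.integers(2**31)), **ck)
    chainset = run_chains(design, hp, config)
    result = aggregate_chains(
        chainset,
        design,
        cut=cut,
        n_bins=n_bins,
        min_mode_samples=min_mode_samples,
        seed=seed,
        require_converged=False,
    )
    labels = result.clustering.labels
    frac = (
        np.max(np.bincount(labels[labels > 0])[1:]) / design.n_trials
        if result.clustering.n_states else 0.0
    )
    ari = adjusted_rand_score(true_model.x, labels)
    pmf_err = _true_pmf_error(result, true_model, table, design, hp.steepness)
    return RecoveryReport(
        scenario=scenario,
        n_cluster_states=result.clustering.n_states,
        dominant_frac=float(frac),
        ari=float(ari),
        pmf_max_abs_err=pmf_err,
        coverage=result.clustering.coverage,
        aggregation=result,
        table=table,
        true_model=true_model,
    )
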