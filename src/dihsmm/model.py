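"""Generative model: priors, latent variables, and synthetic-data simulation.

The model describes an animal's choices during training as arising from a
small set of latent behavioral states.  Within a session, states follow a
hidden semi-Markov chain: a segment's state is drawn from a transition matrix
with self-transitions prohibited, and the segment's length (in trials) from a
state-specific shifted negative-binomial distribution.  Each state carries a
4-feature logistic-regression readout whose weights perform a Gaussian random
walk across sessions (the "slow process"), while the introduction of new
states is the "fast process".

The transition structure has a hierarchical Dirichlet process prior, handled
throughout in its weak-limit form with at most ``L`` states:

* ``beta ~ Dir(gamma/L, ..., gamma/L)`` — global state popularity,
* ``pi_i ~ Dir(alpha * beta)`` — per-state transition rows,
* ``pi_0 ~ Dir(3/L, ..., 3/L)`` — the session-initial state distribution,
  drawn separately from the hierarchy.

This module also hosts the synthetic task-schedule generator emulating the
staged introduction of weaker contrasts over sessions, and the full simulator
used as ground truth by every recovery experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .trial_features import CONTRAST_SET, build_design, validate_trial_table

__all__ = [
    "HyperParams",
    "ModelSample",
    "sample_prior_model",
    "sample_duration",
    "generate_task_schedule",
    "default_introduction_plan",
    "simulate_dataset",
    "expand_segments",
    "segments_from_states",
    "check_model",
    "save_model",
    "load_model",
]


@dataclass
class HyperParams:
    """Fixed hyperparameters of the model.

    Attributes
    ----------
    L
        Weak-limit cap on the number of states.
    gamma_prior, alpha_prior
        (shape, rate) of the vague Gamma priors on the two Dirichlet-process
        concentrations.
    pi0_concentration
        Concentration of the session-initial state distribution.
    r_min, r_max
        Inclusive support of the uniform prior on the negative-binomial
        stopping parameter r (small values are excluded so durations do not
        collapse to near-geometric laws tracking single trials).
    p_prior
        Beta prior on the negative-binomial success probability.
    w_init_var
        Variance of the diffuse normal prior on first-session weights.
    sigma_drift
        Intersession variance of the Gaussian random walk on weights.
    steepness, decay
        Contrast-transform steepness and perseveration decay (fixed by
        cross-validation, not inferred).
    n_features
        Dimension of the regression feature vector.
    """

    L: int = 15
    gamma_prior: tuple = (0.01, 0.01)
    alpha_prior: tuple = (0.01, 0.01)
    pi0_concentration: float = 3.0
    r_min: int = 5
    r_max: int = 704
    p_prior: tuple = (1.0, 1.0)
    w_init_var: float = 8.0
    sigma_drift: float = 0.04
    steepness: float = 5.0
    decay: float = 0.25
    n_features: int = 4

    def __post_init__(self):
        if self.L < 2:
            raise ValueError("state cap L must be at least 2")
        if self.r_min < 2:
            raise ValueError("r support must start at 2 or above")
        if self.r_max < self.r_min:
            raise ValueError("empty r support")
        if self.w_init_var <= 0:
            raise ValueError("w_init_var must be positive")
        if self.sigma_drift < 0:
            raise ValueError("sigma_drift must be non-negative")

    @property
    def r_support(self) -> np.ndarray:
        return np.arange(self.r_min, self.r_max + 1)


@dataclass
class ModelSample:
    """One full instantiation of every latent variable.

    ``z`` and ``d`` hold per-session segment labels and durations; ``x`` is
    their per-trial expansion, flat over all trials in session order.  ``w``
    is indexed (state, session, feature).  ``censored`` flags, per session,
    whether the final segment was cut off by the session end.
    """

    beta: np.ndarray
    pi0: np.ndarray
    pi: np.ndarray
    alpha: float
    gamma: float
    r: np.ndarray
    p: np.ndarray
    w: np.ndarray
    z: list = None
    d: list = None
    x: np.ndarray = None
    censored: np.ndarray = None

    @property
    def L(self) -> int:
        return len(self.beta)

    @property
    def n_sessions(self) -> int:
        return self.w.shape[1]

    def copy(self) -> "ModelSample":
        return ModelSample(
            beta=self.beta.copy(),
            pi0=self.pi0.copy(),
            pi=self.pi.copy(),
            alpha=self.alpha,
            gamma=self.gamma,
            r=self.r.copy(),
            p=self.p.copy(),
            w=self.w.copy(),
            z=None if self.z is None else [zz.copy() for zz in self.z],
            d=None if self.d is None else [dd.copy() for dd in self.d],
            x=None if self.x is None else self.x.copy(),
            censored=None if self.censored is None else self.censored.copy(),
        )


def expand_segments(z: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Per-trial state labels from segment labels and durations."""
    return np.repeat(np.asarray(z), np.asarray(d))


def segments_from_states(x: np.ndarray):
    """Run-length encode a per-trial state sequence into (labels, durations)."""
    x = np.asarray(x)
    if x.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    change = np.flatnonzero(np.diff(x)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [x.size]])
    return x[starts].astype(int), (ends - starts).astype(int)


def zero_diag_renorm(pi: np.ndarray) -> np.ndarray:
    """Transition rows with the diagonal removed and renormalised."""
    out = pi.copy()
    np.fill_diagonal(out, 0.0)
    rows = out.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return out / rows


def sample_duration(r: int, p: float, rng: np.random.Generator, size=None):
    """Segment duration(s): 1 + NB(r, p) failures-before-r-successes.

    The +1 shift puts the support on {1, 2, ...}; with r = 1 this is the
    geometric law of a plain HMM.
    """
    if r < 1:
        raise ValueError("r must be at least 1")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    return 1 + rng.negative_binomial(r, p, size=size)


def _sample_segments(model: ModelSample, session_lengths, rng):
    """Draw per-session segment structure (z, d, x) given model parameters."""
    pi_bar = zero_diag_renorm(model.pi)
    z_all, d_all, cens = [], [], []
    for T in session_lengths:
        labels, durs = [], []
        t = 0
        prev = None
        censored = False
        while t < T:
            if prev is None:
                state = rng.choice(model.L, p=model.pi0)
            elif pi_bar[prev].sum() == 0:
                state = prev  # single reachable state: the segment continues
            else:
                state = rng.choice(model.L, p=pi_bar[prev])
            dur = int(sample_duration(int(model.r[state]), float(model.p[state]), rng))
            if t + dur >= T:
                censored = dur > T - t
                dur = T - t
            labels.append(state)
            durs.append(dur)
            t += dur
            prev = state
        # run-length re-encode so degenerate continuations merge
        x_sess = expand_segments(np.array(labels, int), np.array(durs, int))
        z_sess, d_sess = segments_from_states(x_sess)
        z_all.append(z_sess)
        d_all.append(d_sess)
        cens.append(censored)
    if len(session_lengths):
        x = np.concatenate([expand_segments(z, d) for z, d in zip(z_all, d_all)])
    else:
        x = np.array([], dtype=int)
    return z_all, d_all, x.astype(int), np.array(cens, dtype=bool)


def _sample_weights_prior(hp: HyperParams, n_sessions, occupied, rng):
    """Random-walk weight draw; unoccupied sessions freeze the walk."""
    L, K = hp.L, hp.n_features
    w = np.zeros((L, n_sessions, K))
    w[:, 0] = rng.normal(0.0, np.sqrt(hp.w_init_var), size=(L, K))
    sd = np.sqrt(hp.sigma_drift)
    for n in range(1, n_sessions):
        step = rng.normal(0.0, sd, size=(L, K)) if sd > 0 else 0.0
        w[:, n] = w[:, n - 1] + np.where(occupied[:, n - 1 : n], step, 0.0)
    return w


def sample_prior_model(
    hp: HyperParams,
    n_sessions: int,
    rng: np.random.Generator,
    session_lengths=None,
) -> ModelSample:
    """Draw a complete model from the prior (no observations).

    If ``session_lengths`` is given, session segmentations are drawn as well
    and the weight random walk freezes across sessions in which a state owns
    no trials; otherwise every state's walk steps every session.
    """
    if n_sessions < 1:
        raise ValueError("need at least one session")
    L = hp.L
    gamma = rng.gamma(hp.gamma_prior[0], 1.0 / hp.gamma_prior[1])
    alpha = rng.gamma(hp.alpha_prior[0], 1.0 / hp.alpha_prior[1])
    beta = rng.dirichlet(np.full(L, max(gamma, 1e-3) / L))
    pi = np.vstack(
        [rng.dirichlet(np.maximum(alpha * beta, 1e-3)) for _ in range(L)]
    )
    pi0 = rng.dirichlet(np.full(L, hp.pi0_concentration / L))
    r = rng.integers(hp.r_min, hp.r_max + 1, size=L)
    p = rng.beta(hp.p_prior[0], hp.p_prior[1], size=L)
    model = ModelSample(
        beta=beta, pi0=pi0, pi=pi, alpha=float(alpha), gamma=float(gamma),
        r=r, p=p, w=np.zeros((L, n_sessions, hp.n_features)),
    )
    if session_lengths is not None:
        if len(session_lengths) != n_sessions:
            raise ValueError("session_lengths must match n_sessions")
        model.z, model.d, model.x, model.censored = _sample_segments(
            model, session_lengths, rng
        )
        occupied = occupancy_matrix(model, n_sessions, session_lengths)
    else:
        occupied = np.ones((L, n_sessions), dtype=bool)
    model.w = _sample_weights_prior(hp, n_sessions, occupied, rng)
    return model


def occupancy_matrix(model: ModelSample, n_sessions, session_lengths) -> np.ndarray:
    """(L, N) flags: does state i own at least one trial of session n."""
    occ = np.zeros((model.L, n_sessions), dtype=bool)
    start = 0
    for n, T in enumerate(session_lengths):
        occ[np.unique(model.x[start : start + T]), n] = True
        start += T
    return occ


def default_introduction_plan(n_sessions: int) -> dict:
    """Staged contrast introduction: easiest stimuli first, the full set
    (including 0%) from session 9 on."""
    plan = {}
    for n in range(1, n_sessions + 1):
        if n <= 2:
            allowed = (1.0, 0.5)
        elif n <= 4:
            allowed = (1.0, 0.5, 0.25)
        elif n <= 6:
            allowed = (1.0, 0.5, 0.25, 0.125)
        elif n <= 8:
            allowed = (1.0, 0.5, 0.25, 0.125, 0.0625)
        else:
            allowed = CONTRAST_SET
        plan[n] = allowed
    return plan


def generate_task_schedule(
    n_sessions: int,
    trials_per_session,
    rng: np.random.Generator,
    introduction_plan: dict | None = None,
) -> pd.DataFrame:
    """Build a trial-table skeleton (contrasts and rewarded sides, no choices).

    ``trials_per_session`` is an int or an inclusive (low, high) range from
    which each session's length is drawn uniformly.  Each trial draws its side
    uniformly and its contrast uniformly from the session's allowed set;
    zero-contrast trials get a uniformly random rewarded side.
    """
    if introduction_plan is None:
        introduction_plan = default_introduction_plan(n_sessions)
    rows = []
    for n in range(1, n_sessions + 1):
        allowed = introduction_plan[n]
        if len(allowed) == 0:
            raise ValueError(f"empty contrast set for session {n}")
        if np.isscalar(trials_per_session):
            T = int(trials_per_session)
        else:
            lo, hi = trials_per_session
            T = int(rng.integers(lo, hi + 1))
        contrasts = rng.choice(allowed, size=T)
        sides = rng.choice(["L", "R"], size=T)
        for t in range(T):
            c, side = contrasts[t], sides[t]
            cl = c if side == "L" else 0.0
            cr = c if side == "R" else 0.0
            rewarded = side if c > 0 else ("L" if rng.random() < 0.5 else "R")
            rows.append((n, t + 1, cl, cr, rewarded))
    return pd.DataFrame(
        rows, columns=["session", "trial", "contrast_left", "contrast_right",
                       "rewarded_side"]
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dataset(
    model: ModelSample,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    hp: HyperParams | None = None,
    timeout_prob: float = 0.01,
):
    """Simulate choices for a task schedule under a model.

    If the model carries a segmentation (``x`` is set) it is reused as ground
    truth; otherwise fresh segments are drawn from ``pi0`` / the zero-diagonal
    transition rows / the duration laws (the session-final segment truncated
    at the session end).  Choices are Bernoulli in the logistic readout, with
    the perseveration feature recomputed online from the simulated choices.

    Returns ``(trial_table, model)`` where the table carries a ``choice``,
    ``rewarded_side`` and ``true_state`` column and the model has its
    segmentation filled in.
    """
    hp = hp or HyperParams(L=max(model.L, 2))  # only steepness/decay are used
    session_lengths = schedule.groupby("session").size().to_numpy()
    n_sessions = len(session_lengths)
    if model.n_sessions < n_sessions:
        raise ValueError("model covers fewer sessions than the schedule")
    model = model.copy()
    if model.x is None:
        model.z, model.d, model.x, model.censored = _sample_segments(
            model, session_lengths, rng
        )
    cl = schedule["contrast_left"].to_numpy(float)
    cr = schedule["contrast_right"].to_numpy(float)
    tl = np.tanh(hp.steepness * cl) / np.tanh(hp.steepness)
    tr = np.tanh(hp.steepness * cr) / np.tanh(hp.steepness)
    session = schedule["session"].to_numpy(int)

    T = len(schedule)
    choice = np.empty(T, dtype=object)
    lam = np.exp(-hp.decay)
    S = Z = 0.0
    prev_session = None
    for t in range(T):
        if session[t] != prev_session:
            S = Z = 0.0
            prev_session = session[t]
        pers = S / Z if Z > 0 else 0.0
        if timeout_prob > 0 and rng.random() < timeout_prob:
            choice[t] = "timeout"
            enc = 0.0
        else:
            f = np.array([tl[t], tr[t], pers, 1.0])
            w = model.w[model.x[t], session[t] - 1]
            y = rng.random() < _sigmoid(float(f @ w))
            choice[t] = "R" if y else "L"
            enc = 1.0 if y else -1.0
        S = lam * (enc + S)
        Z = lam * (1.0 + Z)

    table = schedule.copy()
    table["choice"] = choice
    table["true_state"] = model.x
    validate_trial_table(table)
    return table, model


def check_model(model: ModelSample, session_lengths=None, atol: float = 1e-10):
    """Assert the structural invariants of a model sample.

    Simplex constraints on beta / pi0 / pi rows, zero effective diagonal,
    durations >= 1 summing to the session lengths, expansion consistency of
    (z, d) against x, and no consecutive equal segment labels.
    """
    assert abs(model.beta.sum() - 1) < atol
    assert abs(model.pi0.sum() - 1) < atol
    assert np.allclose(model.pi.sum(axis=1), 1.0, atol=atol)
    assert np.all(np.diag(zero_diag_renorm(model.pi)) == 0)
    assert np.all(model.p > 0) and np.all(model.p < 1)
    if model.z is not None:
        start = 0
        for n, (z, d) in enumerate(zip(model.z, model.d)):
            assert np.all(d >= 1)
            assert np.all(z[1:] != z[:-1]), "consecutive segments share a label"
            if session_lengths is not None:
                assert d.sum() == session_lengths[n]
            seg = expand_segments(z, d)
            assert np.array_equal(seg, model.x[start : start + len(seg)])
            start += len(seg)


def save_model(model: ModelSample, target) -> None:
    """Serialize a model sample to an HDF5 file or group."""
    own = isinstance(target, (str, bytes)) or hasattr(target, "__fspath__")
    h = h5py.File(target, "w") if own else target
    try:
        for name in ("beta", "pi0", "pi", "r", "p", "w"):
            h.create_dataset(name, data=getattr(model, name))
        h.attrs["alpha"] = model.alpha
        h.attrs["gamma"] = model.gamma
        if model.x is not None:
            h.create_dataset("x", data=model.x)
            h.create_dataset("censored", data=model.censored)
            h.create_dataset(
                "session_lengths", data=np.array([len(expand_segments(z, d))
                                                  for z, d in zip(model.z, model.d)])
            )
            for n, (z, d) in enumerate(zip(model.z, model.d)):
                h.create_dataset(f"z/{n}", data=z)
                h.create_dataset(f"d/{n}", data=d)
    finally:
        if own:
            h.close()


def load_model(source) -> ModelSample:
    """Inverse of :func:`save_model`."""
    own = isinstance(source, (str, bytes)) or hasattr(source, "__fspath__")
    h = h5py.File(source, "r") if own else source
    try:
        kwargs = {name: h[name][...] for name in ("beta", "pi0", "pi", "r", "p", "w")}
        model = ModelSample(
            alpha=float(h.attrs["alpha"]), gamma=float(h.attrs["gamma"]), **kwargs
        )
        if "x" in h:
            model.x = h["x"][...]
            model.censored = h["censored"][...]
            n_sessions = len(h["z"])
            model.z = [h[f"z/{n}"][...] for n in range(n_sessions)]
            model.d = [h[f"d/{n}"][...] for n in range(n_sessions)]
        return model
    finally:
        if own:
            h.close()
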