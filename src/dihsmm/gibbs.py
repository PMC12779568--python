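"""Gibbs sampler over every latent variable of the model.

One sweep resamples, in a fixed order:

1. per-session segmentations (state labels, durations) by exact
   forward-filter backward-sampling over the semi-Markov messages,
2. duration parameters (r, p) per state, with session-final durations treated
   as right-censored and imputed from the truncated negative binomial,
3. transition structure (pi rows, pi0, the global popularity vector beta)
   via the weak-limit auxiliary-table construction, with the
   self-transition prohibition handled by augmenting rejected self-draws,
4. the Dirichlet-process concentrations alpha and gamma from their exact
   1-D conditionals on a log grid,
5. per-state dynamic regression weights via Pólya-Gamma augmentation and
   forward-filter backward-sampling of the linear-Gaussian walk.

All message passing runs in the log domain; the segmentation kernels are
numba-compiled.  Randomness flows exclusively through the caller's
:class:`numpy.random.Generator`, so chains are reproducible from their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from numba import njit
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import nbinom

from .model import (
    HyperParams,
    ModelSample,
    expand_segments,
    occupancy_matrix,
    segments_from_states,
    zero_diag_renorm,
)
from .polya_gamma import sample_pg
from .trial_features import DesignMatrix

__all__ = [
    "ChainConfig",
    "ChainSet",
    "emission_loglik",
    "resample_state_sequence",
    "resample_duration_params",
    "resample_transition_params",
    "resample_concentrations",
    "resample_weights",
    "gibbs_sweep",
    "init_model",
    "run_gibbs_chain",
    "run_chains",
    "sample_summary",
    "log_joint",
]

_DIR_FLOOR = 1e-3  # symmetric floor on Dirichlet parameters (numerical guard)


# ---------------------------------------------------------------------------
# emission likelihood
# ---------------------------------------------------------------------------

def emission_loglik(
    design: DesignMatrix, model: ModelSample, heldout=None
) -> np.ndarray:
    """Per-trial, per-state Bernoulli log-likelihood, (T, L).

    Timeout trials and held-out (masked) trials contribute log-likelihood 0
    for every state: they occupy a duration slot but carry no evidence.
    """
    T, L = design.n_trials, model.L
    ll = np.zeros((T, L))
    skip = design.is_timeout.copy()
    if heldout is not None:
        skip |= heldout
    for n in range(1, design.n_sessions + 1):
        sl = design.session_slice(n)
        psi = design.F[sl] @ model.w[:, n - 1, :].T  # (Tn, L)
        y = design.y[sl][:, None]
        # log sigmoid(psi) if y==1 else log sigmoid(-psi)
        signed = np.where(y == 1, psi, -psi)
        ll[sl] = -np.logaddexp(0.0, -signed)
    ll[skip] = 0.0
    return ll


def _duration_tables(model: ModelSample, t_max: int):
    """log pmf and log survival of durations 1..t_max for every state."""
    d = np.arange(1, t_max + 1)
    log_dur = np.empty((model.L, t_max + 1))
    log_sur = np.empty((model.L, t_max + 1))
    log_dur[:, 0] = -np.inf
    log_sur[:, 0] = 0.0
    for i in range(model.L):
        log_dur[i, 1:] = nbinom.logpmf(d - 1, model.r[i], model.p[i])
        # P(duration >= d) = P(NB count >= d-1)
        log_sur[i, 1] = 0.0
        if t_max >= 2:
            log_sur[i, 2:] = nbinom.logsf(d[1:] - 2, model.r[i], model.p[i])
    return log_dur, log_sur


# ---------------------------------------------------------------------------
# semi-Markov messages (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _hsmm_backward(log_pi0, log_A, log_dur, log_sur, cum_ll):
    T = cum_ll.shape[0] - 1
    L = log_pi0.shape[0]
    # beta[t, i]: future likelihood given a segment of some state ended at t
    # with previous state i; beta_star[t, i]: given a segment of state i
    # starts at t (0-based trial index t)
    beta = np.zeros((T + 1, L))
    beta_star = np.full((T + 1, L), -np.inf)
    for t in range(T - 1, -1, -1):
        for i in range(L):
            m = -np.inf
            for d in range(1, T - t + 1):
                ll_seg = cum_ll[t + d, i] - cum_ll[t, i]
                if t + d == T:
                    v = log_sur[i, d] + ll_seg  # right-censored final segment
                else:
                    v = log_dur[i, d] + ll_seg + beta[t + d, i]
                if v > m:
                    m = v
            if m == -np.inf:
                beta_star[t, i] = -np.inf
                continue
            acc = 0.0
            for d in range(1, T - t + 1):
                ll_seg = cum_ll[t + d, i] - cum_ll[t, i]
                if t + d == T:
                    v = log_sur[i, d] + ll_seg
                else:
                    v = log_dur[i, d] + ll_seg + beta[t + d, i]
                acc += math.exp(v - m)
            beta_star[t, i] = m + math.log(acc)
        for i in range(L):
            m = -np.inf
            for j in range(L):
                if j != i:
                    v = log_A[i, j] + beta_star[t, j]
                    if v > m:
                        m = v
            if m == -np.inf:
                beta[t, i] = -np.inf
                continue
            acc = 0.0
            for j in range(L):
                if j != i:
                    acc += math.exp(log_A[i, j] + beta_star[t, j] - m)
            beta[t, i] = m + math.log(acc)
    return beta, beta_star


@njit(cache=True)
def _draw_logits(logw, u):
    n = logw.shape[0]
    m = -np.inf
    for k in range(n):
        if logw[k] > m:
            m = logw[k]
    total = 0.0
    for k in range(n):
        total += math.exp(logw[k] - m)
    target = u * total
    acc = 0.0
    for k in range(n):
        acc += math.exp(logw[k] - m)
        if acc >= target:
            return k
    return n - 1


@njit(cache=True)
def _hsmm_forward_sample(log_pi0, log_A, log_dur, log_sur, cum_ll,
                         beta, beta_star, u):
    T = cum_ll.shape[0] - 1
    L = log_pi0.shape[0]
    x = np.empty(T, np.int64)
    iu = 0
    t = 0
    prev = -1
    wts = np.empty(L)
    while t < T:
        for i in range(L):
            base = log_pi0[i] if prev < 0 else (log_A[prev, i] if i != prev else -np.inf)
            wts[i] = base + beta_star[t, i]
        state = _draw_logits(wts, u[iu])
        iu += 1
        dw = np.empty(T - t)
        for d in range(1, T - t + 1):
            ll_seg = cum_ll[t + d, state] - cum_ll[t, state]
            if t + d == T:
                dw[d - 1] = log_sur[state, d] + ll_seg
            else:
                dw[d - 1] = log_dur[state, d] + ll_seg + beta[t + d, state]
        dur = 1 + _draw_logits(dw, u[iu])
        iu += 1
        for k in range(t, t + dur):
            x[k] = state
        t += dur
        prev = state
    return x


def resample_state_sequence(
    model: ModelSample,
    design: DesignMatrix,
    rng: np.random.Generator,
    heldout=None,
    ll: np.ndarray | None = None,
) -> ModelSample:
    """Exact block draw of every session's segmentation, in place.

    Conditional on emissions, pi0, the zero-diagonal transition rows and the
    duration laws; the final segment of each session is right-censored.
    """
    if ll is None:
        ll = emission_loglik(design, model, heldout)
    pi_bar = zero_diag_renorm(model.pi)
    with np.errstate(divide="ignore"):
        log_A = np.log(pi_bar)
        log_pi0 = np.log(model.pi0)
    t_max = int(design.session_lengths.max())
    log_dur, log_sur = _duration_tables(model, t_max)

    z_all, d_all, x_parts, cens = [], [], [], []
    for n in range(1, design.n_sessions + 1):
        sl = design.session_slice(n)
        cum_ll = np.vstack([np.zeros((1, model.L)), np.cumsum(ll[sl], axis=0)])
        try:
            beta, beta_star = _hsmm_backward(
                log_pi0, log_A, log_dur, log_sur, cum_ll
            )
            u = rng.random(2 * (sl.stop - sl.start) + 2)
            x = _hsmm_forward_sample(
                log_pi0, log_A, log_dur, log_sur, cum_ll, beta, beta_star, u
            )
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"segmentation resampling failed in session {n}") from exc
        z, d = segments_from_states(x)
        z_all.append(z)
        d_all.append(d)
        x_parts.append(x)
        cens.append(True)  # final duration only observed as a lower bound
    model.z, model.d = z_all, d_all
    model.x = np.concatenate(x_parts)
    model.censored = np.array(cens)
    return model


# ---------------------------------------------------------------------------
# duration parameters
# ---------------------------------------------------------------------------

def resample_duration_params(
    model: ModelSample, hp: HyperParams, rng: np.random.Generator
) -> ModelSample:
    """Draw (r_i, p_i) per state from their conditional, in place.

    Censored session-final durations are first completed by sampling the
    unobserved tail from the truncated negative binomial under the current
    (r, p); then r is drawn by enumerating its discrete support with p
    integrated out (Beta-NB conjugacy), and p | r from its Beta conditional.
    """
    a0, b0 = hp.p_prior
    rs = hp.r_support
    counts_per_state = [[] for _ in range(model.L)]
    for z, d in zip(model.z or [], model.d or []):
        for s, (state, dur) in enumerate(zip(z, d)):
            k = int(dur) - 1
            if s == len(z) - 1:
                # censored: impute the NB count given count >= k
                r_i, p_i = int(model.r[state]), float(model.p[state])
                lo = nbinom.cdf(k - 1, r_i, p_i) if k > 0 else 0.0
                if lo > 1 - 1e-12:
                    k_full = k
                else:
                    u = rng.uniform(lo, 1.0)
                    k_full = int(nbinom.ppf(u, r_i, p_i))
                    k_full = max(k_full, k)
                counts_per_state[state].append(k_full)
            else:
                counts_per_state[state].append(k)
    for i in range(model.L):
        ks = np.asarray(counts_per_state[i], dtype=float)
        if ks.size == 0:
            model.r[i] = rng.choice(rs)
            model.p[i] = rng.beta(a0, b0)
            continue
        m = ks.size
        ksum = ks.sum()
        # log marginal likelihood of r with p integrated out
        logml = (
            gammaln(np.add.outer(rs, ks)).sum(axis=1)
            - m * gammaln(rs)
            - gammaln(ks + 1).sum()
            + betaln(a0 + m * rs, b0 + ksum)
            - betaln(a0, b0)
        )
        probs = np.exp(logml - logsumexp(logml))
        r_new = int(rng.choice(rs, p=probs / probs.sum()))
        model.r[i] = r_new
        model.p[i] = rng.beta(a0 + m * r_new, b0 + ksum)
    return model


# ---------------------------------------------------------------------------
# transition structure
# ---------------------------------------------------------------------------

def _crt_tables(n: int, a: float, rng: np.random.Generator) -> int:
    """Chinese-restaurant table count for n customers at concentration a.

    Exact Bernoulli construction for moderate n; for very large n the count
    is drawn from its normal approximation (mean a*(psi(a+n) - psi(a))),
    clipped to the valid range.
    """
    if n <= 0 or a <= 0:
        return 0
    if n > 100_000:
        from scipy.special import digamma

        mean = a * (digamma(a + n) - digamma(a))
        k = np.arange(100_000)
        pr = a / (a + k)
        var = pr.sum() - (pr ** 2).sum() + max(mean - pr.sum(), 0.0)
        draw = rng.normal(mean, np.sqrt(max(var, 1.0)))
        return int(np.clip(round(draw), 1, n))
    k = np.arange(n)
    return int((rng.random(n) < a / (a + k)).sum())


def transition_counts(model: ModelSample):
    """Observed segment-transition counts (off-diagonal) and initial counts."""
    L = model.L
    trans = np.zeros((L, L), dtype=np.int64)
    init = np.zeros(L, dtype=np.int64)
    for z in model.z or []:
        if len(z) == 0:
            continue
        init[z[0]] += 1
        np.add.at(trans, (z[:-1], z[1:]), 1)
    return trans, init


def resample_transition_params(
    model: ModelSample,
    hp: HyperParams,
    rng: np.random.Generator,
    trans: np.ndarray | None = None,
    init: np.ndarray | None = None,
):
    """Draw beta, pi rows, and pi0, in place; returns auxiliary table counts.

    Observed transitions were generated by rejecting self-draws from the full
    pi rows, so the diagonal is augmented with a negative-binomial number of
    virtual self-transitions before the conjugate Dirichlet update.  The
    popularity vector beta is updated through Chinese-restaurant-franchise
    table counts.
    """
    L = model.L
    if trans is None or init is None:
        trans, init = transition_counts(model)
    full = trans.astype(np.int64).copy()
    for i in range(L):
        n_i = int(trans[i].sum())
        if n_i > 0:
            # each observed transition out of i implies a geometric number of
            # rejected self-draws; capped as a numerical guard when the
            # self-transition mass approaches 1
            p_self = min(float(model.pi[i, i]), 1 - 1e-6)
            full[i, i] = min(
                int(rng.negative_binomial(n_i, 1.0 - p_self)), 1_000_000
            )
    ab = model.alpha * model.beta
    tables = np.zeros((L, L), dtype=np.int64)
    for i in range(L):
        for j in range(L):
            if full[i, j] > 0:
                tables[i, j] = _crt_tables(full[i, j], max(ab[j], 1e-12), rng)
    model.beta = rng.dirichlet(
        model.gamma / L + tables.sum(axis=0) + _DIR_FLOOR
    )
    ab = model.alpha * model.beta
    for i in range(L):
        model.pi[i] = rng.dirichlet(ab + full[i] + _DIR_FLOOR)
    model.pi0 = rng.dirichlet(hp.pi0_concentration / L + init + _DIR_FLOOR)
    return tables, full


# ---------------------------------------------------------------------------
# concentration parameters
# ---------------------------------------------------------------------------

_LOG_GRID = np.linspace(np.log(1e-4), np.log(1e4), 600)


def _griddy_draw(logpost_at, rng):
    """Sample from a 1-D density on the fixed log grid (uniform within cell)."""
    logp = logpost_at(np.exp(_LOG_GRID)) + _LOG_GRID  # Jacobian of log transform
    logp -= logp.max()
    w = np.exp(logp)
    w /= w.sum()
    idx = rng.choice(len(_LOG_GRID), p=w)
    half = (_LOG_GRID[1] - _LOG_GRID[0]) / 2
    return float(np.exp(_LOG_GRID[idx] + rng.uniform(-half, half)))


def resample_concentrations(
    model: ModelSample, hp: HyperParams, rng: np.random.Generator
) -> ModelSample:
    """Draw alpha and gamma from their exact conditionals, in place.

    Both conditionals are one-dimensional (gamma given beta; alpha given beta
    and the pi rows) and are sampled on a discretised log grid spanning
    1e-4..1e4.
    """
    L = model.L
    slog_beta = np.log(np.clip(model.beta, 1e-300, 1.0)).sum()
    a_g, b_g = hp.gamma_prior

    def logpost_gamma(g):
        return (
            (a_g - 1) * np.log(g) - b_g * g
            + gammaln(g) - L * gammaln(g / L)
            + (g / L) * slog_beta
        )

    model.gamma = _griddy_draw(logpost_gamma, rng)

    beta = np.clip(model.beta, 1e-12, 1.0)
    sum_log_pi = np.log(np.clip(model.pi, 1e-300, 1.0)).sum(axis=0)  # (L,)
    a_a, b_a = hp.alpha_prior

    def logpost_alpha(a):
        # sum over the L rows of the Dir(alpha*beta) log density
        a = np.atleast_1d(a).astype(float)
        ab = np.outer(a, beta)
        return (
            (a_a - 1) * np.log(a) - b_a * a
            + L * gammaln(a)
            - L * gammaln(ab).sum(axis=1)
            + ab @ sum_log_pi
        )

    model.alpha = _griddy_draw(logpost_alpha, rng)
    return model


# ---------------------------------------------------------------------------
# dynamic weights (Pólya-Gamma + forward filter backward sample)
# ---------------------------------------------------------------------------

def resample_weights(
    model: ModelSample,
    design: DesignMatrix,
    hp: HyperParams,
    rng: np.random.Generator,
    heldout=None,
) -> ModelSample:
    """Draw every state's weight trajectory, in place.

    Per state: Pólya-Gamma auxiliaries for its assigned (response) trials
    yield Gaussian pseudo-observations; a Kalman filter runs across sessions
    with process noise sigma*I after occupied sessions and zero after
    unoccupied ones (freezing the walk); weights are then sampled backward.
    A state with no assigned trials anywhere gets a pure prior-walk draw.
    """
    K = hp.n_features
    N = design.n_sessions
    usable = ~design.is_timeout
    if heldout is not None:
        usable &= ~heldout
    occ = occupancy_matrix(model, N, design.session_lengths)
    eye = np.eye(K)
    for i in range(model.L):
        sel = (model.x == i) & usable
        lam_list = np.zeros((N, K, K))
        h_list = np.zeros((N, K))
        if sel.any():
            psi = np.einsum(
                "tk,tk->t", design.F[sel], model.w[i, design.session[sel] - 1]
            )
            omega = sample_pg(1, psi, rng)
            kappa = design.y[sel] - 0.5
            F_sel = design.F[sel]
            s_sel = design.session[sel] - 1
            for n in np.unique(s_sel):
                m = s_sel == n
                Fm = F_sel[m]
                lam_list[n] = Fm.T @ (Fm * omega[m][:, None])
                h_list[n] = Fm.T @ kappa[m]
        # forward filter
        m_f = np.zeros((N, K))
        P_f = np.zeros((N, K, K))
        m_pred = np.zeros(K)
        P_pred = hp.w_init_var * eye
        for n in range(N):
            prec = np.linalg.inv(P_pred) + lam_list[n]
            P_n = np.linalg.inv(prec)
            m_n = P_n @ (np.linalg.solve(P_pred, m_pred) + h_list[n])
            m_f[n], P_f[n] = m_n, (P_n + P_n.T) / 2
            q = hp.sigma_drift if occ[i, n] else 0.0
            m_pred = m_n
            P_pred = P_f[n] + q * eye
        # backward sample
        w_new = np.zeros((N, K))
        w_new[N - 1] = rng.multivariate_normal(
            m_f[N - 1], P_f[N - 1], method="cholesky"
        )
        for n in range(N - 2, -1, -1):
            q = hp.sigma_drift if occ[i, n] else 0.0
            if q == 0.0:
                w_new[n] = w_new[n + 1]
                continue
            G = np.linalg.solve((P_f[n] + q * eye).T, P_f[n].T).T
            mean = m_f[n] + G @ (w_new[n + 1] - m_f[n])
            cov = P_f[n] - G @ P_f[n]
            cov = (cov + cov.T) / 2 + 1e-12 * eye
            w_new[n] = rng.multivariate_normal(mean, cov, method="cholesky")
        model.w[i] = w_new
    return model


# ---------------------------------------------------------------------------
# sweeps and chains
# ---------------------------------------------------------------------------

def gibbs_sweep(
    model: ModelSample,
    design: DesignMatrix,
    hp: HyperParams,
    rng: np.random.Generator,
    heldout=None,
) -> ModelSample:
    """One full update of every variable, in the documented order."""
    resample_state_sequence(model, design, rng, heldout)
    resample_duration_params(model, hp, rng)
    resample_transition_params(model, hp, rng)
    resample_concentrations(model, hp, rng)
    resample_weights(model, design, hp, rng, heldout)
    return model


def init_model(
    design: DesignMatrix, hp: HyperParams, rng: np.random.Generator
) -> ModelSample:
    """Random starting point: contiguous random segmentation, prior weights."""
    L = hp.L
    model = ModelSample(
        beta=rng.dirichlet(np.ones(L)),
        pi0=rng.dirichlet(np.full(L, hp.pi0_concentration / L) + _DIR_FLOOR),
        pi=np.vstack([rng.dirichlet(np.ones(L)) for _ in range(L)]),
        alpha=1.0,
        gamma=1.0,
        r=rng.integers(hp.r_min, hp.r_max + 1, size=L),
        p=rng.beta(*hp.p_prior, size=L),
        w=np.zeros((L, design.n_sessions, hp.n_features)),
    )
    z_all, d_all, x_parts = [], [], []
    for n in range(1, design.n_sessions + 1):
        T = int(design.session_lengths[n - 1])
        n_seg = min(1 + rng.poisson(1.0), T)
        cuts = np.sort(rng.choice(np.arange(1, T), size=n_seg - 1, replace=False)) \
            if n_seg > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [T]])
        labels = [int(rng.integers(L))]
        for _ in range(n_seg - 1):
            nxt = int(rng.integers(L - 1))
            labels.append(nxt if nxt < labels[-1] else nxt + 1)
        z = np.array(labels)
        d = np.diff(bounds)
        z_all.append(z)
        d_all.append(d)
        x_parts.append(expand_segments(z, d))
    model.z, model.d = z_all, d_all
    model.x = np.concatenate(x_parts)
    model.censored = np.ones(design.n_sessions, dtype=bool)
    occ = occupancy_matrix(model, design.n_sessions, design.session_lengths)
    sd0 = np.sqrt(hp.w_init_var)
    sdd = np.sqrt(hp.sigma_drift)
    model.w[:, 0] = rng.normal(0, sd0, size=(L, hp.n_features))
    for n in range(1, design.n_sessions):
        step = rng.normal(0, sdd, size=(L, hp.n_features))
        model.w[:, n] = model.w[:, n - 1] + np.where(occ[:, n - 1 : n], step, 0.0)
    return model


def sample_summary(model: ModelSample) -> dict:
    """Label-independent scalar features of a sample (the R-hat feature set)."""
    T = len(model.x)
    counts = np.bincount(model.x, minlength=model.L)
    top = np.sort(counts)[::-1]
    frac = counts / max(T, 1)
    return {
        "alpha": model.alpha,
        "gamma": model.gamma,
        "top1_trials": int(top[0]),
        "top2_trials": int(top[1]),
        "n_states_20": int((frac > 0.20).sum()),
        "n_states_10": int((frac > 0.10).sum()),
    }


SUMMARY_FEATURES = (
    "alpha", "gamma", "top1_trials", "top2_trials", "n_states_20", "n_states_10",
)


@dataclass
class ChainConfig:
    """MCMC run lengths; defaults are the full-scale settings."""

    n_chains: int = 16
    n_samples: int = 48_000
    burn_in: int = 4_000
    thin: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_samples:
            raise ValueError("burn_in must be smaller than n_samples")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")

    @property
    def n_stored(self) -> int:
        """Stored samples per chain after burn-in and thinning."""
        return (self.n_samples - self.burn_in) // self.thin


@dataclass
class SampleRecord:
    """Thinned light-weight snapshot of one posterior sample."""

    x: np.ndarray
    w: np.ndarray
    beta: np.ndarray
    pi: np.ndarray
    pi0: np.ndarray
    r: np.ndarray
    p: np.ndarray
    alpha: float
    gamma: float

    @classmethod
    def from_model(cls, model: ModelSample) -> "SampleRecord":
        return cls(
            x=model.x.astype(np.int8),
            w=model.w.astype(np.float32),
            beta=model.beta.astype(np.float32),
            pi=model.pi.astype(np.float32),
            pi0=model.pi0.astype(np.float32),
            r=model.r.astype(np.int32),
            p=model.p.astype(np.float32),
            alpha=float(model.alpha),
            gamma=float(model.gamma),
        )


@dataclass
class ChainSet:
    """Thinned post-burn-in samples from multiple chains plus summaries."""

    chains: list            # list over chains of list[SampleRecord]
    summaries: pd.DataFrame  # columns: chain, sample, + SUMMARY_FEATURES
    hyper: HyperParams
    config: ChainConfig
    session_lengths: np.ndarray

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def pooled_samples(self, chain_ids=None):
        """Flat list of records from the given (default: all) chains."""
        if chain_ids is None:
            chain_ids = range(self.n_chains)
        return [rec for c in chain_ids for rec in self.chains[c]]

    def save(self, path) -> None:
        with h5py.File(path, "w") as h:
            h.attrs["n_chains"] = self.n_chains
            for key, val in vars(self.config).items():
                h.attrs[f"config_{key}"] = val
            for key, val in vars(self.hyper).items():
                h.attrs[f"hp_{key}"] = val
            h.create_dataset("session_lengths", data=self.session_lengths)
            for c, recs in enumerate(self.chains):
                g = h.create_group(f"chains/{c}")
                for name in ("x", "w", "beta", "pi", "pi0", "r", "p"):
                    g.create_dataset(
                        name, data=np.stack([getattr(r, name) for r in recs])
                    )
                g.create_dataset("alpha", data=[r.alpha for r in recs])
                g.create_dataset("gamma", data=[r.gamma for r in recs])
            h.create_dataset(
                "summaries",
                data=self.summaries.to_records(index=False),
            )

    @classmethod
    def load(cls, path) -> "ChainSet":
        with h5py.File(path, "r") as h:
            config = ChainConfig(
                **{k: int(h.attrs[f"config_{k}"]) for k in
                   ("n_chains", "n_samples", "burn_in", "thin", "seed")}
            )
            hp_kwargs = {}
            for key in ("L", "pi0_concentration", "r_min", "r_max", "w_init_var",
                        "sigma_drift", "steepness", "decay", "n_features"):
                v = h.attrs[f"hp_{key}"]
                hp_kwargs[key] = int(v) if key in ("L", "r_min", "r_max", "n_features") else float(v)
            hp_kwargs["gamma_prior"] = tuple(h.attrs["hp_gamma_prior"])
            hp_kwargs["alpha_prior"] = tuple(h.attrs["hp_alpha_prior"])
            hp_kwargs["p_prior"] = tuple(h.attrs["hp_p_prior"])
            hyper = HyperParams(**hp_kwargs)
            chains = []
            for c in range(int(h.attrs["n_chains"])):
                g = h[f"chains/{c}"]
                n = g["x"].shape[0]
                chains.append([
                    SampleRecord(
                        x=g["x"][k], w=g["w"][k], beta=g["beta"][k],
                        pi=g["pi"][k], pi0=g["pi0"][k], r=g["r"][k],
                        p=g["p"][k], alpha=float(g["alpha"][k]),
                        gamma=float(g["gamma"][k]),
                    )
                    for k in range(n)
                ])
            summaries = pd.DataFrame(h["summaries"][...])
            session_lengths = h["session_lengths"][...]
        return cls(chains, summaries, hyper, config, session_lengths)


def run_gibbs_chain(
    design: DesignMatrix,
    hp: HyperParams,
    n_samples: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
    heldout=None,
    init: ModelSample | None = None,
):
    """Run one chain; returns (records, summary rows, final model).

    Passing the final model and the same generator back in as ``init``
    continues the chain bit-exactly.
    """
    model = init if init is not None else init_model(design, hp, rng)
    records, rows = [], []
    for sweep in range(n_samples):
        gibbs_sweep(model, design, hp, rng, heldout)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            records.append(SampleRecord.from_model(model))
            rows.append(sample_summary(model))
    return records, rows, model


def run_chains(
    design: DesignMatrix,
    hp: HyperParams,
    config: ChainConfig,
    heldout=None,
) -> ChainSet:
    """Run independently seeded chains sequentially and collect a ChainSet."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains, summary_rows = [], []
    for c in range(config.n_chains):
        rng = np.random.Generator(np.random.PCG64(seeds[c]))
        records, rows, _ = run_gibbs_chain(
            design, hp, config.n_samples, config.burn_in, config.thin, rng,
            heldout=heldout,
        )
        chains.append(records)
        for k, row in enumerate(rows):
            summary_rows.append({"chain": c, "sample": k, **row})
    summaries = pd.DataFrame(summary_rows)
    return ChainSet(chains, summaries, hp, config, design.session_lengths.copy())


# ---------------------------------------------------------------------------
# log joint (diagnostic)
# ---------------------------------------------------------------------------

def log_joint(
    model: ModelSample, design: DesignMatrix, hp: HyperParams, heldout=None
) -> float:
    """Unnormalised log joint density of data and latents (diagnostic only)."""
    L = model.L
    lp = 0.0
    # emissions
    ll = emission_loglik(design, model, heldout)
    lp += float(ll[np.arange(design.n_trials), model.x].sum())
    # segmentations
    pi_bar = zero_diag_renorm(model.pi)
    with np.errstate(divide="ignore"):
        log_A = np.log(np.clip(pi_bar, 1e-300, 1))
        log_pi0 = np.log(np.clip(model.pi0, 1e-300, 1))
    for z, d in zip(model.z, model.d):
        lp += log_pi0[z[0]]
        lp += log_A[z[:-1], z[1:]].sum()
        for s, (state, dur) in enumerate(zip(z, d)):
            if s == len(z) - 1:
                lp += nbinom.logsf(dur - 2, model.r[state], model.p[state]) \
                    if dur >= 2 else 0.0
            else:
                lp += nbinom.logpmf(dur - 1, model.r[state], model.p[state])
    # weights random walk
    occ = occupancy_matrix(model, design.n_sessions, design.session_lengths)
    for i in range(L):
        lp += float(
            -0.5 * (model.w[i, 0] ** 2).sum() / hp.w_init_var
            - 0.5 * hp.n_features * np.log(2 * np.pi * hp.w_init_var)
        )
        for n in range(design.n_sessions - 1):
            if occ[i, n] and hp.sigma_drift > 0:
                diff = model.w[i, n + 1] - model.w[i, n]
                lp += float(
                    -0.5 * (diff ** 2).sum() / hp.sigma_drift
                    - 0.5 * hp.n_features * np.log(2 * np.pi * hp.sigma_drift)
                )
    return lp
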