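"""Pólya-Gamma random variates for logistic-regression data augmentation.

A Pólya-Gamma variable ``PG(b, c)`` turns a Bernoulli/binomial likelihood with
log-odds ``c`` into a conditionally Gaussian one: given ``omega ~ PG(b, c)``,
the pseudo-observation ``kappa / omega`` (with ``kappa = a - b/2``) is normal
with mean ``c`` and variance ``1 / omega``.

``PG(1, c)`` is drawn with Devroye's alternating-series rejection sampler
(exact, acceptance probability > 0.99); ``PG(b, c)`` for integer ``b`` uses
additivity, summing ``b`` independent ``PG(1, c)`` draws.  The kernel is
numba-compiled; its internal RNG is seeded per call from the caller's
:class:`numpy.random.Generator`, so draws are reproducible.

Useful identity for testing: ``E[PG(b, c)] = b * tanh(c/2) / (2c)``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_pg"]

_TRUNC = 0.64  # crossover point of the two series representations


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _series_coef(n, x):
    # a_n(x) of the alternating-series density of J*(1, z)
    h = n + 0.5
    if x <= _TRUNC:
        return math.pi * h * (2.0 / (math.pi * x)) ** 1.5 * math.exp(-2.0 * h * h / x)
    return math.pi * h * math.exp(-h * h * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _sample_trunc_invgauss(z):
    """Inverse-Gaussian(mu=1/z, lambda=1) restricted to (0, _TRUNC)."""
    t = _TRUNC
    if z < 1.0 / t:
        # mean exceeds the truncation point: sample from the scaled
        # chi-square proposal, thin by the Gaussian tilt
        while True:
            while True:
                e1 = np.random.exponential()
                e2 = np.random.exponential()
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-z * z * x / 2.0):
                return x
    mu = 1.0 / z
    while True:
        nu = np.random.standard_normal()
        y = nu * nu
        x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + mu * mu * y * y)
        if np.random.random() > mu / (mu + x):
            x = mu * mu / x
        if x < t:
            return x


@njit(cache=True)
def _sample_jstar1(z):
    """One draw of J*(1, z), z >= 0; PG(1, c) = J*(1, |c|/2) / 4."""
    t = _TRUNC
    K = math.pi * math.pi / 8.0 + z * z / 2.0
    p = math.pi / (2.0 * K) * math.exp(-K * t)
    if z > 0.0:
        # inverse-Gaussian CDF at t with mean 1/z, shape 1
        sq = 1.0 / math.sqrt(t)
        cdf = _norm_cdf(sq * (t * z - 1.0)) + math.exp(2.0 * z) * _norm_cdf(
            -sq * (t * z + 1.0)
        )
        q = 2.0 * math.exp(-z) * cdf
    else:
        q = 4.0 * _norm_cdf(-1.0 / math.sqrt(t))
    ratio = p / (p + q)
    while True:
        if np.random.random() < ratio:
            x = t + np.random.exponential() / K
        else:
            x = _sample_trunc_invgauss(z)
        # squeeze/accept via the alternating series
        s = _series_coef(0, x)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _series_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _series_coef(n, x)
                if y > s:
                    break
        if accept:
            return x


@njit(cache=True)
def _pg_vec(b, c, seed):
    np.random.seed(seed)
    out = np.empty(c.shape[0])
    for i in range(c.shape[0]):
        z = abs(c[i]) / 2.0
        total = 0.0
        for _ in range(b[i]):
            total += _sample_jstar1(z)
        out[i] = total / 4.0
    return out


def sample_pg(b, c, rng: np.random.Generator) -> np.ndarray:
    """Draw ``PG(b[i], c[i])`` for each i.

    Parameters
    ----------
    b
        Positive integer counts (scalar or array).
    c
        Tilting parameters (scalar or array, broadcast against ``b``).
    rng
        Source of the seed for the compiled kernel.
    """
    b_arr, c_arr = np.broadcast_arrays(
        np.asarray(b, dtype=np.int64), np.asarray(c, dtype=np.float64)
    )
    if np.any(b_arr < 1):
        raise ValueError("b must be a positive integer")
    seed = int(rng.integers(0, 2**32 - 1))
    out = _pg_vec(np.ascontiguousarray(b_arr.ravel()),
                  np.ascontiguousarray(c_arr.ravel()), seed)
    return out.reshape(c_arr.shape)
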