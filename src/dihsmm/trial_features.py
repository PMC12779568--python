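"""Trial tables and design-matrix construction for two-alternative choice data.

The observed record of an animal's training is a table of trials grouped into
sessions.  Each trial presents a visual stimulus of a given contrast on the
left or the right side (or a zero-contrast stimulus), and the animal answers
left (``L``), right (``R``), or not at all within the response window
(``timeout``).

For the logistic-regression emission model each trial is summarised by four
features:

1. transformed left contrast,
2. transformed right contrast,
3. an exponentially decaying average of previous choices (perseveration),
4. a constant bias term of 1.

Raw contrasts are passed through ``tanh(p*c)/tanh(p)`` with steepness ``p = 5``
so that the two easiest stimuli (100% and 50%) map onto nearly the same input,
reflecting their near-identical psychophysical difficulty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONTRAST_SET",
    "LOOKUP_CONTRAST_MAP",
    "DesignMatrix",
    "transform_contrast",
    "perseveration_feature",
    "build_design",
    "read_trial_table",
    "write_trial_table",
    "validate_trial_table",
    "signed_contrast_grid",
]

#: Canonical stimulus contrast levels used during training.
CONTRAST_SET = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.0)

#: Alternative contrast parameterization (named lookup table); maps the
#: canonical contrast levels onto inputs derived from a neural-network model of
#: behaviour on the same task.  Selected with ``transform="lookup"``.
LOOKUP_CONTRAST_MAP = {
    1.0: 1.0,
    0.5: 0.899,
    0.25: 0.705,
    0.125: 0.416,
    0.0625: 0.207,
    0.0: 0.0,
}

REQUIRED_COLUMNS = (
    "session",
    "trial",
    "contrast_left",
    "contrast_right",
    "choice",
)

CHOICES = ("L", "R", "timeout")


class TrialTableError(ValueError):
    """Raised when a trial table violates its structural invariants."""


def transform_contrast(c, steepness: float = 5.0):
    """Map a raw contrast in [0, 1] onto the regression input.

    ``c_tilde = tanh(steepness * c) / tanh(steepness)``; monotone in ``c``
    with fixed points at 0 and 1.  Accepts scalars or arrays.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("contrast must lie in [0, 1]")
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    out = np.tanh(steepness * c) / np.tanh(steepness)
    return float(out) if out.ndim == 0 else out


def _lookup_contrast(c):
    c = np.asarray(c, dtype=float)
    flat = np.atleast_1d(c)
    out = np.empty_like(flat)
    for i, v in enumerate(flat):
        try:
            out[i] = LOOKUP_CONTRAST_MAP[round(float(v), 4)]
        except KeyError:
            raise ValueError(
                f"contrast {v!r} not in the lookup contrast table"
            ) from None
    out = out.reshape(c.shape)
    return float(out) if c.ndim == 0 else out


def perseveration_feature(prior_choices, decay: float = 0.25) -> float:
    """Exponentially weighted average of previous choices, in [-1, 1].

    Parameters
    ----------
    prior_choices
        Encoded responses of earlier trials in the same session, most recent
        first: L -> -1, R -> +1, timeout -> 0.
    decay
        Decay rate of the exponential filter (weight ``exp(-decay*k)`` at lag
        ``k``); the filter is normalised so an all-rightward history gives +1.

    An empty history yields 0.
    """
    if decay <= 0:
        raise ValueError("decay must be positive")
    enc = np.asarray(prior_choices, dtype=float)
    if enc.size == 0:
        return 0.0
    k = np.arange(1, enc.size + 1)
    wts = np.exp(-decay * k)
    return float(np.dot(wts, enc) / wts.sum())


@dataclass
class DesignMatrix:
    """Per-trial regression features and responses, in trial order.

    ``F`` has one row per trial: (transformed left contrast, transformed right
    contrast, perseveration, 1).  ``y`` is 1 for rightward and 0 for leftward
    choices; timeout trials carry ``y = -1`` and ``is_timeout = True`` and are
    excluded from the emission likelihood (they still occupy a trial slot and
    enter the perseveration history as 0).
    """

    F: np.ndarray
    y: np.ndarray
    is_timeout: np.ndarray
    session: np.ndarray
    trial: np.ndarray
    session_lengths: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.session_lengths is None:
            _, counts = np.unique(self.session, return_counts=True)
            self.session_lengths = counts

    @property
    def n_trials(self) -> int:
        return self.F.shape[0]

    @property
    def n_sessions(self) -> int:
        return int(self.session.max()) if self.n_trials else 0

    def session_slice(self, n: int) -> slice:
        """0-based slice of trials belonging to 1-based session ``n``."""
        starts = np.concatenate([[0], np.cumsum(self.session_lengths)])
        return slice(int(starts[n - 1]), int(starts[n]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session": self.session,
                "trial": self.trial,
                "f_contrast_left": self.F[:, 0],
                "f_contrast_right": self.F[:, 1],
                "f_perseveration": self.F[:, 2],
                "f_bias": self.F[:, 3],
                "y": self.y,
                "is_timeout": self.is_timeout.astype(int),
            }
        )


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants of a trial table; return it unchanged.

    Raises :class:`TrialTableError` with the offending rows listed.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"missing columns: {missing}")
    bad_choice = ~table["choice"].isin(CHOICES)
    if bad_choice.any():
        raise TrialTableError(
            f"invalid choice values at rows {list(table.index[bad_choice][:10])}"
        )
    cl = table["contrast_left"].to_numpy(float)
    cr = table["contrast_right"].to_numpy(float)
    bad = (cl < 0) | (cl > 1) | (cr < 0) | (cr > 1) | ((cl > 0) & (cr > 0))
    if bad.any():
        raise TrialTableError(
            "malformed contrasts (outside [0,1] or both sides nonzero) at rows "
            f"{list(table.index[bad][:10])}"
        )
    sessions = np.unique(table["session"].to_numpy(int))
    if len(sessions) and not np.array_equal(
        sessions, np.arange(1, len(sessions) + 1)
    ):
        raise TrialTableError(f"sessions not contiguous from 1: {sessions}")
    for n, grp in table.groupby("session"):
        t = grp["trial"].to_numpy(int)
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise TrialTableError(f"trial indices of session {n} not contiguous from 1")
    return table


def build_design(
    trials: pd.DataFrame,
    steepness: float = 5.0,
    decay: float = 0.25,
    transform: str = "tanh",
) -> DesignMatrix:
    """Assemble the 4-feature design matrix from a validated trial table.

    The perseveration history restarts at every session boundary; timeouts are
    encoded as 0 in the history and flagged in the output.
    """
    validate_trial_table(trials)
    trials = trials.sort_values(["session", "trial"], kind="stable")
    cl = trials["contrast_left"].to_numpy(float)
    cr = trials["contrast_right"].to_numpy(float)
    if transform == "tanh":
        tl, tr = transform_contrast(cl, steepness), transform_contrast(cr, steepness)
    elif transform == "lookup":
        tl, tr = _lookup_contrast(cl), _lookup_contrast(cr)
    else:
        raise ValueError(f"unknown contrast transform {transform!r}")

    choice = trials["choice"].to_numpy()
    is_timeout = choice == "timeout"
    y = np.where(choice == "R", 1, 0).astype(np.int8)
    y[is_timeout] = -1
    enc = np.where(choice == "R", 1.0, -1.0)
    enc[is_timeout] = 0.0

    session = trials["session"].to_numpy(int)
    T = len(trials)
    pers = np.zeros(T)
    lam = np.exp(-decay)
    S = Z = 0.0
    prev_session = None
    for t in range(T):
        if session[t] != prev_session:
            S = Z = 0.0
            prev_session = session[t]
        pers[t] = S / Z if Z > 0 else 0.0
        # one-step filter update: weights shift by one lag and the newest
        # choice enters at lag 1
        S = lam * (enc[t] + S)
        Z = lam * (1.0 + Z)

    F = np.column_stack([tl, tr, pers, np.ones(T)])
    return DesignMatrix(
        F=F,
        y=y,
        is_timeout=is_timeout,
        session=session,
        trial=trials["trial"].to_numpy(int),
    )


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table from a delimited text file."""
    table = pd.read_csv(path)
    return validate_trial_table(table)


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a validated trial table as CSV (UTF-8, '.' decimal)."""
    validate_trial_table(table)
    table.to_csv(path, index=False)


def signed_contrast_grid(contrasts=CONTRAST_SET) -> np.ndarray:
    """Signed-contrast axis of the psychometric function (negative = left)."""
    pos = sorted(c for c in contrasts if c > 0)
    return np.array([-c for c in reversed(pos)] + [0.0] + pos)
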