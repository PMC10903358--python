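"""State-switching step-selection model: parameters, step geometry, simulation.

A track is a sequence of 2-D locations observed at regular time intervals.
Each step is summarised by its length ``l`` (gamma distributed within a state)
and its turning angle ``alpha`` (von Mises with mean 0 or pi, or uniform).  An
``N``-state hidden Markov chain switches the movement kernel and the habitat
selection coefficients over time; given the state, the next location follows
the step-selection density

    f_i(x) ∝ phi(l, alpha; theta_i) * exp(Z(x)' beta_i),

i.e. the movement kernel tilted by a log-linear selection function of the
habitat covariate at the step end point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .landscape import CovariateField

__all__ = [
    "StateParameters",
    "HMMiSSAModel",
    "steps_from_track",
    "movement_covariates",
    "log_step_weight",
    "stationary_distribution",
    "simulate_track",
    "read_track_csv",
    "write_track_csv",
    "wrap_angle",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap angles to the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a, dtype=float), TWO_PI)


@dataclass
class StateParameters:
    """Movement kernel and selection parameters of one behavioural state.

    ``shape`` and ``rate`` parameterise the gamma step-length distribution;
    ``concentration`` is the von Mises turning-angle concentration (a negative
    value encodes mean pi instead of mean 0; ``None`` under the uniform-angle
    model); ``beta`` holds the selection coefficients, one per habitat
    covariate.
    """

    shape: float
    rate: float
    concentration: float | None = None
    beta: np.ndarray = dataclass_field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma shape and rate must be > 0")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("selection coefficients must be finite")

    @property
    def mean_step_length(self) -> float:
        return self.shape / self.rate


@dataclass
class HMMiSSAModel:
    """An N-state hidden Markov step-selection model.

    ``tpm`` is the row-stochastic transition probability matrix Gamma, ``delta``
    the initial state distribution (defaults to the stationary distribution of
    Gamma), ``states`` the per-state parameters, and ``angle_model`` selects a
    von Mises or uniform turning-angle distribution.
    """

    tpm: np.ndarray
    states: list[StateParameters]
    delta: np.ndarray | None = None
    angle_model: str = "von_mises"

    def __post_init__(self) -> None:
        self.tpm = np.atleast_2d(np.asarray(self.tpm, dtype=float))
        n = self.tpm.shape[0]
        if self.tpm.shape != (n, n):
            raise ValueError("tpm must be square")
        if np.any(self.tpm < 0) or not np.allclose(self.tpm.sum(axis=1), 1.0):
            raise ValueError("tpm rows must be nonnegative and sum to 1")
        if len(self.states) != n:
            raise ValueError("need one StateParameters per state")
        if self.angle_model not in ("von_mises", "uniform"):
            raise ValueError(f"unknown angle model {self.angle_model!r}")
        if self.angle_model == "von_mises":
            if any(s.concentration is None for s in self.states):
                raise ValueError("von Mises model requires a concentration per state")
        if self.delta is None:
            self.delta = stationary_distribution(self.tpm)
        else:
            self.delta = np.asarray(self.delta, dtype=float)
            if self.delta.shape != (n,) or not np.isclose(self.delta.sum(), 1.0):
                raise ValueError("delta must be a length-N probability vector")

    @property
    def n_states(self) -> int:
        return self.tpm.shape[0]


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Stationary distribution delta with delta' Gamma = delta'.

    Solves ``delta' (I - Gamma + U) = 1'`` with ``U`` the all-ones matrix.  If
    the chain is reducible or periodic so that the system is singular or gives
    an invalid distribution, falls back to the uniform distribution with a
    warning.
    """
    tpm = np.atleast_2d(np.asarray(tpm, dtype=float))
    n = tpm.shape[0]
    if n == 1:
        return np.ones(1)
    a = np.eye(n) - tpm + np.ones((n, n))
    try:
        delta = np.linalg.solve(a.T, np.ones(n))
    except np.linalg.LinAlgError:
        delta = None
    if delta is None or np.any(delta <= 0) or not np.isfinite(delta).all():
        warnings.warn(
            "transition matrix is reducible or periodic; "
            "falling back to a uniform initial distribution",
            stacklevel=2,
        )
        return np.full(n, 1.0 / n)
    return delta / delta.sum()


def steps_from_track(track, zero_length: str = "error"):
    """Step lengths and turning angles of a track.

    Parameters
    ----------
    track : array-like, shape (T, 2)
        Ordered locations.
    zero_length : {"error", "floor"}
        Policy for zero-length steps (which have no finite log length and no
        defined heading): raise, or floor lengths at 1e-6 times the median
        positive step length.

    Returns
    -------
    lengths : ndarray, shape (T - 1,)
    angles : ndarray, shape (T - 1,)
        Turning angle of step ``j`` relative to the heading of step ``j - 1``,
        wrapped to (-pi, pi]; ``angles[0]`` is NaN (no previous heading).
    """
    xy = np.asarray(track, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 3:
        raise ValueError("track must be an array of at least 3 (x, y) locations")
    d = np.diff(xy, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    if np.any(lengths == 0.0):
        if zero_length == "error":
            raise ValueError(
                f"zero-length step at index {int(np.flatnonzero(lengths == 0)[0])}"
            )
        eps = 1e-6 * np.median(lengths[lengths > 0])
        warnings.warn(
            f"flooring {int((lengths == 0).sum())} zero-length step(s) at {eps:g}",
            stacklevel=2,
        )
        lengths = np.maximum(lengths, eps)
    headings = np.arctan2(d[:, 1], d[:, 0])
    angles = np.full(lengths.shape, np.nan)
    angles[1:] = wrap_angle(np.diff(headings))
    return lengths, angles


def movement_covariates(lengths, angles=None, angle_model: str = "von_mises") -> np.ndarray:
    """Movement covariate vectors C for steps.

    Under the von Mises angle model ``C = (log l, -l, cos alpha)``; under the
    uniform model ``C = (log l, -l)``.
    """
    lengths = np.atleast_1d(np.asarray(lengths, dtype=float))
    if np.any(lengths <= 0):
        raise ValueError("step lengths must be > 0")
    if angle_model == "uniform":
        return np.column_stack([np.log(lengths), -lengths])
    if angle_model != "von_mises":
        raise ValueError(f"unknown angle model {angle_model!r}")
    if angles is None:
        raise ValueError("the von Mises model requires turning angles")
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if np.any(~np.isfinite(angles)):
        raise ValueError("turning angles must be finite under the von Mises model")
    return np.column_stack([np.log(lengths), -lengths, np.cos(angles)])


def log_step_weight(C, Z, state: StateParameters, proposal=None) -> np.ndarray:
    """Log selection weight ``C' theta_i + Z' beta_i`` of steps in state i.

    With ``proposal=None`` the movement coefficient vector is the natural map
    ``theta_i = (k_i - 1, r_i, kappa_i)`` (the exponent of the reduced
    step-selection density up to the ``-log l`` Jacobian term, which is
    omitted because weights are used over choice sets sampled in polar
    coordinates).  With a proposal distribution the coefficients are
    proposal-relative: ``(k_i - k0, r_i - r0, kappa_i - kappa0)``.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not (np.all(np.isfinite(C)) and np.all(np.isfinite(Z))):
        raise ValueError("covariates must be finite")
    kappa = 0.0 if state.concentration is None else state.concentration
    if proposal is None:
        theta = np.array([state.shape - 1.0, state.rate, kappa])
    else:
        theta = np.array(
            [
                state.shape - proposal.shape0,
                state.rate - proposal.rate0,
                kappa - proposal.concentration0,
            ]
        )
    theta = theta[: C.shape[1]]
    w = C @ theta + Z @ state.beta
    return w if w.shape[0] > 1 else float(w[0])


def _draw_kernel(rng, state: StateParameters, angle_model: str, size: int):
    lengths = rng.gamma(shape=state.shape, scale=1.0 / state.rate, size=size)
    if angle_model == "uniform" or state.concentration is None:
        angles = rng.uniform(-np.pi, np.pi, size=size)
    else:
        mu = 0.0 if state.concentration >= 0 else np.pi
        angles = wrap_angle(rng.vonmises(mu, abs(state.concentration), size=size))
    return lengths, angles


def simulate_track(
    model: HMMiSSAModel,
    field: CovariateField,
    T: int,
    x0=None,
    heading0: float | None = None,
    K: int = 1000,
    seed: int | None = None,
):
    """Simulate a track of ``T`` locations from a hidden Markov step-selection model.

    The hidden states follow the Markov chain ``(delta, Gamma)``.  Given the
    state, the next location is drawn by importance resampling: ``K`` candidate
    steps are drawn from the state's movement kernel (gamma length, von
    Mises/uniform angle) and one is selected with probability proportional to
    ``exp(Z' beta_i)`` evaluated at the candidate end points.  The draw is
    exact as ``K`` grows; for a spatially constant field it is exact for any
    ``K``.  Coordinates are continuous and unbounded; the covariate lookup
    wraps toroidally.

    Returns
    -------
    track : ndarray, shape (T, 2)
    states : ndarray, shape (T - 1,)
        True state (1-based) of each step.
    """
    if T < 3:
        raise ValueError("T must be >= 3")
    if K < 100:
        raise ValueError("K must be >= 100 for stable resampling")
    rng = np.random.default_rng(seed)
    n = model.n_states
    width, height = field.extent
    if x0 is None:
        x0 = (field.origin[0] + width / 2.0, field.origin[1] + height / 2.0)
    if heading0 is None:
        heading0 = rng.uniform(-np.pi, np.pi)

    # hidden state sequence, one state per step
    states = np.empty(T - 1, dtype=np.int64)
    states[0] = rng.choice(n, p=model.delta)
    for t in range(1, T - 1):
        states[t] = rng.choice(n, p=model.tpm[states[t - 1]])

    xy = np.empty((T, 2))
    xy[0] = x0
    heading = heading0
    min_ess = np.inf
    for t in range(T - 1):
        st = model.states[states[t]]
        lengths, turns = _draw_kernel(rng, st, model.angle_model, K)
        if t == 0:
            # no previous heading: candidate directions are uniform
            dirs = rng.uniform(-np.pi, np.pi, size=K)
        else:
            dirs = heading + turns
        ends = xy[t] + np.column_stack([lengths * np.cos(dirs), lengths * np.sin(dirs)])
        z = field.value_at(ends)
        logw = np.atleast_2d(z).T @ st.beta if st.beta.size > 1 else st.beta[0] * z
        logw = np.asarray(logw, dtype=float).reshape(K)
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        min_ess = min(min_ess, 1.0 / np.sum(w**2))
        j = int(rng.choice(K, p=w))
        xy[t + 1] = ends[j]
        heading = dirs[j]
    if min_ess < 10:
        warnings.warn(
            f"importance-resampling effective sample size dropped to {min_ess:.1f}; "
            "increase K for a faithful draw from the step-selection density",
            stacklevel=2,
        )
    return xy, states + 1


def write_track_csv(path, track, track_id="sim", burst=None) -> None:
    """Write a track to CSV with columns id, t, x, y (optionally burst)."""
    xy = np.asarray(track, dtype=float)
    frame = pd.DataFrame(
        {"id": track_id, "t": np.arange(xy.shape[0]), "x": xy[:, 0], "y": xy[:, 1]}
    )
    if burst is not None:
        frame["burst"] = np.asarray(burst)
    frame.to_csv(path, index=False)


def read_track_csv(path):
    """Read a track CSV (columns id, t, x, y, optional burst).

    Returns
    -------
    track : ndarray, shape (T, 2)
    burst : ndarray of burst labels, or None
    """
    frame = pd.read_csv(path)
    missing = {"t", "x", "y"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if "id" in frame.columns and frame["id"].nunique() > 1:
        raise ValueError(f"{path}: multiple track ids; read one individual at a time")
    frame = frame.sort_values("t")
    if not np.all(np.isfinite(frame[["x", "y"]].to_numpy())):
        bad = int(np.flatnonzero(~np.isfinite(frame[["x", "y"]].to_numpy()).all(axis=1))[0])
        raise ValueError(f"{path}: non-finite coordinates at row {bad + 2}")
    burst = frame["burst"].to_numpy() if "burst" in frame.columns else None
    return frame[["x", "y"]].to_numpy(), burst
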