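"""Case-control data sets for (Markov-switching) conditional logistic regression.

For every observed step with a defined turning angle, a choice set is formed
from the used step plus ``M`` control steps whose lengths are drawn from a
tentative (proposal) gamma distribution and whose turning angles are drawn
uniformly (or from a von Mises proposal for state-specific two-step fits).
Fitted regression coefficients on the movement covariates ``(log l, -l,
cos alpha)`` are then proposal-relative, and the natural movement parameters
are recovered by the exponential-family tilting identities

    k = k0 + coef(log l),   r = r0 + coef(-l),   kappa = kappa0 + coef(cos alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .landscape import CovariateField
from .movement import movement_covariates, steps_from_track, wrap_angle

__all__ = [
    "ProposalDistribution",
    "CaseControlData",
    "fit_tentative_gamma",
    "build_case_control",
    "recover_movement_parameters",
    "case_control_to_frame",
    "case_control_from_frame",
]


@dataclass(frozen=True)
class ProposalDistribution:
    """Proposal used to draw control steps.

    Lengths are gamma with tentative shape ``shape0`` and rate ``rate0``.
    Angles are uniform on (-pi, pi] when ``concentration0 == 0``; otherwise von
    Mises with concentration ``|concentration0|`` and mean 0 (or pi when
    ``concentration0 < 0``), as used for the state-specific proposals of the
    two-step approach.
    """

    shape0: float
    rate0: float
    concentration0: float = 0.0

    def __post_init__(self) -> None:
        if self.shape0 <= 0 or self.rate0 <= 0:
            raise ValueError("proposal shape and rate must be > 0")


def fit_tentative_gamma(lengths) -> ProposalDistribution:
    """Maximum-likelihood gamma fit to pooled observed step lengths.

    Falls back to a method-of-moments style estimate (with a warning) when the
    MLE is degenerate or fails to converge, e.g. for near-constant samples.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 step lengths")
    if np.any(x <= 0):
        raise ValueError("step lengths must be > 0")
    m, v = float(np.mean(x)), float(np.var(x))
    if v <= 1e-12 * m * m:
        warnings.warn(
            "step-length sample is (near-)constant; gamma MLE is degenerate — "
            "using a tight moment-style proposal around the mean",
            stacklevel=2,
        )
        return ProposalDistribution(shape0=100.0, rate0=100.0 / m)
    try:
        shape, _, scale = stats.gamma.fit(x, floc=0.0)
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
            raise ValueError("non-finite gamma MLE")
    except Exception:  # pragma: no cover - scipy failure path
        warnings.warn(
            "gamma MLE did not converge; falling back to method of moments",
            stacklevel=2,
        )
        return ProposalDistribution(shape0=m * m / v, rate0=m / v)
    return ProposalDistribution(shape0=float(shape), rate0=float(1.0 / scale))


@dataclass
class CaseControlData:
    """Choice sets of 1 used + M control steps with their covariates.

    ``C`` holds the movement covariates (row 0 of each set is the used step),
    ``Z`` the habitat covariates at the step end points, and ``endpoints`` the
    corresponding coordinates.  ``t_index`` is the (0-based) step index within
    the track for each choice set; ``segments`` partitions the sets into
    independent bursts for the forward algorithm.
    """

    C: np.ndarray  # (S, M + 1, pC)
    Z: np.ndarray  # (S, M + 1, pZ)
    endpoints: np.ndarray  # (S, M + 1, 2)
    t_index: np.ndarray  # (S,)
    proposal: ProposalDistribution
    angle_model: str = "von_mises"
    segments: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.segments is None:
            self.segments = [(0, self.C.shape[0])]
        if self.C.shape[:2] != self.Z.shape[:2]:
            raise ValueError("C and Z must agree on (n_sets, M + 1)")
        if not (np.all(np.isfinite(self.C)) and np.all(np.isfinite(self.Z))):
            raise ValueError("covariates must be finite")

    @property
    def n_sets(self) -> int:
        return self.C.shape[0]

    @property
    def M(self) -> int:
        return self.C.shape[1] - 1

    @property
    def used_lengths(self) -> np.ndarray:
        return np.exp(self.C[:, 0, 0])

    def subset(self, mask) -> "CaseControlData":
        """Choice sets selected by a boolean mask, as independent segments.

        Consecutive retained sets that were consecutive in the original data
        stay in one segment; gaps introduce segment boundaries.
        """
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError("subset mask selects no choice sets")
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        bounds = np.concatenate([[0], breaks, [idx.size]])
        segments = [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
        return CaseControlData(
            C=self.C[idx],
            Z=self.Z[idx],
            endpoints=self.endpoints[idx],
            t_index=self.t_index[idx],
            proposal=self.proposal,
            angle_model=self.angle_model,
            segments=segments,
        )


def _control_draws(proposal: ProposalDistribution, step_indices, M: int, seed):
    """Control (length, angle) draws for each choice set.

    Each choice set uses two counter-derived substreams (one for lengths, one
    for angles) keyed by the absolute step index, so increasing ``M`` extends
    the draws without reshuffling earlier ones, and subsetting the track keeps
    each set's controls unchanged.
    """
    S = len(step_indices)
    u = np.empty((S, M))
    angles = np.empty((S, M))
    mu0 = 0.0 if proposal.concentration0 >= 0 else np.pi
    for s, j in enumerate(step_indices):
        gl = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(int(j), 0)))
        ga = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(int(j), 1)))
        u[s] = gl.random(M)
        if proposal.concentration0 == 0.0:
            angles[s] = ga.random(M) * (2.0 * np.pi) - np.pi
        else:
            angles[s] = wrap_angle(ga.vonmises(mu0, abs(proposal.concentration0), M))
    # inverse-CDF transform keeps the per-set uniform draws in counter order
    lengths = special.gammaincinv(proposal.shape0, u) / proposal.rate0
    return lengths, angles


def build_case_control(
    track,
    field,
    M: int,
    proposal: ProposalDistribution,
    seed: int | None = None,
    angle_model: str = "von_mises",
    subset=None,
    burst=None,
    zero_length: str = "error",
) -> CaseControlData:
    """Assemble the case-control data set for a track.

    One choice set per step with a defined turning angle (steps 2..T-1 of a
    T-location track).  Control end points share the start point and reference
    heading of the used step.  ``field`` may be a single
    :class:`~switchssa.landscape.CovariateField` or a sequence of fields (one
    habitat covariate column each).  ``subset`` optionally restricts the choice
    sets by a boolean mask aligned to the steps with defined angles.  ``burst``
    optionally labels each track location; choice set ``j`` requires locations
    ``j - 1``, ``j`` and ``j + 1`` to share a burst, and no forward-algorithm
    segment spans a burst boundary.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    xy = np.asarray(track, dtype=float)
    lengths, angles = steps_from_track(xy, zero_length=zero_length)
    n_steps = lengths.size
    if n_steps < 2:
        raise ValueError("track too short for any choice set")
    d = np.diff(xy, axis=0)
    headings = np.arctan2(d[:, 1], d[:, 0])

    step_idx = np.arange(1, n_steps)  # steps with a defined turning angle
    keep = np.ones(step_idx.size, dtype=bool)
    if burst is not None:
        burst = np.asarray(burst)
        if burst.size != xy.shape[0]:
            raise ValueError("burst labels must align with the track locations")
        # choice set at step j uses locations j-1, j, j+1 (previous heading,
        # start and end point): all four labels must agree
        keep &= (
            (burst[step_idx - 1] == burst[step_idx])
            & (burst[step_idx] == burst[step_idx + 1])
        )
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        if subset.size != step_idx.size:
            raise ValueError("subset mask must align with the choice sets")
        keep &= subset
    restricted = burst is not None or subset is not None
    step_idx = step_idx[keep]
    if step_idx.size == 0:
        raise ValueError("no choice sets remain after subsetting")

    ctrl_len, ctrl_ang = _control_draws(proposal, step_idx, M, seed)
    all_len = np.column_stack([lengths[step_idx], ctrl_len])  # (S, M + 1)
    all_ang = np.column_stack([angles[step_idx], ctrl_ang])

    start = xy[step_idx]  # (S, 2)
    ref_heading = headings[step_idx - 1]
    dirs = ref_heading[:, None] + all_ang
    endpoints = np.stack(
        [
            start[:, 0][:, None] + all_len * np.cos(dirs),
            start[:, 1][:, None] + all_len * np.sin(dirs),
        ],
        axis=-1,
    )

    fields = [field] if isinstance(field, CovariateField) else list(field)
    flat = endpoints.reshape(-1, 2)
    Z = np.stack([f.value_at(flat) for f in fields], axis=-1).reshape(
        len(step_idx), M + 1, len(fields)
    )

    C = movement_covariates(
        all_len.ravel(), all_ang.ravel(), angle_model=angle_model
    ).reshape(len(step_idx), M + 1, -1)

    data = CaseControlData(
        C=C,
        Z=Z,
        endpoints=endpoints,
        t_index=step_idx,
        proposal=proposal,
        angle_model=angle_model,
    )
    if restricted:
        # segment structure must reflect gaps in the retained steps
        breaks = np.flatnonzero(np.diff(step_idx) > 1) + 1
        bounds = np.concatenate([[0], breaks, [step_idx.size]])
        data.segments = [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
    return data


def recover_movement_parameters(theta_hat, proposal: ProposalDistribution, angle_model="von_mises"):
    """Map fitted working coefficients back to natural movement parameters.

    ``theta_hat`` are the regression coefficients on ``(log l, -l, cos alpha)``
    (the last entry absent under the uniform-angle model).  Returns
    ``(shape, rate, concentration)`` with ``concentration=None`` under the
    uniform model.
    """
    theta_hat = np.atleast_1d(np.asarray(theta_hat, dtype=float))
    expected = 3 if angle_model == "von_mises" else 2
    if theta_hat.size != expected:
        raise ValueError(
            f"theta_hat has {theta_hat.size} entries, expected {expected} "
            f"for the {angle_model} model"
        )
    k = proposal.shape0 + theta_hat[0]
    r = proposal.rate0 + theta_hat[1]
    if k <= 0 or r <= 0:
        raise ValueError(
            f"recovered gamma parameters out of range (shape={k:.4g}, rate={r:.4g})"
        )
    kappa = proposal.concentration0 + theta_hat[2] if expected == 3 else None
    return float(k), float(r), None if kappa is None else float(kappa)


def case_control_to_frame(data: CaseControlData) -> pd.DataFrame:
    """Long-format frame: t, row, is_used, x, y, movement and habitat covariates."""
    S, Mp1, _ = data.C.shape
    t = np.repeat(data.t_index, Mp1)
    row = np.tile(np.arange(Mp1), S)
    out = {
        "t": t,
        "row": row,
        "is_used": (row == 0).astype(int),
        "x": data.endpoints[..., 0].ravel(),
        "y": data.endpoints[..., 1].ravel(),
        "log_l": data.C[..., 0].ravel(),
        "neg_l": data.C[..., 1].ravel(),
    }
    if data.angle_model == "von_mises":
        out["cos_a"] = data.C[..., 2].ravel()
    for j in range(data.Z.shape[-1]):
        out[f"z{j + 1}"] = data.Z[..., j].ravel()
    return pd.DataFrame(out)


def case_control_from_frame(
    frame: pd.DataFrame, proposal: ProposalDistribution
) -> CaseControlData:
    """Rebuild a :class:`CaseControlData` from its long-format frame."""
    angle_model = "von_mises" if "cos_a" in frame.columns else "uniform"
    t_vals = np.unique(frame["t"].to_numpy())
    Mp1 = int((frame["t"] == t_vals[0]).sum())
    frame = frame.sort_values(["t", "row"])
    ccols = ["log_l", "neg_l"] + (["cos_a"] if angle_model == "von_mises" else [])
    zcols = sorted(c for c in frame.columns if c.startswith("z"))
    S = t_vals.size
    data = CaseControlData(
        C=frame[ccols].to_numpy().reshape(S, Mp1, len(ccols)),
        Z=frame[zcols].to_numpy().reshape(S, Mp1, len(zcols)),
        endpoints=frame[["x", "y"]].to_numpy().reshape(S, Mp1, 2),
        t_index=t_vals,
        proposal=proposal,
        angle_model=angle_model,
    )
    breaks = np.flatnonzero(np.diff(t_vals) > 1) + 1
    bounds = np.concatenate([[0], breaks, [S]])
    data.segments = [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
    return data
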