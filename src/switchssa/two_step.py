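"""The two-step competitor (TS-iSSA): prior movement-HMM classification,
then state-specific conditional logistic step-selection fits.

Stage one fits a movement-only N-state HMM directly to the observed step
lengths and turning angles (gamma and zero/pi-mean von Mises state-dependent
densities) and Viterbi-decodes a state per step.  Stage two splits the steps
by decoded state and fits one plain conditional logistic step-selection model
per state, with control steps sampled from that state's fitted step-length and
turning-angle distributions.  Classification uncertainty is deliberately not
propagated into the second-stage standard errors — quantifying the
consequences of that omission is the point of including this estimator.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from ._core import (
    forward_backward,
    logits_from_tpm,
    tpm_from_logits,
    tpm_logit_gradient,
    viterbi,
)
from .case_control import ProposalDistribution, build_case_control
from .movement import StateParameters, stationary_distribution, steps_from_track
from .msclogit import HMMiSSA, _a1inv

__all__ = ["MovementHMM", "TwoStepISSA", "fit_movement_hmm", "ts_issa"]

_LOG_2PI = np.log(2.0 * np.pi)


def _emission_logdens(lengths, cos_a, log_l, k, r, kappa):
    """(S, N) log gamma x von Mises densities (uniform angles if kappa is None)."""
    out = (
        k * np.log(r)
        - special.gammaln(k)
        + (k - 1.0) * log_l[:, None]
        - r * lengths[:, None]
    )
    if kappa is None:
        out = out - _LOG_2PI
    else:
        # log I0 computed from the exponentially scaled Bessel function
        log_i0 = np.log(special.i0e(kappa)) + kappa
        out = out + kappa * cos_a[:, None] - _LOG_2PI - log_i0
    return out


def _mhmm_nll_grad(x, lengths, cos_a, log_l, N, vm, segments):
    k = np.exp(x[0:N])
    r = np.exp(x[N : 2 * N])
    i = 2 * N
    if vm:
        kappa = np.exp(x[i : i + N])
        i += N
    else:
        kappa = None
    if N > 1:
        tpm = tpm_from_logits(x[i:], N)
        delta = stationary_distribution(tpm)
    else:
        tpm = np.ones((1, 1))
        delta = np.ones(1)
    logf = _emission_logdens(lengths, cos_a, log_l, k, r, kappa)
    loglik, u, xi_sum, v0 = forward_backward(logf, tpm, delta, segments)

    grad = np.empty_like(x)
    # posterior-weighted scores of the state densities, chained to log scale
    s_k = np.log(r) - special.digamma(k) + 0.0  # constant part
    grad[0:N] = k * (u * (s_k[None, :] + log_l[:, None])).sum(axis=0)
    grad[N : 2 * N] = (u * (k[None, :] - r[None, :] * lengths[:, None])).sum(axis=0)
    i = 2 * N
    if vm:
        A = special.i1e(kappa) / special.i0e(kappa)
        grad[i : i + N] = kappa * (u * (cos_a[:, None] - A[None, :])).sum(axis=0)
        i += N
    if N > 1:
        grad[i:] = tpm_logit_gradient(xi_sum, tpm, delta, v0)
    return -loglik, -grad


class MovementHMM(BaseEstimator):
    """N-state hidden Markov model for step lengths and turning angles.

    State-dependent gamma step-length densities and zero-mean von Mises
    turning-angle densities (or uniform angles), a homogeneous Markov chain,
    forward-algorithm maximum likelihood with multi-start initialisation.
    This is the habitat-blind first stage of the two-step approach; it is also
    the data-generating model of the movement-only simulation scenario.

    Attributes
    ----------
    states_ : list of StateParameters (beta empty)
    tpm_, delta_ : fitted chain parameters
    loglik_, aic_, bic_ : fit summaries
    starts_ : per-start convergence records
    """

    def __init__(
        self,
        n_states: int = 2,
        angle_model: str = "von_mises",
        n_starts: int = 10,
        seed: int | None = None,
        maxiter: int = 2000,
        ftol: float = 1e-11,
        gtol: float = 1e-6,
    ):
        self.n_states = n_states
        self.angle_model = angle_model
        self.n_starts = n_starts
        self.seed = seed
        self.maxiter = maxiter
        self.ftol = ftol
        self.gtol = gtol

    def _starts(self, lengths, angles, rng):
        N = self.n_states
        vm = self.angle_model == "von_mises"
        order = np.argsort(lengths)
        bins = np.array_split(order, N)
        k0 = np.empty(N)
        r0 = np.empty(N)
        kap0 = np.empty(N)
        for i, idx in enumerate(bins):
            m = float(np.mean(lengths[idx]))
            v = max(float(np.var(lengths[idx])), 1e-8 * m * m)
            k0[i], r0[i] = m * m / v, m / v
            if vm:
                R = float(np.hypot(np.mean(np.cos(angles[idx])), np.mean(np.sin(angles[idx]))))
                kap0[i] = max(_a1inv(R), 0.05)
        out = []
        for s in range(self.n_starts):
            if s == 0:
                k, r, kap, diag = k0, r0, kap0, np.full(N, 0.9)
            else:
                mult = np.exp(rng.uniform(np.log(0.25), np.log(4.0), size=(3, N)))
                k, r = k0 * mult[0], r0 * mult[1]
                kap = np.maximum(kap0 * mult[2], 0.05)
                diag = rng.uniform(0.7, 0.95, size=N)
            x = [np.log(k), np.log(r)]
            if vm:
                x.append(np.log(kap))
            if N > 1:
                tpm = np.full((N, N), 0.0)
                for i in range(N):
                    tpm[i] = (1 - diag[i]) / (N - 1)
                    tpm[i, i] = diag[i]
                x.append(logits_from_tpm(tpm))
            out.append(np.concatenate(x))
        return out

    def fit(self, lengths, angles=None, segments=None):
        lengths = np.asarray(lengths, dtype=float)
        vm = self.angle_model == "von_mises"
        if vm:
            if angles is None:
                raise ValueError("the von Mises model requires turning angles")
            angles = np.asarray(angles, dtype=float)
            if np.any(~np.isfinite(angles)):
                raise ValueError("turning angles must be finite (drop undefined ones)")
            cos_a = np.cos(angles)
        else:
            angles = np.zeros_like(lengths)
            cos_a = np.zeros_like(lengths)
        if np.any(lengths <= 0):
            raise ValueError("step lengths must be > 0")
        log_l = np.log(lengths)
        if segments is None:
            segments = [(0, lengths.size)]
        N = self.n_states
        rng = np.random.default_rng(self.seed)

        records, best = [], None
        for s, x0 in enumerate(self._starts(lengths, angles, rng)):
            try:
                res = minimize(
                    _mhmm_nll_grad,
                    x0,
                    args=(lengths, cos_a, log_l, N, vm, segments),
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": self.maxiter, "ftol": self.ftol, "gtol": self.gtol},
                )
            except FloatingPointError as exc:
                records.append({"start": s, "loglik": -np.inf, "converged": False, "message": str(exc)})
                continue
            ll = -float(res.fun)
            records.append(
                {"start": s, "loglik": ll, "converged": bool(res.success), "n_iter": int(res.nit)}
            )
            if np.isfinite(ll) and (best is None or ll > best[1]):
                best = (res, ll)
        self.starts_ = records
        if best is None:
            raise RuntimeError(f"no movement-HMM start converged; diagnostics: {records}")
        res, ll = best

        x = res.x
        k = np.exp(x[0:N])
        r = np.exp(x[N : 2 * N])
        i = 2 * N
        kappa = np.exp(x[i : i + N]) if vm else [None] * N
        if vm:
            i += N
        self.tpm_ = tpm_from_logits(x[i:], N) if N > 1 else np.ones((1, 1))
        self.delta_ = stationary_distribution(self.tpm_)
        self.states_ = [
            StateParameters(
                shape=float(k[j]),
                rate=float(r[j]),
                concentration=None if not vm else float(kappa[j]),
                beta=np.zeros(0),
            )
            for j in range(N)
        ]
        self.working_ = x.copy()
        self.loglik_ = ll
        self.converged_ = bool(res.success)
        n_par = x.size
        self.aic_ = -2 * ll + 2 * n_par
        self.bic_ = -2 * ll + n_par * np.log(lengths.size)
        self._fit_args_ = (lengths, cos_a, log_l, segments)
        return self

    def predict(self, lengths=None, angles=None, segments=None) -> np.ndarray:
        """Viterbi state sequence (1-based); defaults to the training data."""
        if lengths is None:
            lengths, cos_a, log_l, segments = self._fit_args_
        else:
            lengths = np.asarray(lengths, dtype=float)
            cos_a = np.cos(np.asarray(angles, dtype=float)) if angles is not None else np.zeros_like(lengths)
            log_l = np.log(lengths)
            segments = segments or [(0, lengths.size)]
        vm = self.angle_model == "von_mises"
        k = np.array([s.shape for s in self.states_])
        r = np.array([s.rate for s in self.states_])
        kappa = np.array([s.concentration for s in self.states_]) if vm else None
        logf = _emission_logdens(lengths, cos_a, log_l, k, r, kappa)
        return viterbi(logf, self.tpm_, self.delta_, segments) + 1


class TwoStepISSA(BaseEstimator):
    """Two-step step-selection analysis (TS-iSSA).

    Stage one: :class:`MovementHMM` on the observed steps, Viterbi decoding.
    Stage two: for each decoded state, a state-specific case-control data set
    (controls drawn from that state's fitted gamma and von Mises
    distributions) and a single-state conditional logistic fit reusing the
    Markov-switching numerics with ``n_states=1``.  States with fewer than
    ``min_state_steps`` decoded steps are skipped with a warning.

    Attributes
    ----------
    movement_hmm_ : fitted MovementHMM
    decoded_ : 1-based decoded state per choice-set step
    proposals_ : per-state control-sampling proposals
    state_fits_ : dict state -> fitted single-state HMMiSSA (or None if skipped)
    """

    def __init__(
        self,
        n_states: int = 2,
        M: int = 100,
        n_starts: int = 10,
        clogit_starts: int = 2,
        seed: int | None = None,
        min_state_steps: int = 30,
        angle_model: str = "von_mises",
    ):
        self.n_states = n_states
        self.M = M
        self.n_starts = n_starts
        self.clogit_starts = clogit_starts
        self.seed = seed
        self.min_state_steps = min_state_steps
        self.angle_model = angle_model

    def fit(self, track, field):
        xy = np.asarray(track, dtype=float)
        lengths, angles = steps_from_track(xy)
        # steps with a defined turning angle, aligned with the choice sets
        l_obs, a_obs = lengths[1:], angles[1:]
        ss = np.random.SeedSequence(self.seed)
        seeds = [int(s.generate_state(1)[0] % np.iinfo(np.int32).max) for s in ss.spawn(1 + 2 * self.n_states)]
        self.movement_hmm_ = MovementHMM(
            n_states=self.n_states,
            angle_model=self.angle_model,
            n_starts=self.n_starts,
            seed=seeds[0],
        ).fit(l_obs, a_obs)
        self.decoded_ = self.movement_hmm_.predict()

        self.proposals_ = {}
        self.state_fits_ = {}
        for s in range(1, self.n_states + 1):
            mask = self.decoded_ == s
            if mask.sum() < self.min_state_steps:
                warnings.warn(
                    f"state {s}: only {int(mask.sum())} decoded steps "
                    f"(< {self.min_state_steps}); skipping its selection fit",
                    stacklevel=2,
                )
                self.state_fits_[s] = None
                continue
            st = self.movement_hmm_.states_[s - 1]
            proposal = ProposalDistribution(
                shape0=st.shape,
                rate0=st.rate,
                concentration0=0.0 if st.concentration is None else st.concentration,
            )
            self.proposals_[s] = proposal
            cc = build_case_control(
                xy,
                field,
                M=self.M,
                proposal=proposal,
                seed=seeds[2 * s - 1],
                angle_model=self.angle_model,
                subset=mask,
            )
            self.state_fits_[s] = HMMiSSA(
                n_states=1, n_starts=self.clogit_starts, seed=seeds[2 * s]
            ).fit(cc)
        return self

    def summary_frame(self):
        """Stacked per-state coefficient tables (column ``state`` is the decoded state)."""
        import pandas as pd

        frames = []
        for s, fit in self.state_fits_.items():
            if fit is None:
                continue
            f = fit.summary_frame()
            f["state"] = s
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def fit_movement_hmm(track, N: int = 2, n_starts: int = 10, seed=None, angle_model="von_mises") -> MovementHMM:
    """Fit a movement-only HMM to the steps of a track (angle-defined steps)."""
    lengths, angles = steps_from_track(np.asarray(track, dtype=float))
    return MovementHMM(
        n_states=N, angle_model=angle_model, n_starts=n_starts, seed=seed
    ).fit(lengths[1:], angles[1:])


def ts_issa(track, field, N: int = 2, M: int = 100, n_starts: int = 10, seed=None) -> TwoStepISSA:
    """Run the full two-step analysis on a track."""
    return TwoStepISSA(n_states=N, M=M, n_starts=n_starts, seed=seed).fit(track, field)
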