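"""Markov-switching conditional logistic regression (HMM-iSSA estimation core).

The model assigns each choice set a state-dependent choice probability

    p_{0,t,i} = exp(w_{0,t,i}) / sum_m exp(w_{m,t,i}),
    w_{m,t,i} = C_m' theta_i + Z_m' beta_i,

where the movement coefficients ``theta_i`` are proposal-relative
``(k_i - k0, r_i - r0, kappa_i - kappa0)``, and the states follow a hidden
Markov chain.  The likelihood is the HMM form

    L = delta' P(x~_3) Gamma P(x~_4) Gamma ... Gamma P(x~_T) 1,

evaluated by the scaled forward algorithm; independent bursts multiply.
Estimation is constrained maximum likelihood on a working scale (log gamma
shape/rate, free kappa and beta, multinomial logits for Gamma) with random
multi-start initialisation, using the analytic gradient obtained from
forward-backward posteriors.  The initial distribution delta is fixed at the
stationary distribution of Gamma; its dependence on Gamma is differentiated
exactly via the implicit-function theorem.

With ``n_states=1`` the model is the plain integrated step-selection analysis
(conditional logistic regression); with ``include_selection=False`` it is a
movement HMM fitted to the same case-control data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from ._core import (
    forward_backward,
    logits_from_tpm,
    tpm_from_logits,
    tpm_logit_gradient,
    viterbi,
)
from .case_control import CaseControlData, ProposalDistribution
from .movement import HMMiSSAModel, StateParameters, stationary_distribution

__all__ = [
    "HMMiSSA",
    "fit_hmm_issa",
    "choice_log_probabilities",
    "log_likelihood",
    "viterbi_decode",
    "wald_inference",
    "information_criteria",
    "save_fit_json",
    "load_fit_json",
]


@dataclass(frozen=True)
class _Layout:
    """Index layout of the working parameter vector."""

    N: int
    vm: bool  # von Mises angle model (cos alpha column present)
    pZ: int  # habitat covariates entering the selection function

    @property
    def pC(self) -> int:
        return 3 if self.vm else 2

    @property
    def n_free(self) -> int:
        return self.N * (self.pC + self.pZ) + self.N * (self.N - 1)

    def split(self, x: np.ndarray):
        N = self.N
        i = 0
        eta_k = x[i : i + N]
        i += N
        eta_r = x[i : i + N]
        i += N
        if self.vm:
            kappa = x[i : i + N]
            i += N
        else:
            kappa = None
        beta = x[i : i + N * self.pZ].reshape(N, self.pZ)
        i += N * self.pZ
        logits = x[i:] if N > 1 else np.empty(0)
        return eta_k, eta_r, kappa, beta, logits


def _coef_matrix(eta_k, eta_r, kappa, beta, layout: _Layout, proposal: ProposalDistribution):
    """(p, N) regression coefficients on the columns of [C, Z]."""
    k = np.exp(eta_k)
    r = np.exp(eta_r)
    rows = [k - proposal.shape0, r - proposal.rate0]
    if layout.vm:
        rows.append(kappa - proposal.concentration0)
    coefs = np.vstack(rows + [beta.T]) if layout.pZ else np.vstack(rows)
    return coefs, k, r


def _design(data: CaseControlData, layout: _Layout) -> np.ndarray:
    if layout.vm != (data.angle_model == "von_mises"):
        raise ValueError("angle model of the estimator and the data disagree")
    if layout.pZ:
        return np.concatenate([data.C, data.Z[..., : layout.pZ]], axis=-1)
    return data.C


def _nll_grad(x, layout: _Layout, X, data: CaseControlData):
    """Negative log-likelihood and its gradient on the working scale."""
    eta_k, eta_r, kappa, beta, logits = layout.split(x)
    coefs, k, r = _coef_matrix(eta_k, eta_r, kappa, beta, layout, data.proposal)
    N = layout.N
    if N > 1:
        tpm = tpm_from_logits(logits, N)
        delta = stationary_distribution(tpm)
    else:
        tpm = np.ones((1, 1))
        delta = np.ones(1)

    w = np.tensordot(X, coefs, axes=([2], [0]))  # (S, M + 1, N)
    lse = logsumexp(w, axis=1)  # (S, N)
    logp = w[:, 0, :] - lse
    loglik, u, xi_sum, v0 = forward_backward(logp, tpm, delta, data.segments)

    pi = np.exp(w - lse[:, None, :])  # softmax over choice-set rows
    expected = np.einsum("smn,smp->snp", pi, X)
    diff = X[:, 0, None, :] - expected  # (S, N, p)
    G = np.einsum("sn,snp->np", u, diff)

    grad = np.empty_like(x)
    i = 0
    grad[i : i + N] = G[:, 0] * k
    i += N
    grad[i : i + N] = G[:, 1] * r
    i += N
    if layout.vm:
        grad[i : i + N] = G[:, 2]
        i += N
    if layout.pZ:
        grad[i : i + N * layout.pZ] = G[:, layout.pC :].ravel()
        i += N * layout.pZ
    if N > 1:
        grad[i:] = tpm_logit_gradient(xi_sum, tpm, delta, v0)
    return -loglik, -grad


def _log_choice_probs(model: HMMiSSAModel, data: CaseControlData) -> np.ndarray:
    """(S, N) log state-dependent choice probabilities at natural parameters."""
    layout = _Layout(model.n_states, data.angle_model == "von_mises", model.states[0].beta.size)
    eta_k = np.log([s.shape for s in model.states])
    eta_r = np.log([s.rate for s in model.states])
    kappa = (
        np.array([s.concentration for s in model.states]) if layout.vm else None
    )
    beta = np.vstack([s.beta for s in model.states])
    coefs, _, _ = _coef_matrix(eta_k, eta_r, kappa, beta, layout, data.proposal)
    X = _design(data, layout)
    w = np.tensordot(X, coefs, axes=([2], [0]))
    return w[:, 0, :] - logsumexp(w, axis=1)


def choice_log_probabilities(data: CaseControlData, model: HMMiSSAModel) -> np.ndarray:
    """Log choice probabilities ``log p_{0,t,i}`` for every choice set and state."""
    return _log_choice_probs(model, data)


def log_likelihood(model: HMMiSSAModel, data: CaseControlData) -> float:
    """Forward-algorithm log-likelihood of a model on case-control data."""
    logp = _log_choice_probs(model, data)
    ll, *_ = forward_backward(logp, model.tpm, model.delta, data.segments)
    return ll


_A1INV_BREAKS = (0.53, 0.85)


def _a1inv(R: float) -> float:
    """Approximate inverse of the von Mises mean resultant length A(kappa)."""
    R = min(abs(R), 0.975)
    if R < _A1INV_BREAKS[0]:
        return 2 * R + R**3 + 5 * R**5 / 6
    if R < _A1INV_BREAKS[1]:
        return -0.4 + 1.39 * R + 0.43 / (1 - R)
    return 1.0 / (R**3 - 4 * R**2 + 3 * R)


class HMMiSSA(BaseEstimator):
    """Markov-switching conditional logistic regression for step selection.

    Parameters
    ----------
    n_states : int
        Number of hidden behavioural states N (``1`` gives the plain iSSA).
    include_selection : bool
        If False, drop the habitat covariates: the fit is a movement HMM
        approximation on the same case-control data.
    n_starts : int
        Number of random starting-value sets for the numerical maximisation.
    seed : int or None
        Seed for the starting-value draws.
    maxiter, ftol, gtol : optimizer control (L-BFGS-B).
    same_optimum_tol : float
        Two converged starts whose log-likelihoods differ by less than this are
        counted as the same optimum in the multimodality diagnostic.

    Attributes
    ----------
    model_ : HMMiSSAModel
        Natural-scale estimates.
    working_ : ndarray
        Working-scale estimates (log shape, log rate, kappa, beta, tpm logits).
    loglik_, aic_, bic_, n_parameters_, n_obs_ : fit summaries.
    hessian_, cov_ : observed information of the negative log-likelihood at the
        optimum on the working scale, and its inverse.
    starts_ : list of per-start convergence records.
    n_distinct_optima_ : multimodality diagnostic across converged starts.
    """

    def __init__(
        self,
        n_states: int = 2,
        include_selection: bool = True,
        n_starts: int = 50,
        seed: int | None = None,
        maxiter: int = 2000,
        ftol: float = 1e-11,
        gtol: float = 1e-6,
        same_optimum_tol: float = 1e-4,
    ):
        self.n_states = n_states
        self.include_selection = include_selection
        self.n_starts = n_starts
        self.seed = seed
        self.maxiter = maxiter
        self.ftol = ftol
        self.gtol = gtol
        self.same_optimum_tol = same_optimum_tol

    # -- starting values -------------------------------------------------
    def _starting_values(self, data: CaseControlData, layout: _Layout, rng):
        l0 = data.used_lengths
        N = layout.N
        order = np.argsort(l0)
        bins = np.array_split(order, N)
        k0 = np.empty(N)
        r0 = np.empty(N)
        kap0 = np.empty(N)
        for i, idx in enumerate(bins):
            m = float(np.mean(l0[idx]))
            v = max(float(np.var(l0[idx])), 1e-8 * m * m)
            k0[i] = m * m / v
            r0[i] = m / v
            if layout.vm:
                mc = float(np.mean(data.C[idx, 0, 2]))
                kap0[i] = np.sign(mc) * _a1inv(min(abs(mc), 0.95)) if mc != 0 else 0.1
        starts = []
        for s in range(self.n_starts):
            if s == 0:
                k, r, kap = k0, r0, kap0
                beta = np.zeros((N, layout.pZ))
                diag = np.full(N, 0.9)
            else:
                mult = np.exp(rng.uniform(np.log(0.25), np.log(4.0), size=(3, N)))
                k = k0 * mult[0]
                r = r0 * mult[1]
                kap = np.sign(kap0) * np.maximum(np.abs(kap0) * mult[2], 0.05)
                beta = rng.uniform(-2.0, 2.0, size=(N, layout.pZ))
                diag = rng.uniform(0.7, 0.95, size=N)
            x = [np.log(k), np.log(r)]
            if layout.vm:
                x.append(kap)
            x.append(beta.ravel())
            if N > 1:
                tpm = np.full((N, N), 0.0)
                for i in range(N):
                    tpm[i] = (1 - diag[i]) / (N - 1)
                    tpm[i, i] = diag[i]
                x.append(logits_from_tpm(tpm))
            starts.append(np.concatenate(x))
        return starts

    # -- fitting ---------------------------------------------------------
    def fit(self, X: CaseControlData, y=None):
        data = X
        if not isinstance(data, CaseControlData):
            raise TypeError("fit expects a CaseControlData instance")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        pZ = data.Z.shape[-1] if self.include_selection else 0
        layout = _Layout(self.n_states, data.angle_model == "von_mises", pZ)
        Xd = _design(data, layout)
        rng = np.random.default_rng(self.seed)
        starts = self._starting_values(data, layout, rng)

        records = []
        best = None
        for s, x0 in enumerate(starts):
            try:
                res = optimize.minimize(
                    _nll_grad,
                    x0,
                    args=(layout, Xd, data),
                    jac=True,
                    method="L-BFGS-B",
                    options={
                        "maxiter": self.maxiter,
                        "ftol": self.ftol,
                        "gtol": self.gtol,
                    },
                )
            except FloatingPointError as exc:
                records.append(
                    {"start": s, "loglik": -np.inf, "converged": False, "message": str(exc)}
                )
                continue
            ll = -float(res.fun)
            records.append(
                {
                    "start": s,
                    "loglik": ll,
                    "converged": bool(res.success),
                    "n_iter": int(res.nit),
                    "message": str(res.message),
                }
            )
            if np.isfinite(ll) and (best is None or ll > best[1]):
                best = (res, ll)
        self.starts_ = records
        if best is None:
            raise RuntimeError(
                "no starting value led to a finite log-likelihood; "
                f"per-start diagnostics: {records}"
            )
        res, ll = best
        if not res.success:
            warnings.warn(
                f"best start did not formally converge: {res.message}", stacklevel=2
            )
        finite = sorted(
            (r["loglik"] for r in records if np.isfinite(r["loglik"])), reverse=True
        )
        self.n_distinct_optima_ = 1 + sum(
            1
            for a, b in zip(finite[:-1], finite[1:])
            if a - b > self.same_optimum_tol
        )

        self.working_ = res.x.copy()
        self.loglik_ = ll
        self._layout_ = layout
        self.proposal_ = data.proposal
        self.n_obs_ = data.n_sets
        self.n_parameters_ = layout.n_free
        self.converged_ = bool(res.success)

        eta_k, eta_r, kappa, beta, logits = layout.split(self.working_)
        tpm = tpm_from_logits(logits, layout.N) if layout.N > 1 else np.ones((1, 1))
        states = [
            StateParameters(
                shape=float(np.exp(eta_k[i])),
                rate=float(np.exp(eta_r[i])),
                concentration=float(kappa[i]) if layout.vm else None,
                beta=beta[i] if layout.pZ else np.zeros(0),
            )
            for i in range(layout.N)
        ]
        angle_model = "von_mises" if layout.vm else "uniform"
        self.model_ = HMMiSSAModel(tpm=tpm, states=states, angle_model=angle_model)

        self.hessian_ = self._numeric_hessian(self.working_, layout, Xd, data)
        try:
            self.cov_ = np.linalg.inv(self.hessian_)
            if np.any(np.diag(self.cov_) <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
        except np.linalg.LinAlgError:
            warnings.warn(
                "observed information is singular; standard errors are NA",
                stacklevel=2,
            )
            self.cov_ = np.full_like(self.hessian_, np.nan)
        self.aic_ = -2.0 * ll + 2.0 * self.n_parameters_
        self.bic_ = -2.0 * ll + self.n_parameters_ * np.log(self.n_obs_)
        return self

    def _numeric_hessian(self, x, layout, Xd, data, h: float = 1e-5):
        n = x.size
        H = np.empty((n, n))
        for j in range(n):
            step = h * (1.0 + abs(x[j]))
            xp = x.copy()
            xp[j] += step
            xm = x.copy()
            xm[j] -= step
            _, gp = _nll_grad(xp, layout, Xd, data)
            _, gm = _nll_grad(xm, layout, Xd, data)
            H[j] = (gp - gm) / (2.0 * step)
        return 0.5 * (H + H.T)

    # -- post-fit --------------------------------------------------------
    def score(self, X: CaseControlData, y=None) -> float:
        return log_likelihood(self.model_, X)

    def predict(self, X: CaseControlData) -> np.ndarray:
        """Viterbi-decoded state sequence (1-based), bursts decoded independently."""
        logp = _log_choice_probs(self.model_, X)
        return viterbi(logp, self.model_.tpm, self.model_.delta, X.segments) + 1

    def summary_frame(self) -> pd.DataFrame:
        """Per-coefficient estimates, standard errors, z and p-values.

        Selection coefficients are reported on the natural (= working) scale
        with Wald p-values; movement parameters are reported on the natural
        scale with delta-method standard errors and no p-values by default.
        """
        layout = self._layout_
        se_work = np.sqrt(np.diag(self.cov_))
        rows = []
        i = 0
        for name, trans in (("shape", "exp"), ("rate", "exp")):
            for st in range(layout.N):
                est = float(np.exp(self.working_[i]))
                rows.append(
                    {
                        "parameter": name,
                        "state": st + 1,
                        "estimate": est,
                        "se": est * se_work[i],  # delta method from the log scale
                        "z": np.nan,
                        "p": np.nan,
                    }
                )
                i += 1
        if layout.vm:
            for st in range(layout.N):
                rows.append(
                    {
                        "parameter": "concentration",
                        "state": st + 1,
                        "estimate": float(self.working_[i]),
                        "se": se_work[i],
                        "z": np.nan,
                        "p": np.nan,
                    }
                )
                i += 1
        for st in range(layout.N):
            for j in range(layout.pZ):
                est = float(self.working_[i])
                se = se_work[i]
                z = est / se if se > 0 else np.nan
                rows.append(
                    {
                        "parameter": f"beta{j + 1}",
                        "state": st + 1,
                        "estimate": est,
                        "se": se,
                        "z": z,
                        "p": 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    }
                )
                i += 1
        return pd.DataFrame(rows)


def fit_hmm_issa(
    data: CaseControlData,
    N: int = 2,
    n_starts: int = 50,
    seed: int | None = None,
    include_selection: bool = True,
    **control,
) -> HMMiSSA:
    """Fit an N-state Markov-switching conditional logistic regression."""
    return HMMiSSA(
        n_states=N,
        include_selection=include_selection,
        n_starts=n_starts,
        seed=seed,
        **control,
    ).fit(data)


def viterbi_decode(fitted: HMMiSSA, data: CaseControlData) -> np.ndarray:
    """Most likely state sequence (1-based) given the fitted model and data."""
    return fitted.predict(data)


def wald_inference(fitted: HMMiSSA) -> pd.DataFrame:
    """Coefficient table with standard errors, z statistics and p-values."""
    return fitted.summary_frame()


def information_criteria(fitted: HMMiSSA) -> tuple[float, float]:
    """(AIC, BIC) with BIC based on the number of choice sets."""
    return fitted.aic_, fitted.bic_


def fit_to_dict(fitted: HMMiSSA) -> dict:
    model = fitted.model_
    return {
        "n_states": model.n_states,
        "angle_model": model.angle_model,
        "states": [
            {
                "shape": s.shape,
                "rate": s.rate,
                "concentration": s.concentration,
                "beta": s.beta.tolist(),
            }
            for s in model.states
        ],
        "tpm": model.tpm.tolist(),
        "delta": model.delta.tolist(),
        "proposal": {
            "shape0": fitted.proposal_.shape0,
            "rate0": fitted.proposal_.rate0,
            "concentration0": fitted.proposal_.concentration0,
        },
        "working": fitted.working_.tolist(),
        "loglik": fitted.loglik_,
        "aic": fitted.aic_,
        "bic": fitted.bic_,
        "n_parameters": fitted.n_parameters_,
        "n_choice_sets": fitted.n_obs_,
        "coefficients": fitted.summary_frame().to_dict(orient="records"),
        "starts": fitted.starts_,
        "n_distinct_optima": fitted.n_distinct_optima_,
    }


def save_fit_json(fitted: HMMiSSA, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fitted), fh, indent=2, allow_nan=True)


def load_fit_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
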