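"""Simulation scenarios and the study runner comparing iSSA, TS-iSSA and HMM-iSSA.

Four data-generating scenarios on a Gaussian-random-field landscape
(variance 1, correlation range 10), each a 2-state hidden Markov
step-selection model with persistent states (diagonal transition
probabilities 0.9) except the single-state scenario 4:

1. active-inactive      — state 1: short undirected steps, no selection;
                          state 2: long directed steps, attraction (beta = 2).
2. switching preferences — both states share one movement kernel but select in
                          opposite directions (beta = -2 vs +2).
3. movement HMM         — state-dependent kernels, no selection in either state.
4. no state-switching   — a single state with selection (plain iSSA model).

Per simulated track the runner fits any subset of: the plain iSSA (N=1), the
two-step TS-iSSA, the joint HMM-iSSA, the HMM-iSSA without selection
covariates (the "HMM" candidate for model selection on the same case-control
data) and the movement-only HMM fitted directly to the steps.  It collects
natural-scale estimates, Wald p-values, AIC/BIC and Viterbi misclassification
rates, with state labels aligned to the simulation truth by the permutation
minimising misclassification.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .case_control import build_case_control, fit_tentative_gamma
from .landscape import GRFConfig, simulate_grf
from .movement import HMMiSSAModel, StateParameters, simulate_track, steps_from_track
from .msclogit import HMMiSSA
from .two_step import MovementHMM, TwoStepISSA

__all__ = [
    "Scenario",
    "StudyResult",
    "scenario_parameters",
    "misclassification_rate",
    "run_simulation_study",
    "run_single",
]

_DEFAULT_GRF = GRFConfig(nx=100, ny=100, variance=1.0, corr_range=10.0)

_SCENARIO_TABLE = {
    # id: [(beta, shape, rate, concentration) per state]
    1: [(0.0, 1.20, 1.25, 0.30), (2.0, 2.50, 0.29, 1.00)],
    2: [(-2.0, 2.50, 0.29, 1.00), (2.0, 2.50, 0.29, 1.00)],
    3: [(0.0, 1.20, 1.25, 0.30), (0.0, 2.50, 0.29, 1.00)],
    4: [(2.0, 2.50, 0.29, 1.00)],
}

ALL_METHODS = ("issa", "ts_issa", "hmm_issa", "hmm_nosel", "mhmm")


@dataclass
class Scenario:
    """A data-generating configuration of the simulation study."""

    id: int
    model: HMMiSSAModel
    grf: GRFConfig = _DEFAULT_GRF

    @property
    def true_values(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.model.states, start=1):
            rows.append(
                {
                    "state": i,
                    "beta1": float(s.beta[0]) if s.beta.size else 0.0,
                    "shape": s.shape,
                    "rate": s.rate,
                    "concentration": s.concentration,
                }
            )
        return pd.DataFrame(rows)


def scenario_parameters(scenario_id: int, grf: GRFConfig | None = None) -> Scenario:
    """The study's data-generating model for a scenario id in {1, 2, 3, 4}."""
    if scenario_id not in _SCENARIO_TABLE:
        raise ValueError(f"unknown scenario id {scenario_id!r}")
    params = _SCENARIO_TABLE[scenario_id]
    n = len(params)
    tpm = np.array([[0.9, 0.1], [0.1, 0.9]]) if n == 2 else np.ones((1, 1))
    states = [
        StateParameters(shape=k, rate=r, concentration=kap, beta=np.array([b]))
        for b, k, r, kap in params
    ]
    model = HMMiSSAModel(tpm=tpm, states=states, angle_model="von_mises")
    return Scenario(id=scenario_id, model=model, grf=grf or _DEFAULT_GRF)


def _best_permutation(decoded, truth, n_states: int):
    """Permutation of fitted labels minimising the mismatch with the truth.

    Returns ``(perm, misclass_percent)`` where ``perm[j - 1]`` is the true
    state label assigned to fitted state ``j``.
    """
    decoded = np.asarray(decoded)
    truth = np.asarray(truth)
    if decoded.shape != truth.shape:
        raise ValueError("decoded and true state sequences differ in length")
    best = (None, np.inf)
    for perm in itertools.permutations(range(1, n_states + 1)):
        mapped = np.asarray(perm)[decoded - 1]
        err = float(np.mean(mapped != truth))
        if err < best[1]:
            best = (perm, err)
    return best[0], 100.0 * best[1]


def misclassification_rate(decoded, truth) -> float:
    """Percentage of states incorrectly classified, minimised over label permutations."""
    n = int(max(np.max(decoded), np.max(truth)))
    return _best_permutation(decoded, truth, n)[1]


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % np.iinfo(np.int32).max)


def _state_rows(base: dict, est: HMMiSSA, perm) -> list[dict]:
    """Per-state records of a fitted (possibly single-state) model."""
    summary = est.summary_frame()
    rows = []
    for j, st in enumerate(est.model_.states, start=1):
        sub = summary[summary["state"] == j].set_index("parameter")
        has_beta = "beta1" in sub.index
        rows.append(
            base
            | {
                "state": perm[j - 1] if perm is not None else 0,
                "shape": st.shape,
                "rate": st.rate,
                "concentration": st.concentration,
                "beta1": float(st.beta[0]) if st.beta.size else np.nan,
                "se_beta1": float(sub.loc["beta1", "se"]) if has_beta else np.nan,
                "p_beta1": float(sub.loc["beta1", "p"]) if has_beta else np.nan,
                "loglik": est.loglik_,
                "aic": est.aic_,
                "bic": est.bic_,
                "converged": est.converged_,
            }
        )
    return rows


def run_single(
    scenario: Scenario,
    run_idx: int,
    seed: int,
    T: int = 1000,
    M_list=(20,),
    methods=ALL_METHODS,
    n_starts: int = 5,
    n_states_fit: int = 2,
    K: int = 1000,
    ts_min_state_steps: int = 30,
) -> list[dict]:
    """Simulate one track and fit the requested candidate models.

    Returns one record per (method, M, state); state labels are aligned to the
    simulation truth, ``state=0`` marks single-state fits.
    """
    sid = scenario.id
    field = simulate_grf(scenario.grf, seed=_child_seed(seed, sid, run_idx, 0))
    track, truth = simulate_track(
        scenario.model, field, T=T, K=K, seed=_child_seed(seed, sid, run_idx, 1)
    )
    lengths, angles = steps_from_track(track)
    truth_cs = truth[1:]  # truth aligned to the choice sets (angle-defined steps)
    proposal = fit_tentative_gamma(lengths)

    records: list[dict] = []

    def base(method, M):
        return {
            "scenario": sid,
            "run": run_idx,
            "method": method,
            "M": M,
            "n_sets": T - 2,
        }

    if "mhmm" in methods:
        mhmm = MovementHMM(
            n_states=n_states_fit,
            n_starts=n_starts,
            seed=_child_seed(seed, sid, run_idx, 2),
        ).fit(lengths[1:], angles[1:])
        perm, mis = _best_permutation(mhmm.predict(), truth_cs, n_states_fit)
        for j, st in enumerate(mhmm.states_, start=1):
            records.append(
                base("mhmm", 0)
                | {
                    "state": perm[j - 1],
                    "shape": st.shape,
                    "rate": st.rate,
                    "concentration": st.concentration,
                    "beta1": np.nan,
                    "se_beta1": np.nan,
                    "p_beta1": np.nan,
                    "loglik": mhmm.loglik_,
                    "aic": mhmm.aic_,
                    "bic": mhmm.bic_,
                    "misclass": mis,
                    "converged": mhmm.converged_,
                }
            )

    for M in M_list:
        needed = {"issa", "hmm_issa", "hmm_nosel"} & set(methods)
        if needed:
            cc = build_case_control(
                track, field, M=M, proposal=proposal,
                seed=_child_seed(seed, sid, run_idx, 3, M),
            )
        if "issa" in methods:
            est = HMMiSSA(
                n_states=1, n_starts=max(2, n_starts // 2),
                seed=_child_seed(seed, sid, run_idx, 4, M),
            ).fit(cc)
            for row in _state_rows(base("issa", M), est, perm=None):
                records.append(row | {"misclass": np.nan})
        if "hmm_issa" in methods:
            est = HMMiSSA(
                n_states=n_states_fit, n_starts=n_starts,
                seed=_child_seed(seed, sid, run_idx, 5, M),
            ).fit(cc)
            perm, mis = _best_permutation(est.predict(cc), truth_cs, n_states_fit)
            for row in _state_rows(base("hmm_issa", M), est, perm):
                records.append(row | {"misclass": mis})
        if "hmm_nosel" in methods:
            est = HMMiSSA(
                n_states=n_states_fit, include_selection=False, n_starts=n_starts,
                seed=_child_seed(seed, sid, run_idx, 6, M),
            ).fit(cc)
            perm, mis = _best_permutation(est.predict(cc), truth_cs, n_states_fit)
            for row in _state_rows(base("hmm_nosel", M), est, perm):
                records.append(row | {"misclass": mis})
        if "ts_issa" in methods:
            ts = TwoStepISSA(
                n_states=n_states_fit, M=M, n_starts=n_starts,
                seed=_child_seed(seed, sid, run_idx, 7, M),
                min_state_steps=ts_min_state_steps,
            ).fit(track, field)
            perm, mis = _best_permutation(ts.decoded_, truth_cs, n_states_fit)
            for s, fit in ts.state_fits_.items():
                if fit is None:
                    records.append(
                        base("ts_issa", M)
                        | {"state": perm[s - 1], "misclass": mis, "converged": False,
                           "skipped": True}
                    )
                    continue
                row = _state_rows(base("ts_issa", M), fit, perm=None)[0]
                row["state"] = perm[s - 1]
                records.append(row | {"misclass": mis, "skipped": False})
    return records


@dataclass
class StudyResult:
    """Per-run records of the simulation study plus aggregation helpers.

    Aggregations are pure functions of ``records``: re-aggregating the same
    records reproduces the tables exactly.
    """

    records: pd.DataFrame
    scenarios: list[Scenario] = dataclass_field(default_factory=list)

    def table2(self, alpha: float = 0.05) -> pd.DataFrame:
        """% of runs with a significant selection coefficient per state."""
        sel = self.records.dropna(subset=["p_beta1"])
        out = (
            sel.assign(sig=sel["p_beta1"] < alpha)
            .groupby(["scenario", "method", "M", "state"])["sig"]
            .agg(percent_significant=lambda s: 100.0 * s.mean(), n_runs="size")
            .reset_index()
        )
        return out

    def table3(self) -> pd.DataFrame:
        """Mean (sd) Viterbi misclassification rate per scenario and model."""
        mis = self.records.dropna(subset=["misclass"])
        mis = mis[mis["state"] == 1]  # one row per run x method x M
        out = (
            mis.groupby(["scenario", "method", "M"])["misclass"]
            .agg(mean="mean", sd="std", n_runs="size")
            .reset_index()
        )
        return out

    def table4(self) -> pd.DataFrame:
        """% of runs each candidate wins AIC and BIC, per scenario and M."""
        cand = self.records[
            self.records["method"].isin(["issa", "hmm_nosel", "hmm_issa"])
        ]
        one = cand.drop_duplicates(["scenario", "run", "method", "M"])
        rows = []
        for (sc, M), grp in one.groupby(["scenario", "M"]):
            wide_aic = grp.pivot(index="run", columns="method", values="aic").dropna()
            wide_bic = grp.pivot(index="run", columns="method", values="bic").dropna()
            if wide_aic.empty:
                continue
            for crit, wide in (("AIC", wide_aic), ("BIC", wide_bic)):
                winners = wide.idxmin(axis=1)
                for method in wide.columns:
                    rows.append(
                        {
                            "scenario": sc,
                            "M": M,
                            "criterion": crit,
                            "method": method,
                            "percent_selected": 100.0 * float((winners == method).mean()),
                            "n_runs": int(winners.size),
                        }
                    )
        return pd.DataFrame(rows)

    def fig3_summary(self) -> pd.DataFrame:
        """Estimate distributions and bias per scenario, method, M, state, parameter."""
        truth = {}
        for sc in self.scenarios:
            for _, row in sc.true_values.iterrows():
                for par in ("beta1", "shape", "rate", "concentration"):
                    truth[(sc.id, int(row["state"]), par)] = row[par]
        frames = []
        est = self.records
        for par in ("beta1", "shape", "rate", "concentration"):
            if par not in est.columns:
                continue
            sub = est.dropna(subset=[par])
            g = (
                sub.groupby(["scenario", "method", "M", "state"])[par]
                .agg(
                    mean="mean",
                    sd="std",
                    median="median",
                    q25=lambda s: s.quantile(0.25),
                    q75=lambda s: s.quantile(0.75),
                    n_runs="size",
                )
                .reset_index()
            )
            g["parameter"] = par
            g["truth"] = [
                truth.get((sc, st, par), np.nan)
                for sc, st in zip(g["scenario"], g["state"])
            ]
            g["bias"] = g["mean"] - g["truth"]
            frames.append(g)
        return pd.concat(frames, ignore_index=True)

    def save_tables(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "runs.csv", index=False)
        self.table2().to_csv(out / "table2.csv", index=False)
        self.table3().to_csv(out / "table3.csv", index=False)
        self.table4().to_csv(out / "table4.csv", index=False)
        self.fig3_summary().to_csv(out / "fig3_summary.csv", index=False)


def run_simulation_study(
    scenario_ids=(1, 2, 3),
    n_runs: int = 20,
    T: int = 1000,
    M_list=(20,),
    methods=ALL_METHODS,
    seed: int = 0,
    n_starts: int = 5,
    K: int = 1000,
    workers: int = 1,
    grf: GRFConfig | None = None,
    skip=frozenset(),
    progress: bool = False,
) -> StudyResult:
    """Run the simulation study.

    Runs are independent given the master seed: each run's landscape, track,
    control draws and fit initialisations use seeds derived from
    ``(seed, scenario, run)``, so any scheduling (``workers`` > 1 uses joblib)
    yields identical per-run records, and a run's simulated data are the same
    whichever method subset or M list is requested.
    """
    scenarios = [scenario_parameters(sid, grf) for sid in scenario_ids]
    tasks = [
        (sc, i) for sc in scenarios for i in range(n_runs) if (sc.id, i) not in skip
    ]

    def _one(sc, i):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return run_single(
                sc, i, seed=seed, T=T, M_list=M_list, methods=methods,
                n_starts=n_starts, K=K,
                n_states_fit=max(2, sc.model.n_states),
            )

    if workers > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=workers)(delayed(_one)(sc, i) for sc, i in tasks)
    else:
        chunks = []
        for j, (sc, i) in enumerate(tasks):
            chunks.append(_one(sc, i))
            if progress:
                print(f"run {j + 1}/{len(tasks)} done", flush=True)
    records = pd.DataFrame([r for chunk in chunks for r in chunk])
    return StudyResult(records=records, scenarios=scenarios)
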