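"""Shared fixtures: small landscapes, simulated tracks and case-control data."""

import numpy as np
import pytest

import switchssa as sw


@pytest.fixture(scope="session")
def flat_field():
    """Spatially constant covariate field (value 0 everywhere)."""
    return sw.CovariateField(np.zeros((20, 20)), resolution=1.0)


@pytest.fixture(scope="session")
def rough_field():
    """A small simulated landscape with the study covariance (var 1, range 10)."""
    return sw.simulate_grf(sw.GRFConfig(nx=60, ny=60), seed=42)


@pytest.fixture(scope="session")
def scenario1():
    return sw.scenario_parameters(1)


@pytest.fixture(scope="session")
def scenario1_data(scenario1, rough_field):
    """One scenario-1 track with its truth, proposal and an M=20 choice-set data set."""
    track, truth = sw.simulate_track(scenario1.model, rough_field, T=800, K=500, seed=7)
    lengths, angles = sw.steps_from_track(track)
    proposal = sw.fit_tentative_gamma(lengths)
    cc = sw.build_case_control(track, rough_field, M=20, proposal=proposal, seed=8)
    return {
        "track": track,
        "truth": truth,
        "lengths": lengths,
        "angles": angles,
        "proposal": proposal,
        "cc": cc,
        "field": rough_field,
    }


@pytest.fixture(scope="session")
def toy_choice_data():
    """Tiny random choice-set data (4 sets, M=3, 2 states feasible) for oracles."""
    rng = np.random.default_rng(5)
    S, M = 4, 3
    lengths = rng.gamma(2.0, 1.0, size=(S, M + 1)) + 0.1
    angles = rng.uniform(-np.pi, np.pi, size=(S, M + 1))
    C = np.stack(
        [np.column_stack([np.log(l), -l, np.cos(a)]) for l, a in zip(lengths, angles)]
    )
    Z = rng.normal(size=(S, M + 1, 1))
    return sw.CaseControlData(
        C=C,
        Z=Z,
        endpoints=np.zeros((S, M + 1, 2)),
        t_index=np.arange(1, S + 1),
        proposal=sw.ProposalDistribution(2.0, 1.0),
    )
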