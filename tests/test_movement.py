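"""Step geometry, movement covariates, weights and track simulation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import switchssa as sw
from switchssa.movement import wrap_angle


class TestStepsFromTrack:
    def test_collinear_equally_spaced_points_give_zero_angles(self):
        track = np.column_stack([np.arange(6.0), np.arange(6.0) * 2.0])
        lengths, angles = sw.steps_from_track(track)
        assert np.allclose(lengths, np.hypot(1.0, 2.0))
        assert np.isnan(angles[0])
        assert np.allclose(angles[1:], 0.0)

    def test_right_angle_left_turn_is_plus_half_pi(self):
        track = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        _, angles = sw.steps_from_track(track)
        assert angles[1] == pytest.approx(np.pi / 2)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_matches_direct_trigonometric_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        track = rng.normal(size=(15, 2)).cumsum(axis=0)
        lengths, angles = sw.steps_from_track(track, zero_length="floor")
        steps = (track[1:] - track[:-1]).view(complex).ravel()
        assert np.allclose(lengths, np.abs(steps))
        expected = np.angle(steps[1:] / steps[:-1])
        expected[expected == -np.pi] = np.pi
        assert np.allclose(wrap_angle(angles[1:]), expected)

    def test_zero_length_policies(self):
        track = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="zero-length"):
            sw.steps_from_track(track)
        with pytest.warns(UserWarning, match="flooring"):
            lengths, _ = sw.steps_from_track(track, zero_length="floor")
        assert lengths[0] > 0

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            sw.steps_from_track([[0, 0], [1, 1]])


class TestMovementCovariates:
    @pytest.mark.parametrize(
        "l, a, model, expected",
        [
            (1.0, 0.0, "von_mises", [0.0, -1.0, 1.0]),
            (2.0, np.pi, "von_mises", [np.log(2.0), -2.0, -1.0]),
            (np.e, None, "uniform", [1.0, -np.e]),
        ],
    )
    def test_known_values(self, l, a, model, expected):
        C = sw.movement_covariates([l], None if a is None else [a], angle_model=model)
        assert np.allclose(C[0], expected)

    def test_missing_angle_under_von_mises_errors(self):
        with pytest.raises(ValueError, match="angle"):
            sw.movement_covariates([1.0], None, angle_model="von_mises")
        with pytest.raises(ValueError, match="finite"):
            sw.movement_covariates([1.0], [np.nan], angle_model="von_mises")


class TestLogStepWeight:
    def test_simple_arithmetic(self):
        # k=2, r=1, kappa=0, beta=0 at l=1: (2-1)*0 + 1*(-1) + 0 = -1
        state = sw.StateParameters(2.0, 1.0, 0.0, [0.0])
        C = sw.movement_covariates([1.0], [0.7])
        assert sw.log_step_weight(C, [[0.0]], state) == pytest.approx(-1.0)

    def test_active_state_example(self):
        # k=2.5, r=0.29, kappa=1, beta=2 at l=1, alpha=0, Z=1 -> 2.71
        state = sw.StateParameters(2.5, 0.29, 1.0, [2.0])
        C = sw.movement_covariates([1.0], [0.0])
        assert sw.log_step_weight(C, [[1.0]], state) == pytest.approx(2.71)

    def test_state_equal_to_proposal_gives_zero_weight(self):
        prop = sw.ProposalDistribution(1.7, 0.4, 0.2)
        state = sw.StateParameters(1.7, 0.4, 0.2, [0.0])
        C = sw.movement_covariates([2.3], [1.1])
        assert sw.log_step_weight(C, [[5.0]], state, proposal=prop) == pytest.approx(0.0)


class TestStationaryDistribution:
    def test_symmetric_persistent_chain_is_uniform(self):
        tpm = [[0.9, 0.1], [0.1, 0.9]]
        assert np.allclose(sw.stationary_distribution(tpm), [0.5, 0.5])

    def test_asymmetric_chain_solved_exactly(self):
        delta = sw.stationary_distribution([[0.8, 0.2], [0.4, 0.6]])
        assert np.allclose(delta, [2.0 / 3.0, 1.0 / 3.0])

    def test_reducible_chain_falls_back_to_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="reducible"):
            delta = sw.stationary_distribution(np.eye(2))
        assert np.allclose(delta, [0.5, 0.5])


class TestWrapAngle:
    @given(a=st.floats(-50.0, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_range_and_equivalence(self, a):
        w = float(wrap_angle(a))
        assert -np.pi < w <= np.pi
        assert np.isclose(np.exp(1j * w), np.exp(1j * a), atol=1e-9)


class TestSimulateTrack:
    def test_single_state_chain_is_all_ones(self, flat_field):
        model = sw.HMMiSSAModel(
            tpm=[[1.0]], states=[sw.StateParameters(2.0, 1.0, 0.5, [0.0])]
        )
        _, states = sw.simulate_track(model, flat_field, T=50, K=200, seed=0)
        assert np.all(states == 1)

    def test_flat_field_steps_are_exact_kernel_draws(self, flat_field):
        """With no selection signal the resampler reduces to exact sampling."""
        model = sw.HMMiSSAModel(
            tpm=[[1.0]], states=[sw.StateParameters(2.5, 0.29, 1.0, [3.0])]
        )
        track, _ = sw.simulate_track(model, flat_field, T=3000, K=200, seed=3)
        lengths, angles = sw.steps_from_track(track)
        ks_l = stats.kstest(lengths, stats.gamma(a=2.5, scale=1 / 0.29).cdf)
        assert ks_l.pvalue > 0.01
        ks_a = stats.kstest(angles[1:], stats.vonmises(kappa=1.0).cdf)
        assert ks_a.pvalue > 0.01

    def test_chain_frequencies_and_persistence(self, flat_field, scenario1):
        _, states = sw.simulate_track(scenario1.model, flat_field, T=4000, K=200, seed=11)
        freq = np.mean(states == 1)
        persistence = np.mean(states[1:] == states[:-1])
        assert freq == pytest.approx(0.5, abs=0.06)
        assert persistence == pytest.approx(0.9, abs=0.03)

    def test_positive_selection_increases_occupancy_of_high_covariate_cells(self, rough_field):
        def mean_z(beta, seed):
            model = sw.HMMiSSAModel(
                tpm=[[1.0]], states=[sw.StateParameters(2.5, 0.29, 1.0, [beta])]
            )
            track, _ = sw.simulate_track(model, rough_field, T=1200, K=500, seed=seed)
            return rough_field.value_at(track).mean()

        assert mean_z(2.0, 21) > mean_z(0.0, 21) + 0.2

    def test_identical_states_reduce_to_single_state_model(self, rough_field):
        st_par = sw.StateParameters(2.5, 0.29, 1.0, [1.0])
        two = sw.HMMiSSAModel(tpm=[[0.9, 0.1], [0.1, 0.9]], states=[st_par, st_par])
        one = sw.HMMiSSAModel(tpm=[[1.0]], states=[st_par])
        t2, _ = sw.simulate_track(two, rough_field, T=2500, K=300, seed=31)
        t1, _ = sw.simulate_track(one, rough_field, T=2500, K=300, seed=32)
        l2, a2 = sw.steps_from_track(t2)
        l1, a1 = sw.steps_from_track(t1)
        assert stats.ks_2samp(l1, l2).pvalue > 0.01
        assert stats.ks_2samp(np.cos(a1[1:]), np.cos(a2[1:])).pvalue > 0.01

    def test_reproducible_and_validated(self, flat_field, scenario1):
        a, sa = sw.simulate_track(scenario1.model, flat_field, T=60, K=150, seed=5)
        b, sb = sw.simulate_track(scenario1.model, flat_field, T=60, K=150, seed=5)
        assert np.array_equal(a, b) and np.array_equal(sa, sb)
        with pytest.raises(ValueError):
            sw.simulate_track(scenario1.model, flat_field, T=2, seed=0)
        with pytest.raises(ValueError):
            sw.simulate_track(scenario1.model, flat_field, T=50, K=10, seed=0)


class TestTrackCSV:
    def test_roundtrip(self, tmp_path):
        from switchssa.movement import read_track_csv, write_track_csv

        rng = np.random.default_rng(1)
        track = rng.normal(size=(20, 2)).cumsum(axis=0)
        path = tmp_path / "track.csv"
        write_track_csv(path, track)
        back, burst = read_track_csv(path)
        assert np.allclose(back, track)
        assert burst is None

    def test_missing_columns_rejected(self, tmp_path):
        from switchssa.movement import read_track_csv

        path = tmp_path / "bad.csv"
        path.write_text("id,t,x\nA,0,1\n")
        with pytest.raises(ValueError, match="missing"):
            read_track_csv(path)
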