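"""Conformer classification, populations, transitions, distances, IDA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from junctionlab.conformers import (
    ClassificationConfig,
    ConformerState,
    CoreDistances,
    classify_frame,
    classify_trajectory,
    conformer_structure_stats,
    core_distances,
    distance_distribution,
    inter_duplex_angle,
    population_fractions,
    transition_matrix,
)
from junctionlab.geometry import idealized_geometry
from junctionlab.kinetics import KineticModel, StateSeries, simulate_state_ensemble
from junctionlab.synthetic import render_trajectory
from junctionlab.topology import Site, core_marker_index_pairs
from junctionlab.trajectory import Trajectory

O, I, II, AMB = (
    ConformerState.OPEN,
    ConformerState.ISO_I,
    ConformerState.ISO_II,
    ConformerState.AMBIGUOUS,
)


def truth_table_oracle(d: CoreDistances, cutoff: float) -> ConformerState:
    """Exhaustive 16-row truth table over the four below-cutoff booleans."""
    key = (d.d_tt < cutoff, d.d_cc < cutoff, d.d_ag1 < cutoff, d.d_ag2 < cutoff)
    table = {
        (True, True, True, True): AMB,
        (True, True, True, False): I,
        (True, True, False, True): I,
        (True, True, False, False): I,
        (True, False, True, True): II,
        (False, True, True, True): II,
        (False, False, True, True): II,
        (True, False, True, False): O,
        (True, False, False, True): O,
        (False, True, True, False): O,
        (False, True, False, True): O,
        (True, False, False, False): O,
        (False, True, False, False): O,
        (False, False, True, False): O,
        (False, False, False, True): O,
        (False, False, False, False): O,
    }
    return table[key]


class TestClassifyFrame:
    @pytest.mark.parametrize(
        "quad,expected",
        [
            ((8, 9, 20, 21), I),
            ((20, 21, 8, 9), II),
            ((20, 20, 20, 20), O),
            ((8, 8, 8, 8), AMB),
            ((11.9, 11.9, 12.0, 12.0), I),  # cutoff is strict on the short side
            ((12.0, 12.0, 11.9, 11.9), II),
        ],
    )
    def test_examples(self, quad, expected):
        d = CoreDistances(*map(float, quad))
        assert classify_frame(d, ClassificationConfig(cutoff=12.0)) == expected

    @given(
        tt=st.floats(0.1, 30), cc=st.floats(0.1, 30),
        ag1=st.floats(0.1, 30), ag2=st.floats(0.1, 30),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_truth_table(self, tt, cc, ag1, ag2):
        d = CoreDistances(tt, cc, ag1, ag2)
        assert classify_frame(d) == truth_table_oracle(d, 12.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            CoreDistances(-1.0, 5.0, 5.0, 5.0)


class TestCoreDistances:
    def test_template_distance_structure(self, j34_topology, marker_pairs):
        iso1 = idealized_geometry(j34_topology, "iso_I")
        d = core_distances(iso1.coordinates, marker_pairs)
        assert d.d_tt < 12 and d.d_cc < 12
        assert d.d_ag1 >= 12 and d.d_ag2 >= 12
        open_t = idealized_geometry(j34_topology, "open_planar")
        d_open = core_distances(open_t.coordinates, marker_pairs).as_array()
        assert d_open.max() - d_open.min() < 1.0

    def test_translation_invariance(self, j34_topology, marker_pairs):
        tpl = idealized_geometry(j34_topology, "iso_II")
        moved = tpl.coordinates + np.array([100.0, 0.0, 0.0])
        np.testing.assert_allclose(
            core_distances(moved, marker_pairs).as_array(),
            core_distances(tpl.coordinates, marker_pairs).as_array(),
            atol=1e-9,
        )

    def test_missing_site_rejected(self, marker_pairs):
        with pytest.raises(IndexError):
            core_distances(np.zeros((10, 3)), marker_pairs)


class TestClassifyTrajectory:
    def test_all_open_sigma_zero(self, j34_topology, templates):
        series = StateSeries(np.arange(50.0), np.full(50, int(O), dtype=np.int8))
        traj = render_trajectory(series, templates, sigma=0.0, seed=2)
        out = classify_trajectory(traj, j34_topology)
        assert (out.states == int(O)).all()
        np.testing.assert_array_equal(out.times_ns, series.times_ns)

    def test_rotation_invariance(self, j34_topology, templates, rng):
        from scipy.spatial.transform import Rotation

        series = StateSeries(np.arange(20.0), np.full(20, int(II), dtype=np.int8))
        traj = render_trajectory(series, templates, sigma=1.0, seed=3)
        rot = Rotation.random(rng=rng).as_matrix()
        rotated = Trajectory(traj.coords @ rot.T, traj.times_ns, dict(traj.metadata))
        np.testing.assert_array_equal(
            classify_trajectory(traj, j34_topology).states,
            classify_trajectory(rotated, j34_topology).states,
        )

    def test_empty_rejected(self, j34_topology):
        empty = Trajectory(np.zeros((0, j34_topology.n_sites, 3)), np.zeros(0))
        with pytest.raises(ValueError, match="empty"):
            classify_trajectory(empty, j34_topology)


class TestDistanceDistribution:
    def test_normalization(self, j34_topology, templates):
        series = StateSeries(np.arange(100.0), np.full(100, int(I), dtype=np.int8))
        traj = render_trajectory(series, templates, sigma=1.0, seed=4)
        hist = distance_distribution([traj], j34_topology, which="AG", bin_width=0.5)
        assert np.sum(hist.density * hist.bin_width) == pytest.approx(1.0, abs=1e-10)

    def test_mixed_ensemble_ag_bimodal(self, j34_topology, templates):
        model = KineticModel()
        series = simulate_state_ensemble(model, 4, 500.0, 1.0, (0.06, 0.36, 0.58), master_seed=5)
        trajs = [render_trajectory(s, templates, sigma=1.0, seed=10 + m) for m, s in enumerate(series)]
        hist = distance_distribution(trajs, j34_topology, which="AG", bin_width=1.0)
        assert hist.mode_count() >= 2
        # minimum between the peaks sits near the 12 A cutoff
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        inner = (centers > 6) & (centers < 20)
        trough = centers[inner][np.argmin(hist.density[inner])]
        assert 8.0 < trough < 18.0

    def test_all_open_no_mass_below_cutoff(self, j34_topology, templates):
        series = StateSeries(np.arange(200.0), np.full(200, int(O), dtype=np.int8))
        traj = render_trajectory(series, templates, sigma=1.0, seed=6)
        for which in ("AG", "TTCC"):
            hist = distance_distribution([traj], j34_topology, which=which, bin_width=0.5)
            below = hist.bin_edges[1:] <= 12.0
            assert hist.density[below].sum() == 0.0

    def test_empty_rejected(self, j34_topology):
        with pytest.raises(ValueError):
            distance_distribution([], j34_topology)


class TestPopulationFractions:
    def test_single_member_all_iso_ii(self):
        s = StateSeries(np.arange(10.0), np.full(10, int(II), dtype=np.int8))
        est = population_fractions([s])
        np.testing.assert_allclose(est.fractions, [0, 0, 1, 0], atol=1e-15)

    def test_member_permutation_invariance(self):
        rng = np.random.default_rng(0)
        members = [
            StateSeries(np.arange(50.0), rng.integers(0, 3, 50).astype(np.int8))
            for _ in range(6)
        ]
        a = population_fractions(members)
        b = population_fractions(members[::-1])
        np.testing.assert_allclose(a.fractions, b.fractions, atol=1e-15)
        np.testing.assert_allclose(a.se, b.se, atol=1e-15)

    def test_fractions_sum_to_one_including_ambiguous(self):
        rng = np.random.default_rng(1)
        members = [
            StateSeries(np.arange(40.0), rng.integers(0, 4, 40).astype(np.int8))
            for _ in range(5)
        ]
        est = population_fractions(members)
        assert est.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            population_fractions([])

    def test_equilibration_window_discarded(self):
        s = StateSeries(np.arange(10.0), np.array([0] * 5 + [2] * 5, dtype=np.int8))
        est = population_fractions([s], equilibration_ns=5.0)
        np.testing.assert_allclose(est.fractions, [0, 0, 1, 0], atol=1e-15)

    def test_stage1_and_stage2_populations_agree(self):
        """All-open starts vs population-seeded starts give the same estimate
        within 3 combined SE once the initial transient is discarded."""
        model = KineticModel()
        stage1 = simulate_state_ensemble(model, 100, 2000.0, 1.0, (1.0, 0.0, 0.0), master_seed=31)
        est1 = population_fractions(stage1, equilibration_ns=50.0)
        p = est1.fractions[:3] / est1.fractions[:3].sum()
        stage2 = simulate_state_ensemble(model, 100, 2000.0, 1.0, tuple(p), master_seed=32)
        est2 = population_fractions(stage2, equilibration_ns=50.0)
        z = np.abs(est1.fractions[:3] - est2.fractions[:3]) / np.sqrt(
            est1.se[:3] ** 2 + est2.se[:3] ** 2 + 1e-12
        )
        assert z.max() < 3.0


class TestTransitionMatrix:
    def test_hand_counted_example(self):
        s = StateSeries(np.arange(5.0), np.array([0, 1, 1, 0, 2], dtype=np.int8))
        tm = transition_matrix([s], lag=1)
        np.testing.assert_allclose(tm.probabilities[0], [0.0, 0.5, 0.5])
        np.testing.assert_allclose(tm.probabilities[1], [0.5, 0.5, 0.0])
        assert tm.n_transitions == 4
        assert 2 in tm.undefined_rows

    def test_constant_series_identity_row(self):
        s = StateSeries(np.arange(10.0), np.full(10, int(I), dtype=np.int8))
        tm = transition_matrix([s], lag=1)
        np.testing.assert_allclose(tm.probabilities[int(I)], [0.0, 1.0, 0.0])
        assert set(tm.undefined_rows) == {0, 2}

    def test_occupied_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        members = [
            StateSeries(np.arange(100.0), rng.integers(0, 3, 100).astype(np.int8))
            for _ in range(3)
        ]
        tm = transition_matrix(members, lag=1)
        np.testing.assert_allclose(tm.probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_ambiguous_frames_excluded_and_counted(self):
        s = StateSeries(np.arange(5.0), np.array([0, 3, 1, 1, 0], dtype=np.int8))
        tm = transition_matrix([s], lag=1)
        assert tm.n_excluded == 2
        assert tm.n_transitions == 2

    def test_no_cross_member_pairs(self):
        a = StateSeries(np.arange(2.0), np.array([1, 1], dtype=np.int8))
        b = StateSeries(np.arange(2.0), np.array([2, 2], dtype=np.int8))
        tm = transition_matrix([a, b], lag=1)
        assert tm.counts[int(I), int(II)] == 0
        assert tm.n_transitions == 2

    def test_member_shorter_than_lag_rejected(self):
        s = StateSeries(np.arange(3.0), np.array([0, 1, 2], dtype=np.int8))
        with pytest.raises(ValueError, match="lag"):
            transition_matrix([s], lag=3)

    def test_detailed_balance_at_stationarity(self):
        model = KineticModel()
        pi = model.stationary_distribution()
        members = simulate_state_ensemble(model, 40, 2000.0, 1.0, tuple(pi), master_seed=11)
        tm = transition_matrix(members, lag=1)
        # reversible chain: pi_i P_ij = pi_j P_ji within sampling error
        for i, j in ((0, 1), (0, 2)):
            flux_ij = pi[i] * tm.probabilities[i, j]
            flux_ji = pi[j] * tm.probabilities[j, i]
            n_eff = tm.counts[i, j] + tm.counts[j, i]
            se = np.sqrt(max(n_eff, 1)) / tm.n_transitions
            assert abs(flux_ij - flux_ji) < 3.0 * se + 1e-12


class TestInterDuplexAngle:
    def make_arm_frame(self, topology, xr_dir, hx_dir):
        coords = np.zeros((topology.n_sites, 3))
        for name, direction in (("XR", np.asarray(xr_dir)), ("HX", np.asarray(hx_dir))):
            a, b = topology.arms[name].terminal_pair
            coords[topology.index_of(a)] = 50.0 * direction
            coords[topology.index_of(b)] = 50.0 * direction
        return coords

    def test_orthogonal_arms(self, toy_topology):
        frame = self.make_arm_frame(toy_topology, (1, 0, 0), (0, 1, 0))
        assert inter_duplex_angle(frame, toy_topology) == pytest.approx(90.0, abs=1e-9)

    def test_collinear_opposite_arms(self, toy_topology):
        frame = self.make_arm_frame(toy_topology, (1, 0, 0), (-1, 0, 0))
        assert inter_duplex_angle(frame, toy_topology) == pytest.approx(180.0, abs=1e-9)

    def test_rh_alias_names_hx_arm(self, toy_topology):
        frame = self.make_arm_frame(toy_topology, (1, 0, 0), (0, 1, 0))
        assert inter_duplex_angle(frame, toy_topology, arms=("XR", "RH")) == pytest.approx(90.0)

    def test_degenerate_arm_rejected(self, toy_topology):
        frame = np.zeros((toy_topology.n_sites, 3))
        with pytest.raises(ValueError, match="degenerate"):
            inter_duplex_angle(frame, toy_topology)


class TestConformerStructureStats:
    def test_iso_ii_template_mean_and_zero_sd(self, j34_topology):
        tpl = idealized_geometry(j34_topology, "iso_II", nominal_ida=95.7)
        series = StateSeries(np.arange(30.0), np.full(30, int(II), dtype=np.int8))
        traj = render_trajectory(series, {II: tpl}, sigma=0.0, seed=9)
        stats = conformer_structure_stats(traj, series, j34_topology)
        assert stats.mean[II] == pytest.approx(95.7, abs=1e-6)
        assert stats.sd[II] == pytest.approx(0.0, abs=1e-9)
        assert II in stats.histograms and O not in stats.mean

    def test_two_delta_mixture_recovers_both_means(self, j34_topology):
        tpl_i = idealized_geometry(j34_topology, "iso_I", nominal_ida=140.0)
        tpl_ii = idealized_geometry(j34_topology, "iso_II", nominal_ida=90.0)
        states = np.tile([int(I), int(II)], 20).astype(np.int8)
        series = StateSeries(np.arange(40.0), states)
        traj = render_trajectory(series, {I: tpl_i, II: tpl_ii}, sigma=0.0, seed=10)
        stats = conformer_structure_stats(traj, series, j34_topology)
        assert stats.mean[I] == pytest.approx(140.0, abs=1e-6)
        assert stats.mean[II] == pytest.approx(90.0, abs=1e-6)
        assert stats.n[I] == stats.n[II] == 20

    def test_site_noise_broadens_ida_monotonically(self, j34_topology, templates):
        series = StateSeries(np.arange(200.0), np.full(200, int(II), dtype=np.int8))
        sds = []
        for sigma in (0.0, 1.0, 2.0):
            traj = render_trajectory(series, templates, sigma=sigma, seed=123)
            stats = conformer_structure_stats(traj, series, j34_topology)
            sds.append(stats.sd[II])
        assert sds[0] < sds[1] < sds[2]

    def test_equilibration_window_discarded(self, j34_topology, templates):
        series = StateSeries(np.arange(100.0), np.full(100, int(I), dtype=np.int8))
        traj = render_trajectory(series, templates, sigma=0.0, seed=1)
        stats = conformer_structure_stats(traj, series, j34_topology, equilibration_ns=50.0)
        assert stats.n[I] == 50

    def test_misaligned_states_rejected(self, j34_topology, templates):
        series = StateSeries(np.arange(10.0), np.full(10, int(I), dtype=np.int8))
        traj = render_trajectory(series, templates, sigma=0.0, seed=1)
        short = StateSeries(np.arange(5.0), np.full(5, int(I), dtype=np.int8))
        with pytest.raises(ValueError, match="align"):
            conformer_structure_stats(traj, short, j34_topology)
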