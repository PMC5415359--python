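import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from k2pflex.core import Frame, K2PFlexError, SelectionError, SelectionSpec, Trajectory
from k2pflex import synthetic as syn
from k2pflex.state import (
    GatingPairConfig,
    classify_states,
    detect_event_sequence,
    gating_distances,
    landscape_table,
    rmsd_series,
    superpose,
)
from .oracles import brute_force_rmsd


def random_ca_frame(rng, n=5):
    return Frame(
        names=["CA"] * n,
        resnames=["ALA"] * n,
        resids=list(range(1, n + 1)),
        chains=["A"] * n,
        elements=["C"] * n,
        positions=rng.uniform(-5, 5, size=(n, 3)),
    )


def rigid_copy(frame, rng):
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    shift = rng.uniform(-20, 20, 3)
    out = frame.copy()
    out.positions = frame.positions @ rot.T + shift
    return out


class TestSuperpose:
    def test_identical_frames(self, reference_pair, ca_spec):
        down, _ = reference_pair
        rot, trans, rmsd = superpose(down, down, ca_spec)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-6)

    def test_rigid_transform_invariance(self, ca_spec):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = random_ca_frame(rng)
            b = rigid_copy(a, rng)
            _, _, rmsd = superpose(b, a, ca_spec)
            assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_proper_rotation(self, ca_spec):
        rng = np.random.default_rng(8)
        a = random_ca_frame(rng)
        b = random_ca_frame(rng)
        rot, _, _ = superpose(b, a, ca_spec)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_grid_oracle(self, ca_spec):
        rng = np.random.default_rng(17)
        for trial in range(10):
            a = random_ca_frame(rng)
            noisy = a.copy()
            noisy.positions = a.positions + rng.normal(0, 0.5, size=(5, 3))
            _, _, rmsd = superpose(noisy, a, ca_spec)
            oracle = brute_force_rmsd(noisy.positions, a.positions, seed=trial)
            assert rmsd == pytest.approx(oracle, abs=1e-3)

    def test_symmetry(self, ca_spec):
        rng = np.random.default_rng(9)
        a, b = random_ca_frame(rng), random_ca_frame(rng)
        _, _, r_ab = superpose(a, b, ca_spec)
        _, _, r_ba = superpose(b, a, ca_spec)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

    def test_collinear_selection_rejected(self, ca_spec):
        f = Frame(
            names=["CA"] * 4, resnames=["ALA"] * 4, resids=[1, 2, 3, 4],
            chains=["A"] * 4, elements=["C"] * 4,
            positions=np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float),
        )
        with pytest.raises(K2PFlexError, match="collinear"):
            superpose(f, f.copy(), ca_spec)

    def test_mapping_mismatch_rejected(self, ca_spec):
        rng = np.random.default_rng(2)
        a = random_ca_frame(rng)
        b = random_ca_frame(rng)
        b.resids = b.resids + 100
        with pytest.raises(SelectionError):
            superpose(a, b, ca_spec)


class TestRmsdSeries:
    def test_copies_of_reference_are_zero(self, reference_pair, ca_spec):
        down, _ = reference_pair
        frames = [down.copy() for _ in range(4)]
        for k, f in enumerate(frames):
            f.time = float(k)
        series = rmsd_series(Trajectory(frames), down, ca_spec)
        assert np.allclose(series[:, 1], 0.0, atol=1e-9)

    def test_interpolation_monotone(self, reference_pair, ca_spec):
        down, up = reference_pair
        traj = syn.make_interpolated_trajectory(down, up, n_frames=11)
        rd = rmsd_series(traj, down, ca_spec)[:, 1]
        ru = rmsd_series(traj, up, ca_spec)[:, 1]
        assert np.all(np.diff(rd) >= -1e-9)
        assert np.all(np.diff(ru) <= 1e-9)

    def test_single_frame_equals_superpose(self, reference_pair, ca_spec):
        down, up = reference_pair
        series = rmsd_series(Trajectory([up]), down, ca_spec)
        _, _, direct = superpose(up, down, ca_spec)
        assert series.shape == (1, 2)
        assert series[0, 1] == pytest.approx(direct, abs=1e-12)


class TestGatingDistances:
    def test_two_atoms_4A_apart(self):
        f = Frame(
            names=["CA", "CA"], resnames=["TRP", "ARG"], resids=[326, 237],
            chains=["A", "A"], elements=["C", "C"],
            positions=np.array([[0.0, 0, 0], [4.0, 0, 0]]),
            box=np.array([50.0, 50.0, 50.0]),
        )
        from k2pflex.state import _pair_distance, _residue_atoms
        d = _pair_distance(f, _residue_atoms(f, "A", 326, "CA"), _residue_atoms(f, "A", 237, "CA"))
        assert d == pytest.approx(4.0)

    def test_missing_residue_named_in_error(self, noiseless_transition):
        traj, _ = noiseless_transition
        cfg = GatingPairConfig(zipper=(326, 999))
        with pytest.raises(SelectionError, match="999"):
            gating_distances(traj, cfg)

    def test_ca_mode_at_least_min_heavy(self):
        # residue with a side-chain atom closer than the CA
        f = Frame(
            names=["CA", "CB", "CA"], resnames=["TRP", "TRP", "ARG"],
            resids=[326, 326, 237], chains=["A"] * 3, elements=["C"] * 3,
            positions=np.array([[0.0, 0, 0], [2.0, 0, 0], [6.0, 0, 0]]),
            box=np.array([50.0, 50.0, 50.0]),
        )
        from k2pflex.state import _pair_distance, _residue_atoms
        d_ca = _pair_distance(f, _residue_atoms(f, "A", 326, "CA"),
                              _residue_atoms(f, "A", 237, "CA"))
        d_heavy = _pair_distance(f, _residue_atoms(f, "A", 326, "min-heavy"),
                                 _residue_atoms(f, "A", 237, "min-heavy"))
        assert d_ca >= d_heavy
        assert d_heavy == pytest.approx(4.0)


class TestClassifyStates:
    def test_reference_trajectories_get_their_label(self, reference_pair, ca_spec):
        down, up = reference_pair
        for ref, label in ((down, "down"), (up, "up")):
            frames = [ref.copy() for _ in range(3)]
            for k, f in enumerate(frames):
                f.time = float(k)
            series = classify_states(Trajectory(frames), down, up, ca_spec, margin=0.5)
            assert series.labels == [label] * 3

    def test_midpoint_is_intermediate(self, reference_pair, ca_spec):
        down, up = reference_pair
        traj = syn.make_interpolated_trajectory(down, up, n_frames=3)
        series = classify_states(traj, down, up, ca_spec, margin=0.5)
        assert series.labels[1] == "intermediate"

    def test_label_invariant_implies_margin(self, reference_pair, ca_spec):
        down, up = reference_pair
        traj = syn.make_interpolated_trajectory(down, up, n_frames=5)
        series = classify_states(traj, down, up, ca_spec, margin=0.2)
        for label, d, u in zip(series.labels, series.rmsd_down, series.rmsd_up):
            if label == "down":
                assert d + series.margin < u
            elif label == "up":
                assert u + series.margin < d


class TestLandscapeTable:
    def test_stride_and_reference_rows(self, noiseless_transition, reference_pair):
        traj, _ = noiseless_transition
        down, up = reference_pair
        table = landscape_table(traj, {"down": down, "up": up}, stride=10)
        traj_rows = table[table.source == "trajectory"]
        assert len(traj_rows) == 10 * 2  # 10 sampled frames x 2 chains
        down_rows = table[table.source == "down"]
        assert down_rows.fenestration.iloc[0] == pytest.approx(12.0, abs=1e-6)
        assert down_rows.zipper.iloc[0] == pytest.approx(6.0, abs=1e-6)

    def test_empty_crystal_set(self, noiseless_transition):
        traj, _ = noiseless_transition
        table = landscape_table(traj, {}, stride=25)
        assert set(table.source) == {"trajectory"}


class TestEventDetection:
    def test_noiseless_recovery_within_one_frame(self, noiseless_transition, transition_spec):
        traj, truth = noiseless_transition
        gd = gating_distances(traj)
        report = detect_event_sequence(
            gd, transition_spec.reference_distances["down"],
            transition_spec.reference_distances["up"],
            smoothing_window=1, dwell=3,
        )
        assert report.all_ordered
        for chain in "AB":
            for event in ("unzip", "expand", "close"):
                assert report.events[chain][event] == pytest.approx(
                    truth.event_times[chain][event], abs=transition_spec.dt
                )

    def test_constant_series_detects_nothing(self, reference_pair):
        down, _ = reference_pair
        frames = [down.copy() for _ in range(20)]
        for k, f in enumerate(frames):
            f.time = float(k)
        gd = gating_distances(Trajectory(frames))
        report = detect_event_sequence(
            gd, syn.DEFAULT_REFERENCE_DISTANCES["down"],
            syn.DEFAULT_REFERENCE_DISTANCES["up"],
            smoothing_window=3, dwell=3,
        )
        assert not any(report.order_ok.values())
        assert all(t is None for ev in report.events.values() for t in ev.values())

    def test_noisy_recovery_rate(self):
        # 10% relative noise (of the smallest step height); a larger
        # replicate count runs in the acceptance suite
        ok = 0
        n_runs = 20
        for seed in range(n_runs):
            spec = syn.TransitionSpec(noise_sd=0.6, seed=seed)
            traj, _ = syn.make_transition_trajectory(spec)
            gd = gating_distances(traj)
            report = detect_event_sequence(
                gd, spec.reference_distances["down"], spec.reference_distances["up"],
                smoothing_window=5, dwell=5,
            )
            ok += report.all_ordered
        assert ok >= int(0.95 * n_runs)

    def test_equal_references_rejected(self, noiseless_transition):
        traj, _ = noiseless_transition
        gd = gating_distances(traj)
        refs = dict(syn.DEFAULT_REFERENCE_DISTANCES["down"])
        with pytest.raises(K2PFlexError, match="differ"):
            detect_event_sequence(gd, refs, refs)
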