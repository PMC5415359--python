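import numpy as np
import pytest

from k2pflex.core import Frame, K2PFlexError, SelectionError, SelectionSpec, Trajectory
from k2pflex import synthetic as syn
from k2pflex.occupancy import (
    FilterSites,
    detect_dewetting,
    groove_series,
    ion_occupancy,
    lipid_contact_series,
    sites_from_planes,
    water_profile,
)
from .oracles import run_length_dry_intervals

ION_SPEC = SelectionSpec(atom_names=["K"])
WATER_SPEC = SelectionSpec(atom_names=["OW"])


def default_sites():
    return FilterSites(intervals=[
        ("S0", 12.0, 15.0), ("S1", 9.0, 12.0), ("S2", 6.0, 9.0),
        ("S3", 3.0, 6.0), ("S4", 0.0, 3.0),
    ])


class TestIonOccupancy:
    def test_fixed_ion_at_s1(self):
        traj, truth = syn.make_pore_trace(
            syn.PoreTraceSpec(ion_site_schedule=[["S1"]] * 30)
        )
        res = ion_occupancy(traj, default_sites(), ION_SPEC)
        assert res.site_probability == {"S0": 0.0, "S1": 1.0, "S2": 0.0,
                                        "S3": 0.0, "S4": 0.0}

    def test_alternating_half_occupancy(self):
        # exhaustive count: 50 even frames in S0, 50 odd frames in S1
        schedule = [["S0"] if k % 2 == 0 else ["S1"] for k in range(100)]
        traj, truth = syn.make_pore_trace(syn.PoreTraceSpec(ion_site_schedule=schedule))
        res = ion_occupancy(traj, default_sites(), ION_SPEC)
        assert res.site_probability["S0"] == pytest.approx(0.5)
        assert res.site_probability["S1"] == pytest.approx(0.5)
        assert res.site_probability == truth.site_occupancy

    def test_matches_ground_truth_on_random_schedule(self):
        rng = np.random.default_rng(12)
        names = ["S0", "S1", "S2", "S3", "S4"]
        schedule = [
            [str(rng.choice(names)), str(rng.choice(names + [None] * 2))]
            for _ in range(200)
        ]
        schedule = [[a, None if b == "None" else b] for a, b in schedule]
        traj, truth = syn.make_pore_trace(syn.PoreTraceSpec(ion_site_schedule=schedule))
        res = ion_occupancy(traj, default_sites(), ION_SPEC)
        assert res.site_probability == truth.site_occupancy

    def test_density_integrates_to_mean_ion_count(self):
        schedule = [["S1", "S3"]] * 40
        traj, _ = syn.make_pore_trace(syn.PoreTraceSpec(ion_site_schedule=schedule))
        res = ion_occupancy(traj, default_sites(), ION_SPEC)
        assert res.density.sum() == pytest.approx(2.0, abs=1e-6)

    def test_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(3)
        schedule = [[str(rng.choice(["S0", "S2", "S4"]))] for _ in range(50)]
        traj, _ = syn.make_pore_trace(syn.PoreTraceSpec(ion_site_schedule=schedule))
        res = ion_occupancy(traj, default_sites(), ION_SPEC)
        assert all(0.0 <= p <= 1.0 for p in res.site_probability.values())

    def test_empty_ion_selection_is_error(self):
        traj, _ = syn.make_pore_trace(syn.PoreTraceSpec(ion_site_schedule=[["S1"]] * 3))
        with pytest.raises(SelectionError):
            ion_occupancy(traj, default_sites(), SelectionSpec(atom_names=["RB"]))


class TestSitesFromPlanes:
    def test_uniform_planes(self):
        sites = sites_from_planes([12.0, 9.0, 6.0, 3.0, 0.0])
        names = sites.names
        assert names == ["S0", "S1", "S2", "S3", "S4"]
        s0 = sites.intervals[0]
        assert s0[2] == pytest.approx(15.0)  # one spacing above top plane
        assert s0[1] == pytest.approx(10.5)  # midpoint of planes 0 and 1
        # ordered, non-overlapping by construction (validated in __post_init__)


class TestWaterProfile:
    def test_constant_cavity_count(self):
        spec = syn.PoreTraceSpec(ion_site_schedule=[["S1"]] * 25,
                                 water_counts=[10] * 25)
        traj, truth = syn.make_pore_trace(spec)
        prof = water_profile(traj, WATER_SPEC, cavity_z=(-12.0, 0.0),
                             cylinder_radius=5.0, axis_xy=(30.0, 30.0))
        assert np.array_equal(prof.cavity_counts, truth.water_counts)

    def test_waters_outside_radius_not_counted(self):
        spec = syn.PoreTraceSpec(ion_site_schedule=[["S1"]] * 10,
                                 water_counts=[0] * 10, dewet_count=0)
        traj, _ = syn.make_pore_trace(spec)
        prof = water_profile(traj, WATER_SPEC, cavity_z=(-12.0, 0.0),
                             cylinder_radius=5.0, axis_xy=(30.0, 30.0))
        assert prof.cavity_counts.max() == 0
        assert prof.density.sum() == 0

    def test_uniform_fill_roughly_flat(self):
        spec = syn.PoreTraceSpec(ion_site_schedule=[["S1"]] * 200,
                                 water_counts=[60] * 200, seed=5)
        traj, _ = syn.make_pore_trace(spec)
        prof = water_profile(traj, WATER_SPEC, cavity_z=(-12.0, 0.0),
                             cylinder_radius=5.0, axis_xy=(30.0, 30.0),
                             bin_width=3.0, z_range=(-12.0, 0.0))
        expected = 60 / prof.z.size
        assert np.all(np.abs(prof.density - expected) < 5 * np.sqrt(expected / 200))


class TestDetectDewetting:
    def test_always_wet(self):
        rep = detect_dewetting(np.full(50, 10.0), threshold=5.0, min_duration=1)
        assert rep.intervals == []

    def test_planted_interval_recovered(self):
        spec = syn.PoreTraceSpec(ion_site_schedule=[["S1"]] * 100,
                                 water_counts=[10] * 100,
                                 dewetting_intervals=[(40, 60)])
        traj, truth = syn.make_pore_trace(spec)
        prof = water_profile(traj, WATER_SPEC, cavity_z=(-12.0, 0.0),
                             cylinder_radius=5.0, axis_xy=(30.0, 30.0))
        rep = detect_dewetting(prof.cavity_counts, threshold=5.0, min_duration=2)
        assert rep.intervals == [(40, 60)]
        assert rep.intervals == truth.dewetting_intervals

    def test_no_merging_across_single_wet_frame(self):
        counts = np.full(20, 10.0)
        counts[3:6] = 0
        counts[7:10] = 0  # frame 6 is wet
        rep = detect_dewetting(counts, threshold=5.0, min_duration=2)
        assert rep.intervals == [(3, 5), (7, 9)]

    def test_min_duration_filters_short_runs(self):
        counts = np.full(10, 10.0)
        counts[4] = 0
        rep = detect_dewetting(counts, threshold=5.0, min_duration=2)
        assert rep.intervals == []

    def test_matches_run_length_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            counts = rng.integers(0, 10, size=rng.integers(5, 60)).astype(float)
            thr = float(rng.integers(1, 9))
            dur = int(rng.integers(1, 4))
            rep = detect_dewetting(counts, threshold=thr, min_duration=dur)
            assert rep.intervals == run_length_dry_intervals(counts < thr, dur)

    def test_intervals_disjoint_and_long_enough(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 12, size=300).astype(float)
        rep = detect_dewetting(counts, threshold=6.0, min_duration=3)
        for (a1, b1), (a2, b2) in zip(rep.intervals, rep.intervals[1:]):
            assert b1 < a2
        assert all(b - a + 1 >= 3 for a, b in rep.intervals)


def contact_frame(tail_xyz, n_extra=0, rng=None):
    """P198 CA at origin plus one lipid tail atom (and optional cloud)."""
    names = ["CA", "C2"]
    resnames = ["PRO", "LIP"]
    resids = [198, 500]
    chains = ["A", "M"]
    elements = ["C", "C"]
    pos = [[0.0, 0.0, 0.0], list(tail_xyz)]
    for i in range(n_extra):
        names.append("C3")
        resnames.append("LIP")
        resids.append(501 + i)
        chains.append("M")
        elements.append("C")
        pos.append(list(rng.uniform(-15, 15, 3)))
    return Frame(names=names, resnames=resnames, resids=resids, chains=chains,
                 elements=elements, positions=np.array(pos),
                 box=np.array([40.0, 40.0, 40.0]))


TAILS = SelectionSpec(resnames=["LIP"])


class TestLipidContacts:
    def test_bound_within_threshold(self):
        traj = Trajectory([contact_frame((3.0, 0.0, 0.0))])
        s = lipid_contact_series(traj, 198, TAILS, threshold=4.0)
        assert s.bound[0]
        assert s.min_distance[0] == pytest.approx(3.0)

    def test_unbound_beyond_threshold(self):
        traj = Trajectory([contact_frame((10.0, 0.0, 0.0))])
        s = lipid_contact_series(traj, 198, TAILS, threshold=4.0)
        assert not s.bound[0]

    def test_bound_flag_iff_distance_below_threshold(self):
        rng = np.random.default_rng(31)
        frames = [contact_frame(rng.uniform(-8, 8, 3), n_extra=3, rng=rng)]
        frames[0].time = 0.0
        s = lipid_contact_series(Trajectory(frames), 198, TAILS, threshold=4.0)
        assert bool(s.bound[0]) == (s.min_distance[0] < 4.0)

    def test_matches_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            f = contact_frame(rng.uniform(-10, 10, 3), n_extra=8, rng=rng)
            traj = Trajectory([f])
            s = lipid_contact_series(traj, 198, TAILS)
            from k2pflex.core import min_image_distance, select
            lipid_idx = select(f, TAILS)
            target_idx = select(f, SelectionSpec(resid_ranges=[(198, 198)]))
            brute = min(
                min_image_distance(f.positions[i], f.positions[j], f.box)
                for i in lipid_idx for j in target_idx
            )
            assert s.min_distance[0] == pytest.approx(brute, abs=1e-9)

    def test_missing_target_is_error(self):
        traj = Trajectory([contact_frame((3.0, 0.0, 0.0))])
        with pytest.raises(SelectionError):
            lipid_contact_series(traj, 999, TAILS)


def groove_frame(lipid_xyz):
    names = ["CA", "CA", "CA", "C2"]
    resnames = ["PHE", "LEU", "SER", "LIP"]
    resids = [226, 243, 240, 500]
    chains = ["A", "A", "A", "M"]
    elements = ["C", "C", "C", "C"]
    pos = [[-4.0, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 2.0, 0.0], list(lipid_xyz)]
    return Frame(names=names, resnames=resnames, resids=resids, chains=chains,
                 elements=elements, positions=np.array(pos),
                 box=np.array([40.0, 40.0, 40.0]))


class TestGrooveSeries:
    def test_groove_width(self):
        traj = Trajectory([groove_frame((20.0, 0.0, 0.0))])
        s = groove_series(traj, TAILS)
        assert s.structural_metric[0] == pytest.approx(8.0)

    def test_lipid_at_groove_centre(self):
        traj = Trajectory([groove_frame((0.0, 2.0, 1.0))])
        s = groove_series(traj, TAILS)
        assert s.min_distance[0] < s.structural_metric[0] / 2

    def test_no_lipids_is_error(self):
        traj = Trajectory([groove_frame((0.0, 0.0, 0.0))])
        with pytest.raises(SelectionError):
            groove_series(traj, SelectionSpec(resnames=["POPC"]))
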