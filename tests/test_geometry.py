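import numpy as np
import pytest

from k2pflex.core import Frame, K2PFlexError, SelectionSpec, Trajectory
from k2pflex.geometry import (
    area_per_lipid,
    area_profile,
    area_profile_series,
    bilayer_thickness,
)
from k2pflex import synthetic as syn
from .conftest import single_atom_frame
from .oracles import lens_area


def two_atom_frame(separation, r=2.0):
    f = Frame(
        names=["X", "Y"], resnames=["UNK"] * 2, resids=[1, 2], chains=["A"] * 2,
        elements=["C"] * 2,
        positions=np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]),
        box=np.array([50.0, 50.0, 50.0]),
    )
    f.radii[:] = r
    return f


class TestAreaProfile:
    def test_single_sphere_slice_through_centre(self):
        f = single_atom_frame(radius=2.0)
        p = area_profile(f, SelectionSpec(), slice_thickness=1.0, raster=0.1,
                         z_origin=0.0)
        i = int(np.argmin(np.abs(p.z - 0.5)))
        # disk radius at the slice centre z = 0.5
        expected = np.pi * (2.0**2 - 0.5**2) / 100.0  # nm^2
        assert p.area[i] == pytest.approx(expected, rel=0.01)

    def test_two_sphere_union_matches_lens_formula(self):
        f = two_atom_frame(separation=2.0, r=2.0)
        p = area_profile(f, SelectionSpec(), slice_thickness=1.0, raster=0.1,
                         z_origin=0.0)
        i = int(np.argmin(np.abs(p.z - 0.5)))
        disk_r = np.sqrt(4 - 0.25)
        expected = lens_area(disk_r, disk_r, 2.0) / 100.0
        assert p.area[i] == pytest.approx(expected, rel=0.01)

    def test_zero_outside_protein(self):
        f = single_atom_frame(radius=2.0)
        p = area_profile(f, SelectionSpec(), z_origin=0.0)
        assert p.area[np.abs(p.z) > 2.5].max(initial=0.0) == 0.0
        assert np.all(p.area >= 0.0)

    def test_monotone_under_atom_addition(self, make_cloud):
        rng = np.random.default_rng(21)
        for _ in range(20):
            big = make_cloud(rng, 8, box=30.0)
            small = Frame(
                names=big.names[:5], resnames=big.resnames[:5], resids=big.resids[:5],
                chains=big.chains[:5], elements=big.elements[:5],
                positions=big.positions[:5], box=big.box,
            )
            small.radii[:] = big.radii[:5]
            pa = area_profile(small, SelectionSpec(), z_origin=15.0)
            pb = area_profile(big, SelectionSpec(), z_origin=15.0)
            common = np.intersect1d(np.round(pa.z, 6), np.round(pb.z, 6))
            for z in common:
                a = pa.area[np.round(pa.z, 6) == z][0]
                b = pb.area[np.round(pb.z, 6) == z][0]
                assert b >= a - 1e-12

    def test_raster_convergence(self):
        f = single_atom_frame(radius=2.0)
        a1 = area_profile(f, SelectionSpec(), raster=0.25, z_origin=0.0)
        a2 = area_profile(f, SelectionSpec(), raster=0.125, z_origin=0.0)
        i1 = int(np.argmin(np.abs(a1.z - 0.5)))
        i2 = int(np.argmin(np.abs(a2.z - 0.5)))
        assert abs(a2.area[i2] - a1.area[i1]) / a2.area[i2] < 0.005

    def test_raster_coarser_than_radius_rejected(self):
        f = single_atom_frame(radius=2.0)
        with pytest.raises(K2PFlexError, match="raster"):
            area_profile(f, SelectionSpec(), raster=2.5, z_origin=0.0)


class TestAreaProfileSeries:
    def test_identical_frames_zero_spread(self):
        f = single_atom_frame(radius=2.0)
        frames = [f.copy() for _ in range(3)]
        for k, fr in enumerate(frames):
            fr.time = float(k)
        p = area_profile_series(Trajectory(frames), SelectionSpec(), z_origin=0.0)
        assert np.allclose(p.spread, 0.0)
        single = area_profile(f, SelectionSpec(), z_origin=0.0)
        assert np.allclose(p.area, single.area)

    def test_expansion_localised_to_lower_half(self):
        rng = np.random.default_rng(4)
        n = 30
        base = rng.uniform(-3, 3, size=(n, 2))
        z = rng.uniform(-10, 10, size=n)
        compact = Frame(
            names=[f"A{i}" for i in range(n)], resnames=["UNK"] * n,
            resids=list(range(n)), chains=["A"] * n, elements=["C"] * n,
            positions=np.column_stack([base, z]), box=np.full(3, 60.0),
        )
        expanded = compact.copy()
        lower = z < 0
        expanded.positions[lower, :2] *= 2.0  # spread the cytoplasmic half
        pa = area_profile(compact, SelectionSpec(), z_origin=0.0)
        pb = area_profile(expanded, SelectionSpec(), z_origin=0.0)
        grid = np.intersect1d(np.round(pa.z, 6), np.round(pb.z, 6))
        diffs = {
            z0: pb.area[np.round(pb.z, 6) == z0][0] - pa.area[np.round(pa.z, 6) == z0][0]
            for z0 in grid
        }
        lower_max = max(d for z0, d in diffs.items() if z0 < 0)
        # spheres reach ~1.7 Å past the midplane; above that nothing moved
        upper_max = max(abs(d) for z0, d in diffs.items() if z0 > 2)
        assert lower_max > 0.05
        assert upper_max < 1e-9


class TestBilayerSummary:
    def test_exact_planes(self):
        frame, _ = syn.make_bilayer(syn.BilayerSpec(n_lipids_per_leaflet=25,
                                                    thickness=36.0, leaflet_z_jitter=0.0))
        out = bilayer_thickness(Trajectory([frame]), SelectionSpec(atom_names=["P"]))
        assert out.thickness == pytest.approx(36.0, abs=1e-9)

    def test_jittered_recovery_within_3_se(self):
        spec = syn.BilayerSpec(n_lipids_per_leaflet=64, thickness=36.0,
                               leaflet_z_jitter=1.0, seed=13)
        traj, _ = syn.make_bilayer_trajectory(spec, n_frames=50)
        out = bilayer_thickness(traj, SelectionSpec(atom_names=["P"]))
        se = out.thickness_series.std(ddof=1) / np.sqrt(len(traj))
        # per-frame sd of the leaflet-mean difference ~ sqrt(2/64) Å
        assert abs(out.thickness - 36.0) < max(3 * se, 3 * np.sqrt(2 / 64))

    def test_translation_invariance(self):
        frame, _ = syn.make_bilayer(syn.BilayerSpec(n_lipids_per_leaflet=16,
                                                    leaflet_z_jitter=0.5, seed=2))
        shifted = frame.copy()
        shifted.positions[:, 2] += 7.3
        a = bilayer_thickness(Trajectory([frame]), SelectionSpec(atom_names=["P"]))
        b = bilayer_thickness(Trajectory([shifted]), SelectionSpec(atom_names=["P"]))
        assert a.thickness == pytest.approx(b.thickness, abs=1e-9)

    def test_single_leaflet_is_error(self):
        frame, _ = syn.make_bilayer(syn.BilayerSpec(n_lipids_per_leaflet=9))
        upper_only = frame.positions[:, 2] > 0
        f = Frame(
            names=frame.names[upper_only], resnames=frame.resnames[upper_only],
            resids=frame.resids[upper_only], chains=frame.chains[upper_only],
            elements=frame.elements[upper_only],
            positions=frame.positions[upper_only], box=frame.box,
        )
        with pytest.raises(K2PFlexError, match="leaflet"):
            bilayer_thickness(Trajectory([f]), SelectionSpec(atom_names=["P"]))


class TestAreaPerLipid:
    def test_exact_arithmetic(self):
        frame, _ = syn.make_bilayer(syn.BilayerSpec(n_lipids_per_leaflet=100,
                                                    area_per_lipid=64.0))
        out = area_per_lipid(Trajectory([frame]), 100)
        assert out.area_per_lipid == pytest.approx(64.0, abs=1e-9)

    def test_linearity_in_box(self):
        frame, _ = syn.make_bilayer(syn.BilayerSpec(n_lipids_per_leaflet=100,
                                                    area_per_lipid=64.0))
        doubled = frame.copy()
        doubled.box = frame.box * np.array([2.0, 1.0, 1.0])
        out = area_per_lipid(Trajectory([doubled]), 100)
        assert out.area_per_lipid == pytest.approx(128.0, abs=1e-9)

    def test_nonpositive_n_rejected(self):
        frame, _ = syn.make_bilayer(syn.BilayerSpec(n_lipids_per_leaflet=4))
        with pytest.raises(K2PFlexError):
            area_per_lipid(Trajectory([frame]), 0)
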