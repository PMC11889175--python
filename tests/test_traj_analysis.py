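"""Trajectory analytics: distances, classification, densities, PMFs,
pathway continuity — checked against closed forms and generator truth."""

import numpy as np
import pandas as pd
import pytest

from rnfpump import traj_analysis as ta
from rnfpump.units import rt_kcal


def simple_traj(coords, names=None, groups=None):
    coords = np.asarray(coords, float)
    n_atoms = coords.shape[1]
    names = names or [f"A{k}" for k in range(n_atoms)]
    atoms = pd.DataFrame({"name": names, "element": ["C"] * n_atoms})
    return ta.TrajectoryEnsemble(coords=coords, atoms=atoms, groups=groups or {})


class TestDistanceSeries:
    def test_constant_separation(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 1, 0] = 12.0
        traj = simple_traj(coords, groups={"a": [0], "b": [1]})
        assert np.allclose(ta.distance_series(traj, "a", "b"), 12.0)

    def test_min_equals_centroid_for_single_atoms(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(20, 2, 3))
        traj = simple_traj(coords, groups={"a": [0], "b": [1]})
        assert np.allclose(
            ta.distance_series(traj, "a", "b", "min"),
            ta.distance_series(traj, "a", "b", "centroid"),
        )

    def test_min_pair_over_multi_atom_groups(self):
        coords = np.zeros((1, 4, 3))
        coords[0] = [[0, 0, 0], [0, 0, 3], [0, 0, 10], [0, 0, 30]]
        traj = simple_traj(coords, groups={"a": [0, 1], "b": [2, 3]})
        assert ta.distance_series(traj, "a", "b")[0] == pytest.approx(7.0)

    def test_bimodal_series_recovers_generator_modes(self, synthetic_traj):
        traj, manifest = synthetic_traj
        d = ta.distance_series(traj, "b8", "ae1")
        labels = np.array(manifest["labels"])
        for state, mean in manifest["state_means_A"].items():
            sel = d[labels == state]
            se = manifest["state_noise_A"] / np.sqrt(len(sel))
            assert abs(sel.mean() - mean) < 4 * se

    def test_empty_selection_names_the_group(self):
        traj = simple_traj(np.zeros((2, 2, 3)), groups={"a": [0]})
        with pytest.raises(KeyError, match="missing"):
            ta.distance_series(traj, "a", "missing")


class TestRollingAverage:
    def test_hand_computed_centered_means(self):
        out = ta.rolling_average(np.array([1.0, 2, 3, 4, 5]), 3)
        assert np.allclose(out, [1.5, 2, 3, 4, 4.5])

    def test_constant_series_unchanged(self):
        assert np.allclose(ta.rolling_average(np.full(10, 3.3), 5), 3.3)

    def test_window_one_is_identity(self):
        x = np.array([3.0, 1, 4, 1, 5])
        assert np.allclose(ta.rolling_average(x, 1), x)

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            ta.rolling_average(np.arange(3.0), 4)


class TestClassification:
    def test_recovers_generator_labels(self, synthetic_traj):
        traj, manifest = synthetic_traj
        res = ta.classify_conformations(traj)
        agreement = np.mean(res.labels == np.array(manifest["labels"]))
        assert agreement >= 0.95

    def test_all_gates_closed_means_occluded(self):
        coords = np.zeros((3, 4, 3))
        coords[:, 1, 0] = 4.0  # ic pair at 4 A (closed)
        coords[:, 2, 1] = 50.0
        coords[:, 3, 1] = 54.0  # ec pair at 4 A (closed)
        traj = simple_traj(
            coords,
            groups={"gate_ic_a": [0], "gate_ic_b": [1],
                    "gate_ec_a": [2], "gate_ec_b": [3]},
        )
        res = ta.classify_conformations(traj)
        assert list(res.labels) == ["occluded"] * 3 and res.leak_count == 0

    def test_both_gates_open_flags_leak(self):
        coords = np.zeros((2, 4, 3))
        coords[:, 1, 0] = 12.0
        coords[:, 2, 1] = 50.0
        coords[:, 3, 1] = 62.0
        traj = simple_traj(
            coords,
            groups={"gate_ic_a": [0], "gate_ic_b": [1],
                    "gate_ec_a": [2], "gate_ec_b": [3]},
        )
        with pytest.warns(UserWarning, match="leak"):
            res = ta.classify_conformations(traj)
        assert res.leak_count == 2

    def test_invariant_to_frame_permutation(self, synthetic_traj):
        traj, _ = synthetic_traj
        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_frames)
        shuffled = ta.TrajectoryEnsemble(
            coords=traj.coords[perm], atoms=traj.atoms, groups=traj.groups
        )
        a = ta.classify_conformations(traj).labels[perm]
        b = ta.classify_conformations(shuffled).labels
        assert (a == b).all()

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            ta.GatingDefinition(open_A=5.0, closed_A=6.0)


class TestIonPair:
    def test_always_closed(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 3.0
        traj = simple_traj(coords, groups={"ionpair_n": [0], "ionpair_o": [1]})
        assert ta.ion_pair_fraction(traj) == {"all": 1.0}

    def test_zero_cutoff_gives_zero(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 3.0
        traj = simple_traj(coords, groups={"ionpair_n": [0], "ionpair_o": [1]})
        assert ta.ion_pair_fraction(traj, cutoff_A=0.0) == {"all": 0.0}

    def test_recovers_generator_proportions_per_class(self, synthetic_traj):
        traj, manifest = synthetic_traj
        labels = np.array(manifest["labels"])
        fracs = ta.ion_pair_fraction(traj, labels=labels)
        for state, p_open in manifest["ion_pair_open_p"].items():
            n = int((labels == state).sum())
            expected_closed = 1.0 - p_open
            se = np.sqrt(expected_closed * (1 - expected_closed) / n)
            assert abs(fracs[state] - expected_closed) < 4 * se


class TestAxialDensity:
    def test_point_ions_occupy_single_bin(self):
        coords = np.zeros((6, 2, 3))
        coords[:, 1, 2] = 5.0
        traj = simple_traj(coords, groups={"sodium": [1], "ae1": [0]})
        prof = ta.sodium_axial_density(traj, bins=50, z_range=(-10, 10))
        assert prof.integral() == pytest.approx(1.0)
        occupied = prof.density > 0
        assert occupied.sum() == 1
        assert prof.bin_centers_A[occupied][0] == pytest.approx(5.0, abs=0.25)

    def test_uniform_ions_give_flat_profile(self):
        rng = np.random.default_rng(2)
        n = 20000
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 2] = rng.uniform(-10, 10, n)
        traj = simple_traj(coords, groups={"sodium": [1], "ae1": [0]})
        prof = ta.sodium_axial_density(traj, bins=20, z_range=(-10, 10))
        expected = 1.0 / 20.0  # per-bin probability
        counts = prof.density * 1.0  # bin width 1 A
        assert np.abs(counts - expected * 1.0 / 1.0).max() < 5 * np.sqrt(
            expected / (n * 1.0)
        )

    def test_buried_peak_only_in_occupied_frames(self, synthetic_traj):
        traj, manifest = synthetic_traj
        occ = np.array(manifest["occupied"])
        lab = np.where(occ, "occ", "free")
        peak = ta.sodium_axial_density(traj, labels=lab, label="occ")
        base = ta.sodium_axial_density(traj, labels=lab, label="free")
        center = np.abs(peak.bin_centers_A) < 1.5
        assert peak.density[center].sum() > 10 * max(base.density[center].sum(), 1e-9)

    def test_no_ions_in_range_warns_and_zeroes(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 2] = 100.0
        traj = simple_traj(coords, groups={"sodium": [1], "ae1": [0]})
        with pytest.warns(UserWarning):
            prof = ta.sodium_axial_density(traj, z_range=(-10, 10))
        assert prof.density.sum() == 0.0


class TestPmf2d:
    def test_gaussian_curvature_recovered_within_ten_percent(self):
        rng = np.random.default_rng(3)
        sigma, n = 1.0, 150000
        pmf = ta.pmf_2d(rng.normal(0, sigma, n), rng.normal(0, sigma, n), 310.0)
        kx, ky = ta.fit_parabolic_curvature(pmf, max_radius=2 * sigma)
        true = rt_kcal(310.0) / sigma**2
        assert abs(kx - true) / true < 0.10
        assert abs(ky - true) / true < 0.10

    def test_uniform_samples_are_flat(self):
        rng = np.random.default_rng(4)
        n = 200000
        bins = 10
        pmf = ta.pmf_2d(rng.uniform(0, 1, n), rng.uniform(0, 1, n), 310.0, bins=bins)
        spread = np.nanmax(pmf.free_energy_kcal) - np.nanmin(pmf.free_energy_kcal)
        # max-min of ln(count) across bins^2 multinomial bins: ~8 sigma window
        noise = rt_kcal(310.0) * 8.0 / np.sqrt(n / bins**2)
        assert spread < noise

    def test_linear_in_temperature(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        a = ta.pmf_2d(x, y, 300.0).free_energy_kcal
        b = ta.pmf_2d(x, y, 600.0).free_energy_kcal
        mask = ~np.isnan(a)
        assert np.allclose(b[mask], 2.0 * a[mask], atol=1e-12)

    def test_invariant_to_coordinate_shift(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        a = ta.pmf_2d(x, y, 310.0).free_energy_kcal
        b = ta.pmf_2d(x + 7.5, y - 3.25, 310.0).free_energy_kcal
        mask = ~np.isnan(a)
        assert np.allclose(b[mask], a[mask], atol=1e-12)

    def test_degenerate_sampling_is_an_error(self):
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            ta.pmf_2d(np.zeros(100), np.zeros(100))


def slab_with_bore(bore_radius):
    """Carbon slab spanning x,y in [-10,10], z in [-6,6], optional axial bore."""
    pts = []
    for x in np.arange(-10, 10.1, 1.5):
        for y in np.arange(-10, 10.1, 1.5):
            if bore_radius and x**2 + y**2 <= bore_radius**2:
                continue
            for z in np.arange(-6, 6.1, 1.5):
                pts.append((x, y, z))
    return np.array(pts)


class TestPathwayContinuity:
    def test_bore_admits_the_probe(self):
        coords = slab_with_bore(4.5)
        res = ta.pathway_continuity(coords, ["C"] * len(coords), z_bounds=(-6, 6))
        assert res.continuous

    def test_sealed_slab_blocks(self):
        coords = slab_with_bore(0.0)
        res = ta.pathway_continuity(coords, ["C"] * len(coords), z_bounds=(-6, 6))
        assert not res.continuous

    def test_bore_narrower_than_probe_blocks(self):
        coords = slab_with_bore(2.0)  # < vdw + probe = 3.1
        res = ta.pathway_continuity(coords, ["C"] * len(coords), z_bounds=(-6, 6))
        assert not res.continuous

    def test_monotone_in_probe_radius(self):
        coords = slab_with_bore(4.5)
        open_small = ta.pathway_continuity(
            coords, ["C"] * len(coords), z_bounds=(-6, 6), probe_radius_A=1.2,
            grid_A=0.7,
        )
        open_large = ta.pathway_continuity(
            coords, ["C"] * len(coords), z_bounds=(-6, 6), probe_radius_A=2.6,
            grid_A=0.7,
        )
        assert open_small.continuous >= open_large.continuous
        if open_large.continuous:
            assert open_small.n_path_voxels >= open_large.n_path_voxels

    def test_toy_complex_bore_and_sealed(self, toy_atoms, sealed_complex_dir):
        from rnfpump import structure_cofactors as sc

        atoms, manifest = toy_atoms
        res = ta.pathway_continuity(
            atoms[["x", "y", "z"]].to_numpy(), atoms["element"],
            z_bounds=tuple(manifest["slab_z_bounds"]),
        )
        assert res.continuous
        out, manifest2 = sealed_complex_dir
        sealed = sc.load_structure(out / "toy_complex.pdb")
        res2 = ta.pathway_continuity(
            sealed[["x", "y", "z"]].to_numpy(), sealed["element"],
            z_bounds=tuple(manifest2["slab_z_bounds"]),
        )
        assert not res2.continuous

    def test_coarse_grid_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            ta.pathway_continuity(
                np.zeros((1, 3)), ["C"], z_bounds=(-5, 5), grid_A=2.0
            )


def test_ensemble_validation():
    with pytest.raises(ValueError):
        ta.TrajectoryEnsemble(np.zeros((0, 2, 3)), pd.DataFrame({"name": ["a", "b"]}))
    with pytest.raises(ValueError):
        ta.TrajectoryEnsemble(np.zeros((2, 3, 3)), pd.DataFrame({"name": ["a", "b"]}))
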