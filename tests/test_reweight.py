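import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from photopull.builders import ideal_helix, toy_pdb
from photopull.reweight import (
    CholesterolModel, StateSplit, generate_ensemble, helix_angle, helix_axis,
    population_ratio, residue_sasa, reweight, shrake_rupley_sasa,
    transmembrane_sasa_split,
)
from photopull.structure import parse_structure


class TestHelixAxis:
    def test_axis_of_z_aligned_helix(self):
        axis = helix_axis(ideal_helix(36))
        assert helix_angle(axis, np.array([0.0, 0.0, 1.0])) < 0.02

    def test_rotation_equivariance(self):
        rot = Rotation.from_rotvec([0.7, -0.2, 1.1]).as_matrix()
        ca = ideal_helix(24)
        np.testing.assert_allclose(helix_axis(ca @ rot.T), rot @ helix_axis(ca),
                                   atol=1e-9)

    def test_noisy_helix_axis_within_two_degrees(self):
        rng = np.random.default_rng(0)
        ca = ideal_helix(26) + rng.normal(0, 0.3, (26, 3))
        axis = helix_axis(ca)
        assert helix_angle(axis, np.array([0.0, 0.0, 1.0])) < np.deg2rad(2.0)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            helix_axis(np.zeros((3, 3)))

    def test_orientation_follows_chain_direction(self):
        ca = ideal_helix(20)
        assert helix_axis(ca)[2] > 0
        assert helix_axis(ca[::-1])[2] < 0


class TestHelixAngle:
    @pytest.mark.parametrize("v,expected", [
        ([0, 0, 1], 0.0),
        ([0, 0, -1], np.pi),
        ([1, 0, 0], np.pi / 2),
    ])
    def test_reference_angles(self, v, expected):
        u = np.array([0.0, 0.0, 1.0])
        assert helix_angle(u, np.array(v, float)) == pytest.approx(expected)


class TestSasa:
    def test_isolated_sphere(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]))
        assert area[0] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-3)

    def test_distant_atoms_additive(self):
        pos = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        areas = shrake_rupley_sasa(pos, np.array([1.7, 1.5]))
        assert areas[0] == pytest.approx(4 * np.pi * 3.1**2, rel=1e-3)
        assert areas[1] == pytest.approx(4 * np.pi * 2.9**2, rel=1e-3)

    def test_overlapping_atoms_match_monte_carlo_oracle(self):
        """Shrake-Rupley against an independent dense Monte-Carlo estimate
        on a three-atom toy, within 2%."""
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 1.5, 0]])
        radii = np.array([1.7, 1.5, 1.6])
        probe = 1.4
        areas = shrake_rupley_sasa(pos, radii, probe, n_points=960)
        rng = np.random.default_rng(42)
        ext = radii + probe
        for i in range(3):
            u = rng.normal(size=(200_000, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pts = pos[i] + ext[i] * u
            exposed = np.ones(len(pts), dtype=bool)
            for j in range(3):
                if j == i:
                    continue
                exposed &= np.linalg.norm(pts - pos[j], axis=1) >= ext[j]
            oracle = exposed.mean() * 4 * np.pi * ext[i] ** 2
            assert areas[i] == pytest.approx(oracle, rel=0.02)
        assert areas.sum() < (4 * np.pi * ext**2).sum()

    def test_matches_independent_library_implementation(self):
        """Cross-check against biotite's SASA on a small helix (same radii,
        probe and a comparable point count), within a few percent."""
        import biotite.structure as struc

        from photopull.builders import ideal_helix

        n = 12
        pos = ideal_helix(n)
        radii = np.full(n, 1.7)
        mine = shrake_rupley_sasa(pos, radii, probe_radius=1.4, n_points=960)
        atoms = struc.AtomArray(n)
        atoms.coord = pos.astype(np.float32)
        atoms.element = np.array(["C"] * n)
        atoms.res_id = np.arange(1, n + 1)
        atoms.atom_name = np.array(["CA"] * n)
        atoms.res_name = np.array(["ALA"] * n)
        ref = struc.sasa(atoms, probe_radius=1.4, point_number=960,
                         vdw_radii=np.full(n, 1.7))
        np.testing.assert_allclose(mine, ref, rtol=0.04)

    def test_per_residue_aggregation(self):
        text = toy_pdb([("ALA", [0, 0, 0]), ("GLY", [0, 0, 3.8]),
                        ("LEU", [0, 0, 7.6])],
                       extra_atoms=[(1, "CB", "C", [1.5, 0, 0])])
        s = parse_structure(text, "A")
        areas = residue_sasa(s)
        assert areas.shape == (3,)
        assert np.all(areas > 0)


class TestTransmembraneSplit:
    def test_bookkeeping(self):
        areas = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        hyd = np.array([True, True, False, False, True])
        tm = np.array([True, True, True, False, False])
        a_phob, a_phil = transmembrane_sasa_split(areas, hyd, tm)
        assert a_phob == 30.0
        assert a_phil == 30.0

    def test_all_hydrophobic_tm(self):
        areas = np.ones(4)
        a_phob, a_phil = transmembrane_sasa_split(areas, np.ones(4, bool),
                                                  np.ones(4, bool))
        assert a_phil == 0.0

    def test_empty_tm_set(self):
        a_phob, a_phil = transmembrane_sasa_split(np.ones(4), np.ones(4, bool),
                                                  np.zeros(4, bool))
        assert a_phob == a_phil == 0.0


class TestCholesterolModel:
    def test_must_anchor_at_zero(self):
        with pytest.raises(ValueError):
            CholesterolModel(np.array([0.0, 0.5]), np.array([0.1, 0.2]))

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            CholesterolModel(np.array([0.0, 0.3, 0.5]),
                             np.array([0.0, 0.02, 0.01]))

    def test_out_of_range_query(self):
        model = CholesterolModel.example()
        with pytest.raises(ValueError):
            model.kappa(0.9)


class TestReweight:
    @pytest.fixture()
    def ensemble(self):
        return generate_ensemble(20_000, seed=11)

    def test_zero_cholesterol_uniform_weights(self, ensemble):
        model = CholesterolModel.example()
        w, hist, _ = reweight(ensemble, model, 0.0)
        np.testing.assert_allclose(w, 1.0 / len(ensemble), rtol=1e-12)

    def test_two_frame_weight_ratio(self):
        import pandas as pd

        model = CholesterolModel.example()
        samples = pd.DataFrame({"frame": [0, 1], "alpha_rad": [2.0, 2.5],
                                "a_hphob_A2": [2000.0, 2150.0],
                                "a_hphil_A2": [700.0, 650.0]})
        w, _, _ = reweight(samples, model, 0.5)
        expected = np.exp(model.kappa(0.5) * 150.0)
        assert w[1] / w[0] == pytest.approx(expected, rel=1e-9)

    def test_weights_conserve_probability(self, ensemble):
        model = CholesterolModel.example(a_ref=2500.0)
        for c in (0.1, 0.3, 0.5):
            w, _, _ = reweight(ensemble, model, c)
            assert abs(w.sum() - 1.0) < 1e-12

    def test_distribution_shifts_toward_mode_and_narrows(self, ensemble):
        """Cholesterol favors large hydrophobic SASA, so P(alpha) moves
        toward the SASA-optimal angle and does not broaden."""
        model = CholesterolModel.example()
        w0, _, _ = reweight(ensemble, model, 0.0)
        w5, _, _ = reweight(ensemble, model, 0.5)
        alpha = ensemble.alpha_rad.to_numpy()
        mean0 = np.sum(w0 * alpha)
        mean5 = np.sum(w5 * alpha)
        # the c = 0 mean sits slightly below the mode (left tail); the
        # reweighted mean moves toward the mode
        mode = 2.72
        assert abs(mean5 - mode) < abs(mean0 - mode)
        sd0 = np.sqrt(np.sum(w0 * (alpha - mean0) ** 2))
        sd5 = np.sqrt(np.sum(w5 * (alpha - mean5) ** 2))
        assert sd5 <= sd0 + 1e-6


class TestPopulationRatio:
    @pytest.fixture()
    def ensemble(self):
        return generate_ensemble(20_000, seed=13)

    def test_unity_at_zero_cholesterol(self, ensemble):
        model = CholesterolModel.example()
        w, _, _ = reweight(ensemble, model, 0.0)
        r = population_ratio(ensemble.alpha_rad.to_numpy(), StateSplit(), w)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_monotone_decreasing_in_cholesterol(self, ensemble):
        """The active-like state exposes less hydrophobic surface, so its
        normalized population falls as the membrane gets more hydrophobic."""
        model = CholesterolModel.example()
        alpha = ensemble.alpha_rad.to_numpy()
        ratios = []
        for c in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            w, _, _ = reweight(ensemble, model, c)
            ratios.append(population_ratio(alpha, StateSplit(), w))
        assert ratios[0] == pytest.approx(1.0)
        assert all(b < a for a, b in zip(ratios, ratios[1:]))

    def test_identical_sasa_distributions_keep_ratio_unity(self):
        import pandas as pd

        rng = np.random.default_rng(14)
        # alpha split across both states, A_HPHOB independent of alpha
        alpha = np.concatenate([rng.uniform(1.0, 2.6, 5000),
                                rng.uniform(2.6, 3.1, 5000)])
        a = np.tile(rng.normal(2500, 100, 5000), 2)
        samples = pd.DataFrame({"frame": np.arange(10_000), "alpha_rad": alpha,
                                "a_hphob_A2": a, "a_hphil_A2": 600 - 0 * a})
        model = CholesterolModel.example()
        w, _, _ = reweight(samples, model, 0.5)
        r = population_ratio(alpha, StateSplit(), w)
        assert r == pytest.approx(1.0, abs=0.05)

    def test_zero_mass_state_raises(self):
        alpha = np.full(10, 1.0)  # no mass in the inactive range
        with pytest.raises(ZeroDivisionError):
            population_ratio(alpha, StateSplit(), np.full(10, 0.1))


class TestGenerateEnsemble:
    def test_deterministic(self):
        a = generate_ensemble(500, seed=3)
        b = generate_ensemble(500, seed=3)
        assert a.equals(b)

    def test_mode_near_requested(self):
        ens = generate_ensemble(10_000, seed=4)
        assert ens.alpha_rad.mean() == pytest.approx(2.72, abs=0.02)
        assert ens.alpha_rad.between(0, np.pi).all()

    def test_sasa_anticorrelation(self):
        ens = generate_ensemble(5_000, seed=5)
        corr = np.corrcoef(ens.a_hphob_A2, -ens.a_hphil_A2)[0, 1]
        assert corr > 0.3

    def test_split_validation(self):
        with pytest.raises(ValueError):
            StateSplit(active_range=(0.0, 2.8), inactive_range=(2.6, np.pi))

    def test_split_from_bimodal_distribution(self):
        rng = np.random.default_rng(15)
        alpha = np.concatenate([rng.normal(1.8, 0.1, 4000),
                                rng.normal(2.7, 0.1, 6000)])
        split = StateSplit.from_distribution(alpha)
        assert 2.0 < split.active_range[1] < 2.5

    def test_split_from_unimodal_falls_back(self):
        alpha = generate_ensemble(4000, seed=16).alpha_rad.to_numpy()
        split = StateSplit.from_distribution(alpha)
        assert split.active_range[1] == pytest.approx(2.60)
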