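import numpy as np
import pytest

import vectorshift as vs
from vectorshift.niche import (
    COUEDecomposition,
    breadth_ratio,
    conservatism_verdict,
    coue_indices,
    density_grid,
    equivalency_test,
    niche_similarity_index,
    pca_env,
    schoener_D,
    similarity_test,
)


class TestPCAEnv:
    def test_rank_one_cloud_explained_by_axis1(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        env = np.column_stack([x, 2 * x])  # perfectly correlated pair
        pca = pca_env(env)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_cloud_splits_variance(self):
        rng = np.random.default_rng(1)
        env = rng.normal(size=(5000, 2))
        pca = pca_env(env)
        assert pca.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)
        assert pca.explained_variance_ratio[1] == pytest.approx(0.5, abs=0.05)

    def test_background_mean_projects_to_origin(self):
        rng = np.random.default_rng(2)
        env = rng.normal(size=(100, 4)) * [1, 2, 3, 4] + [5, 6, 7, 8]
        pca = pca_env(env)
        proj = pca.transform(env.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(proj, 0.0, atol=1e-9)

    def test_constant_predictor_dropped(self, caplog):
        rng = np.random.default_rng(3)
        env = np.column_stack([rng.normal(size=50), np.full(50, 7.0), rng.normal(size=50)])
        with caplog.at_level("WARNING"):
            pca = pca_env(env)
        assert "constant" in caplog.text
        assert pca.components.shape == (2, 2)


class TestDensityGrid:
    def test_density_sums_to_one(self):
        rng = np.random.default_rng(4)
        occ = rng.normal(size=(200, 2))
        bg = rng.normal(0, 2, size=(1000, 2))
        g = density_grid(occ, bg, R=50)
        assert g.occ_density.sum() == pytest.approx(1.0, abs=1e-9)
        assert g.env_density.sum() == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_concentrates_at_its_cell(self):
        occ = np.tile([[0.5, -0.5]], (10, 1))
        rng = np.random.default_rng(5)
        bg = rng.uniform(-2, 2, size=(500, 2))
        g = density_grid(occ, bg, R=40, bandwidth=(0.05, 0.05))
        i, j = np.unravel_index(np.argmax(g.occ_density), g.occ_density.shape)
        assert g.axis1[i] == pytest.approx(0.5, abs=0.1)
        assert g.axis2[j] == pytest.approx(-0.5, abs=0.1)

    def test_identical_inputs_identical_grids(self):
        rng = np.random.default_rng(6)
        occ = rng.normal(size=(50, 2))
        bg = rng.normal(size=(300, 2))
        a = density_grid(occ, bg, R=30)
        b = density_grid(occ.copy(), bg.copy(), R=30)
        np.testing.assert_array_equal(a.occ_density, b.occ_density)

    def test_too_few_points_error(self):
        bg = np.random.default_rng(7).normal(size=(100, 2))
        with pytest.raises(ValueError, match="5"):
            density_grid(bg[:4], bg, R=10)


class TestSchoenerD:
    def test_identical_grids(self):
        z = np.random.default_rng(8).uniform(size=(10, 10))
        assert schoener_D(z, z) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        z1 = np.zeros((2, 2))
        z2 = np.zeros((2, 2))
        z1[0, 0] = 1.0
        z2[1, 1] = 1.0
        assert schoener_D(z1, z2) == 0.0

    def test_hand_arithmetic_two_cells(self):
        assert schoener_D(np.array([0.7, 0.3]), np.array([0.3, 0.7])) == pytest.approx(0.6)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        z1 = rng.uniform(size=(6, 6))
        z2 = rng.uniform(size=(6, 6))
        assert schoener_D(z1, z2) == pytest.approx(schoener_D(z2, z1), abs=1e-12)

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError, match="shape"):
            schoener_D(np.ones((2, 2)), np.ones((3, 3)))


class TestCOUEIndices:
    def test_identical_occupancy(self):
        z = np.random.default_rng(10).uniform(size=(5, 5))
        d = coue_indices(z, z)
        assert (d.E, d.S, d.U) == (0.0, 1.0, 0.0)

    def test_disjoint_occupancy(self):
        z1 = np.zeros((3, 3))
        z2 = np.zeros((3, 3))
        z1[0, :] = 1.0
        z2[2, :] = 1.0
        d = coue_indices(z1, z2)
        assert (d.E, d.S, d.U) == (1.0, 0.0, 1.0)

    def test_toy_grid_matches_counting_oracle(self):
        z_nat = np.array([[0.2, 0.3, 0.0], [0.1, 0.0, 0.0], [0.0, 0.0, 0.0]])
        z_int = np.array([[0.0, 0.4, 0.1], [0.0, 0.2, 0.0], [0.0, 0.0, 0.3]])
        d = coue_indices(z_nat, z_int)
        # exhaustive cell-by-cell sums
        e_mass = s_mass = u_mass = 0.0
        for i in range(3):
            for j in range(3):
                if z_int[i, j] > 0 and z_nat[i, j] == 0:
                    e_mass += z_int[i, j]
                if z_nat[i, j] > 0 and z_int[i, j] == 0:
                    u_mass += z_nat[i, j]
        assert d.E == pytest.approx(e_mass / z_int.sum())
        assert d.U == pytest.approx(u_mass / z_nat.sum())
        assert d.E + d.S == 1.0

    def test_analog_restriction(self):
        z_nat = np.array([[0.5, 0.5], [0.0, 0.0]])
        z_int = np.array([[0.5, 0.0], [0.0, 0.5]])
        mask_nat = np.array([[True, True], [False, False]])
        mask_int = np.ones((2, 2), bool)
        # restricted to the shared (top) row, the introduced mass at (1,1)
        # is outside the analog space and E becomes 0
        d = coue_indices(z_nat, z_int, mask_nat, mask_int, analog_only=True)
        assert d.E == 0.0

    def test_empty_occupancy_error(self):
        with pytest.raises(ValueError, match="empty"):
            coue_indices(np.zeros((2, 2)), np.ones((2, 2)))

    def test_decomposition_validation(self):
        with pytest.raises(ValueError):
            COUEDecomposition(E=0.3, S=0.6, U=0.1)  # E + S != 1
        with pytest.raises(ValueError):
            COUEDecomposition(E=-0.1, S=1.1, U=0.0)


class TestShiftIndices:
    # printed niche-dynamics rows: (E, S, U) -> (BR, SI)
    TABLE = [
        ((0.045, 0.955, 0.027), 1.018, 0.964),  # yellow fever mosquito, global
        ((0.382, 0.618, 0.101), 1.391, 0.719),  # tiger mosquito, global
        ((0.499, 0.501, 0.806), 0.765, 0.434),  # tiger mosquito, Europe
    ]

    @pytest.mark.parametrize("esu,br,si", TABLE)
    def test_breadth_and_similarity_reproduce_published_rows(self, esu, br, si):
        d = COUEDecomposition(E=esu[0], S=esu[1], U=esu[2])
        assert round(breadth_ratio(d), 3) == br
        assert round(niche_similarity_index(d), 3) == si

    def test_identical_niches(self):
        d = COUEDecomposition(E=0.0, S=1.0, U=0.0)
        assert breadth_ratio(d) == 1.0
        assert niche_similarity_index(d) == 1.0

    def test_zero_native_breadth_error(self):
        d = COUEDecomposition(E=1.0, S=0.0, U=0.0)
        with pytest.raises(ValueError, match="breadth"):
            breadth_ratio(d)

    @pytest.mark.parametrize(
        "br,si,verdict",
        [
            (1.018, 0.964, "conserved"),
            (1.5, 0.4, "not_conserved"),
            (0.9, 0.4, "conserved"),  # both conditions required
            (1.5, 0.6, "conserved"),
        ],
    )
    def test_conservatism_verdict(self, br, si, verdict):
        assert conservatism_verdict(br, si) == verdict


def _two_clusters(rng, sep):
    occ1 = rng.normal([0, 0], 0.5, size=(60, 2))
    occ2 = rng.normal([sep, 0], 0.5, size=(60, 2))
    bg = rng.uniform(-3, 3 + sep, size=(800, 2))
    return occ1, occ2, bg


class TestPermutationTests:
    def test_equivalency_identical_sets_not_significant(self):
        rng = np.random.default_rng(11)
        occ = rng.normal(size=(40, 2))
        bg = rng.uniform(-3, 3, size=(400, 2))
        d_obs, p = equivalency_test(occ, occ.copy(), bg, n_perm=19, R=40, seed=1)
        assert d_obs == pytest.approx(1.0)
        assert p > 0.5

    def test_equivalency_separated_clusters_significant(self):
        rng = np.random.default_rng(12)
        occ1, occ2, bg = _two_clusters(rng, sep=5.0)
        d_obs, p = equivalency_test(occ1, occ2, bg, n_perm=99, R=40, seed=2)
        assert p <= 0.05
        assert d_obs < 0.2

    def test_p_within_rank_bounds_and_deterministic(self):
        rng = np.random.default_rng(13)
        occ1, occ2, bg = _two_clusters(rng, sep=1.0)
        _, p1 = equivalency_test(occ1, occ2, bg, n_perm=9, R=30, seed=3)
        _, p2 = equivalency_test(occ1, occ2, bg, n_perm=9, R=30, seed=3)
        assert p1 == p2
        assert 0.1 <= p1 <= 1.0

    def test_similarity_centred_niche_significant(self):
        rng = np.random.default_rng(14)
        occ1 = rng.normal([0, 0], 0.4, size=(60, 2))
        occ2 = rng.normal([0, 0], 0.4, size=(60, 2))
        bg2 = rng.uniform(-4, 4, size=(800, 2))
        d_obs, p = similarity_test(occ1, occ2, bg2, n_perm=99, R=40, seed=4)
        assert p <= 0.05

    def test_similarity_deterministic(self):
        rng = np.random.default_rng(15)
        occ1, occ2, bg = _two_clusters(rng, sep=2.0)
        _, p1 = similarity_test(occ1, occ2, bg, n_perm=9, R=30, seed=5)
        _, p2 = similarity_test(occ1, occ2, bg, n_perm=9, R=30, seed=5)
        assert p1 == p2

    def test_zero_permutations_error(self):
        rng = np.random.default_rng(16)
        occ1, occ2, bg = _two_clusters(rng, sep=1.0)
        with pytest.raises(ValueError, match="n_perm"):
            equivalency_test(occ1, occ2, bg, n_perm=0)


class TestRecovery:
    def test_zero_shift_species_recovers_identical_niche(self):
        land = vs.LandscapeConfig(n_rows=100, n_cols=100, n_gradient_layers=4,
                                  noise_sd=0.5, seed=7)
        niche = vs.VirtualNiche(mu=(5, 5, 5, 5), sigma=(1.5, 1.5, 1.5, 1.5))
        for seed in (11, 23, 31):
            sp = vs.VirtualSpeciesConfig(native=niche, introduced=niche,
                                         n_native=2000, n_introduced=2000, seed=seed)
            b = vs.simulate_virtual_species(land, sp)
            rep = vs.niche_analysis(b["native_occurrences"], b["introduced_occurrences"],
                                    b["stack"])
            # truth is E=0, U=0; estimates must land within 0.1
            assert abs(rep["E"] - b["true_E"]) < 0.1
            assert abs(rep["U"] - b["true_U"]) < 0.1
            assert rep["SI"] > 0.9

    def test_expansion_monotone_in_niche_separation(self):
        land = vs.LandscapeConfig(n_rows=100, n_cols=100, n_gradient_layers=4,
                                  noise_sd=0.5, seed=7)
        niche = vs.VirtualNiche(mu=(5, 5, 5, 5), sigma=(1.5, 1.5, 1.5, 1.5))
        estimates = []
        for shift in (0.0, 1.5, 3.0):
            sp = vs.VirtualSpeciesConfig(native=niche, introduced=niche.shifted(shift),
                                         n_native=2000, n_introduced=2000, seed=11)
            b = vs.simulate_virtual_species(land, sp)
            rep = vs.niche_analysis(b["native_occurrences"], b["introduced_occurrences"],
                                    b["stack"])
            estimates.append(rep["E"])
        assert estimates == sorted(estimates)
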