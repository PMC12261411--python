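import numpy as np
import pytest
from scipy.stats import special_ortho_group

from unicorn_hic import metrics
from unicorn_hic import reconstruct3d as r3
from unicorn_hic.hic_io import ContactMap
from unicorn_hic.simulate import SimulationConfig, generate_structure, structure_to_contacts


@pytest.fixture
def small_instance():
    """10-locus random structure with wish distances from noiseless contacts."""
    cfg = SimulationConfig(n_loci=10, alpha_true=1.0, seed=3)
    s = generate_structure(cfg)
    cm = structure_to_contacts(s, cfg)
    return s, r3.wish_distances(cm, 1.0)


class TestWishDistances:
    def test_unit_frequency_gives_unit_distance(self):
        cm = ContactMap([[0, 1], [1, 0]])
        for alpha in (0.3, 1.0, 1.7):
            assert r3.wish_distances(cm, alpha).x[0] == pytest.approx(1.0)

    def test_power_convention(self):
        cm = ContactMap([[0, 4], [4, 0]])
        assert r3.wish_distances(cm, 0.5).x[0] == pytest.approx(0.5)

    def test_zero_pairs_excluded(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 2.0
        wd = r3.wish_distances(ContactMap(m), 1.0)
        assert wd.n_pairs == 1 and wd.i[0] == 0 and wd.j[0] == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            r3.wish_distances(ContactMap(np.zeros((3, 3))), 1.0)


class TestLogLikelihood:
    def test_perfect_fit_hits_floor(self, small_instance):
        s, wd = small_instance
        n = wd.n_pairs
        eps = 1e-12
        val = r3.log_likelihood(s, wd, mse_floor=eps)
        assert val == pytest.approx(-n / 2 - n * np.log(eps))

    def test_single_pair_unit_deviation(self):
        wd = r3.WishDistances(i=np.array([0]), j=np.array([1]),
                              x=np.array([2.0]), alpha=1.0, n_bins=2)
        s = r3.Structure3D(np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        # deviation 1 -> L = -1/2 - log(1) = -0.5
        assert r3.log_likelihood(s, wd) == pytest.approx(-0.5)

    def test_doubling_deviations_drops_n_log4(self, small_instance):
        s, wd = small_instance
        rng = np.random.default_rng(0)
        base = r3.Structure3D(s.coords + rng.normal(scale=0.5, size=s.coords.shape))
        d = base.pair_distances(wd.i, wd.j)
        doubled_x = d - 2 * (d - wd.x)  # deviations doubled, same distances
        wd2 = r3.WishDistances(i=wd.i, j=wd.j, x=doubled_x, alpha=wd.alpha,
                               n_bins=wd.n_bins)
        drop = r3.log_likelihood(base, wd) - r3.log_likelihood(base, wd2)
        assert drop == pytest.approx(wd.n_pairs * np.log(4.0), abs=1e-9)

    def test_rigid_transform_invariance(self, small_instance):
        s, wd = small_instance
        rng = np.random.default_rng(1)
        base = r3.Structure3D(s.coords + rng.normal(scale=0.3, size=s.coords.shape))
        l0 = r3.log_likelihood(base, wd)
        for k in range(5):
            q = special_ortho_group.rvs(3, random_state=k)
            if k % 2:
                q = -q  # improper rotation (reflection)
            moved = r3.Structure3D(base.coords @ q.T + np.array([3.0, -1.0, 2.0]))
            assert abs(r3.log_likelihood(moved, wd) - l0) < 1e-8


class TestGradient:
    def test_matches_finite_differences(self, small_instance):
        s, wd = small_instance
        rng = np.random.default_rng(5)
        for trial in range(3):
            coords = rng.normal(scale=2.0, size=(10, 3))
            st = r3.Structure3D(coords)
            g = r3.likelihood_gradient(st, wd)
            eps = 1e-6
            for i, k in [(0, 0), (3, 1), (7, 2), (9, 0)]:
                cp = coords.copy()
                cp[i, k] += eps
                hi = r3.log_likelihood(r3.Structure3D(cp), wd)
                cp[i, k] -= 2 * eps
                lo = r3.log_likelihood(r3.Structure3D(cp), wd)
                fd = (hi - lo) / (2 * eps)
                assert g[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_zero_at_perfect_fit(self, small_instance):
        s, wd = small_instance
        g = r3.likelihood_gradient(s, wd)
        assert np.linalg.norm(g) < 1e-6

    def test_translation_invariance(self, small_instance):
        s, wd = small_instance
        rng = np.random.default_rng(6)
        base = s.coords + rng.normal(size=s.coords.shape)
        g1 = r3.likelihood_gradient(r3.Structure3D(base), wd)
        g2 = r3.likelihood_gradient(r3.Structure3D(base + 11.0), wd)
        np.testing.assert_allclose(g1, g2, atol=1e-9)


class TestOptimizer:
    def test_seeded_determinism(self, small_instance):
        _, wd = small_instance
        cfg = r3.ReconstructionConfig(seed=2, max_iters=200)
        s1, l1, i1 = r3.optimize_structure(wd, cfg)
        s2, l2, i2 = r3.optimize_structure(wd, cfg)
        np.testing.assert_array_equal(s1.coords, s2.coords)
        assert l1 == l2 and i1 == i2

    def test_likelihood_never_decreases(self, small_instance):
        _, wd = small_instance
        cfg = r3.ReconstructionConfig(seed=2, max_iters=50)
        s0 = r3.Structure3D(r3._init_coords(wd, wd.n_bins, 2))
        initial = r3.log_likelihood(s0, wd, cfg.mse_floor)
        _, final, _ = r3.optimize_structure(wd, cfg)
        assert final >= initial

    def test_structure_recovery_on_noiseless_chain(self, chain60):
        cfg, s_true, cm = chain60
        rcfg = r3.ReconstructionConfig(seed=5)
        wd = r3.wish_distances(cm, cfg.alpha_true)
        s_rec, _, _ = r3.optimize_structure(wd, rcfg)
        pcc = metrics.pearson(s_rec.pair_distances(wd.i, wd.j), wd.x)
        assert pcc >= 0.99
        assert metrics.tm_score(s_true, s_rec) >= 0.95


class TestEstimateAlpha:
    def test_single_value_grid(self, chain60):
        _, _, cm = chain60
        cfg = r3.ReconstructionConfig(alpha_grid=[0.7], seed=1,
                                      alpha_search_iters=50)
        best, table = r3.estimate_alpha(cm, cfg)
        assert best == 0.7 and len(table) == 1

    def test_table_has_row_per_alpha(self, chain60):
        _, _, cm = chain60
        grid = [0.5, 1.0, 1.5]
        cfg = r3.ReconstructionConfig(alpha_grid=grid, seed=1,
                                      alpha_search_iters=100)
        _, table = r3.estimate_alpha(cm, cfg)
        assert list(table["alpha"]) == grid

    def test_recovers_true_alpha_on_default_grid(self, chain60):
        cfg_sim, _, cm = chain60
        best, _ = r3.estimate_alpha(cm, r3.ReconstructionConfig(seed=5))
        assert abs(best - cfg_sim.alpha_true) <= 0.1


class TestEnsemble:
    def test_single_member_matches_direct_run(self, chain60):
        _, _, cm = chain60
        cfg = r3.ReconstructionConfig(ensemble_size=1, seed=9, max_iters=300)
        ens = r3.build_ensemble(cm, cfg, alpha=1.0)
        wd = r3.wish_distances(cm, 1.0)
        direct, like, _ = r3.optimize_structure(
            wd, cfg, seed=(cfg.seed + 7919) % (2 ** 31 - 1))
        np.testing.assert_array_equal(ens.structures[0].coords, direct.coords)
        assert ens.likelihoods[0] == like

    def test_distinct_seeds_give_distinct_raw_structures(self, chain60):
        _, _, cm = chain60
        cfg = r3.ReconstructionConfig(ensemble_size=3, seed=9, max_iters=100)
        ens = r3.build_ensemble(cm, cfg, alpha=1.0)
        a, b = ens.structures[0].coords, ens.structures[1].coords
        assert np.abs(a - b).max() > 1e-6

    def test_representative_selectors(self, chain60):
        _, _, cm = chain60
        cfg = r3.ReconstructionConfig(ensemble_size=3, seed=9, max_iters=300)
        ens = r3.build_ensemble(cm, cfg, alpha=1.0)
        best = r3.select_representative(ens, "likelihood")
        assert best is ens.structures[int(np.argmax(ens.likelihoods))]
        medoid = r3.select_representative(ens, "medoid")
        assert any(medoid is s for s in ens.structures)


class TestProbeDistance:
    def test_identical_ranges_zero(self):
        s = r3.Structure3D(np.random.default_rng(0).normal(size=(10, 3)))
        assert r3.probe_distance(s, (2, 5), (2, 5)) == 0.0

    def test_three_four_five(self):
        s = r3.Structure3D(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        assert r3.probe_distance(s, [0], [1]) == pytest.approx(5.0)

    def test_symmetric_and_validates_range(self):
        s = r3.Structure3D(np.random.default_rng(1).normal(size=(8, 3)))
        assert r3.probe_distance(s, (0, 3), (4, 8)) == pytest.approx(
            r3.probe_distance(s, (4, 8), (0, 3)))
        with pytest.raises(ValueError):
            r3.probe_distance(s, (0, 0), (4, 8))
        with pytest.raises(ValueError):
            r3.probe_distance(s, (0, 3), (6, 12))


class TestStructureIO:
    def test_xyz_round_trip_exact(self, tmp_path):
        s = r3.Structure3D(np.random.default_rng(2).normal(size=(12, 3)))
        path = tmp_path / "s.xyz"
        r3.write_structure(s, path, format="xyz")
        back = r3.read_xyz(path)
        np.testing.assert_array_equal(back.coords, s.coords)
        np.testing.assert_array_equal(back.locus_bins, s.locus_bins)

    def test_pdb_line_count_and_precision(self, tmp_path):
        coords = np.random.default_rng(3).normal(scale=10.0, size=(15, 3))
        s = r3.Structure3D(coords)
        path = tmp_path / "s.pdb"
        r3.write_structure(s, path, format="pdb")
        lines = path.read_text().splitlines()
        atom_lines = [l for l in lines if l.startswith("ATOM")]
        assert len(atom_lines) == 15
        assert len(lines) == 15 + 3  # HEADER + TER + END
        parsed = np.array([[float(l[30:38]), float(l[38:46]), float(l[46:54])]
                           for l in atom_lines])
        np.testing.assert_allclose(parsed, coords, atol=1e-3)

    def test_unknown_format_rejected(self, tmp_path):
        s = r3.Structure3D(np.zeros((3, 3)) + np.arange(3)[:, None])
        with pytest.raises(ValueError):
            r3.write_structure(s, tmp_path / "x", format="cif")
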