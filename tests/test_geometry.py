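"""Cell placement: uniform sampling, collision analysis, surface layouts,
growth transformations."""

import numpy as np
import pytest
from scipy import stats

from raybnn import geometry
from raybnn.geometry import (
    CellPopulation,
    GeometryConfig,
    collision_probability_analytic,
    densify_inputs,
    detect_collisions,
    grid_vectors,
    grow_sphere,
    migrate_inputs_concat,
    min_sphere_radius,
    place_input_grid,
    place_input_helix,
    place_input_stacked,
    populate_sphere,
    radial_density,
    sample_hidden_positions,
    spherical_to_cartesian,
)


class TestSampleHiddenPositions:
    def test_inverse_cdf_endpoints(self, monkeypatch):
        # R_r=1, R_theta=0.5, R_phi=0 -> (r_s, pi/2, 0); R_r=0 -> origin
        class FakeRng:
            def __init__(self, rows):
                self.rows = np.asarray(rows, float)

            def random(self, shape):
                return self.rows[: shape[0]]

        pts = sample_hidden_positions(1, 5.0, FakeRng([[1.0, 0.5, 0.0]]))
        np.testing.assert_allclose(pts[0], [5.0, 0.0, 0.0], atol=1e-12)
        pts = sample_hidden_positions(1, 5.0, FakeRng([[0.0, 0.9, 0.3]]))
        np.testing.assert_allclose(pts[0], [0.0, 0.0, 0.0], atol=1e-12)

    def test_radial_cdf_is_cubic(self, rng):
        r_s = 10.0
        pts = sample_hidden_positions(50_000, r_s, rng)
        radii = np.linalg.norm(pts, axis=1)
        res = stats.kstest(radii, lambda r: (r / r_s) ** 3)
        assert res.pvalue > 0.01

    def test_isotropy(self, rng):
        pts = sample_hidden_positions(50_000, 1.0, rng)
        cosines = pts[:, 2] / np.linalg.norm(pts, axis=1)
        res = stats.kstest(cosines, stats.uniform(loc=-1, scale=2).cdf)
        assert res.pvalue > 0.01

    def test_negative_count_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_hidden_positions(-1, 1.0, rng)


class TestRadialDensity:
    def test_single_cell_single_bin(self):
        pop = CellPopulation(
            positions=[[0.5, 0, 0]], cell_type=np.array(["hidden"], object), r_s=1.0
        )
        table, _ = radial_density(pop, 1)
        assert table["count"].tolist() == [1]

    def test_quadratic_coefficient_matches_uniform_density(self, rng):
        # fitted a ~ 3 N_T / r_s^3 for uniformly placed cells
        r_s, n = 50.0, 200_000
        pts = sample_hidden_positions(n, r_s, rng)
        pop = CellPopulation(
            positions=pts, cell_type=np.array(["hidden"] * n, object), r_s=r_s
        )
        _, a = radial_density(pop, 50)
        expected = 3 * n / r_s**3
        assert abs(a - expected) / expected < 0.05

    def test_empty_shell_signalled(self):
        pop = CellPopulation(
            positions=[[0, 0, 0]], cell_type=np.array(["output"], object), r_s=1.0
        )
        table, a = radial_density(pop, 3)
        assert table["count"].sum() == 0 and np.isnan(a)

    def test_bad_bins(self, small_population):
        with pytest.raises(ValueError):
            radial_density(small_population, 0)


class TestAnalyticRelations:
    def test_collision_probability(self):
        assert collision_probability_analytic(0.0) == 0.0
        # density at the 1% threshold
        assert collision_probability_analytic(2.98e-4) == pytest.approx(0.01, rel=5e-3)
        assert collision_probability_analytic(1e-4) == pytest.approx(3.351e-3, rel=1e-3)
        with pytest.raises(ValueError):
            collision_probability_analytic(-1.0)

    def test_min_sphere_radius(self):
        assert min_sphere_radius(480_000, 0.01) == pytest.approx(726.8, abs=0.05)
        assert min_sphere_radius(1, 1.0) == pytest.approx(2.0)
        assert min_sphere_radius(1, 0.01) == pytest.approx(9.283, abs=5e-4)


class TestDetectCollisions:
    def test_boundary_inclusive(self):
        pos = np.array([[0, 0, 0], [2.0 + 1e-9, 0, 0]])
        assert len(detect_collisions(pos, method="batch")) == 0
        pos = np.array([[0, 0, 0], [2.0, 0, 0]])
        assert detect_collisions(pos, method="batch").tolist() == [0, 1]

    @pytest.mark.parametrize("m", [50, 400, 2000])
    def test_all_methods_match_bruteforce_oracle(self, m, rng):
        box = (m / 5e-3 * 3 / (4 * np.pi)) ** (1 / 3)
        pos = rng.uniform(-box, box, (m, 3))
        # brute-force O(M^2) oracle
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        oracle = np.flatnonzero((d <= 2.0).any(axis=1))
        for method in ("serial", "batch", "minibatch", "kdtree"):
            np.testing.assert_array_equal(
                detect_collisions(pos, method=method, chunk_size=97), oracle
            )

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            detect_collisions(np.zeros((3, 3)), method="quantum")


class TestPopulateSphere:
    def test_only_io_neurons(self):
        cfg = GeometryConfig(n_input=4, n_output=2, r_s=20.0, seed=0)
        pop, _ = populate_sphere(cfg)
        assert pop.n_cells == 6 and pop.n_hidden == 0 and pop.n_glial == 0
        np.testing.assert_allclose(
            np.linalg.norm(pop.positions[pop.mask("input")], axis=1), pop.r_s
        )
        np.testing.assert_allclose(pop.positions[pop.mask("output")], 0.0)

    def test_determinism(self):
        cfg = GeometryConfig(n_hidden=200, n_glial=200, n_input=4, n_output=2, seed=11)
        p1, _ = populate_sphere(cfg)
        p2, _ = populate_sphere(cfg)
        np.testing.assert_array_equal(p1.positions, p2.positions)
        np.testing.assert_array_equal(p1.cell_type, p2.cell_type)

    def test_no_residual_collisions_among_interior(self):
        cfg = GeometryConfig(n_hidden=500, n_glial=500, seed=3)
        pop, _ = populate_sphere(cfg)
        interior = pop.positions[(pop.cell_type == "hidden") | (pop.cell_type == "glial")]
        assert len(detect_collisions(interior, method="kdtree")) == 0

    def test_rejection_rate_follows_analytic_collision_probability(self):
        # Probe placements against the final population measure exactly the
        # quantity the analytic one-more-cell formula predicts; the run's own
        # rejection fraction integrates that rate over the growing population
        # (about half the final value).
        n = 20_000
        eta = 2e-4
        r_s = (3 * n / (4 * np.pi * eta)) ** (1 / 3)
        cfg = GeometryConfig(n_hidden=n // 2, n_glial=n // 2, r_s=r_s,
                             p_c_threshold=0.999, seed=5)
        pop, stats_run = populate_sphere(cfg)
        from scipy.spatial import cKDTree

        tree = cKDTree(pop.positions[(pop.cell_type == "hidden") | (pop.cell_type == "glial")])
        rng = np.random.default_rng(99)
        n_probe = 40_000
        probes = sample_hidden_positions(n_probe, r_s, rng)
        hits = tree.query_ball_point(probes, 2.0, return_length=True)
        p_hat = np.mean(hits > 0)
        p_exp = collision_probability_analytic(pop.density())
        # 99% binomial interval around the analytic prediction
        half_width = 2.576 * np.sqrt(p_exp * (1 - p_exp) / n_probe)
        assert abs(p_hat - p_exp) < half_width + 1e-12
        # process-integrated prediction for the sequential run itself
        assert stats_run["rejection_fraction"] == pytest.approx(p_exp / 2, rel=0.5)

    def test_radius_floor_prevents_infeasible_packing(self):
        # a 5 r_n sphere cannot hold 1000 cells; the radius is raised to the
        # collision-threshold minimum so placement always terminates
        cfg = GeometryConfig(n_hidden=500, n_glial=500, r_s=5.0,
                             p_c_threshold=0.999, seed=0)
        pop, _ = populate_sphere(cfg)
        assert pop.r_s >= min_sphere_radius(1000, 0.999)
        assert pop.r_s > 5.0


class TestInputLayouts:
    def test_single_site(self):
        pos = place_input_grid(1, 1, 2.0)
        # v = 1/2 -> theta = pi/2, phi = pi
        np.testing.assert_allclose(pos[0], [-2.0, 0.0, 0.0], atol=1e-12)

    def test_three_by_one_polar_angles(self):
        pos = place_input_grid(3, 1, 1.0)
        theta = np.arccos(pos[:, 2] / np.linalg.norm(pos, axis=1))
        np.testing.assert_allclose(theta, [2 * np.pi / 3, np.pi / 2, np.pi / 3], atol=1e-12)

    @pytest.mark.parametrize("nx,ny", [(2, 3), (4, 4), (5, 2)])
    def test_all_sites_distinct_on_surface(self, nx, ny):
        pos = place_input_grid(nx, ny, 7.0)
        assert len(np.unique(np.round(pos, 9), axis=0)) == nx * ny
        np.testing.assert_allclose(np.linalg.norm(pos, axis=1), 7.0)

    def test_equal_solid_angle(self):
        # equal cos(theta) spacing: each row band spans the same solid angle
        v_theta, _ = grid_vectors(6, 1)
        cos_t = 2 * (v_theta - 0.5)
        np.testing.assert_allclose(np.diff(cos_t), np.diff(cos_t)[0])

    def test_helix_is_rowmajor_grid_prefix(self):
        full = place_input_grid(3, 3, 1.0)
        np.testing.assert_array_equal(place_input_helix(5, 1.0), full[:5])
        np.testing.assert_array_equal(place_input_helix(9, 1.0), full)
        np.testing.assert_array_equal(place_input_helix(1, 1.0), place_input_grid(1, 1, 1.0))

    def test_stacked_channels_colocated(self):
        pos = place_input_stacked(2, 2, 3, 1.0)
        base = place_input_grid(2, 2, 1.0)
        np.testing.assert_array_equal(pos, np.repeat(base, 3, axis=0))
        np.testing.assert_array_equal(place_input_stacked(2, 2, 1, 1.0), base)


class TestGrowthTransforms:
    def test_grow_identity_and_scaling(self, small_population):
        same = grow_sphere(small_population, small_population.r_s)
        np.testing.assert_array_equal(same.positions, small_population.positions)
        grown = grow_sphere(small_population, small_population.r_s * 45 / 42)
        np.testing.assert_allclose(
            grown.positions, small_population.positions * (45 / 42), rtol=1e-15
        )
        # unit directions preserved exactly for nonzero cells
        norms = np.linalg.norm(small_population.positions, axis=1)
        nz = norms > 0
        np.testing.assert_allclose(
            grown.positions[nz] / np.linalg.norm(grown.positions[nz], axis=1)[:, None],
            small_population.positions[nz] / norms[nz, None],
            rtol=0, atol=1e-15,
        )

    def test_shrink_rejected(self, small_population):
        with pytest.raises(ValueError):
            grow_sphere(small_population, small_population.r_s * 0.5)

    def test_densify_retains_old_rows(self):
        vt_new, vp_new, index_map = densify_inputs(2, 2, 4, 4)
        vt_old, _ = grid_vectors(2, 2)
        # identity when nothing changes
        _, _, id_map = densify_inputs(2, 2, 2, 2)
        assert id_map == {(i, j): (i, j) for i in range(2) for j in range(2)}
        # each old theta row maps to its nearest new row; old values 1/3, 2/3
        # sit between new values (1/5..4/5)
        np.testing.assert_allclose(vt_new, [0.2, 0.4, 0.6, 0.8])
        assert {index_map[(i, j)][0] for i in range(2) for j in range(2)} <= {1, 2}
        with pytest.raises(ValueError):
            densify_inputs(4, 4, 2, 2)

    def test_migrate_concat_formula(self):
        pop, _ = populate_sphere(
            GeometryConfig(n_input=4, n_output=1, r_s=10.0, input_layout="helix", seed=0)
        )
        migrated = migrate_inputs_concat(pop, 1.0)
        np.testing.assert_allclose(migrated.positions, pop.positions, atol=1e-12)
        half = migrate_inputs_concat(pop, 0.5)
        sel = pop.cell_type == "input"
        v = pop.input_v[:, 0]
        expected_theta = np.arccos(2 * (0.5 * v - 0.5))
        got_theta = np.arccos(half.positions[sel][:, 2] / pop.r_s)
        np.testing.assert_allclose(got_theta, expected_theta, atol=1e-12)
        # kappa = 0.5 compresses everything into the southern-theta hemisphere
        assert np.all(got_theta > np.pi / 2)
        with pytest.raises(ValueError):
            migrate_inputs_concat(pop, 0.0)


def test_positions_roundtrip(tmp_path, small_population):
    path = tmp_path / "positions.csv"
    geometry.write_positions(small_population, path)
    back = geometry.read_positions(path, r_s=small_population.r_s)
    np.testing.assert_allclose(back.positions, small_population.positions)
    np.testing.assert_array_equal(back.cell_type, small_population.cell_type)
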