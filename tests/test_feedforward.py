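"""Force scans, pooled solution-set PCA, and the bootstrap."""

import numpy as np
import pytest

import mechsynergy as ms
from mechsynergy.feedforward import bootstrap_ci, planar_directions


@pytest.fixture(scope="module")
def finger_results():
    """One fitted finger feedforward analysis shared across tests (the scan
    plus enumeration is the expensive step)."""
    model = ms.make_finger_like()
    ff = ms.FeedforwardSynergy(model, k_directions=16, increment=1.0)
    return ff.fit(threshold=0.8, per_level=False)


class TestScanForceLevels:
    def test_box_geometry(self):
        # one muscle per half-axis: feasible set is the unit square's
        # symmetric hull, max magnitude 1 along each axis direction
        A = ms.ActionMatrix(np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]]), ["fx", "fy"])
        scan = ms.scan_force_levels(A, k_directions=4, increment=0.25, zero_components=())
        assert np.allclose(scan.levels, [0.25, 0.5, 0.75, 1.0])
        assert np.allclose(scan.max_feasible_per_direction, 1.0)

    def test_every_retained_level_feasible_everywhere(self, finger_results):
        scan = finger_results.scan
        A = finger_results.model.action
        # spot-check the top level in all 16 directions
        top = scan.levels[-1]
        for u in scan.directions:
            poly = ms.build_activation_polytope(A, u, top, scan.zero_components)
            assert ms.enumerate_vertices(poly).is_feasible

    def test_min_radial_matches_inscribed_circle(self):
        """Axis-symmetric case: min radial feasibility over sampled
        directions equals the inscribed-circle radius exactly."""
        A = ms.ActionMatrix(np.array([[2.0, -2.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]]), ["fx", "fy"])
        dirs = planar_directions(4)
        radial = np.array([ms.max_feasible_magnitude(A, u, ()) for u in dirs])
        # feasible set is the rectangle [-2,2]x[-1,1]; inscribed radius 1
        assert np.min(radial) == pytest.approx(1.0, abs=1e-6)

    def test_min_radial_sandwiched_by_support_and_inradius(self, finger_results):
        """min_k radial(u_k) lies between the fine-grid inradius (below) and
        min_k support(u_k) (above): consistency of the LP-traced polygon."""
        A = finger_results.model.action
        scan = finger_results.scan
        min_radial = float(np.min(scan.max_feasible_per_direction))
        fine = planar_directions(256)
        inradius = min(ms.max_feasible_magnitude(A, u) for u in fine)
        assert inradius <= min_radial + 1e-9
        assert min_radial <= inradius * 1.2  # 16 directions sample the min well

    def test_empty_scan_warns(self):
        A = ms.ActionMatrix(1e-6 * np.eye(2), ["fx", "fy"])
        with pytest.warns(UserWarning):
            scan = ms.scan_force_levels(A, 4, increment=1.0, zero_components=())
        assert scan.is_empty

    def test_increment_validation(self, finger):
        A = ms.action_matrix(finger)
        with pytest.raises(ms.ConfigError):
            ms.scan_force_levels(A, 16, increment=0.0)


class TestCombinedSolutionPca:
    def test_low_dimensional_at_every_level(self, finger_results):
        """The headline structure: pooled omnidirectional solution sets need
        fewer components than muscles at every feasible force level."""
        sol = finger_results.solution_pca
        assert len(sol.levels) >= 2
        assert all(k < 7 for k in sol.n_components)
        assert all(1 <= k for k in sol.n_components)
        assert sol.pooled_n_components is not None and sol.pooled_n_components < 7

    def test_affine_subspace_rank_bound(self, finger_results):
        """Centered single-task vertex cloud has rank <= n - rank(A_eq)."""
        A = finger_results.model.action
        u = np.array([1.0, 0.0])
        poly = ms.build_activation_polytope(A, u, finger_results.scan.levels[0])
        vs = ms.enumerate_vertices(poly)
        X = vs.vertices - vs.vertices.mean(axis=0)
        rank = np.linalg.matrix_rank(X, tol=1e-8)
        assert rank <= 7 - np.linalg.matrix_rank(poly.a_eq)

    def test_exact_rank_reached_in_curve(self):
        """Vertices in an r-dimensional affine subspace: cumulative VAF
        reaches 1 at r components."""
        A = ms.ActionMatrix(np.array([[1.0, 1.0, 1.0]]), ["fx"])
        # single direction in a 1-D force 'plane'
        scan = ms.ForceScan(np.array([[1.0]]), 0.5, np.array([0.5]), np.array([3.0]), ())
        sol = ms.combined_solution_pca(A, scan, threshold=0.8)
        # simplex {a : sum a = 0.5} has affine dimension 2
        assert sol.cumulative_vaf[0][1] == pytest.approx(1.0, abs=1e-10)

    def test_components_bounded_by_muscle_count_and_hull_rank(self, finger_results):
        sol = finger_results.solution_pca
        for cum, k in zip(sol.cumulative_vaf, sol.n_components):
            assert k <= len(cum) <= 7
            assert np.all(np.diff(cum) >= -1e-12)


class TestBootstrapCi:
    def test_degenerate_samples_zero_width(self):
        lo, hi = bootstrap_ci(np.full(10, 3.0), seed=0)
        assert lo == hi == 3.0

    def test_percentile_definition(self):
        """Endpoints are the (1 +/- level)/2 quantiles of the bootstrap
        distribution, reproduced with the same seed."""
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        rng = np.random.default_rng(7)
        idx = rng.integers(0, 5, size=(500, 5))
        stats = x[idx].mean(axis=1)
        expected = np.quantile(stats, [0.025, 0.975])
        lo, hi = bootstrap_ci(x, level=0.95, n_boot=500, seed=7)
        assert (lo, hi) == pytest.approx(tuple(expected))

    def test_coverage_close_to_nominal(self):
        """Percentile-bootstrap coverage for a Gaussian mean at n=30 is
        within 5 points of the nominal 95%."""
        rng = np.random.default_rng(11)
        hits = 0
        n_data = 400
        for i in range(n_data):
            x = rng.standard_normal(30)
            lo, hi = bootstrap_ci(x, level=0.95, n_boot=600, seed=1000 + i)
            hits += lo <= 0.0 <= hi
        assert hits / n_data == pytest.approx(0.95, abs=0.05)

    def test_validation(self):
        with pytest.raises(ms.ConfigError):
            bootstrap_ci(np.array([1.0]))
        with pytest.raises(ms.ConfigError):
            bootstrap_ci(np.array([1.0, 2.0]), level=1.5)


class TestFeedforwardSynergyModel:
    def test_summary_lists_levels(self, finger_results):
        text = finger_results.summary()
        assert "level" in text and "vertices" in text

    def test_over_cap_model_refused(self):
        rng = np.random.default_rng(0)
        A = ms.ActionMatrix(rng.standard_normal((3, 20)), ["fx", "fy", "tz"])
        with pytest.raises(ms.DimensionError):
            ms.FeedforwardSynergy(A)

    def test_ci_method(self, finger_results):
        lo, hi = finger_results.n_components_ci(seed=3)
        ks = finger_results.n_components_per_level
        assert min(ks) <= lo <= hi <= max(ks)
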