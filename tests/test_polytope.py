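"""Activation polytopes: construction, exact vertex enumeration against the
combinatorial active-set oracle, and feasibility LPs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mechsynergy as ms
from mechsynergy.errors import SizeCapError
from mechsynergy.polytope import ActivationPolytope


class TestBuildActivationPolytope:
    def test_row_count_is_plane_plus_zeroed(self, finger):
        A = ms.action_matrix(finger)
        poly = ms.build_activation_polytope(A, np.array([1.0, 0.0]), 2.0, ("tz",))
        assert poly.n_equalities == 2 + 1
        assert poly.n_muscles == 7
        assert np.allclose(poly.b_eq, [2.0, 0.0, 0.0])

    def test_unknown_label_rejected(self, finger):
        A = ms.action_matrix(finger)
        with pytest.raises(ms.ConfigError):
            ms.build_activation_polytope(A, np.array([1.0, 0.0]), 1.0, ("mz",))

    def test_zero_magnitude_origin_feasible(self, finger):
        A = ms.action_matrix(finger)
        poly = ms.build_activation_polytope(A, np.array([0.0, 1.0]), 0.0, ("tz",))
        vs = ms.enumerate_vertices(poly)
        assert vs.is_feasible
        assert np.allclose(poly.a_eq @ np.zeros(7) - poly.b_eq, 0.0)

    def test_non_unit_direction_rejected(self, finger):
        A = ms.action_matrix(finger)
        with pytest.raises(ms.ConfigError):
            ms.build_activation_polytope(A, np.array([1.0, 1.0]), 1.0, ("tz",))


class TestEnumerateVertices:
    def test_standard_simplex(self):
        vs = ms.enumerate_vertices(ActivationPolytope([[1.0, 1.0, 1.0]], [1.0]))
        assert np.allclose(vs.vertices, [[0, 0, 1], [0, 1, 0], [1, 0, 0]])

    def test_diagonal_segment(self):
        vs = ms.enumerate_vertices(ActivationPolytope([[1.0, -1.0]], [0.0]))
        assert np.allclose(vs.vertices, [[0, 0], [1, 1]])

    def test_infeasible_vs_degenerate_point(self):
        empty = ms.enumerate_vertices(ActivationPolytope([[1.0, 1.0]], [3.0]))
        assert not empty.is_feasible and empty.n_vertices == 0
        point = ms.enumerate_vertices(
            ActivationPolytope([[1.0, 0.0], [0.0, 1.0]], [0.5, 0.25])
        )
        assert point.is_feasible and point.n_vertices == 1
        assert np.allclose(point.vertices, [[0.5, 0.25]])

    def test_full_box_when_no_equalities(self):
        vs = ms.enumerate_vertices(ActivationPolytope(np.empty((0, 3)), np.empty(0)))
        assert vs.n_vertices == 8  # the unit cube

    def test_lexicographic_order_and_dedup(self):
        vs = ms.enumerate_vertices(ActivationPolytope([[1.0, 1.0]], [1.0]))
        assert np.allclose(vs.vertices, [[0, 1], [1, 0]])
        as_tuples = [tuple(v) for v in vs.vertices]
        assert as_tuples == sorted(as_tuples)
        assert len(set(as_tuples)) == len(as_tuples)

    def test_cap_refusal(self):
        poly = ActivationPolytope(np.ones((1, 17)), [1.0])
        with pytest.raises(SizeCapError):
            ms.enumerate_vertices(poly)

    def test_matches_active_set_oracle_random(self, vertex_oracle):
        """Exact agreement with the brute-force basic-solution oracle on
        seeded random feasible polytopes (n <= 6, <= 3 equalities)."""
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(3, 7))
            m = int(rng.integers(1, min(n - 1, 3) + 1))
            A = rng.standard_normal((m, n))
            b = A @ rng.uniform(0, 1, n)
            got = ms.enumerate_vertices(ActivationPolytope(A, b)).vertices
            expected = vertex_oracle(A, b)
            assert got.shape == expected.shape
            if got.size:
                assert np.max(np.abs(got - expected)) < 1e-8

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_wrench_conservation_property(self, seed):
        """Every enumerated vertex satisfies the equalities to 1e-8 and the
        box bounds to 1e-10."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        m = int(rng.integers(1, 3))
        A = rng.standard_normal((m, n))
        b = A @ rng.uniform(0, 1, n)
        vs = ms.enumerate_vertices(ActivationPolytope(A, b))
        for v in vs.vertices:
            assert np.max(np.abs(A @ v - b)) <= 1e-8
            assert np.all(v >= -1e-10) and np.all(v <= 1 + 1e-10)

    def test_vertices_have_enough_tight_constraints(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((2, 5))
        b = A @ rng.uniform(0, 1, 5)
        vs = ms.enumerate_vertices(ActivationPolytope(A, b))
        for v in vs.vertices:
            tight_bounds = np.sum((np.abs(v) < 1e-10) | (np.abs(v - 1) < 1e-10))
            assert tight_bounds + 2 >= 5  # bounds + equalities >= n_muscles


class TestMaxFeasibleMagnitude:
    def test_box_edge(self):
        A = ms.ActionMatrix(np.eye(2), ["fx", "fy"])
        assert ms.max_feasible_magnitude(A, np.array([1.0, 0.0]), ()) == pytest.approx(1.0)

    def test_homogeneous_in_max_forces(self, finger):
        import dataclasses
        A1 = ms.action_matrix(finger)
        A2 = ms.action_matrix(dataclasses.replace(finger, max_forces=3 * finger.max_forces))
        u = np.array([np.cos(0.7), np.sin(0.7)])
        m1 = ms.max_feasible_magnitude(A1, u)
        m2 = ms.max_feasible_magnitude(A2, u)
        assert m2 == pytest.approx(3 * m1, rel=1e-8)

    def test_lp_agrees_with_enumeration_feasibility(self, finger):
        """Bisection cross-check: vertex enumeration is nonempty just below
        the LP magnitude and empty just above it."""
        A = ms.action_matrix(finger)
        u = np.array([0.0, 1.0])
        c = ms.max_feasible_magnitude(A, u)
        below = ms.build_activation_polytope(A, u, 0.999 * c)
        above = ms.build_activation_polytope(A, u, 1.001 * c)
        assert ms.enumerate_vertices(below).is_feasible
        assert not ms.enumerate_vertices(above).is_feasible

    def test_feasible_set_convex_midpoints(self, finger):
        """Midpoint of two feasible boundary wrenches is feasible (LP)."""
        from scipy.optimize import linprog

        A = ms.action_matrix(finger)
        u1, u2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        w1 = ms.max_feasible_magnitude(A, u1) * u1
        w2 = ms.max_feasible_magnitude(A, u2) * u2
        mid = 0.5 * (w1 + w2)
        res = linprog(
            np.zeros(7),
            A_eq=A.matrix,
            b_eq=np.array([mid[0], mid[1], 0.0]),
            bounds=[(0, 1)] * 7,
            method="highs",
        )
        assert res.success
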