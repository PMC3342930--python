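"""Kinetostatic mappings: stretch, Jacobian inversion, action matrices,
tension protocols and action-matrix regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import mechsynergy as ms
from mechsynergy.errors import RankError, SingularityError, SizeCapError
from mechsynergy.limb import planar_chain_jacobian


def tiny_model(moment_arm=0.02, max_force=100.0, jac=0.3):
    return ms.LimbModel(
        muscle_names=["m0"],
        joint_names=["j0"],
        moment_arms=[[moment_arm]],
        jacobian=[[jac]],
        max_forces=[max_force],
        posture=[0.0],
        wrench_labels=["fx"],
    )


class TestComputeStretch:
    def test_zero_delta_zero_stretch(self, schematic):
        assert np.allclose(ms.compute_stretch(schematic, np.zeros(2)), 0.0)

    def test_positive_arm_positive_rotation_shortens(self):
        # moment arm +0.02 m, joint delta +0.1 rad -> stretch -0.002 m
        s = ms.compute_stretch(tiny_model(), np.array([0.1]))
        assert s == pytest.approx(-0.002)

    @given(
        a=st.floats(-2, 2), b=st.floats(-2, 2),
        u0=st.floats(-0.5, 0.5), u1=st.floats(-0.5, 0.5),
        v0=st.floats(-0.5, 0.5), v1=st.floats(-0.5, 0.5),
    )
    @settings(deadline=None, max_examples=50)
    def test_linearity(self, a, b, u0, u1, v0, v1):
        m = ms.make_schematic_limb()
        u, v = np.array([u0, u1]), np.array([v0, v1])
        lhs = ms.compute_stretch(m, a * u + b * v)
        rhs = a * ms.compute_stretch(m, u) + b * ms.compute_stretch(m, v)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_path_integral_matches_quadrature_oracle(self):
        """Posture-dependent arms: exact polynomial path integral equals an
        independent numerical quadrature of the length-change integral."""
        rng = np.random.default_rng(7)
        n_m, n_j = 4, 2
        coeffs = rng.normal(scale=0.01, size=(n_m, n_j, 3))
        q0 = rng.uniform(-0.5, 0.5, n_j)
        model = ms.LimbModel(
            muscle_names=[f"m{i}" for i in range(n_m)],
            joint_names=["j0", "j1"],
            moment_arms=np.array(
                [[np.polynomial.polynomial.polyval(q0[j], coeffs[i, j]) for j in range(n_j)]
                 for i in range(n_m)]
            ),
            jacobian=np.eye(2),
            max_forces=np.ones(n_m),
            posture=q0,
            moment_arm_coeffs=coeffs,
        )
        for _ in range(5):
            dq = rng.uniform(-0.05, 0.05, n_j)
            s = ms.compute_stretch(model, dq)
            for i in range(n_m):
                def integrand(t, i=i):
                    q = q0 + t * dq
                    r = [np.polynomial.polynomial.polyval(q[j], coeffs[i, j]) for j in range(n_j)]
                    return -np.dot(r, dq)
                expected, _ = quad(integrand, 0.0, 1.0, epsabs=1e-12)
                assert s[i] == pytest.approx(expected, abs=1e-8)

    def test_dimension_mismatch(self, schematic):
        with pytest.raises(ms.DimensionError):
            ms.compute_stretch(schematic, np.zeros(3))

    def test_stretch_rank_bounded_by_joint_count(self):
        """Stretch over e-dimensional displacement sets has rank
        <= min(n_joints, e): the length-change subspace property."""
        model = ms.random_model(9, 3, seed=11)
        mov = ms.perturbation_directions(24, 0.01, model.n_endpoint_dofs)
        S = ms.stretch_matrix(model, mov)
        sv = np.linalg.svd(S, compute_uv=False)
        assert sv[1] / sv[0] > 1e-6  # planar movements genuinely span 2 dims
        assert np.all(sv[2:] < 1e-10 * sv[0])


class TestEndpointToJointDelta:
    def test_identity_jacobian(self):
        m = ms.LimbModel(
            muscle_names=["a", "b"], joint_names=["x", "y"],
            moment_arms=[[0.02, 0.0], [0.0, 0.02]], jacobian=np.eye(2),
            max_forces=[1.0, 1.0], posture=[0.0, 0.0],
        )
        dx = np.array([0.3, -0.2])
        assert np.allclose(ms.endpoint_to_joint_delta(m, dx), dx)

    def test_forward_kinematics_oracle(self):
        """Returned joint delta reproduces the endpoint displacement through
        the exact (nonlinear) forward kinematics of a 3-link chain."""
        L = np.array([0.3, 0.25, 0.2])
        q0 = np.array([0.4, 0.7, -0.5])

        def fk(q):
            th = np.cumsum(q)
            return np.array([np.sum(L * np.cos(th)), np.sum(L * np.sin(th)), th[-1]])

        model = ms.LimbModel(
            muscle_names=[f"m{i}" for i in range(4)], joint_names=["j1", "j2", "j3"],
            moment_arms=np.full((4, 3), 0.01), jacobian=planar_chain_jacobian(L, q0),
            max_forces=np.ones(4), posture=q0,
        )
        rng = np.random.default_rng(3)
        for _ in range(5):
            dx = 1e-8 * rng.standard_normal(3)
            dq = ms.endpoint_to_joint_delta(model, dx)
            recovered = fk(q0 + dq) - fk(q0)
            assert np.linalg.norm(recovered - dx) < 1e-6 * np.linalg.norm(dx)

    def test_fully_extended_arm_is_singular(self):
        L = np.array([0.3, 0.25, 0.2])
        q = np.array([0.5, 0.0, 0.0])  # all links aligned
        with pytest.raises(SingularityError):
            ms.LimbModel(
                muscle_names=[f"m{i}" for i in range(4)], joint_names=["a", "b", "c"],
                moment_arms=np.full((4, 3), 0.01),
                jacobian=planar_chain_jacobian(L, q),
                max_forces=np.ones(4), posture=q,
            )

    def test_condition_bound_reported(self, schematic):
        near_singular = ms.LimbModel(
            muscle_names=list(schematic.muscle_names),
            joint_names=list(schematic.joint_names),
            moment_arms=schematic.moment_arms,
            jacobian=[[1.0, 0.0], [0.0, 1e-12]],
            max_forces=schematic.max_forces,
            posture=schematic.posture,
        )
        with pytest.raises(SingularityError) as err:
            ms.endpoint_to_joint_delta(near_singular, np.array([0.1, 0.1]))
        assert err.value.condition_number > 1e8

    def test_inverse_composes_to_identity(self, finger):
        rng = np.random.default_rng(0)
        dq = rng.standard_normal(3) * 0.01
        dx = finger.jacobian @ dq
        assert np.allclose(ms.endpoint_to_joint_delta(finger, dx), dq, atol=1e-10)


class TestActionMatrix:
    def test_closed_form_1x1(self):
        A = ms.action_matrix(tiny_model(0.02, 100.0, 0.3))
        assert A.matrix[0, 0] == pytest.approx(0.02 * 100.0 / 0.3)

    def test_linear_in_max_forces(self, finger):
        import dataclasses
        doubled = dataclasses.replace(finger, max_forces=2 * finger.max_forces)
        assert np.allclose(ms.action_matrix(doubled).matrix, 2 * ms.action_matrix(finger).matrix)

    def test_stepwise_composition_oracle(self, finger):
        """A @ a equals J^{-T} (R^T (F0 * a)) computed step by step."""
        A = ms.action_matrix(finger).matrix
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.uniform(0, 1, finger.n_muscles)
            tau = finger.moment_arms.T @ (finger.max_forces * a)
            w = np.linalg.solve(finger.jacobian.T, tau)
            assert np.allclose(A @ a, w, atol=1e-10)


class TestTensionProtocol:
    @pytest.mark.parametrize("n,expected", [(1, 2), (4, 16), (7, 128)])
    def test_pattern_counts(self, n, expected):
        proto = ms.generate_tension_protocol(n, 10.0, 0.0)
        assert proto.n_patterns == expected
        assert len({tuple(r) for r in proto.patterns}) == expected
        assert set(np.unique(proto.patterns)) <= {0.0, 10.0}

    def test_binary_counting_order(self):
        proto = ms.generate_tension_protocol(3, 10.0, 0.0)
        assert np.allclose(proto.patterns[0], [0, 0, 0])
        assert np.allclose(proto.patterns[1], [10, 0, 0])  # muscle 0 = LSB
        assert np.allclose(proto.patterns[5], [10, 0, 10])

    def test_cap_refusal(self):
        with pytest.raises(SizeCapError):
            ms.generate_tension_protocol(21, 10.0, 0.0)


class TestEstimateActionMatrix:
    def test_noiseless_recovery(self, finger):
        A_true = ms.action_matrix(finger).matrix
        proto = ms.generate_tension_protocol(7, 10.0, 0.0)
        # wrench per pattern: tensions are F0*a, so unit-tension matrix is A/F0
        A_per_tension = A_true / finger.max_forces[np.newaxis, :]
        wrenches = proto.patterns @ A_per_tension.T
        est = ms.estimate_action_matrix(proto, wrenches)
        assert np.max(np.abs(est.matrix - A_per_tension)) < 1e-9 * np.max(np.abs(A_per_tension))

    def test_baseline_wrench_absorbed_by_intercept(self, finger):
        """A constant rig baseline added to every observation must not bias
        the estimate (the regression fits and discards an intercept)."""
        A = ms.action_matrix(finger).matrix / finger.max_forces[np.newaxis, :]
        proto = ms.generate_tension_protocol(7, 10.0, 0.0)
        wrenches = proto.patterns @ A.T + np.array([1.7, -2.2, 0.4])[np.newaxis, :]
        est = ms.estimate_action_matrix(proto, wrenches)
        assert np.allclose(est.matrix, A, atol=1e-9)

    def test_noise_error_shrinks_with_replicates(self):
        """Estimation error scales ~1/sqrt(replicates): log-log slope -0.5
        within 20% over 4 replicate counts (Monte Carlo, fixed seed)."""
        rng = np.random.default_rng(42)
        n = 4
        A = rng.standard_normal((3, n))
        proto1 = ms.generate_tension_protocol(n, 10.0, 0.0)
        reps = [1, 2, 4, 8]
        errs = []
        for m in reps:
            tiled = ms.TensionProtocol(np.tile(proto1.patterns, (m, 1)), 10.0, 0.0)
            trial_errs = []
            for _ in range(60):
                w = tiled.patterns @ A.T + 0.5 * rng.standard_normal((tiled.n_patterns, 3))
                est = ms.estimate_action_matrix(tiled, w)
                trial_errs.append(np.linalg.norm(est.matrix - A))
            errs.append(np.mean(trial_errs))
        slope = np.polyfit(np.log(reps), np.log(errs), 1)[0]
        assert slope == pytest.approx(-0.5, rel=0.2)

    def test_rank_deficient_design_rejected(self):
        patterns = np.array([[10.0, 10.0], [0.0, 0.0], [10.0, 10.0], [0.0, 0.0]])
        proto = ms.TensionProtocol(patterns, 10.0, 0.0)
        with pytest.raises(RankError):
            ms.estimate_action_matrix(proto, np.zeros((4, 2)))

    def test_protocol_then_estimate_roundtrip_small(self):
        """Exact recovery for all n <= 8 on random action matrices."""
        rng = np.random.default_rng(1)
        for n in range(2, 9):
            A = rng.standard_normal((3, n))
            proto = ms.generate_tension_protocol(n, 10.0, 0.0)
            est = ms.estimate_action_matrix(proto, proto.patterns @ A.T)
            assert np.allclose(est.matrix, A, atol=1e-10)
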