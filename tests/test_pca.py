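import numpy as np
import pytest

from respmotion import (
    VentilatorSpec,
    back_project,
    covariance,
    explained_ratios,
    generate_trajectory,
    positions_matrix,
    principal_frame,
    project,
)
from respmotion.pca import DegenerateDataError, PrincipalFrame, ScalarSignal
from respmotion.simulate import PAPER_AXIS


def char_poly_eigenvalues(cov):
    """Independent oracle: roots of the characteristic polynomial det(C - λI)."""
    c = np.asarray(cov, dtype=float)
    # det expansion for 3x3: λ^3 - tr λ^2 + m2 λ - det
    tr = np.trace(c)
    m2 = (
        c[1, 1] * c[2, 2] - c[1, 2] * c[2, 1]
        + c[0, 0] * c[2, 2] - c[0, 2] * c[2, 0]
        + c[0, 0] * c[1, 1] - c[0, 1] * c[1, 0]
    )
    det = np.linalg.det(c)
    roots = np.roots([1.0, -tr, m2, -det])
    return np.sort(roots.real)[::-1]


class TestCovariance:
    def test_identical_points_give_zero_matrix(self):
        pos = np.tile([[1.0], [2.0], [3.0]], 5)
        _, cov = covariance(pos)
        np.testing.assert_array_equal(cov, np.zeros((3, 3)))

    def test_two_point_hand_example(self):
        pos = np.array([[0.0, 2.0], [0.0, 0.0], [0.0, 0.0]])
        mean, cov = covariance(pos)
        np.testing.assert_array_equal(mean, [1, 0, 0])
        np.testing.assert_allclose(cov, [[1, 0, 0], [0, 0, 0], [0, 0, 0]], atol=1e-15)

    def test_rank_one_line_gives_v_uuT(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        s = rng.normal(size=40)
        pos = u[:, None] * s[None, :]
        _, cov = covariance(pos)
        v = np.mean((s - s.mean()) ** 2)
        np.testing.assert_allclose(cov, v * np.outer(u, u), atol=1e-12)

    def test_population_normalisation_1_over_n(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(size=(3, 7))
        _, cov = covariance(pos)
        np.testing.assert_allclose(cov, np.cov(pos, bias=True), atol=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            covariance(np.zeros((3, 1)))


class TestPrincipalFrame:
    def test_diagonal_covariance(self):
        frame = principal_frame(np.zeros(3), np.diag([4.0, 1.0, 0.25]))
        np.testing.assert_allclose(frame.eigenvalues, [4, 1, 0.25])
        np.testing.assert_allclose(np.abs(frame.axes), np.eye(3), atol=1e-12)

    def test_isotropic_tie_case_succeeds(self):
        frame = principal_frame(np.zeros(3), np.eye(3))
        np.testing.assert_allclose(frame.eigenvalues, [1, 1, 1])
        np.testing.assert_allclose(frame.axes.T @ frame.axes, np.eye(3), atol=1e-12)

    def test_non_symmetric_rejected(self):
        cov = np.array([[1.0, 0.5, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="symmetric"):
            principal_frame(np.zeros(3), cov)

    def test_eigenvalues_match_char_poly_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(4, 50)
            pos = rng.normal(size=(3, n)) * rng.uniform(0.1, 3.0, size=(3, 1))
            mean, cov = covariance(pos)
            frame = principal_frame(mean, cov)
            np.testing.assert_allclose(
                frame.eigenvalues, char_poly_eigenvalues(cov), atol=1e-8
            )

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(3, 30)) * np.array([[3.0], [1.0], [0.3]])
        # rotation from QR of a random matrix
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        f1 = principal_frame(*covariance(pos))
        f2 = principal_frame(*covariance(q @ pos))
        np.testing.assert_allclose(f2.eigenvalues, f1.eigenvalues, atol=1e-9)
        for k in range(3):
            cos = abs((q @ f1.axes[:, k]) @ f2.axes[:, k])
            assert cos == pytest.approx(1.0, abs=1e-9)

    def test_axis_recovery_noiseless_and_noisy(self):
        clean = VentilatorSpec(noise_sd=0.0, quat_jitter=0.0)
        traj = generate_trajectory(clean, 30.0, 30.0, seed=0)
        frame = principal_frame(*covariance(positions_matrix(traj)))
        cos = min(abs(frame.primary_axis @ PAPER_AXIS / np.linalg.norm(PAPER_AXIS)), 1.0)
        assert np.arccos(cos) < 1e-6
        # 2% of the 2 mm amplitude = 0.04 mm noise
        angles = []
        for seed in range(20):
            spec = VentilatorSpec(noise_sd=0.04, quat_jitter=0.0)
            traj = generate_trajectory(spec, 30.0, 30.0, seed=seed)
            frame = principal_frame(*covariance(positions_matrix(traj)))
            cos = min(abs(frame.primary_axis @ spec.primary_axis), 1.0)
            angles.append(np.arccos(cos))
        assert max(angles) < np.deg2rad(2.0)


class TestProjection:
    def test_positions_at_mean_give_zero_signal(self):
        frame = principal_frame(np.zeros(3), np.diag([2.0, 1.0, 0.5]))
        pos = np.zeros((3, 4))
        sig = project(pos, frame, 0)
        np.testing.assert_array_equal(sig.values, np.zeros(4))

    def test_pure_x_motion_projects_to_centered_x(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        pos = np.vstack([x, np.zeros(4), np.zeros(4)])
        frame = principal_frame(*covariance(pos))
        sig = project(pos, frame, 0)
        np.testing.assert_allclose(sig.values, x - x.mean(), atol=1e-12)

    def test_mean_square_equals_eigenvalue(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(size=(3, 40)) * np.array([[2.0], [1.0], [0.2]])
        frame = principal_frame(*covariance(pos))
        for k in range(3):
            sig = project(pos, frame, k)
            assert np.mean(sig.values**2) == pytest.approx(
                frame.eigenvalues[k], rel=1e-10
            )

    def test_bad_component_rejected(self):
        frame = principal_frame(np.zeros(3), np.eye(3))
        with pytest.raises(ValueError):
            project(np.zeros((3, 4)), frame, 3)


class TestBackProjection:
    def test_inverse_on_pc1_line(self):
        u = PAPER_AXIS / np.linalg.norm(PAPER_AXIS)
        s = np.linspace(-1, 1, 20)
        pos = np.array([1.0, 2.0, 3.0])[:, None] + u[:, None] * s[None, :]
        frame = principal_frame(*covariance(pos))
        sig = project(pos, frame, 0)
        np.testing.assert_allclose(back_project(sig, frame), pos, atol=1e-9)

    def test_zero_signal_maps_to_mean(self):
        frame = principal_frame(np.array([1.0, 2, 3]), np.diag([2.0, 1, 0.5]))
        out = back_project(ScalarSignal(values=np.zeros(5)), frame)
        np.testing.assert_array_equal(out, np.tile([[1.0], [2.0], [3.0]], 5))

    def test_scalar_displacement_splits_into_axis_components(self):
        u = PAPER_AXIS / np.linalg.norm(PAPER_AXIS)
        frame = PrincipalFrame(
            mean=np.zeros(3),
            axes=np.column_stack([u, *_complete_basis(u)]),
            eigenvalues=np.array([1.0, 0.5, 0.1]),
        )
        out = back_project(ScalarSignal(values=np.array([2.0])), frame)
        np.testing.assert_allclose(out[:, 0], 2.0 * u, atol=1e-12)


def _complete_basis(u):
    a = np.array([0.0, 0.0, 1.0])
    v1 = np.cross(u, a)
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(u, v1)
    return v1, v2


class TestExplainedRatios:
    def test_clinical_eigenvalue_row(self):
        frame = PrincipalFrame(
            mean=np.zeros(3),
            axes=np.eye(3),
            eigenvalues=np.array([0.295, 0.031, 0.002]),
        )
        np.testing.assert_allclose(
            explained_ratios(frame), [0.899, 0.0945, 0.0061], atol=5e-4
        )

    def test_rank_one(self):
        frame = PrincipalFrame(
            mean=np.zeros(3), axes=np.eye(3), eigenvalues=np.array([1.0, 0.0, 0.0])
        )
        np.testing.assert_array_equal(explained_ratios(frame), [1, 0, 0])

    def test_sum_to_one(self):
        frame = PrincipalFrame(
            mean=np.zeros(3), axes=np.eye(3), eigenvalues=np.array([0.7, 0.2, 0.1])
        )
        assert explained_ratios(frame).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        frame = PrincipalFrame(
            mean=np.zeros(3), axes=np.eye(3), eigenvalues=np.zeros(3)
        )
        with pytest.raises(DegenerateDataError):
            explained_ratios(frame)
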