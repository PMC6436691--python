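"""GLM, GLS, interpolation and classification estimators."""

import numpy as np
import pytest

from lamglm.design import LayerDesign
from lamglm.estimate import (
    build_covariance,
    classify_rows,
    estimate_classification,
    estimate_interpolation,
    extract_timecourses,
    fit_gls,
    fit_ols,
)
from lamglm.grid import Grid


def design_from(X):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    return LayerDesign(
        X=X,
        voxel_index=np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], 1),
        voxel_xyz=np.column_stack([np.arange(n, dtype=float), np.zeros((n, 2))]),
        grid=Grid((n, 1, 1), 1.0, (0, 0, 0)),
        mode="oriented",
    )


class TestCovariance:
    def test_zero_length_gives_identity(self, rng):
        xyz = rng.uniform(size=(7, 3))
        cov = build_covariance(xyz, 0.0)
        assert np.array_equal(cov.Omega, np.eye(7))

    def test_half_maximum_at_half_fwhm(self):
        xyz = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        cov = build_covariance(xyz, 2.0)  # distance 1 mm = Lc/2
        assert cov.Omega[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_unit_diagonal_and_symmetry(self, rng):
        xyz = rng.uniform(0, 10, size=(12, 3))
        cov = build_covariance(xyz, 3.0)
        assert np.allclose(np.diag(cov.Omega), 1.0)
        assert np.allclose(cov.Omega, cov.Omega.T)
        assert np.all(cov.Omega > 0) and np.all(cov.Omega <= 1)

    def test_rejects_non_finite_coordinates(self):
        with pytest.raises(ValueError, match="finite"):
            build_covariance(np.array([[0.0, 0, np.nan]]), 1.0)


class TestOLS:
    def test_hand_worked_normal_equations(self):
        d = design_from([[1, 0], [0, 1], [1, 1]])
        est = fit_ols(d, np.array([2.0, 3.0, 5.0]))
        assert np.allclose(est.B_hat[:, 0], [2.0, 3.0], atol=1e-12)
        assert np.allclose(est.residuals, 0.0, atol=1e-12)

    def test_exact_recovery_of_consistent_system(self, rng):
        X = rng.uniform(size=(40, 5))
        s = rng.normal(size=(5, 3))
        est = fit_ols(design_from(X), X @ s)
        assert np.allclose(est.B_hat, s, atol=1e-10)

    def test_monte_carlo_unbiasedness(self, rng):
        X = rng.uniform(size=(150, 4))
        s = np.array([1.0, -2.0, 0.5, 3.0])
        reps = 400
        noise = rng.normal(scale=0.5, size=(150, reps))
        Y = (X @ s)[:, None] + noise
        B = fit_ols(design_from(X), Y).B_hat
        se = B.std(axis=1) / np.sqrt(reps)
        assert np.all(np.abs(B.mean(axis=1) - s) < 4 * se)

    def test_underdetermined_rejected(self):
        d = design_from(np.eye(3))
        with pytest.raises(ValueError, match="n > k"):
            fit_ols(d, np.zeros(3))

    def test_rank_deficiency_rejected(self):
        d = design_from(np.column_stack([np.ones(6), np.ones(6)]))
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(d, np.zeros(6))


class TestGLS:
    def test_identity_covariance_equals_ols(self, rng):
        X = rng.uniform(size=(25, 4))
        Y = rng.normal(size=(25, 2))
        d = design_from(X)
        cov = build_covariance(d.voxel_xyz, 0.0)
        assert np.allclose(
            fit_gls(d, Y, cov).B_hat, fit_ols(d, Y).B_hat, atol=1e-10
        )

    def test_diagonal_weights_match_weighted_ols_oracle(self, rng):
        from dataclasses import replace

        X = rng.uniform(size=(20, 3))
        Y = rng.normal(size=(20, 1))
        d = design_from(X)
        w = rng.uniform(0.5, 2.0, size=20)
        cov = replace(build_covariance(d.voxel_xyz, 0.0), Omega=np.diag(w))
        got = fit_gls(d, Y, cov).B_hat
        # oracle: rescale rows by 1/sqrt(w) and run plain least squares
        sw = 1.0 / np.sqrt(w)
        expect, *_ = np.linalg.lstsq(X * sw[:, None], Y * sw[:, None], rcond=None)
        assert np.allclose(got, expect, atol=1e-10)

    def test_exact_recovery_under_any_valid_covariance(self, rng):
        X = rng.uniform(size=(30, 4))
        s = rng.normal(size=(4, 1))
        d = design_from(X)
        cov = build_covariance(d.voxel_xyz, 2.5)
        est = fit_gls(d, X @ s, cov)
        assert np.allclose(est.B_hat, s, atol=1e-8)


class TestInterpolation:
    def test_constant_data_gives_constant_estimates(self, rng):
        X = rng.uniform(0.1, 1.0, size=(15, 3))
        est = estimate_interpolation(design_from(X), np.full(15, 4.2))
        assert np.allclose(est.B_hat, 4.2, atol=1e-12)

    def test_orthogonal_binary_design_equals_classification(self, rng):
        X = np.repeat(np.eye(3), 5, axis=0)
        Y = rng.normal(size=15)
        d = design_from(X)
        assert np.allclose(
            estimate_interpolation(d, Y).B_hat,
            estimate_classification(d, Y).B_hat,
            atol=1e-12,
        )

    def test_two_voxel_leakage_versus_glm_unmixing(self):
        # hand-worked 2x2 mixture: interpolation leaks, the GLM inverts
        d = design_from([[0.8, 0.2], [0.2, 0.8]])
        Y = np.array([1.0, 0.0])
        interp = estimate_interpolation(d, Y).B_hat[:, 0]
        assert np.allclose(interp, [0.8, 0.2], atol=1e-12)
        # X is square and invertible: OLS through lstsq = X^-1 Y
        ols = np.linalg.solve(np.asarray(d.X), Y)
        assert np.allclose(ols, [4 / 3, -1 / 3], atol=1e-12)

    def test_estimates_stay_within_data_range(self, rng):
        X = rng.uniform(0.01, 1.0, size=(30, 4))
        Y = rng.normal(size=30)
        est = estimate_interpolation(design_from(X), Y)
        assert est.B_hat.min() >= Y.min() - 1e-12
        assert est.B_hat.max() <= Y.max() + 1e-12

    def test_count_normalisation_variant(self):
        d = design_from([[1.0, 0.0], [0.0, 1.0]])
        est = estimate_interpolation(d, np.array([2.0, 4.0]), normalise="count")
        assert np.allclose(est.B_hat[:, 0], [1.0, 2.0])

    def test_zero_column_raises_with_layer_name(self):
        d = design_from([[1.0, 0.0], [0.5, 0.0], [0.2, 0.0]])
        with pytest.raises(ValueError, match="layer2"):
            estimate_interpolation(d, np.zeros(3))


class TestClassification:
    def test_pure_voxels_give_exact_layer_means(self):
        X = np.repeat(np.eye(2), 3, axis=0)
        Y = np.array([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        est = estimate_classification(design_from(X), Y)
        assert np.allclose(est.B_hat[:, 0], [2.0, 20.0])

    def test_ties_assigned_to_deeper_layer(self):
        rows = classify_rows(np.array([[0.5, 0.5], [0.2, 0.8], [0.0, 0.0]]))
        assert np.array_equal(rows, [[1, 0], [0, 1], [0, 0]])

    def test_regression_on_binary_design_equals_group_means(self, rng):
        X = rng.uniform(size=(24, 3))
        Y = rng.normal(size=24)
        d = design_from(X)
        est = estimate_classification(d, Y)
        binary = classify_rows(np.asarray(d.X))
        lstsq, *_ = np.linalg.lstsq(binary, Y[:, None], rcond=None)
        assert np.allclose(est.B_hat, lstsq, atol=1e-12)

    def test_empty_layer_raises(self):
        X = np.array([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3]])
        with pytest.raises(ValueError, match="layer2"):
            estimate_classification(design_from(X), np.zeros(3))


class TestTimecourses:
    def test_single_volume_matches_per_volume_call(self, rng):
        X = rng.uniform(size=(20, 3))
        Y = rng.normal(size=(20, 1))
        d = design_from(X)
        assert np.allclose(
            extract_timecourses(d, Y, method="glm").B_hat,
            fit_ols(d, Y[:, 0]).B_hat,
            atol=1e-12,
        )

    def test_permuting_volumes_permutes_output(self, rng):
        X = rng.uniform(size=(20, 3))
        Y = rng.normal(size=(20, 5))
        d = design_from(X)
        perm = [3, 0, 4, 1, 2]
        assert np.allclose(
            extract_timecourses(d, Y[:, perm], "interpolation").B_hat,
            extract_timecourses(d, Y, "interpolation").B_hat[:, perm],
        )

    def test_noiseless_sinusoids_recovered_per_layer(self, rng):
        X = rng.uniform(size=(60, 4))
        t = np.linspace(0, 2 * np.pi, 50)
        S = np.stack([np.sin((j + 1) * t) for j in range(4)])
        est = extract_timecourses(design_from(X), X @ S, method="glm")
        assert np.allclose(est.B_hat, S, atol=1e-9)

    def test_gls_route_used_when_covariance_given(self, rng):
        X = rng.uniform(size=(15, 3))
        Y = rng.normal(size=(15, 2))
        d = design_from(X)
        cov = build_covariance(d.voxel_xyz, 2.0)
        est = extract_timecourses(d, Y, method="glm", cov=cov)
        assert est.method == "glm-gls"
        assert np.allclose(est.B_hat, fit_gls(d, Y, cov).B_hat)
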