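import numpy as np
import pytest
import scipy.linalg

import densitycloud as dc
from densitycloud.decompose import SEQUENCES, _build_samples


class TestMeanShift:
    def test_identity_when_target_is_own_centroid(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        np.testing.assert_allclose(dc.mean_shift(X, X.mean(0)), X)

    def test_translation(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        np.testing.assert_allclose(dc.mean_shift(X, [5.0, 5.0]),
                                   [[4.0, 4.0], [6.0, 6.0]])

    def test_isometry(self):
        from scipy.spatial.distance import pdist
        X = np.random.default_rng(1).normal(size=(30, 4))
        shifted = dc.mean_shift(X, np.array([10.0, -3.0, 0.0, 7.0]))
        np.testing.assert_allclose(pdist(shifted), pdist(X), rtol=1e-10)
        np.testing.assert_allclose(shifted.mean(0), [10, -3, 0, 7], atol=1e-10)


class TestScaleTo:
    def test_identity_when_target_is_own_sd(self):
        X = np.random.default_rng(2).normal(size=(25, 3))
        np.testing.assert_allclose(dc.scale_to(X, X.std(0, ddof=1)), X)

    def test_doubling(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        out = dc.scale_to(X, 2 * X.std(0, ddof=1))
        np.testing.assert_allclose(out[:, 0], [-2, 2, 0, 0])

    def test_preserves_correlation_and_centroid(self):
        X = np.random.default_rng(3).normal(size=(40, 3)) @ \
            np.array([[1, 0.5, 0], [0, 1, 0.3], [0, 0, 1.0]])
        out = dc.scale_to(X, np.array([2.0, 0.5, 1.5]))
        np.testing.assert_allclose(out.std(0, ddof=1), [2, 0.5, 1.5],
                                   atol=1e-10)
        np.testing.assert_allclose(out.mean(0), X.mean(0), atol=1e-10)
        np.testing.assert_allclose(np.corrcoef(out, rowvar=False),
                                   np.corrcoef(X, rowvar=False), atol=1e-10)

    def test_zero_variance_fatal(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        with pytest.raises(ValueError, match="zero variance"):
            dc.scale_to(X, np.array([1.0, 1.0]))


class TestZcaCor:
    def test_identity_when_already_white(self):
        """Uncorrelated unit-variance data give W = I (up to sampling exactness)."""
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        X *= np.sqrt(3) / 2  # unit sample variance with ddof=1
        op = dc.zca_cor_op(X)
        np.testing.assert_allclose(op.W, np.eye(2), atol=1e-10)

    def test_inverse_correlation_sqrt_against_scipy(self):
        """R^(-1/2) for r=0.6 matches an independent matrix square root."""
        rng = np.random.default_rng(4)
        L = np.linalg.cholesky(np.array([[1.0, 0.6], [0.6, 1.0]]))
        X = rng.standard_normal((2000, 2)) @ L.T
        op = dc.zca_cor_op(X)
        R = np.corrcoef(X, rowvar=False)
        expected = np.linalg.inv(scipy.linalg.sqrtm(R).real)
        np.testing.assert_allclose(op.W @ np.diag(X.std(0, ddof=1)),
                                   expected, atol=1e-8)
        # frozen value from the r = 0.6 population matrix
        pop = np.linalg.inv(scipy.linalg.sqrtm(
            np.array([[1.0, 0.6], [0.6, 1.0]])).real)
        np.testing.assert_allclose(pop, [[1.1859, -0.3953],
                                         [-0.3953, 1.1859]], atol=2e-4)

    def test_whitened_covariance_is_identity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 4)) @ rng.normal(size=(4, 4))
        op = dc.zca_cor_op(X)
        Z = (X - op.centroid) @ op.W.T
        np.testing.assert_allclose(np.cov(Z, rowvar=False), np.eye(4),
                                   atol=1e-8)

    def test_whiten_color_roundtrip(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3)) @ np.diag([1.0, 3.0, 0.5])
        op = dc.zca_cor_op(X)
        np.testing.assert_allclose(op.W @ op.W_inv, np.eye(3), atol=1e-8)
        Z = (X - op.centroid) @ op.W.T
        back = Z @ op.W_inv.T + op.centroid
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_zca_cor_keeps_variables_aligned(self):
        """Each whitened variable correlates positively with its original."""
        rng = np.random.default_rng(7)
        for trial in range(5):
            d = int(rng.integers(2, 6))
            M = rng.normal(size=(d, d))
            X = rng.normal(size=(300, d)) @ (M + d * np.eye(d))
            op = dc.zca_cor_op(X)
            Z = (X - op.centroid) @ op.W.T
            diag_corr = np.array([np.corrcoef(X[:, j], Z[:, j])[0, 1]
                                  for j in range(d)])
            assert (diag_corr > 0).all()

    def test_singular_correlation_fatal(self):
        X = np.random.default_rng(8).normal(size=(50, 1)) @ np.ones((1, 2))
        X += 1e-9 * np.random.default_rng(9).normal(size=(50, 2))
        with pytest.raises(Exception, match="singular"):
            dc.zca_cor_op(X)


class TestRecolor:
    def test_roundtrip_to_own_target(self):
        X = np.random.default_rng(10).normal(size=(100, 3)) @ \
            np.array([[1, 0.4, 0], [0, 1, -0.3], [0, 0, 1.0]])
        out = dc.recolor(X, dc.zca_cor_op(X))
        np.testing.assert_allclose(out, X, atol=1e-8)

    def test_correlation_sign_flip(self):
        rng = np.random.default_rng(11)
        L_neg = np.linalg.cholesky([[1, -0.5], [-0.5, 1]])
        L_pos = np.linalg.cholesky([[1, 0.5], [0.5, 1]])
        X_B = rng.standard_normal((1000, 2)) @ L_neg.T
        X_A = rng.standard_normal((1000, 2)) @ L_pos.T
        out = dc.recolor(X_B, dc.zca_cor_op(X_A))
        r_out = np.corrcoef(out, rowvar=False)[0, 1]
        r_target = np.corrcoef(X_A, rowvar=False)[0, 1]
        assert r_out == pytest.approx(r_target, abs=1e-6)

    def test_covariance_matches_target(self):
        rng = np.random.default_rng(12)
        X_B = rng.normal(size=(400, 3)) * np.array([0.5, 2.0, 1.0])
        X_A = rng.normal(size=(400, 3)) @ rng.normal(size=(3, 3))
        target = dc.zca_cor_op(X_A)
        out = dc.recolor(X_B, target)
        np.testing.assert_allclose(np.cov(out, rowvar=False),
                                   np.cov(X_A, rowvar=False), rtol=1e-6,
                                   atol=1e-8)
        np.testing.assert_allclose(out.mean(0), X_A.mean(0), atol=1e-8)


class TestDecompose:
    def test_identical_groups_unit_ratios(self, identical_ds):
        probes = dc.generate_probes(identical_ds, n_probes=150, seed=1)
        res = dc.decompose(identical_ds, "LSCS", probes=probes, seed=2, k=6)
        for comp in res.components:
            np.testing.assert_allclose(comp.ratio, 1.0, rtol=1e-6)

    @pytest.mark.parametrize("sequence", ["LS", "LSS", "LSCS"])
    def test_telescoping_product(self, gauss_ds, sequence):
        """Component ratios multiply exactly to the overall ratio A/B."""
        probes = dc.generate_probes(gauss_ds, n_probes=300, seed=3)
        res = dc.decompose(gauss_ds, sequence, probes=probes, seed=4)
        overall = dc.decompose(gauss_ds, "overall", probes=probes, seed=4)
        product = np.prod([c.ratio for c in res.components], axis=0)
        np.testing.assert_allclose(product, overall.components[0].ratio,
                                   rtol=1e-12)

    @pytest.mark.parametrize("sequence,n_components", [
        ("overall", 1), ("LS", 2), ("LSS", 3), ("LSCS", 4),
        ("LSS+", 5), ("LSCS+", 7),
    ])
    def test_component_counts(self, gauss_ds, sequence, n_components):
        probes = dc.generate_probes(gauss_ds, n_probes=100, seed=5)
        res = dc.decompose(gauss_ds, sequence, probes=probes, seed=6)
        assert len(res.components) == n_components

    def test_lscs_plus_component_order(self, gauss_ds):
        probes = dc.generate_probes(gauss_ds, n_probes=100, seed=5)
        res = dc.decompose(gauss_ds, "LSCS+", probes=probes, seed=6)
        assert [c.component for c in res.components] == [
            "overall", "location", "shape", "scale", "residual_shape",
            "covariation", "residual_shape"]

    def test_transform_chain_contracts(self, gauss_ds):
        A, B = dc.equalize_groups(gauss_ds, seed=7)
        s = _build_samples(A, B, {"B_shift", "B_shift_scaled",
                                  "B_shift_scaled_colored"})
        np.testing.assert_allclose(s["B_shift"].mean(0), A.mean(0),
                                   atol=1e-10)
        np.testing.assert_allclose(s["B_shift_scaled"].std(0, ddof=1),
                                   A.std(0, ddof=1), atol=1e-10)
        np.testing.assert_allclose(
            np.corrcoef(s["B_shift_scaled_colored"], rowvar=False),
            np.corrcoef(A, rowvar=False), atol=1e-6)

    def test_unknown_sequence_fatal(self, gauss_ds):
        with pytest.raises(ValueError, match="unknown sequence"):
            dc.decompose(gauss_ds, "XYZ")

    def test_location_dominates_under_pure_shift(self):
        spec = dc.ScenarioSpec(n_per_group=2000, d=3,
                               centroid_shift=[1.0, 0, 0], seed=31)
        ds = dc.gaussian_groups(spec)
        probes = dc.generate_probes(ds, n_probes=1000, seed=32)
        res = dc.decompose(ds, "LS", probes=probes, seed=33)
        by_name = {c.component: np.mean(np.abs(c.log_ratio))
                   for c in res.components}
        assert by_name["location"] > by_name["shape"]

    def test_covariation_dominates_under_pure_correlation_difference(self):
        rA = np.eye(3); rA[0, 1] = rA[1, 0] = 0.6
        rB = np.eye(3); rB[0, 1] = rB[1, 0] = -0.6
        spec = dc.ScenarioSpec(n_per_group=2000, d=3, corr_A=rA, corr_B=rB,
                               seed=34)
        ds = dc.gaussian_groups(spec)
        probes = dc.generate_probes(ds, n_probes=1000, seed=35)
        res = dc.decompose(ds, "LSCS", probes=probes, seed=36)
        by_name = {c.component: np.mean(np.abs(c.log_ratio))
                   for c in res.components}
        assert by_name["covariation"] > by_name["location"]
        assert by_name["covariation"] > by_name["scale"]
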