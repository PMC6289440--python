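"""Treelet transform: rotations, hierarchy, factors, scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treeletcox import (
    TreeletTransform,
    cut_basis,
    fit_treelet,
    jacobi_angle,
    score_subjects,
    standardize,
)
from treeletcox.treelet import StandardizationParams


def rotated(cov, i, j, theta):
    g = np.eye(len(cov))
    g[i, i] = g[j, j] = np.cos(theta)
    g[j, i] = -np.sin(theta)
    g[i, j] = np.sin(theta)
    return g @ cov @ g.T


class TestJacobiAngle:
    def test_equal_variance_pair_rotates_quarter_turn(self):
        r = 0.7
        cov = np.array([[1.0, r], [r, 1.0]])
        theta = jacobi_angle(1.0, 1.0, r)
        assert theta == pytest.approx(np.pi / 4)
        out = rotated(cov, 0, 1, theta)
        assert out[0, 0] == pytest.approx(1 + r)
        assert out[1, 1] == pytest.approx(1 - r)

    def test_zero_covariance_means_identity_rotation(self):
        assert jacobi_angle(3.0, 1.0, 0.0) == 0.0

    def test_general_angle_against_eigendecomposition(self):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        theta = jacobi_angle(2.0, 1.0, 0.5)
        assert theta == pytest.approx(0.5 * np.arctan2(1.0, 1.0))
        out = rotated(cov, 0, 1, theta)
        assert abs(out[0, 1]) < 1e-15
        assert np.trace(out) == pytest.approx(np.trace(cov))
        # post-rotation variances are the 2x2 eigenvalues
        assert sorted(np.diag(out)) == pytest.approx(sorted(np.linalg.eigvalsh(cov)))

    @given(
        c_ii=st.floats(0.1, 10),
        c_jj=st.floats(0.1, 10),
        rho=st.floats(-0.99, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_angle_zeroes_covariance_within_quarter_branch(self, c_ii, c_jj, rho):
        c_ij = rho * np.sqrt(c_ii * c_jj)
        theta = jacobi_angle(c_ii, c_jj, c_ij)
        assert -np.pi / 4 <= theta <= np.pi / 4
        cov = np.array([[c_ii, c_ij], [c_ij, c_jj]])
        out = rotated(cov, 0, 1, theta)
        assert abs(out[0, 1]) < 1e-12 * max(1.0, c_ii, c_jj)


class TestHierarchy:
    def test_two_channels_reduce_to_principal_components(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((500, 2)) @ np.linalg.cholesky(
            np.array([[1.0, 0.6], [0.6, 1.0]])
        ).T
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        model = fit_treelet(z)
        corr = np.corrcoef(z, rowvar=False)
        _, vecs = np.linalg.eigh(corr)
        basis = model.basis(1)
        for k in range(2):
            overlaps = np.abs(vecs.T @ basis[:, k])
            assert overlaps.max() == pytest.approx(1.0, abs=1e-10)

    def test_independent_channels_are_isotropic(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((4000, 8))
        model = fit_treelet(z)
        for level in range(8):
            v = model.variances(level)
            assert np.allclose(v, 1.0, atol=0.15)
        fs = cut_basis(model, 7, 8)
        assert np.allclose(fs.explained_variance_pct, 100 / 8, atol=2.0)

    def test_two_block_structure_recovered(self):
        # 6 channels, two equicorrelated blocks (rho=0.6 within, 0 between)
        rng = np.random.default_rng(2)
        p, rho, n = 6, 0.6, 5000
        corr = np.eye(p)
        for blk in (range(0, 3), range(3, 6)):
            for i in blk:
                for j in blk:
                    if i != j:
                        corr[i, j] = rho
        z = rng.standard_normal((n, p)) @ np.linalg.cholesky(corr).T
        model = fit_treelet(z)
        blocks = [{0, 1, 2}, {3, 4, 5}]
        for merge in model.merges[:2]:
            assert any({merge.i, merge.j} <= b for b in blocks)
        fs = cut_basis(model, 4, 2)
        supports = [set(s) for s in fs.supports(tol=1e-10)]
        assert sorted(map(sorted, supports)) == [[0, 1, 2], [3, 4, 5]]
        # equicorrelated block of size k has top eigenvalue 1 + (k-1) rho
        expected = 100 * (1 + 2 * rho) / p
        assert np.allclose(fs.explained_variance_pct, expected, atol=1.5)

    def test_basis_exactness_invariants(self, block_panel):
        tt = TreeletTransform().fit(block_panel)
        model = tt.model_
        z = standardize(block_panel, tt.params_)
        corr = np.corrcoef(z, rowvar=False)
        p = model.p
        for level in range(p):
            basis = model.basis(level)
            assert np.abs(basis.T @ basis - np.eye(p)).max() < 1e-10
            rot = basis.T @ corr @ basis
            assert np.allclose(np.diag(rot), model.variances(level), atol=1e-10)
            assert abs(model.variances(level).sum() - p) < 1e-8
        for merge in model.merges:
            rot = model.basis(merge.level).T @ corr @ model.basis(merge.level)
            assert abs(rot[merge.i, merge.j]) < 1e-12

    def test_determinism_bit_identical(self, block_panel):
        a = TreeletTransform(cut_level=23, n_factors=7).fit(block_panel)
        b = TreeletTransform(cut_level=23, n_factors=7).fit(block_panel)
        assert a.model_.merges == b.model_.merges
        assert np.array_equal(a.loadings_, b.loadings_)

    def test_zero_variance_channel_named_in_error(self):
        z = np.random.default_rng(3).standard_normal((100, 3))
        z[:, 1] = 2.5
        with pytest.raises(ValueError, match="x1"):
            fit_treelet(z)

    @given(st.integers(0, 10_000))
    @settings(max_examples=10, deadline=None)
    def test_small_panel_invariants(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 9))
        z = rng.standard_normal((60, p))
        model = fit_treelet(z)
        for level in range(p):
            basis = model.basis(level)
            assert np.abs(basis.T @ basis - np.eye(p)).max() < 1e-10
            assert abs(model.variances(level).sum() - p) < 1e-8


class TestFactors:
    def test_complete_basis_conserves_all_variance(self, block_panel):
        tt = TreeletTransform().fit(block_panel)
        for level in (1, 10, 23, 31):
            fs = cut_basis(tt.model_, level, 32)
            assert fs.cumulative_pct == pytest.approx(100.0, abs=1e-8)

    def test_study_shape_cut(self, block_panel):
        """Cut 23 with 7 factors: sparse patterns of at most 8 channels."""
        tt = TreeletTransform(cut_level=23, n_factors=7).fit(block_panel)
        assert tt.factors_.m == 7
        sizes = [len(s) for s in tt.factors_.supports()]
        assert max(sizes) <= 8
        assert all(s >= 2 for s in sizes)

    def test_sign_convention_positive_leading_entry(self, block_panel):
        tt = TreeletTransform(cut_level=23, n_factors=7).fit(block_panel)
        for k in range(7):
            col = tt.loadings_[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_out_of_range_arguments_rejected(self, block_panel):
        tt = TreeletTransform().fit(block_panel)
        with pytest.raises(ValueError):
            cut_basis(tt.model_, 0, 5)
        with pytest.raises(ValueError):
            cut_basis(tt.model_, 32, 5)
        with pytest.raises(ValueError):
            cut_basis(tt.model_, 23, 0)


class TestStandardizeAndScore:
    def toy_params(self):
        return StandardizationParams(
            channel_ids=("a", "b"), means=np.array([10.0, 20.0]), sds=np.array([2.0, 4.0])
        )

    def test_self_standardization_gives_unit_moments(self, block_panel):
        params = StandardizationParams.fit(block_panel)
        z = standardize(block_panel, params)
        assert np.abs(z.mean(0)).max() < 1e-12
        assert np.abs(z.std(0, ddof=1) - 1).max() < 1e-12

    def test_fixed_params_are_location_equivariant(self):
        params = self.toy_params()
        panel = pd.DataFrame({"a": [10.0, 12.0, 8.0], "b": [20.0, 24.0, 16.0]})
        z = standardize(panel, params)
        z_shift = standardize(panel + 2.0, params)
        assert np.allclose(z_shift - z, [[1.0, 0.5]] * 3)

    def test_external_subjects_scored_on_reference_scale(self):
        # external cases sit one reference SD above the mean on every channel
        params = self.toy_params()
        external = pd.DataFrame({"a": [12.0], "b": [24.0]})
        z = standardize(external, params)
        assert np.allclose(z, 1.0)

    def test_missing_channel_error_lists_channels(self):
        params = self.toy_params()
        with pytest.raises(ValueError, match="'b'"):
            standardize(pd.DataFrame({"a": [1.0]}), params)

    def test_scores_by_hand(self):
        from treeletcox.treelet import FactorSet

        params = self.toy_params()
        panel = pd.DataFrame({"a": [10.0, 12.0, 14.0], "b": [20.0, 16.0, 28.0]})
        z = np.array([[0.0, 0.0], [1.0, -1.0], [2.0, 2.0]])
        w = np.array([[1 / np.sqrt(2)], [1 / np.sqrt(2)]])
        factors = FactorSet(
            channel_ids=("a", "b"), cut_level=1, loadings=w,
            explained_variance_pct=np.array([50.0]),
        )
        scores = score_subjects(panel, params, factors)
        assert np.allclose(scores.to_numpy().ravel(), (z @ w).ravel())
        # subject at the reference mean scores zero on every factor
        assert scores.iloc[0, 0] == pytest.approx(0.0)
        # indicator loading returns the raw z-value
        ind = FactorSet(
            channel_ids=("a", "b"), cut_level=1,
            loadings=np.array([[1.0], [0.0]]),
            explained_variance_pct=np.array([50.0]),
        )
        s2 = score_subjects(panel, params, ind)
        assert np.allclose(s2.to_numpy().ravel(), z[:, 0])

    def test_transform_matches_score_subjects(self, block_panel):
        tt = TreeletTransform(cut_level=23, n_factors=7).fit(block_panel)
        direct = score_subjects(block_panel, tt.params_, tt.factors_)
        assert np.allclose(tt.transform(block_panel), direct.to_numpy())
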