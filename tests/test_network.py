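"""Covariance-network construction: Pearson matrices and FDR binarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import small_atlas
from oracles import bh_oracle
from scnkit.io import CovarianceMatrix, MorphometryError
from scnkit.network import (
    correlation_matrix,
    fdr_network_from_values,
    threshold_fdr,
)


class TestCorrelationMatrix:
    def test_duplicated_roi_has_unit_correlation(self):
        atlas = small_atlas(3)
        rng = np.random.default_rng(0)
        x = 2.5 + 0.2 * rng.standard_normal((10, 3))
        x[:, 1] = x[:, 0]
        cov = correlation_matrix(x, atlas)
        assert cov.r[0, 1] == pytest.approx(1.0)
        assert cov.p[0, 1] == pytest.approx(0.0)

    def test_known_pearson_value_and_t_transform(self):
        # x=(1..5), y=(2,1,4,3,6): r = 10/sqrt(10*14.8) = 0.821995,
        # t = r*sqrt(3/(1-r^2)) = 2.5 exactly, p two-sided on 3 df
        atlas = small_atlas(2)
        x = np.column_stack([[1, 2, 3, 4, 5], [2, 1, 4, 3, 6]]).astype(float)
        cov = correlation_matrix(x, atlas)
        r_expect = 10 / np.sqrt(10 * 14.8)
        assert cov.r[0, 1] == pytest.approx(r_expect, abs=1e-12)
        t_expect = r_expect * np.sqrt(3 / (1 - r_expect**2))
        assert t_expect == pytest.approx(2.5, abs=1e-12)
        assert cov.p[0, 1] == pytest.approx(2 * stats.t.sf(2.5, 3), abs=1e-12)
        # cross-check against an independent statistics routine
        r_sp, p_sp = stats.pearsonr(x[:, 0], x[:, 1])
        assert cov.r[0, 1] == pytest.approx(r_sp, abs=1e-12)
        assert cov.p[0, 1] == pytest.approx(p_sp, abs=1e-10)

    def test_independent_rois_have_small_correlations(self):
        atlas = small_atlas(8)
        rng = np.random.default_rng(7)
        x = 2.5 + 0.2 * rng.standard_normal((2000, 8))
        cov = correlation_matrix(x, atlas)
        off = cov.r[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 3.0 / np.sqrt(2000)

    def test_zero_variance_roi_is_hard_error_naming_roi(self):
        atlas = small_atlas(3)
        x = np.full((6, 3), 2.5)
        x[:, 0] = np.linspace(2, 3, 6)
        x[:, 2] = np.linspace(3, 2, 6)
        with pytest.raises(MorphometryError, match="roi01"):
            correlation_matrix(x, atlas)

    def test_fewer_than_four_subjects_rejected(self):
        atlas = small_atlas(2)
        with pytest.raises(MorphometryError, match="4 subjects"):
            correlation_matrix(np.random.default_rng(0).random((3, 2)), atlas)


def cov_from_p(p_upper, atlas, r_sign=1.0, n=30):
    """Build a CovarianceMatrix with prescribed upper-triangle p-values."""
    k = atlas.n
    p = np.zeros((k, k))
    r = np.eye(k)
    iu = np.triu_indices(k, 1)
    p[iu] = p_upper
    p = p + p.T
    # invert the t transform so r and p are mutually consistent
    t = stats.t.isf(np.asarray(p_upper) / 2, df=n - 2)
    rv = r_sign * t / np.sqrt(t**2 + n - 2)
    r[iu] = rv
    r.T[iu] = rv
    return CovarianceMatrix(r=r, p=p, n=n, atlas=atlas)


class TestThresholdFdr:
    def test_all_p_one_gives_empty_network(self):
        atlas = small_atlas(4)
        cov = cov_from_p([1.0] * 6, atlas)
        assert threshold_fdr(cov, 0.05).n_edges == 0

    def test_all_tiny_p_gives_complete_graph(self):
        atlas = small_atlas(4)
        cov = cov_from_p([1e-8] * 6, atlas)
        assert threshold_fdr(cov, 0.05).n_edges == 6

    def test_textbook_step_up_example(self):
        # p = (0.01, 0.02, 0.03, 0.5) at q=0.05, m=4: thresholds
        # 0.0125, 0.025, 0.0375, 0.05; largest k with p(k) <= k q/m is 3
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.02, 0.03, 0.5]
        reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert list(reject) == [True, True, True, False]
        assert bh_oracle(p, 0.05) == [True, True, True, False]

    def test_network_edges_follow_step_up_decisions(self):
        atlas = small_atlas(4)
        iu = np.triu_indices(atlas.n, 1)
        p_upper = np.array([0.004, 0.012, 0.03, 0.5, 0.9, 0.95])
        cov = cov_from_p(p_upper, atlas)
        net = threshold_fdr(cov, 0.05)
        assert list(net.adjacency[iu]) == [int(b) for b in bh_oracle(p_upper, 0.05)]

    def test_negative_correlation_never_becomes_edge(self):
        atlas = small_atlas(4)
        cov = cov_from_p([1e-8] * 6, atlas, r_sign=-1.0)
        assert threshold_fdr(cov, 0.05).n_edges == 0

    def test_raising_q_never_removes_edges(self):
        atlas = small_atlas(6)
        rng = np.random.default_rng(3)
        p_upper = rng.uniform(0, 0.3, size=15)
        cov = cov_from_p(p_upper, atlas)
        prev = threshold_fdr(cov, 0.01).adjacency
        for q in (0.05, 0.1, 0.2, 0.4):
            cur = threshold_fdr(cov, q).adjacency
            assert (cur >= prev).all()
            prev = cur

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20),
           st.floats(min_value=0.01, max_value=0.3))
    def test_bh_decisions_match_brute_force_step_up(self, pvals, q):
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
        assert list(reject) == bh_oracle(pvals, q)

    def test_hot_path_matches_reference_route(self):
        atlas = small_atlas(12)
        rng = np.random.default_rng(5)
        for q in (0.01, 0.05, 0.2):
            x = rng.standard_normal((25, 12)) + 0.4 * rng.standard_normal((25, 1))
            ref = threshold_fdr(correlation_matrix(x, atlas), q).adjacency
            assert (fdr_network_from_values(x, q) == ref).all()

    def test_output_is_symmetric_binary_hollow(self):
        atlas = small_atlas(10)
        rng = np.random.default_rng(9)
        x = rng.standard_normal((20, 10))
        net = threshold_fdr(correlation_matrix(x, atlas), 0.2)
        a = net.adjacency
        assert (a == a.T).all()
        assert np.isin(a, (0, 1)).all()
        assert np.diag(a).sum() == 0
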