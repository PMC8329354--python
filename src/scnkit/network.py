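"""Structural covariance network construction.

A structural covariance network is built per condition by (1) correlating
mean cortical thickness of every ROI pair across subjects (Pearson r),
(2) thresholding the upper-triangle p-values with the Benjamini-Hochberg
step-up procedure at rate q, and (3) keeping only positive correlations,
yielding an undirected binary adjacency matrix.

The negativity filter is applied after the FDR step: negative-r pairs are
part of the BH hypothesis pool but can never become edges. Applying it
before BH would shrink the pool and change the step-up threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import BinaryNetwork, CovarianceMatrix, MorphometryError, ThicknessTable

__all__ = ["correlation_matrix", "condition_covariance", "threshold_fdr"]


def correlation_matrix(values: np.ndarray, atlas) -> CovarianceMatrix:
    """Across-subject Pearson correlation matrix with two-sided p-values.

    Parameters
    ----------
    values
        ``(n_subjects, n_roi)`` thickness array, one row per subject.
    atlas
        The ROI atlas labelling the columns.

    p-values come from the exact t transform ``t = r*sqrt((n-2)/(1-r^2))``
    referred to a t distribution on n-2 degrees of freedom.

    Raises
    ------
    MorphometryError
        If fewer than 4 subjects, or any ROI has zero variance across
        subjects (its correlations are undefined; silently dropping the
        node would change every graph metric, so this is a hard error).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != atlas.n:
        raise MorphometryError("values must be (n_subjects, n_roi)")
    n = x.shape[0]
    if n < 4:
        raise MorphometryError(f"correlation requires >= 4 subjects, got {n}")
    sd = x.std(axis=0)
    if (sd == 0).any():
        roi = atlas.names[int(np.argmax(sd == 0))]
        raise MorphometryError(f"ROI {roi!r} has zero variance across subjects")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0  # |r| == 1
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2.0  # enforce exact symmetry
    return CovarianceMatrix(r=r, p=p, n=n, atlas=atlas)


def condition_covariance(table: ThicknessTable, condition: str, group: str | None = None) -> CovarianceMatrix:
    """Correlation matrix for one condition (optionally one age group)."""
    _, x = table.condition_values(condition, group)
    return correlation_matrix(x, table.atlas)


def threshold_fdr(cov: CovarianceMatrix, q: float = 0.05) -> BinaryNetwork:
    """Binarize a correlation matrix by BH-FDR on the upper-triangle p-values.

    Each undirected ROI pair is one hypothesis (m = k(k-1)/2 = 2278 for the
    68-ROI atlas). An edge is present iff its p-value is BH-significant at
    rate ``q`` and its correlation is positive; the diagonal is zero.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    k = cov.atlas.n
    iu = np.triu_indices(k, 1)
    reject, *_ = multipletests(cov.p[iu], alpha=q, method="fdr_bh")
    edges = reject & (cov.r[iu] > 0)
    adj = np.zeros((k, k), dtype=np.int8)
    adj[iu] = edges
    adj += adj.T
    return BinaryNetwork(adj, cov.atlas)


def _bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions (vectorized hot-path variant)."""
    m = p.size
    order = np.argsort(p, kind="stable")
    passed = p[order] <= q * np.arange(1, m + 1) / m
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = int(np.flatnonzero(passed)[-1])
        reject[order[: kmax + 1]] = True
    return reject


def fdr_network_from_values(values: np.ndarray, q: float) -> np.ndarray:
    """Adjacency of the FDR-thresholded covariance network, hot-path form.

    Equivalent to ``threshold_fdr(correlation_matrix(values, atlas), q)``
    but skips container construction and works on the upper triangle only;
    the permutation engine calls this once per permuted condition. The
    equivalence is pinned by a test.
    """
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    xc = x - x.mean(axis=0)
    norm = np.sqrt((xc * xc).sum(axis=0))
    if (norm == 0).any():
        raise MorphometryError("zero-variance ROI; correlation undefined")
    xc /= norm
    r = np.clip(xc.T @ xc, -1.0, 1.0)
    iu = np.triu_indices(k, 1)
    rv = r[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv * rv))
    # special.stdtr is the t CDF ufunc behind stats.t.sf, minus call overhead
    p = 2.0 * special.stdtr(n - 2, -np.abs(t))
    p[np.isnan(p)] = 0.0
    edges = _bh_reject(p, q) & (rv > 0)
    adj = np.zeros((k, k), dtype=np.int8)
    adj[iu] = edges
    adj += adj.T
    return adj
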