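"""Vectorised ordinary-least-squares helpers shared by the model stages.

All fits share one design matrix across many response rows (probes), so the
projection is computed once: B = Y X (X'X)^-1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_fit(Y: np.ndarray, X: np.ndarray):
    """Row-wise OLS of each row of Y (probes x samples) on design X (samples x p).

    Returns ``(coefs, resid_var, df_resid, xtx_inv)`` where ``coefs`` is
    probes x p and ``resid_var`` the per-row residual variance (ddof = p).
    """
    n, p = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.pinv(xtx)
    B = Y @ X @ xtx_inv                      # probes x p
    resid = Y - B @ X.T
    df = n - np.linalg.matrix_rank(X)
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / df if df > 0 else np.full(Y.shape[0], np.nan)
    return B, s2, df, xtx_inv


def nested_f_pvalues(Y: np.ndarray, X0: np.ndarray, X1: np.ndarray) -> np.ndarray:
    """Row-wise F-test p-values comparing nested designs X0 within X1."""
    def rss_df(X):
        H = X @ np.linalg.pinv(X.T @ X) @ X.T
        resid = Y - Y @ H
        return np.einsum("ij,ij->i", resid, resid), Y.shape[1] - np.linalg.matrix_rank(X)

    rss0, df0 = rss_df(X0)
    rss1, df1 = rss_df(X1)
    ddf = df0 - df1
    if ddf <= 0 or df1 <= 0:
        raise ValueError("designs are not strictly nested")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / ddf) / (rss1 / df1)
    p = stats.f.sf(f, ddf, df1)
    p[~np.isfinite(f)] = 1.0
    return p


def design_from_groups(groups: np.ndarray) -> np.ndarray:
    """Intercept + dummy columns for a categorical vector (first level ref)."""
    levels = sorted(set(groups))
    cols = [np.ones(len(groups))]
    for lev in levels[1:]:
        cols.append((np.asarray(groups) == lev).astype(float))
    return np.column_stack(cols)
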