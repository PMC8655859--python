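"""Surrogate variable estimation with outcome protection, and lambda-guided
selection of how many surrogate variables to adjust for.

Surrogate variables capture unmodelled technical and biological variation
(batch, cell composition drift, ancestry) directly from the methylation
matrix while protecting the diagnosis effect. The estimator is an
iteratively reweighted SVD: residualise on the primary model, take the top
right-singular vectors, then repeatedly re-weight probes by the empirical
probability that they are associated with the candidate surrogate variables
but NOT with the primary variable, and recompute the SVD on the weighted
matrix.

The number of surrogate variables carried into the site-wise model is the k
in 0..K_max whose genome-wide p-values give a genomic-inflation lambda
closest to 1.0, with ties resolved toward fewer surrogate variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ._lm import design_from_groups, nested_f_pvalues
from .data_model import BetaMatrix
from .stats_kernels import inflation_lambda

__all__ = [
    "SurrogateSet",
    "estimate_svs",
    "select_k_by_lambda",
    "estimate_k_permutation",
]


@dataclass
class SurrogateSet:
    """Estimated surrogate variables and the lambda-based selection audit."""

    sv_scores: pd.DataFrame                 # samples x K, singular-value order
    k_selected: int | None = None
    lambda_by_k: list[float] = field(default_factory=list)
    iterations: int = 0

    @property
    def k_max(self) -> int:
        return self.sv_scores.shape[1]

    def selected(self) -> pd.DataFrame:
        k = self.k_selected if self.k_selected is not None else self.k_max
        return self.sv_scores.iloc[:, :k]


def _posterior_alt(p: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Empirical posterior probability of being a true association.

    A histogram-based local-fdr: pi0 is estimated from the right half of the
    p-value distribution, the marginal density from binned counts, and
    prob_alt = 1 - min(1, pi0 / f(p)).
    """
    p = np.clip(p, 1e-12, 1.0)
    pi0 = min(1.0, 2.0 * np.mean(p > 0.5))
    edges = np.linspace(0, 1, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    dens = counts / max(p.size, 1) * n_bins
    # enforce a decreasing density so lfdr is monotone in p
    dens = np.maximum.accumulate(dens[::-1])[::-1]
    dens = np.maximum(dens, 1e-8)
    idx = np.minimum((p * n_bins).astype(int), n_bins - 1)
    lfdr = np.minimum(1.0, pi0 / dens[idx])
    return 1.0 - lfdr


def _as_matrix(y) -> tuple[np.ndarray, list, list]:
    if hasattr(y, "values") and isinstance(y.values, pd.DataFrame):
        # BetaMatrix / MValueMatrix wrappers
        return y.values.to_numpy(float), list(y.values.index), list(y.values.columns)
    df = pd.DataFrame(y)
    return df.to_numpy(float), list(df.index), list(df.columns)


def _primary_design(primary, n: int) -> np.ndarray:
    arr = np.asarray(primary)
    if arr.ndim == 1:
        if arr.dtype.kind in "OUS" or len(set(arr)) <= max(3, int(np.sqrt(n))):
            return design_from_groups(arr)
        return np.column_stack([np.ones(n), arr.astype(float)])
    return np.asarray(arr, dtype=float)


def estimate_svs(
    y: BetaMatrix | pd.DataFrame,
    primary,
    k_max: int = 10,
    n_iter: int = 5,
) -> SurrogateSet:
    """Estimate up to ``k_max`` surrogate variables protecting ``primary``.

    ``primary`` is the outcome vector (or a full design matrix including an
    intercept). Constant probes are dropped with a warning. The returned SV
    columns are orthonormal, ordered by singular value.
    """
    if k_max <= 0:
        raise ValueError("k_max must be positive")
    Y, probe_ids, sample_ids = _as_matrix(y)
    n = Y.shape[1]
    X = _primary_design(primary, n)
    if k_max >= n - np.linalg.matrix_rank(X):
        raise ValueError("k_max must be below the residual degrees of freedom")

    const = Y.std(axis=1) == 0
    if const.any():
        import warnings

        warnings.warn(f"dropping {const.sum()} constant probes", stacklevel=2)
        Y = Y[~const]

    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    resid = Y - Y @ H

    # initial candidates: right-singular vectors of the residual matrix
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    svs = vt[:k_max].T                          # samples x k_max
    intercept = np.ones((n, 1))
    # marginal association with the primary variable; the protection factor.
    # Marginal (not SV-conditional) so that a latent direction collinear
    # with the outcome still carries outcome-associated probes' penalty
    p_primary = nested_f_pvalues(Y, intercept, X)
    protect = 1.0 - _posterior_alt(p_primary)
    iterations = 0
    for _ in range(n_iter):
        iterations += 1
        X_both = np.column_stack([X, svs])
        # association with the SVs given the primary variable
        p_sv = nested_f_pvalues(Y, X, X_both)
        w = _posterior_alt(p_sv) * protect
        # SVD of the weighted, row-centred data (not the residuals): the
        # resulting SVs are free to correlate with the primary design, and
        # protection comes from the down-weighting of outcome-associated
        # probes rather than from forced orthogonality
        weighted = w[:, None] * Y
        weighted = weighted - weighted.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(weighted, full_matrices=False)
        svs = vt[:k_max].T
    return SurrogateSet(
        sv_scores=pd.DataFrame(
            svs, index=sample_ids, columns=[f"SV{i+1}" for i in range(k_max)]
        ),
        iterations=iterations,
    )


def default_pvalue_fn(
    y: BetaMatrix | pd.DataFrame, primary, svs: SurrogateSet
) -> Callable[[int], np.ndarray]:
    """Per-probe OLS p-values for the primary effect adjusted for k SVs."""
    Y, _, _ = _as_matrix(y)
    n = Y.shape[1]
    X_primary = _primary_design(primary, n)
    sv_arr = svs.sv_scores.to_numpy(float)

    def pvals(k: int) -> np.ndarray:
        adj = sv_arr[:, :k]
        X0 = np.column_stack([np.ones(n), adj])
        X1 = np.column_stack([X_primary, adj])
        return nested_f_pvalues(Y, X0, X1)

    return pvals


def select_k_by_lambda(
    y: BetaMatrix | pd.DataFrame,
    primary,
    svs: SurrogateSet,
    ewas_fn: Callable[[int], np.ndarray] | None = None,
    tol: float = 0.05,
) -> SurrogateSet:
    """Choose the number of SVs whose EWAS lambda is closest to 1.0.

    ``ewas_fn(k)`` must return per-probe p-values for the primary contrast
    adjusted for the first k surrogate variables; when omitted, an
    unmoderated OLS fit is used. Models whose |lambda - 1| comes within
    ``tol`` of the best are treated as equally well calibrated (the
    median-based lambda estimate carries sampling noise of that order) and
    the smallest such k wins; exact ties likewise go to the smaller k, and
    k = 0 is admissible. The SurrogateSet is updated in place with
    ``k_selected`` and ``lambda_by_k`` and returned.
    """
    if ewas_fn is None:
        ewas_fn = default_pvalue_fn(y, primary, svs)
    lambdas = []
    for k in range(svs.k_max + 1):
        p = np.asarray(ewas_fn(k), dtype=float)
        p = p[np.isfinite(p)]
        if p.size == 0:
            raise ValueError(f"ewas_fn returned no finite p-values for k={k}")
        lambdas.append(inflation_lambda(p))
    dist = np.abs(np.array(lambdas) - 1.0)
    candidates = np.flatnonzero(dist <= dist.min() + tol)
    svs.k_selected = int(candidates.min())
    svs.lambda_by_k = [float(v) for v in lambdas]
    return svs


def estimate_k_permutation(
    y: BetaMatrix | pd.DataFrame,
    primary,
    n_perm: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
    k_cap: int | None = None,
) -> int:
    """Permutation (parallel-analysis) estimate of the number of latent factors.

    Compares the singular values of the primary-model residual matrix with
    those of matrices whose rows are independently permuted (destroying
    cross-probe structure); a factor is counted while its singular value
    exceeds the (1 - alpha) permutation quantile.
    """
    Y, _, _ = _as_matrix(y)
    n = Y.shape[1]
    X = _primary_design(primary, n)
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    resid = Y - Y @ H
    resid = resid / np.sqrt(max(n, 1))
    sv_obs = np.linalg.svd(resid, compute_uv=False)
    rng = np.random.default_rng(seed)
    cap = k_cap or min(20, n - np.linalg.matrix_rank(X) - 1)
    null = np.empty((n_perm, len(sv_obs)))
    for b in range(n_perm):
        perm = np.array([rng.permutation(row) for row in resid])
        perm = perm - perm @ H
        null[b] = np.linalg.svd(perm, compute_uv=False)
    thresh = np.quantile(null, 1 - alpha, axis=0)
    k = 0
    for i in range(min(cap, len(sv_obs))):
        if sv_obs[i] > thresh[i]:
            k += 1
        else:
            break
    return k
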