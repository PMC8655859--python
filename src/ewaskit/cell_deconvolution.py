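"""Reference-based cell-type deconvolution by constrained projection.

Bulk methylation at discriminating probes is modelled as a nonnegative
mixture of sorted-cell reference profiles. Per sample we solve

    min_w || y - R^T w ||^2   subject to  w >= 0,  sum(w) <= 1,

with an active-set nonnegative least-squares solver; the sum constraint is
handled by a heavily weighted slack-variable augmentation, so the solution
is deterministic (no random starts). The inequality (rather than equality)
lets unmodelled cell types absorb residual mass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data_model import BetaMatrix

__all__ = ["select_discriminating_probes", "estimate_proportions"]


def select_discriminating_probes(
    reference_full: pd.DataFrame, per_type: int = 50
) -> list[str]:
    """Pick probes with the largest one-vs-rest contrast for each cell type.

    For each cell type, the ``per_type`` probes with the largest and the
    ``per_type`` with the smallest (most negative) mean difference against
    the other cell types are taken; the union over cell types is returned.
    Ties break by probe id (lexicographic), so the output is deterministic.
    If fewer probes are available than requested, all probes are returned.
    """
    if per_type < 1:
        raise ValueError("per_type must be >= 1")
    k, p = reference_full.shape
    if k < 2:
        raise ValueError("need at least 2 cell types to discriminate")
    if 2 * per_type >= p:
        import warnings

        warnings.warn(
            f"requested {2 * per_type} probes per type but only {p} available; "
            "returning all probes",
            stacklevel=2,
        )
        return list(reference_full.columns)
    arr = reference_full.to_numpy(float)
    chosen: set[str] = set()
    probe_ids = np.array(reference_full.columns)
    for i in range(k):
        rest = np.delete(arr, i, axis=0).mean(axis=0)
        contrast = arr[i] - rest
        # sort by (contrast, probe id) for deterministic tie-breaks
        order = np.lexsort((probe_ids, contrast))
        chosen.update(probe_ids[order[:per_type]])     # most hypo
        chosen.update(probe_ids[order[-per_type:]])    # most hyper
    return sorted(chosen)


def _solve_one(R: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    """NNLS with sum(w) + slack = 1 enforced by a weighted augmentation row."""
    k = R.shape[0]
    A = np.vstack([np.hstack([R.T, np.zeros((R.shape[1], 1))]),
                   penalty * np.ones((1, k + 1))])
    b = np.concatenate([y, [penalty]])
    w, _ = nnls(A, b)
    return w[:k]


def estimate_proportions(
    b: BetaMatrix | pd.DataFrame, ref: pd.DataFrame, penalty: float = 1000.0
) -> pd.DataFrame:
    """Estimate sample-by-cell-type mixing proportions.

    ``ref`` is a cell-type-by-probe reference beta table; its probes must be
    a subset of the analysed probes. Returns weights >= 0 with row sums <= 1
    (up to the augmentation tolerance). Raises on a rank-deficient
    reference, naming the collinear cell types.
    """
    values = b.values if isinstance(b, BetaMatrix) else b
    missing = [p for p in ref.columns if p not in values.index]
    if missing:
        raise ValueError(
            f"{len(missing)} reference probes absent from the beta matrix "
            f"(first: {missing[:5]})"
        )
    R = ref.to_numpy(float)
    rank = np.linalg.matrix_rank(R, tol=1e-8)
    if rank < R.shape[0]:
        # identify collinear types by near-duplicate profile correlation
        cc = np.corrcoef(R)
        pairs = [
            (ref.index[i], ref.index[j])
            for i in range(len(cc))
            for j in range(i + 1, len(cc))
            if cc[i, j] > 1 - 1e-8
        ]
        raise ValueError(f"reference is rank-deficient; collinear cell types: {pairs}")
    Y = values.loc[list(ref.columns)].to_numpy(float)
    W = np.stack(
        [_solve_one(R, Y[:, j], penalty) for j in range(Y.shape[1])]
    )
    return pd.DataFrame(W, index=list(values.columns), columns=list(ref.index))
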