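"""Site-wise epigenome-wide association with empirical-Bayes moderation.

Each CpG is fit by ordinary least squares, methylation ~ intercept + group +
adjustment terms, for one pairwise contrast (ASD vs TD, or nonTD vs TD; the
excluded third group is dropped, not dummy-coded). Per-probe residual
variances are shrunk toward a scaled inverse-chi-square prior whose
hyperparameters (d0, s0^2) are estimated by matching the moments of
log s^2 through digamma/trigamma relations; the moderated t-statistic
gains d0 extra degrees of freedom. Effects are reported as differences in
percent methylation (beta x 100), ASD minus TD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from ._lm import ols_fit
from .data_model import BetaMatrix, MValueMatrix, SampleSheet
from .stats_kernels import bh_fdr
from .surrogate_variables import SurrogateSet

__all__ = [
    "fit_sitewise",
    "moderate_variances",
    "summarize_ewas",
    "cross_model_correlation",
    "EwasSummary",
]

CONTRASTS = {"ASD-vs-TD": ("TD", "ASD"), "nonTD-vs-TD": ("TD", "nonTD")}


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(
    residual_vars: np.ndarray,
    dfs: np.ndarray | float,
    prior_df: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Fit a scaled inverse-chi-square prior to per-probe variances.

    Returns ``(d0, s0_sq, posterior_vars)`` where posterior_vars are the
    shrunken variances (d0 s0^2 + d s^2) / (d0 + d). Hyperparameters come
    from matching the mean and variance of log s^2: with z = log s^2,
    E z = log s0^2 + digamma(d0/2) - log(d0/2) - (digamma(d/2) - log(d/2))
    and Var z = trigamma(d/2) + trigamma(d0/2). Non-finite or nonpositive
    variances are excluded from the fit (their posterior is s0^2-based).
    ``prior_df`` overrides the estimated d0 (0 disables shrinkage, inf
    pools completely).
    """
    s2 = np.asarray(residual_vars, dtype=float)
    d = np.broadcast_to(np.asarray(dfs, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (d > 0)
    if ok.sum() < 2 and prior_df is None:
        raise ValueError("too few finite positive variances to fit the prior")
    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0:
            return 0.0, float(np.nan), s2.copy()
        s0_sq = float(np.exp(np.mean(np.log(s2[ok])))) if ok.any() else np.nan
    else:
        z = np.log(s2[ok])
        if np.ptp(z) == 0:
            # all variances identical: the natural fit is complete pooling
            # at exactly that value (the log-moment correction assumes
            # chi-square scatter that is absent here)
            val = float(s2[ok][0])
            return float(np.inf), val, np.full_like(s2, val)
        e = z - special.digamma(d[ok] / 2) + np.log(d[ok] / 2)
        emean = float(np.mean(e))
        evar = float(np.var(e, ddof=1))
        evar_resid = evar - float(np.mean(special.polygamma(1, d[ok] / 2)))
        if evar_resid > 0:
            d0 = 2.0 * _trigamma_inverse(evar_resid)
            s0_sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
        else:
            d0 = np.inf
            s0_sq = float(np.exp(emean))
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + d * s2) / (d0 + d)
        post = np.where(ok, post, s0_sq * d0 / max(d0, 1e-300) if d0 > 0 else np.nan)
    return float(d0), s0_sq, post


def _adjustment_matrix(
    adjustment, sheet: SampleSheet, samples: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Build the adjustment design block for the given samples."""
    if adjustment is None:
        return np.empty((len(samples), 0)), []
    if isinstance(adjustment, SurrogateSet):
        block = adjustment.selected().loc[samples]
        return block.to_numpy(float), list(block.columns)
    if isinstance(adjustment, pd.DataFrame):
        block = adjustment.loc[samples]
        return block.to_numpy(float), list(block.columns)
    # list of sample-sheet column names: dummy-code categoricals
    cols, names = [], []
    meta = sheet.table.loc[samples]
    for cov in adjustment:
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(float))
            names.append(cov)
        else:
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                cols.append((col == lev).astype(float).to_numpy())
                names.append(f"{cov}[{lev}]")
            if col.isna().any():
                cols[-1] = np.where(col.isna().to_numpy(), np.nan, cols[-1])
    X = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return X, names


def fit_sitewise(
    y: BetaMatrix | MValueMatrix,
    sheet: SampleSheet,
    adjustment=None,
    contrast: str = "ASD-vs-TD",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-CpG moderated regression of methylation on diagnosis.

    ``adjustment`` may be a SurrogateSet (its selected columns are used), a
    DataFrame of numeric covariates indexed by sample, or a list of
    sample-sheet column names (categoricals dummy-coded). Samples with
    missing covariate values are dropped (complete case). Returns a table
    indexed by probe id with columns mean_percent, effect_percent,
    se_percent, t_moderated, p_value, fdr_q, n_used.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    ref, case = CONTRASTS[contrast]
    outcome = sheet.table["outcome"]
    samples = [
        s for s in y.sample_ids if s in outcome.index and outcome[s] in (ref, case)
    ]
    if len(samples) < 4:
        raise ValueError("need at least 4 samples in the contrasted groups")
    adj, adj_names = _adjustment_matrix(adjustment, sheet, samples)
    group = (outcome.loc[samples] == case).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(samples)), group, adj])
    complete = np.isfinite(X).all(axis=1)
    samples = [s for s, c in zip(samples, complete) if c]
    X = X[complete]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                aliased.append((["intercept", "group"] + adj_names)[j])
        raise ValueError(f"design is rank-deficient; aliased terms: {aliased}")
    if X.shape[0] - rank < 1:
        raise ValueError("no residual degrees of freedom")

    Y = y.values[samples].to_numpy(float)
    B, s2, df, xtx_inv = ols_fit(Y, X)
    effect = B[:, 1]
    c_gg = xtx_inv[1, 1]
    d0, s0_sq, post = moderate_variances(s2, df, prior_df=prior_df)
    se = np.sqrt(c_gg * post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    total_df = df if (prior_df == 0) else d0 + df
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    res = pd.DataFrame(
        {
            "mean_percent": Y.mean(axis=1) * 100.0,
            "effect_percent": effect * 100.0,
            "se_percent": se * 100.0,
            "t_moderated": t,
            "p_value": p,
            "fdr_q": bh_fdr(p),
            "n_used": len(samples),
        },
        index=pd.Index(y.probe_ids, name="probe_id"),
    )
    res.attrs["contrast"] = contrast
    res.attrs["d0"] = d0
    res.attrs["s0_sq"] = s0_sq
    res.attrs["df_resid"] = df
    return res


@dataclass
class EwasSummary:
    n_probes: int
    n_nominal: int
    percent_hyper: float
    percent_hypo: float
    volcano: pd.DataFrame

    def __str__(self) -> str:
        return (
            f"{self.n_nominal}/{self.n_probes} probes at nominal p < 0.05; "
            f"{self.percent_hyper:.1f}% hypermethylated"
        )


def summarize_ewas(res: pd.DataFrame, p_cut: float = 0.05) -> EwasSummary:
    """Count nominal sites and the share hyper/hypomethylated in cases."""
    if res.empty:
        raise ValueError("empty EWAS result")
    nominal = res[res["p_value"] < p_cut]
    n = len(nominal)
    hyper = float((nominal["effect_percent"] > 0).mean() * 100) if n else float("nan")
    volcano = pd.DataFrame(
        {
            "effect_percent": res["effect_percent"],
            "neg_log10_p": -np.log10(res["p_value"]),
        },
        index=res.index,
    )
    return EwasSummary(
        n_probes=len(res),
        n_nominal=n,
        percent_hyper=hyper,
        percent_hypo=100.0 - hyper if n else float("nan"),
        volcano=volcano,
    )


def cross_model_correlation(res_a: pd.DataFrame, res_b: pd.DataFrame) -> float:
    """Pearson correlation of effect estimates over shared probes."""
    shared = res_a.index.intersection(res_b.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared probes")
    a = res_a.loc[shared, "effect_percent"].to_numpy(float)
    b = res_b.loc[shared, "effect_percent"].to_numpy(float)
    return float(np.corrcoef(a, b)[0, 1])
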