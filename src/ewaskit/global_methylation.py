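"""Global and region-stratified methylation summaries and group tests.

Per-sample global methylation is the unweighted mean over autosomal CpGs,
reported in percent, overall and within each island-relation stratum
(island / shore / shelf / open sea) and the overlapping enhancer flag.
Group differences are tested with a linear model adjusted for surrogate
variables, optionally stratified by child sex; distributional differences
use an integrated-absolute-difference statistic between mean empirical CDFs
with a group-label permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BetaMatrix, CpGAnnotation, REGION_CLASSES, SampleSheet
from .ewas import CONTRASTS
from .surrogate_variables import SurrogateSet

__all__ = ["GlobalSummary", "global_means", "test_global_difference", "cdf_difference_test"]

STRATA = ("overall",) + REGION_CLASSES + ("enhancer",)


@dataclass
class GlobalSummary:
    """Per-sample stratum means (percent) and per-stratum CpG counts."""

    means: pd.DataFrame                    # samples x strata, percent
    cpg_counts: dict[str, int] = field(default_factory=dict)
    effects: pd.DataFrame | None = None
    cdf_tests: pd.DataFrame | None = None


def _stratum_probes(ann: CpGAnnotation, analyzed: pd.Index) -> dict[str, list[str]]:
    auto = [p for p in ann.autosomal_probes() if p in analyzed]
    tab = ann.table.loc[auto]
    out = {"overall": auto}
    for region in REGION_CLASSES:
        out[region] = list(tab.index[tab["region_class"] == region])
    out["enhancer"] = list(tab.index[tab["enhancer"]])
    return out


def global_means(b: BetaMatrix, ann: CpGAnnotation) -> GlobalSummary:
    """Unweighted per-sample means (x100) per stratum, autosomes only."""
    strata = _stratum_probes(ann, b.values.index)
    cols = {}
    for name, probes in strata.items():
        if not probes:
            warnings.warn(f"stratum {name!r} has no probes", stacklevel=2)
            cols[name] = pd.Series(np.nan, index=b.values.columns)
        else:
            cols[name] = b.values.loc[probes].mean(axis=0) * 100.0
    means = pd.DataFrame(cols)
    return GlobalSummary(means=means, cpg_counts={k: len(v) for k, v in strata.items()})


def _ols_single(yv: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """OLS of one response; returns (coef[1], se, p) for the group column."""
    n, p = X.shape
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ X.T @ yv
    resid = yv - X @ beta
    df = n - np.linalg.matrix_rank(X)
    if df <= 0:
        return float(beta[1]), float("nan"), float("nan")
    s2 = float(resid @ resid) / df
    se = float(np.sqrt(s2 * xtx_inv[1, 1]))
    t = beta[1] / se if se > 0 else 0.0
    return float(beta[1]), se, float(2 * stats.t.sf(abs(t), df))


def test_global_difference(
    gs: GlobalSummary,
    sheet: SampleSheet,
    svs: SurrogateSet | None = None,
    contrast: str = "ASD-vs-TD",
    stratify_sex: bool = False,
) -> pd.DataFrame:
    """Group difference in each stratum mean, adjusted for surrogate variables.

    Fits mean_percent ~ group + SVs per stratum; reports the case-minus-
    reference difference in percent with its SE and p. With
    ``stratify_sex`` the model runs within each sex; a cell with fewer than
    3 samples per group is skipped with a warning.
    """
    ref, case = CONTRASTS[contrast]
    outcome = sheet.table["outcome"]
    rows = []
    sex_levels = [None] if not stratify_sex else ["F", "M"]
    for sex in sex_levels:
        samples = [
            s
            for s in gs.means.index
            if outcome.get(s) in (ref, case)
            and (sex is None or sheet.table.loc[s, "sex"] == sex)
        ]
        grp = (outcome.loc[samples] == case).astype(float).to_numpy()
        if min((grp == 1).sum(), (grp == 0).sum()) < 3:
            warnings.warn(
                f"fewer than 3 samples per group (sex={sex}); stratum skipped",
                stacklevel=2,
            )
            continue
        adj = (
            svs.selected().loc[samples].to_numpy(float)
            if svs is not None
            else np.empty((len(samples), 0))
        )
        X = np.column_stack([np.ones(len(samples)), grp, adj])
        for stratum in gs.means.columns:
            yv = gs.means.loc[samples, stratum].to_numpy(float)
            if not np.isfinite(yv).all():
                continue
            diff, se, p = _ols_single(yv, X)
            rows.append(
                {
                    "stratum": stratum,
                    "sex": sex or "all",
                    "difference_percent": diff,
                    "se": se,
                    "p_value": p,
                    "n": len(samples),
                }
            )
    eff = pd.DataFrame(rows)
    gs.effects = eff
    return eff


def cdf_difference_test(
    b: BetaMatrix,
    ann: CpGAnnotation,
    sheet: SampleSheet,
    stratum: str = "overall",
    n_perm: int = 999,
    seed: int = 0,
    contrast: str = "ASD-vs-TD",
    grid_points: int = 101,
) -> tuple[float, float]:
    """Permutation test on the methylation cumulative distribution function.

    Each sample contributes its empirical CDF over the stratum's probes,
    evaluated on a fixed grid of ``grid_points`` equally spaced beta values;
    the statistic is the mean absolute difference between the two group-mean
    CDFs (an integrated L1 distance). The p-value is
    (1 + #{perm >= observed}) / (1 + n_perm) under group-label permutation.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a meaningful permutation p")
    ref, case = CONTRASTS[contrast]
    outcome = sheet.table["outcome"]
    samples = [s for s in b.sample_ids if outcome.get(s) in (ref, case)]
    if len(set(outcome.loc[samples])) < 2:
        raise ValueError("both contrast groups must be present")
    probes = _stratum_probes(ann, b.values.index)[stratum]
    if not probes:
        raise ValueError(f"stratum {stratum!r} has no probes")
    vals = b.values.loc[probes, samples].to_numpy(float)
    if np.ptp(vals) == 0:
        return 0.0, 1.0
    grid = np.linspace(0.0, 1.0, grid_points)
    # per-sample empirical CDF on the grid: fraction of probes <= g
    sorted_vals = np.sort(vals, axis=0)
    cdfs = np.stack(
        [
            np.searchsorted(sorted_vals[:, j], grid, side="right") / len(probes)
            for j in range(len(samples))
        ]
    )  # samples x grid
    labels = (outcome.loc[samples] == case).to_numpy()

    def statistic(lab: np.ndarray) -> float:
        return float(np.abs(cdfs[lab].mean(axis=0) - cdfs[~lab].mean(axis=0)).mean())

    obs = statistic(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += statistic(rng.permutation(labels)) >= obs
    return obs, (1 + exceed) / (1 + n_perm)
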