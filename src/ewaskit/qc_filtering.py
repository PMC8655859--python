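"""Probe and sample quality control.

Probes are removed when their detection p-value exceeds 0.01 in strictly
more than 10% of samples, then when they appear on a supplied
cross-reactive list. Samples are removed for low overall array intensity
(< 10.5 on the log2 scale), a high (> 20%) fraction of failed detection
p-values, or discordance between methylation-predicted and recorded sex.
Diagnostics include replicate-pair correlations and a principal-component
by covariate ANOVA scan for batch effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BetaMatrix, CpGAnnotation, SampleSheet

__all__ = [
    "QcReport",
    "filter_probes",
    "filter_samples",
    "predict_sex",
    "replicate_concordance",
    "pc_covariate_scan",
]


@dataclass
class QcReport:
    probes_removed_detection: int = 0
    probes_removed_crossreactive: int = 0
    samples_removed_intensity: int = 0
    samples_removed_failfrac: int = 0
    samples_removed_sexmismatch: int = 0
    removed_probes_detection: list[str] = field(default_factory=list)
    removed_probes_crossreactive: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    replicate_correlations: list[float] = field(default_factory=list)
    pc_covariate_pvalues: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "probes_removed_detection",
                    "probes_removed_crossreactive",
                    "samples_removed_intensity",
                    "samples_removed_failfrac",
                    "samples_removed_sexmismatch",
                ],
                "count": [
                    self.probes_removed_detection,
                    self.probes_removed_crossreactive,
                    self.samples_removed_intensity,
                    self.samples_removed_failfrac,
                    self.samples_removed_sexmismatch,
                ],
            }
        )


def filter_probes(
    b: BetaMatrix,
    detp: pd.DataFrame,
    crossreactive: list[str] | None = None,
    det_p_cut: float = 0.01,
    sample_frac_cut: float = 0.10,
    report: QcReport | None = None,
) -> tuple[BetaMatrix, QcReport]:
    """Remove failed-detection probes, then cross-reactive probes.

    A probe fails when its detection p-value is > ``det_p_cut`` in strictly
    more than ``sample_frac_cut`` of samples (both inequalities strict).
    """
    if report is None:
        report = QcReport()
    if list(detp.index) != b.probe_ids or list(detp.columns) != b.sample_ids:
        raise ValueError("detection-p matrix is not aligned with the beta matrix")
    frac_failed = (detp.to_numpy() > det_p_cut).mean(axis=1)
    failed = frac_failed > sample_frac_cut
    det_removed = [p for p, f in zip(b.probe_ids, failed) if f]
    kept = b.values.loc[~failed]
    xr = set(crossreactive or [])
    xr_removed = [p for p in kept.index if p in xr]
    kept = kept.loc[[p for p in kept.index if p not in xr]]
    report.probes_removed_detection = len(det_removed)
    report.probes_removed_crossreactive = len(xr_removed)
    report.removed_probes_detection = det_removed
    report.removed_probes_crossreactive = xr_removed
    return BetaMatrix(kept), report


def predict_sex(b: BetaMatrix, ann: CpGAnnotation) -> pd.Series | None:
    """Predict sample sex from the chrY-minus-chrX median methylation split.

    Per sample, compute median(chrY probe beta) - median(chrX probe beta);
    split the samples at the midpoint of the two 1-D cluster means (males
    carry chrY signal, so the higher cluster is male). Returns None when no
    sex-chromosome probes are present.
    """
    x_probes = ann.probes_on("chrX")
    y_probes = ann.probes_on("chrY")
    x_probes = [p for p in x_probes if p in b.values.index]
    y_probes = [p for p in y_probes if p in b.values.index]
    if not x_probes or not y_probes:
        return None
    score = (
        b.values.loc[y_probes].median(axis=0) - b.values.loc[x_probes].median(axis=0)
    )
    # 1-D two-means split, deterministic: start from the extremes
    vals = score.to_numpy(float)
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-12:
        return pd.Series("F", index=score.index)
    c_lo, c_hi = lo, hi
    for _ in range(100):
        assign = np.abs(vals - c_hi) < np.abs(vals - c_lo)
        if assign.all() or (~assign).all():
            break
        new_lo, new_hi = vals[~assign].mean(), vals[assign].mean()
        if np.isclose(new_lo, c_lo) and np.isclose(new_hi, c_hi):
            break
        c_lo, c_hi = new_lo, new_hi
    cut = (c_lo + c_hi) / 2
    return pd.Series(np.where(vals > cut, "M", "F"), index=score.index)


def filter_samples(
    b: BetaMatrix,
    detp: pd.DataFrame,
    sheet: SampleSheet,
    ann: CpGAnnotation | None = None,
    intensity_col: str = "mean_log2_intensity",
    intensity_cut: float = 10.5,
    det_p_cut: float = 0.01,
    fail_frac_cut: float = 0.20,
    report: QcReport | None = None,
) -> tuple[list[str], QcReport]:
    """Return the samples that pass intensity, detection, and sex checks.

    Drops samples below ``intensity_cut`` mean log2 intensity, with a failed
    detection fraction above ``fail_frac_cut``, or whose methylation-predicted
    sex disagrees with the recorded sex. Without sex-chromosome probes the
    sex check is skipped with a recorded warning.
    """
    if report is None:
        report = QcReport()
    samples = b.sample_ids
    low_intensity: set[str] = set()
    if intensity_col in sheet.table.columns:
        inten = sheet.table.loc[samples, intensity_col]
        low_intensity = set(inten.index[inten < intensity_cut])
    else:
        report.warnings.append(
            f"sample sheet has no {intensity_col!r} column; intensity check skipped"
        )
    frac_failed = (detp[samples].to_numpy() > det_p_cut).mean(axis=0)
    high_fail = {s for s, f in zip(samples, frac_failed) if f > fail_frac_cut}
    mismatched: set[str] = set()
    predicted = predict_sex(b, ann) if ann is not None else None
    if predicted is None:
        report.warnings.append("no chrX/chrY probes present; sex check skipped")
    else:
        recorded = sheet.table.loc[samples, "recorded_sex"]
        mismatched = {s for s in samples if predicted[s] != recorded[s]}
    removed = low_intensity | high_fail | mismatched
    kept = [s for s in samples if s not in removed]
    report.samples_removed_intensity = len(low_intensity)
    report.samples_removed_failfrac = len(high_fail)
    report.samples_removed_sexmismatch = len(mismatched)
    report.removed_samples = sorted(removed)
    return kept, report


def replicate_concordance(
    b: BetaMatrix, replicate_pairs: list[tuple[str, str]]
) -> list[float]:
    """Pearson correlation across probes for each replicate sample pair.

    A pair with a constant profile has no defined correlation and is
    reported as NaN.
    """
    out = []
    for s1, s2 in replicate_pairs:
        if s1 not in b.values.columns or s2 not in b.values.columns:
            raise ValueError(f"replicate pair ({s1}, {s2}) references unknown samples")
        x = b.values[s1].to_numpy(float)
        y = b.values[s2].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(float("nan"))
        else:
            out.append(float(np.corrcoef(x, y)[0, 1]))
    return out


def pc_covariate_scan(
    b: BetaMatrix,
    sheet: SampleSheet,
    n_pcs: int = 10,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """One-way ANOVA p-values of top methylation PCs against covariates.

    Principal components are the right-singular vectors of the probe-centred
    beta matrix. Returns a PC-by-covariate p-value table (heat-map ready);
    a covariate with fewer than two observed levels gives NaN.
    """
    n_samples = b.shape[1]
    if n_pcs > n_samples - 1:
        raise ValueError("n_pcs must be at most n_samples - 1")
    if covariates is None:
        covariates = [
            c
            for c in sheet.table.columns
            if c not in ("recorded_sex", "mean_log2_intensity")
        ]
    arr = b.values.to_numpy(float)
    centred = arr - arr.mean(axis=1, keepdims=True)
    # right singular vectors = sample-space PCs
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    pcs = vt[:n_pcs]
    meta = sheet.table.loc[b.sample_ids]
    rows = {}
    for ci, cov in enumerate(covariates):
        col = meta[cov]
        pvals = []
        for k in range(n_pcs):
            pc = pd.Series(pcs[k], index=b.sample_ids)
            if pd.api.types.is_numeric_dtype(col) and col.nunique() > 5:
                keep = col.notna()
                if keep.sum() < 3 or col[keep].nunique() < 2:
                    pvals.append(np.nan)
                    continue
                res = stats.linregress(col[keep].to_numpy(float), pc[keep].to_numpy())
                pvals.append(float(res.pvalue))
            else:
                groups = [
                    pc[col == lev].to_numpy()
                    for lev in col.dropna().unique()
                    if (col == lev).sum() >= 2
                ]
                if len(groups) < 2:
                    pvals.append(np.nan)
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    f, p = stats.f_oneway(*groups)
                pvals.append(float(p))
        rows[cov] = pvals
    return pd.DataFrame(rows, index=[f"PC{k+1}" for k in range(n_pcs)])
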