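"""End-to-end pipeline orchestration.

Runs QC -> cell-type deconvolution -> surrogate variables -> site-wise EWAS
-> global methylation -> risk-gene enrichment -> ontology testing, writing
per-stage TSV outputs and a run log recording the seed, package versions,
and the number of records filtered at each stage. Outputs are a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_deconvolution import estimate_proportions
from .data_model import (
    PipelineConfig,
    read_annotation,
    read_beta_matrix,
    read_detection_p,
    read_gene_set,
    read_probe_list,
    read_sample_sheet,
    write_beta_matrix,
)
from .enrichment_and_ontology import enrichment_curve, ontology_enrichment
from .ewas import fit_sitewise, summarize_ewas
from .global_methylation import cdf_difference_test, global_means, test_global_difference
from .qc_filtering import QcReport, filter_probes, filter_samples, pc_covariate_scan
from .surrogate_variables import estimate_svs, select_k_by_lambda

__all__ = ["run_pipeline"]


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def run_pipeline(config: PipelineConfig, inputs: dict, out_dir: str | Path) -> dict:
    """Execute every stage in order and write stage tables under ``out_dir``.

    ``inputs`` maps names to file paths: required ``beta``, ``detection_p``,
    ``annotation``, ``samples``, ``risk_genes``; optional ``crossreactive``
    (probe list), ``reference`` (cell-type-by-probe TSV), ``meqtl_cpgs``
    (probe list), ``go_map`` (gene/category TSV). Returns a dict of
    in-memory stage results. A stage failure aborts with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    _log(log, f"ewaskit {__version__} | python {sys.version.split()[0]} | "
              f"numpy {np.__version__} | pandas {pd.__version__}")
    _log(log, f"seed={config.seed} contrast={config.contrast} model={config.model}")
    results: dict = {"config": config}
    stage = "read_inputs"
    try:
        beta = read_beta_matrix(inputs["beta"])
        detp = read_detection_p(inputs["detection_p"])
        ann = read_annotation(inputs["annotation"])
        sheet = read_sample_sheet(inputs["samples"])
        risk = read_gene_set(inputs["risk_genes"], name="risk_genes")
        crossreactive = (
            read_probe_list(inputs["crossreactive"]) if inputs.get("crossreactive") else []
        )
        _log(log, f"input: {beta.shape[0]} probes x {beta.shape[1]} samples")

        stage = "qc"
        report = QcReport()
        beta_f, report = filter_probes(
            beta, detp, crossreactive,
            det_p_cut=config.det_p_cut, sample_frac_cut=config.sample_frac_cut,
            report=report,
        )
        detp_f = detp.loc[beta_f.probe_ids]
        kept_samples, report = filter_samples(
            beta_f, detp_f, sheet, ann,
            intensity_cut=config.intensity_cut,
            det_p_cut=config.det_p_cut,
            fail_frac_cut=config.fail_frac_cut,
            report=report,
        )
        beta_f = beta_f.subset_samples(kept_samples)
        _log(log, f"qc: removed {report.probes_removed_detection} detection-failed "
                  f"and {report.probes_removed_crossreactive} cross-reactive probes; "
                  f"removed samples {report.removed_samples}")
        scan = pc_covariate_scan(beta_f, sheet, n_pcs=min(10, len(kept_samples) - 1))
        report.pc_covariate_pvalues = scan
        report.to_frame().to_csv(out / "qc_summary.tsv", sep="\t", index=False)
        scan.to_csv(out / "qc_pc_covariate_p.tsv", sep="\t", index_label="PC")
        write_beta_matrix(beta_f, out / "beta_filtered.tsv")
        results["qc_report"] = report
        results["beta"] = beta_f

        stage = "deconvolution"
        if inputs.get("reference"):
            ref = pd.read_csv(inputs["reference"], sep="\t", index_col=0)
            ref = ref[[p for p in ref.columns if p in set(beta_f.probe_ids)]]
            props = estimate_proportions(beta_f, ref)
            props.to_csv(out / "cell_proportions.tsv", sep="\t", index_label="sample_id")
            results["cell_proportions"] = props
            _log(log, f"deconvolution: {props.shape[1]} cell types estimated")
        else:
            _log(log, "deconvolution: no reference supplied; stage skipped")

        stage = "surrogate_variables"
        k_max = min(config.sv_max, len(kept_samples) - 3)
        svs = estimate_svs(beta_f, sheet.table.loc[kept_samples, "outcome"], k_max=k_max)
        svs = select_k_by_lambda(beta_f, sheet.table.loc[kept_samples, "outcome"], svs)
        svs.sv_scores.to_csv(out / "sv_scores.tsv", sep="\t", index_label="sample_id")
        pd.DataFrame(
            {"k": range(len(svs.lambda_by_k)), "lambda": svs.lambda_by_k}
        ).to_csv(out / "sv_lambda_by_k.tsv", sep="\t", index=False)
        _log(log, f"sva: k_max={k_max} selected k={svs.k_selected} "
                  f"(lambda={svs.lambda_by_k[svs.k_selected]:.3f})")
        results["svs"] = svs

        stage = "ewas"
        if config.model == "surrogate":
            adjustment = svs
        else:
            adjustment = [
                c for c in ("batch", "maternal_age", "sex")
                if c in sheet.table.columns
            ]
        res = fit_sitewise(beta_f, sheet, adjustment, contrast=config.contrast)
        ewas_out = res.copy()
        ewas_out.insert(0, "gene_symbols", [
            ";".join(ann.table.loc[p, "genes"]) if p in ann.table.index else ""
            for p in ewas_out.index
        ])
        ewas_out.insert(1, "chrom", [
            ann.table.loc[p, "chrom"] if p in ann.table.index else ""
            for p in ewas_out.index
        ])
        ewas_out.insert(2, "pos", [
            ann.table.loc[p, "pos"] if p in ann.table.index else -1
            for p in ewas_out.index
        ])
        ewas_out.to_csv(
            out / f"ewas_{config.contrast}.tsv", sep="\t", index_label="probe_id",
            float_format="%.6g",
        )
        summ = summarize_ewas(res)
        _log(log, f"ewas[{config.contrast}]: {summ}")
        results["ewas"] = res
        results["ewas_summary"] = summ

        stage = "global_methylation"
        gs = global_means(beta_f, ann)
        eff = test_global_difference(gs, sheet, svs, contrast=config.contrast)
        cdf_stat, cdf_p = cdf_difference_test(
            beta_f, ann, sheet,
            n_perm=config.cdf_permutations, seed=config.seed,
            contrast=config.contrast, grid_points=config.cdf_grid_points,
        )
        gs.means.to_csv(out / "global_means.tsv", sep="\t", index_label="sample_id")
        eff.to_csv(out / "global_effects.tsv", sep="\t", index=False)
        _log(log, f"global: overall diff "
                  f"{eff.loc[eff['stratum'] == 'overall', 'difference_percent'].iloc[0]:+.3f}% ; "
                  f"cdf stat {cdf_stat:.4f} p {cdf_p:.4f}")
        results["global"] = gs
        results["cdf_test"] = (cdf_stat, cdf_p)

        stage = "enrichment"
        curve = enrichment_curve(
            res, ann, risk, grid=config.thresholds,
            n_perm=config.n_permutations, seed=config.seed,
        )
        curve.table.to_csv(out / "enrichment_curve.tsv", sep="\t")
        if curve.permutation_p is not None:
            curve.permutation_p.to_csv(out / "enrichment_permutations.tsv", sep="\t")
        if inputs.get("meqtl_cpgs"):
            meqtl = read_probe_list(inputs["meqtl_cpgs"])
            curve_meqtl = enrichment_curve(
                res, ann, risk, grid=config.thresholds,
                n_perm=config.n_permutations, seed=config.seed,
                restrict_cpgs=meqtl,
            )
            curve_meqtl.table.to_csv(out / "enrichment_curve_meqtl.tsv", sep="\t")
            results["enrichment_meqtl"] = curve_meqtl
        row05 = curve.table.loc[0.05] if 0.05 in curve.table.index else curve.table.iloc[-1]
        _log(log, f"enrichment: at p<0.05 observed {int(row05['risk_overlap_observed'])} "
                  f"expected {row05['risk_overlap_expected']:.1f} "
                  f"chi2 p {row05['p_value']:.3g}")
        results["enrichment"] = curve

        stage = "ontology"
        if inputs.get("go_map"):
            go_map = pd.read_csv(inputs["go_map"], sep="\t")
            go = ontology_enrichment(
                res, ann, go_map, min_genes=config.min_genes_per_term
            )
            go.to_csv(out / "ontology.tsv", sep="\t")
            _log(log, f"ontology: {len(go)} categories tested")
            results["ontology"] = go
        else:
            _log(log, "ontology: no category map supplied; stage skipped")
    except Exception as exc:
        _log(log, f"FAILED at stage {stage}: {exc}")
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    config.to_yaml(out / "config_used.yaml")
    return results
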