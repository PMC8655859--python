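"""Generator of 450k-like methylation datasets with known ground truth.

Each dataset is built from the generative model the downstream stages assume:
per-sample cell-type mixtures of reference methylation profiles, latent
technical/biological factors, sex effects carried by dedicated chrX/chrY
probe blocks, and a diagnosis effect spiked preferentially into CpGs
annotated to a designated risk-gene set. All effects act on the logit scale
and are mapped back through the logistic, so generated beta values always
lie strictly inside (0, 1):

    beta_ij = logistic( logit(sum_k w_ik r_kj) + sum_l f_il load_lj
                        + male_i s_j + dx_i d_j + eps_ij )

The spiked effect ``delta`` is calibrated per CpG so that the beta-scale
ASD-vs-TD difference is approximately ``delta`` at that CpG's baseline mean,
not only at beta = 0.5.

Default condition: 10,000 CpGs x 120 samples; outcome prevalence 22% ASD,
43% non-typically developing, 35% typically developing; seven cord-blood
cell types mixed at realistic mean proportions; ~0.1% of detection
p-values planted as failures; 69% of spiked effects hypermethylated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import BetaMatrix, CpGAnnotation, GeneSet, SampleSheet

__all__ = ["SimulationTruth", "simulate_dataset", "make_reference_panel", "write_dataset"]

# mean cord-blood cell proportions (granulocyte-dominated), normalised at use
DEFAULT_CELL_TYPES = ("Gran", "CD8T", "CD4T", "NK", "Bcell", "Mono", "nRBC")
DEFAULT_CELL_PROPS = (0.430, 0.134, 0.191, 0.005, 0.110, 0.083, 0.101)

DEFAULT_OUTCOME_PREVALENCE = {"TD": 0.35, "nonTD": 0.43, "ASD": 0.22}

REGION_PROBS = {"island": 0.31, "shore": 0.23, "shelf": 0.10, "open_sea": 0.36}


def _logit(x):
    return np.log(x / (1.0 - x))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated dataset, for recovery tests."""

    cell_profiles: pd.DataFrame        # cell-type x CpG reference betas
    mixing: pd.DataFrame               # sample x cell-type proportions
    latent_scores: pd.DataFrame        # sample x K factor scores
    latent_loadings: pd.DataFrame      # K x CpG logit-scale loadings
    effect_cpgs: frozenset[str]        # truly affected probes
    effect_signs: pd.Series            # +1 hyper / -1 hypo per effect CpG
    delta: float                       # intended beta-scale group difference
    risk_genes: GeneSet
    seed: int


def _baseline_means(rng: np.random.Generator, n: int, delta: float) -> np.ndarray:
    """Bimodal 450k-like baseline means, kept clear of the boundaries."""
    kind = rng.choice(3, size=n, p=[0.35, 0.35, 0.30])
    m = np.empty(n)
    low = rng.beta(2.0, 8.0, size=n)
    m[kind == 0] = low[kind == 0]
    m[kind == 1] = 1.0 - low[kind == 1]
    m[kind == 2] = rng.uniform(0.2, 0.8, size=n)[kind == 2]
    lo, hi = 0.02 + delta / 2, 0.98 - delta / 2
    return np.clip(m, lo, hi)


def _make_annotation(
    rng: np.random.Generator,
    n_cpgs: int,
    frac_chrx: float,
    frac_chry: float,
    n_genes: int,
    risk_gene_fraction: float,
) -> tuple[CpGAnnotation, GeneSet]:
    probes = [f"cg{i:08d}" for i in range(n_cpgs)]
    n_x = int(round(frac_chrx * n_cpgs))
    n_y = int(round(frac_chry * n_cpgs))
    chroms = np.array(
        [f"chr{c}" for c in rng.integers(1, 23, size=n_cpgs)], dtype=object
    )
    chroms[:n_x] = "chrX"
    chroms[n_x:n_x + n_y] = "chrY"
    pos = rng.integers(10_000, 50_000_000, size=n_cpgs)
    region = rng.choice(
        list(REGION_PROBS), size=n_cpgs, p=list(REGION_PROBS.values())
    )
    enhancer = rng.random(n_cpgs) < 0.22

    gene_names = [f"GENE{i:05d}" for i in range(n_genes)]
    # Zipf-ish gene sizes so probe-count-per-gene bias is realistic
    weights = 1.0 / np.arange(1, n_genes + 1) ** 0.5
    weights /= weights.sum()
    genes: list[list[str]] = []
    for i in range(n_cpgs):
        if rng.random() < 0.25:          # intergenic probe
            genes.append([])
            continue
        g = [gene_names[rng.choice(n_genes, p=weights)]]
        if rng.random() < 0.05:          # overlapping transcripts
            other = gene_names[rng.choice(n_genes, p=weights)]
            if other not in g:
                g.append(other)
        genes.append(g)

    table = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "genes": genes,
            "region_class": region,
            "enhancer": enhancer,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    n_risk = max(2, int(round(risk_gene_fraction * n_genes)))
    risk = rng.choice(n_genes, size=n_risk, replace=False)
    risk_set = GeneSet.from_iterable("risk_genes", [gene_names[i] for i in risk])
    return CpGAnnotation(table), risk_set


def simulate_dataset(
    n_samples: int = 120,
    n_cpgs: int = 10_000,
    n_celltypes: int = 7,
    k_latent: int = 2,
    spike_fraction: float = 0.3,
    delta: float = 0.05,
    seed: int = 1,
    *,
    noise_sd: float = 0.25,
    latent_sd: float = 0.35,
    latent_probe_fraction: float = 0.30,
    latent_outcome_corr: float = 0.0,
    cell_sd: float = 0.30,
    markers_per_type: int = 50,
    mixing_concentration: float = 50.0,
    hyper_fraction: float = 0.69,
    detection_failure_rate: float = 0.001,
    frac_chrx: float = 0.02,
    frac_chry: float = 0.005,
    n_genes: int | None = None,
    risk_gene_fraction: float = 0.05,
    outcome_prevalence: dict[str, float] | None = None,
    cell_types: tuple[str, ...] | None = None,
) -> tuple[BetaMatrix, pd.DataFrame, CpGAnnotation, SampleSheet, GeneSet, SimulationTruth]:
    """Simulate a 450k-like dataset and return it with its ground truth.

    Returns ``(beta, detection_p, annotation, sheet, risk_genes, truth)``.
    ``delta`` is the intended beta-scale ASD-minus-TD difference at each
    spiked CpG; ``spike_fraction`` is the fraction of risk-gene CpGs that
    carry it. ``k_latent`` latent factors load on a random
    ``latent_probe_fraction`` of probes with logit-scale sd ``latent_sd``.
    """
    if min(n_samples, n_cpgs, n_celltypes) < 1 or k_latent < 0:
        raise ValueError("all counts must be positive (k_latent may be 0)")
    if not 0 < spike_fraction <= 1:
        raise ValueError("spike_fraction must be in (0, 1]")
    if not 0 <= delta < 0.9:
        raise ValueError(
            f"delta={delta} would push group means outside (0, 1)"
        )
    rng = np.random.default_rng(seed)
    prevalence = outcome_prevalence or DEFAULT_OUTCOME_PREVALENCE
    if abs(sum(prevalence.values()) - 1) > 1e-9:
        raise ValueError("outcome prevalence must sum to 1")

    if n_genes is None:
        n_genes = max(n_cpgs // 10, 20)
    ann, risk = _make_annotation(
        rng, n_cpgs, frac_chrx, frac_chry, n_genes, risk_gene_fraction
    )
    probes = ann.probe_ids
    is_x = (ann.table["chrom"] == "chrX").to_numpy()
    is_y = (ann.table["chrom"] == "chrY").to_numpy()

    # --- samples ---------------------------------------------------------
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    outcomes = rng.choice(
        list(prevalence), size=n_samples, p=list(prevalence.values())
    )
    sex = rng.choice(["M", "F"], size=n_samples)
    batch = rng.choice(["b1", "b2"], size=n_samples, p=[0.65, 0.35])
    site = rng.choice(["Drexel", "JHU", "Kaiser", "UCDavis"], size=n_samples)
    maternal_age = np.round(rng.normal(33.6, 4.7, size=n_samples), 1)
    intensity = np.round(rng.normal(12.0, 0.3, size=n_samples), 3)

    # --- cell profiles and mixtures --------------------------------------
    if cell_types is None:
        cell_types = DEFAULT_CELL_TYPES[:n_celltypes]
        if len(cell_types) < n_celltypes:
            cell_types = cell_types + tuple(
                f"cell{i}" for i in range(len(cell_types), n_celltypes)
            )
    props = np.array(DEFAULT_CELL_PROPS[:n_celltypes], dtype=float)
    if len(props) < n_celltypes:
        props = np.concatenate([props, np.full(n_celltypes - len(props), 0.05)])
    props /= props.sum()

    m0 = _baseline_means(rng, n_cpgs, delta)
    logit_m0 = _logit(m0)
    cell_dev = rng.normal(0.0, cell_sd, size=(n_celltypes, n_cpgs))
    # sex-chromosome probes carry sex structure, not cell-type contrast;
    # keeping them out of the profiles keeps the reference panel autosomal
    cell_dev[:, is_x | is_y] = 0.0
    # planted marker probes: strong one-vs-rest contrast per cell type
    if n_celltypes > 1 and markers_per_type > 0:
        auto_idx = np.flatnonzero(~(is_x | is_y))
        need = 2 * markers_per_type * n_celltypes
        take = min(need, auto_idx.size)
        marker_idx = rng.choice(auto_idx, size=take, replace=False)
        per = take // n_celltypes
        for k in range(n_celltypes):
            mk = marker_idx[k * per:(k + 1) * per]
            half = len(mk) // 2
            cell_dev[k, mk[:half]] += 2.5
            cell_dev[k, mk[half:]] -= 2.5
    profiles = _logistic(logit_m0[None, :] + cell_dev)
    if n_celltypes == 1:
        profiles = _logistic(logit_m0[None, :])
    mixing = rng.dirichlet(props * mixing_concentration, size=n_samples)

    # --- latent factors ---------------------------------------------------
    scores = rng.normal(size=(n_samples, k_latent)) if k_latent else np.zeros((n_samples, 0))
    if k_latent and latent_outcome_corr:
        # confound factor 1 with diagnosis (e.g. cases enriched in a batch)
        dx_std = (outcomes == "ASD").astype(float)
        dx_std = (dx_std - dx_std.mean()) / max(dx_std.std(), 1e-12)
        c = latent_outcome_corr
        scores[:, 0] = np.sqrt(1 - c * c) * scores[:, 0] + c * dx_std
    loadings = np.zeros((k_latent, n_cpgs))
    for l in range(k_latent):
        on = rng.random(n_cpgs) < latent_probe_fraction
        loadings[l, on] = rng.normal(0.0, latent_sd, size=on.sum())

    # --- sex effects via chrX/chrY probe blocks ---------------------------
    male = (sex == "M").astype(float)
    sex_effect = np.zeros(n_cpgs)
    sex_effect[is_x] = -0.8          # males lower on chrX (X-inactivation)
    sex_effect[is_y] = 3.0           # males carry chrY signal
    base_shift = np.zeros(n_cpgs)
    base_shift[is_y] = -3.0          # females near-unmethylated-looking on chrY

    # --- spiked diagnosis effect ------------------------------------------
    risk_probe_mask = np.array(
        [bool(set(g) & risk.genes) for g in ann.table["genes"]]
    )
    risk_probe_idx = np.flatnonzero(risk_probe_mask & ~(is_x | is_y))
    n_effect = int(round(spike_fraction * risk_probe_idx.size))
    effect_idx = (
        rng.choice(risk_probe_idx, size=n_effect, replace=False)
        if n_effect
        else np.array([], dtype=int)
    )
    signs = np.where(rng.random(n_effect) < hyper_fraction, 1.0, -1.0)
    d_logit = np.zeros(n_cpgs)
    if delta > 0 and n_effect:
        mj = m0[effect_idx]
        d_logit[effect_idx] = signs * (
            _logit(mj + delta / 2) - _logit(mj - delta / 2)
        )
    dx = (outcomes == "ASD").astype(float)

    # --- assemble ----------------------------------------------------------
    mix_mean = mixing @ profiles                      # samples x CpGs, in (0,1)
    logit_mu = (
        _logit(np.clip(mix_mean, 1e-6, 1 - 1e-6))
        + base_shift[None, :]
        + scores @ loadings
        + male[:, None] * sex_effect[None, :]
        + dx[:, None] * d_logit[None, :]
    )
    if noise_sd > 0:
        logit_mu = logit_mu + rng.normal(0.0, noise_sd, size=logit_mu.shape)
    beta_vals = _logistic(logit_mu).T                 # CpGs x samples
    beta = BetaMatrix(
        pd.DataFrame(beta_vals, index=probes, columns=sample_ids)
    )

    detp = rng.uniform(0.0, 0.005, size=(n_cpgs, n_samples))
    fails = rng.random((n_cpgs, n_samples)) < detection_failure_rate
    detp[fails] = rng.uniform(0.011, 0.8, size=int(fails.sum()))
    detp = pd.DataFrame(detp, index=probes, columns=sample_ids)

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "outcome": outcomes,
                "sex": sex,
                "recorded_sex": sex,
                "batch": batch,
                "site": site,
                "maternal_age": maternal_age,
                "mean_log2_intensity": intensity,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SimulationTruth(
        cell_profiles=pd.DataFrame(profiles, index=list(cell_types), columns=probes),
        mixing=pd.DataFrame(mixing, index=sample_ids, columns=list(cell_types)),
        latent_scores=pd.DataFrame(
            scores, index=sample_ids, columns=[f"F{l+1}" for l in range(k_latent)]
        ),
        latent_loadings=pd.DataFrame(
            loadings, index=[f"F{l+1}" for l in range(k_latent)], columns=probes
        ),
        effect_cpgs=frozenset(probes[i] for i in effect_idx),
        effect_signs=pd.Series(signs, index=[probes[i] for i in effect_idx]),
        delta=delta,
        risk_genes=risk,
        seed=seed,
    )
    return beta, detp, ann, sheet, risk, truth


def make_reference_panel(
    truth: SimulationTruth, per_type: int = 50, min_contrast: float = 0.05
) -> pd.DataFrame:
    """Build a deconvolution reference from the true cell profiles.

    Restricts the profiles to probes with large one-vs-rest between-cell-type
    contrast (the discriminating probes a sorted-cell reference would
    provide). Raises if the profiles carry no discriminating probes.
    """
    from .cell_deconvolution import select_discriminating_probes

    profiles = truth.cell_profiles
    if profiles.shape[0] < 2:
        raise ValueError("reference panel needs at least 2 cell types")
    chosen = select_discriminating_probes(profiles, per_type=per_type)
    contrasts = []
    for p in chosen:
        col = profiles[p]
        contrasts.append(np.abs(col.to_numpy()[:, None] - col.to_numpy()).max())
    chosen = [p for p, c in zip(chosen, contrasts) if c >= min_contrast]
    if not chosen:
        raise ValueError("cell profiles have no discriminating probes")
    return profiles[chosen]


def write_dataset(out_dir, beta, detp, ann, sheet, risk, truth) -> None:
    """Serialise a simulated dataset in the TSV formats the readers consume."""
    from pathlib import Path

    from .data_model import (
        write_annotation,
        write_beta_matrix,
        write_gene_set,
        write_sample_sheet,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(beta, out / "beta.tsv")
    detp.to_csv(out / "detection_p.tsv", sep="\t", index_label="probe_id")
    write_annotation(ann, out / "annotation.tsv")
    write_sample_sheet(sheet, out / "samples.tsv")
    write_gene_set(risk, out / "risk_genes.txt")
    truth.mixing.to_csv(out / "truth_mixing.tsv", sep="\t", index_label="sample_id")
    truth.cell_profiles.to_csv(
        out / "truth_cell_profiles.tsv", sep="\t", index_label="cell_type"
    )
    pd.Series(sorted(truth.effect_cpgs)).to_csv(
        out / "truth_effect_cpgs.txt", index=False, header=False
    )
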