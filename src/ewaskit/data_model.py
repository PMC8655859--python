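"""Domain types, file readers/writers, validation, and pipeline configuration.

All tabular artefacts are delimited text (TSV by default): inspectable,
diffable, language-neutral. Matrices are CpG-by-sample with probe ids in the
first column and sample ids in the header. The CpG annotation table mirrors
the Illumina 450k manifest column names (IlmnID, CHR, MAPINFO,
UCSC_RefGene_Name, Relation_to_UCSC_CpG_Island, Enhancer) with 1-based
coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BetaMatrix",
    "MValueMatrix",
    "CpGAnnotation",
    "SampleSheet",
    "GeneSet",
    "PipelineConfig",
    "REGION_CLASSES",
    "DEFAULT_THRESHOLD_GRID",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_detection_p",
    "read_annotation",
    "write_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_set",
    "write_gene_set",
    "read_probe_list",
    "beta_to_m",
]

REGION_CLASSES = ("island", "shore", "shelf", "open_sea")

# significance grid used for risk-gene enrichment curves
DEFAULT_THRESHOLD_GRID = (
    0.0001, 0.001, 0.005, 0.01, 0.02, 0.03, 0.04, 0.05,
    0.1, 0.15, 0.2, 0.3, 0.5, 0.7, 0.99,
)


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of methylation proportions in [0, 1].

    ``values`` is a DataFrame indexed by probe id with sample-id columns.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index, "probe ids")
        _check_unique(v.columns, "sample ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("beta matrix contains non-numeric cells")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite beta value at probe {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        if (arr < 0).any() or (arr > 1).any():
            bad = np.argwhere((arr < 0) | (arr > 1))[0]
            raise ValueError(
                f"beta value outside [0,1] at probe {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}: {arr[tuple(bad)]}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probes)])

    def subset_samples(self, samples) -> "BetaMatrix":
        return BetaMatrix(self.values[list(samples)])


@dataclass
class MValueMatrix:
    """CpG-by-sample matrix on the log2-odds (M-value) scale; unbounded."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite M-value")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def beta_to_m(b: BetaMatrix, offset: float = 0.0) -> MValueMatrix:
    """Convert beta values to M-values: M = log2((beta+offset)/(1-beta+offset)).

    The offset regularises probes at the 0/1 boundary; with offset 0 a
    boundary beta value is an error (the log-odds would be infinite).
    """
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    arr = b.values.to_numpy(float)
    if offset == 0 and ((arr == 0) | (arr == 1)).any():
        raise ValueError("beta value of exactly 0 or 1 requires a positive offset")
    m = np.log2((arr + offset) / (1.0 - arr + offset))
    return MValueMatrix(pd.DataFrame(m, index=b.values.index, columns=b.values.columns))


@dataclass
class CpGAnnotation:
    """Per-probe genomic metadata.

    ``table`` is indexed by probe id with columns: chrom (str), pos (int,
    1-based), genes (list of deduplicated symbols, possibly empty),
    region_class (island/shore/shelf/open_sea), enhancer (bool). The
    enhancer flag overlaps the island-relation classes, as in the manifest.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "annotation probe ids")
        bad = set(self.table["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region classes: {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def autosomal_probes(self) -> list[str]:
        sex = self.table["chrom"].isin(["chrX", "chrY", "X", "Y"])
        return list(self.table.index[~sex])

    def probes_on(self, chrom: str) -> list[str]:
        return list(self.table.index[self.table["chrom"] == chrom])


@dataclass
class SampleSheet:
    """Per-sample phenotype and technical covariates.

    ``table`` is indexed by sample id; must contain ``outcome`` with levels
    TD / nonTD / ASD and ``sex`` with levels M / F. ``recorded_sex`` (used by
    the QC sex-concordance check) defaults to ``sex`` when absent.
    """

    table: pd.DataFrame
    OUTCOMES = ("TD", "nonTD", "ASD")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        if "outcome" not in self.table.columns:
            raise ValueError("sample sheet must contain an 'outcome' column")
        bad = set(self.table["outcome"].dropna()) - set(self.OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcome levels: {sorted(bad)}")
        if "recorded_sex" not in self.table.columns and "sex" in self.table.columns:
            self.table = self.table.assign(recorded_sex=self.table["sex"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def outcome_codes(self, order=("TD", "nonTD", "ASD")) -> pd.Series:
        return self.table["outcome"].map({g: i for i, g in enumerate(order)})


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of gene symbols (case-sensitive HGNC style)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneSet":
        cleaned = {g.strip() for g in genes if g and g.strip()}
        return cls(name, frozenset(cleaned))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in self.genes


@dataclass
class PipelineConfig:
    """All tunable settings of a pipeline run, serialisable to YAML."""

    seed: int = 1
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    n_permutations: int = 10
    det_p_cut: float = 0.01
    sample_frac_cut: float = 0.10
    intensity_cut: float = 10.5
    fail_frac_cut: float = 0.20
    sv_max: int = 10
    model: str = "surrogate"  # or "known-covariate"
    contrast: str = "ASD-vs-TD"  # or "nonTD-vs-TD"
    m_offset: float = 0.0
    cdf_grid_points: int = 101
    cdf_permutations: int = 999
    min_genes_per_term: int = 5

    def __post_init__(self) -> None:
        t = tuple(self.thresholds)
        if not all(0 < a <= 1 for a in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("permutation count must be >= 1")
        if self.contrast not in ("ASD-vs-TD", "nonTD-vs-TD"):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.model not in ("surrogate", "known-covariate"):
            raise ValueError(f"unknown model {self.model!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(d["thresholds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {bad.index[0]!r}: "
                f"{bad.iloc[0]!r}"
            )
    return df


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a delimited CpG-by-sample beta table; values outside [0,1] rejected."""
    return BetaMatrix(_read_matrix(path))


def write_beta_matrix(b: BetaMatrix, path: str | Path, digits: int = 6) -> None:
    b.values.round(digits).to_csv(path, sep="\t", index_label="probe_id")


def read_detection_p(path: str | Path) -> pd.DataFrame:
    """Read a detection p-value matrix aligned like a beta matrix."""
    df = _read_matrix(path)
    if ((df < 0) | (df > 1)).any().any():
        raise ValueError("detection p-values must lie in [0, 1]")
    return df


_MANIFEST_COLS = {
    "IlmnID": "probe_id",
    "CHR": "chrom",
    "MAPINFO": "pos",
    "UCSC_RefGene_Name": "genes",
    "Relation_to_UCSC_CpG_Island": "island_relation",
    "Enhancer": "enhancer",
}

_RELATION_MAP = {
    "Island": "island",
    "N_Shore": "shore",
    "S_Shore": "shore",
    "N_Shelf": "shelf",
    "S_Shelf": "shelf",
    "": "open_sea",
}


def parse_gene_field(raw) -> list[str]:
    """Split a semicolon-separated manifest gene field into unique symbols."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    seen: list[str] = []
    for g in str(raw).split(";"):
        g = g.strip()
        if g and g not in seen:
            seen.append(g)
    return seen


def read_annotation(path: str | Path) -> CpGAnnotation:
    """Read a 450k-manifest-style annotation table.

    Accepts manifest column names (IlmnID, CHR, MAPINFO, UCSC_RefGene_Name,
    Relation_to_UCSC_CpG_Island, Enhancer) or the internal names. Island
    relations N/S_Shore and N/S_Shelf collapse to shore/shelf; an absent
    relation is open sea.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df = df.rename(columns=_MANIFEST_COLS)
    required = {"probe_id", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    chrom = df["chrom"].map(lambda c: c if c.startswith("chr") else f"chr{c}")
    genes = df.get("genes", pd.Series([""] * len(df))).map(parse_gene_field)
    if "region_class" in df.columns:
        region = df["region_class"]
    else:
        rel = df.get("island_relation", pd.Series([""] * len(df)))
        region = rel.map(lambda r: _RELATION_MAP.get(r.strip(), "open_sea"))
    enhancer = df.get("enhancer", pd.Series([""] * len(df))).map(
        lambda v: str(v).strip().upper() in ("TRUE", "1", "YES")
    )
    table = pd.DataFrame(
        {
            "chrom": chrom.to_numpy(),
            "pos": df["pos"].astype(int).to_numpy(),
            "genes": genes.to_numpy(),
            "region_class": region.to_numpy(),
            "enhancer": enhancer.to_numpy(),
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    return CpGAnnotation(table)


def write_annotation(ann: CpGAnnotation, path: str | Path) -> None:
    """Write the annotation back out with manifest column names."""
    t = ann.table
    back_rel = {"island": "Island", "shore": "N_Shore", "shelf": "N_Shelf", "open_sea": ""}
    out = pd.DataFrame(
        {
            "IlmnID": t.index,
            "CHR": [c.removeprefix("chr") for c in t["chrom"]],
            "MAPINFO": t["pos"].to_numpy(),
            "UCSC_RefGene_Name": [";".join(g) for g in t["genes"]],
            "Relation_to_UCSC_CpG_Island": [back_rel[r] for r in t["region_class"]],
            "Enhancer": ["TRUE" if e else "" for e in t["enhancer"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list, one symbol per line; '#' comments allowed."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                genes.append(line)
    return GeneSet.from_iterable(name or Path(path).stem, genes)


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gs.genes):
            fh.write(g + "\n")


def read_probe_list(path: str | Path) -> list[str]:
    """Read a plain-text probe-id list, one id per line."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]
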