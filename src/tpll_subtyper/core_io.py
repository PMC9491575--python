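"""Readers/writers for on-disk formats plus validated in-memory containers.

Expression and copy-number matrices travel as TSV with genes in rows and a
header of sample ids; gene sets travel as GMT; sample metadata as a TSV with
fixed column names.  All expression values are assumed to arrive already
normalized on log2 scale — nothing here re-normalizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("tpll_subtyper")

#: canonical metadata column names
META_COLUMNS = [
    "sample_id", "group", "sex", "age_years", "pretreated",
    "stage", "tcl1a_status", "time_days", "status",
]

NA_TOKENS = {"", "NA", "nan", "NaN", None}


class ParseError(ValueError):
    """A malformed on-disk table (message names the offending row/column)."""


@dataclass
class ExpressionMatrix:
    """Gene × sample matrix of log2 expression values.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    Construction validates uniqueness of ids and finiteness of every value.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs >=2 genes and >=2 samples, got {v.shape}"
            )
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ParseError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("non-numeric expression values")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ParseError(
                f"non-finite value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)])


@dataclass
class AnnotationCatalog:
    """Named gene sets, optionally grouped into families.

    ``sets`` maps category name -> set of gene ids; ``families`` maps category
    name -> family label (e.g. signaling / metabolic / gene-class).  Families
    define the multiple-testing units for enrichment.
    """

    sets: dict[str, set[str]]
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty annotation category: {name!r}")

    def family(self, name: str) -> str:
        return self.families.get(name, "default")


@dataclass
class ProbeMap:
    """Many-to-one probe → gene mapping plus an optional replicate map.

    ``replicates`` maps sample (array) id -> patient id; technical replicates
    of the same patient are averaged before probe collapsing.
    """

    probe_to_gene: dict[str, str]
    replicates: dict[str, str] = field(default_factory=dict)

    def patient_of(self, sample_id: str) -> str:
        return self.replicates.get(sample_id, sample_id)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path, orientation: str = "genes") -> ExpressionMatrix:
    """Read a TSV matrix (header row of sample ids, first column gene ids).

    ``orientation="samples"`` transposes after reading for tables stored with
    samples in rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if orientation == "samples":
        df = df.T
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"{path}: non-numeric cell in column {col!r}"
                + (f" at row {bad.index[0]!r}" if len(bad) else "")
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: ProbeMap) -> ExpressionMatrix:
    """Average replicate columns per patient, then probe rows per gene.

    Every probe row must be present in the map; unknown probes are reported
    together in one error.  Output gene count equals the number of distinct
    genes among the mapped probes.
    """
    missing = [p for p in probe_matrix.index if p not in probe_map.probe_to_gene]
    if missing:
        shown = ", ".join(map(repr, missing[:10]))
        raise ParseError(f"probes absent from probe map: {shown}")
    # replicate columns first (patient-level averaging)
    patients = [probe_map.patient_of(s) for s in probe_matrix.columns]
    by_patient = probe_matrix.T.groupby(pd.Index(patients, name="patient")).mean().T
    # then probe rows per gene
    genes = [probe_map.probe_to_gene[p] for p in by_patient.index]
    by_gene = by_patient.groupby(pd.Index(genes, name="gene_id")).mean()
    return ExpressionMatrix(by_gene)


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_table(path) -> pd.DataFrame:
    """Read the sample metadata TSV (fixed column names, 'NA' for missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    if (df["sample_id"] == "").any():
        raise ParseError(f"{path}: empty sample_id")
    df = df.replace(list(NA_TOKENS - {None}), np.nan)
    for col in ("age_years", "time_days"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if (df[col].dropna() < 0).any():
                raise ParseError(f"{path}: negative value in {col}")
    if "status" in df.columns:
        bad = set(df["status"].dropna()) - {"died", "censored"}
        if bad:
            raise ParseError(f"{path}: invalid status values {sorted(bad)}")
    return df.set_index("sample_id", drop=False)


def write_sample_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_annotation_sets(path, family: str | None = None) -> AnnotationCatalog:
    """Read a GMT file: per line, name TAB description TAB gene TAB gene ...

    Duplicate genes within a line are deduplicated.  The optional ``family``
    label is attached to every category (pass one file per family).
    """
    sets: dict[str, set[str]] = {}
    families: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ParseError(f"{path}:{lineno}: category {name!r} has no genes")
            sets[name] = genes
            if family is not None:
                families[name] = family
    return AnnotationCatalog(sets=sets, families=families)


def write_annotation_sets(catalog: AnnotationCatalog, path) -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.sets.items():
            fh.write("\t".join([name, catalog.family(name)] + sorted(genes)) + "\n")
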