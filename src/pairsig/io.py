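"""Readers, writers and the shared data model.

The pipeline exchanges plain tab-separated text: a genes x samples
abundance matrix (FPKM-like, non-negative), a gene -> biotype map (from
a GTF or a two-column table), an immune gene list (one symbol per
line), and a clinical table with survival and covariates.  All readers
accept gzip-compressed files transparently (pandas/gzip sniffing).

Gene symbols are case-normalized to upper case on input so that
expression, annotation and gene-list sources match exactly by symbol;
unmatched symbols are logged, never fatal.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("pairsig")

TUMOR = "tumor"
NORMAL = "normal"

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "read_expression",
    "read_condition_map",
    "read_gtf_biotypes",
    "read_biotype_table",
    "read_gene_list",
    "read_clinical",
    "write_expression",
    "log2p1",
]


def log2p1(x):
    """The pipeline-wide log transform, log2(x + 1), for abundance values."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


# ---------------------------------------------------------------------------
# data model


@dataclass
class ExpressionMatrix:
    """Gene-level abundance matrix with gene and sample metadata.

    ``values`` is a genes x samples DataFrame of finite, non-negative
    abundances; ``gene_biotype`` maps gene symbol -> biotype string
    (genes may be missing from the map); ``sample_condition`` maps every
    sample -> 'tumor' or 'normal'.
    """

    values: pd.DataFrame
    gene_biotype: dict = field(default_factory=dict)
    sample_condition: dict = field(default_factory=dict)

    def __post_init__(self):
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        arr = v.to_numpy()
        if not np.all(np.isfinite(arr)):
            bad = [
                (v.index[i], v.columns[j])
                for i, j in zip(*np.where(~np.isfinite(arr)))
            ]
            raise ValueError(f"non-finite expression values at {bad[:10]}")
        if (arr < 0).any():
            bad = [(v.index[i], v.columns[j]) for i, j in zip(*np.where(arr < 0))]
            raise ValueError(f"negative expression values at {bad[:10]}")
        missing = [s for s in v.columns if s not in self.sample_condition]
        if missing:
            raise ValueError(f"samples without a condition label: {missing[:10]}")
        bad_cond = {
            s: c
            for s, c in self.sample_condition.items()
            if s in v.columns and c not in (TUMOR, NORMAL)
        }
        if bad_cond:
            raise ValueError(f"condition labels must be tumor/normal, got {bad_cond}")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list:
        return [s for s in self.values.columns if self.sample_condition[s] == condition]

    def genes_of_biotype(self, biotype: str) -> list:
        return [g for g in self.values.index if self.gene_biotype.get(g) == biotype]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            values=self.values.loc[genes],
            gene_biotype=self.gene_biotype,
            sample_condition=self.sample_condition,
        )


@dataclass
class ClinicalTable:
    """Per-sample survival and clinical covariates.

    ``data`` is indexed by sample ID with columns ``os_time`` (> 0,
    unit given by ``time_unit``), ``os_event`` in {0, 1}, and whichever
    of ``age``, ``sex`` (female=0, male=1), ``grade``, ``stage``
    (ordinal integers) are available.
    """

    data: pd.DataFrame
    time_unit: str = "days"
    n_dropped_incomplete: int = 0

    def __post_init__(self):
        d = self.data
        if d.index.duplicated().any():
            raise ValueError("duplicate sample IDs in clinical table")
        for col in ("os_time", "os_event"):
            if col not in d.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if (d["os_time"] <= 0).any():
            bad = d.index[d["os_time"] <= 0].tolist()
            raise ValueError(f"non-positive os_time for samples {bad[:10]}")
        if not d["os_event"].isin([0, 1]).all():
            bad = sorted(set(d.loc[~d["os_event"].isin([0, 1]), "os_event"]))
            raise ValueError(f"os_event must be 0 or 1, found {bad}")
        if len(d) == 0:
            raise ValueError("clinical table has zero complete rows")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def covariate_columns(self) -> list:
        return [c for c in self.data.columns if c not in ("os_time", "os_event")]


# ---------------------------------------------------------------------------
# readers


def read_condition_map(path) -> dict:
    """Two-column TSV (sample, condition) -> {sample: 'tumor'|'normal'}."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: condition map needs two columns")
    # tolerate a header row
    if df.iloc[0, 1].strip().lower() not in (TUMOR, NORMAL):
        df = df.iloc[1:]
    return {
        str(s).strip(): str(c).strip().lower()
        for s, c in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def read_expression(path, condition_map_path=None, condition_map=None) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene symbols, header sample IDs).

    Duplicate gene rows are collapsed by their mean (logged).  Every
    sample must appear in the condition map; any mismatch is a hard
    error naming the offenders.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (malformed header?)")
    if not all(df.dtypes.apply(lambda t: np.issubdtype(t, np.number))):
        nonnum = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        raise ValueError(f"{path}: non-numeric sample columns {nonnum}")
    df.index = df.index.astype(str).str.upper()
    n_dup = int(df.index.duplicated().sum())
    if n_dup:
        logger.info("read_expression: collapsed %d duplicate gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()
    df = df.sort_index()

    if condition_map is None:
        if condition_map_path is None:
            raise ValueError("a condition map (path or dict) is required")
        condition_map = read_condition_map(condition_map_path)
    missing = [s for s in df.columns if s not in condition_map]
    if missing:
        raise ValueError(
            f"{path}: samples absent from condition map: {missing[:20]}"
        )
    return ExpressionMatrix(values=df, sample_condition=dict(condition_map))


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_gtf_biotypes(path) -> dict:
    """Extract gene -> biotype from GTF ``gene`` records.

    Attributes are parsed for ``gene_name`` (falling back to
    ``gene_id``) and ``gene_biotype`` (falling back to ``gene_type``,
    the GENCODE spelling).  Gene records lacking any biotype attribute
    are omitted with a logged count; a file with zero parseable gene
    records is a hard error.
    """
    biotypes: dict = {}
    n_gene_rows = 0
    n_missing = 0
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            n_gene_rows += 1
            attrs = dict(_ATTR_RE.findall(fields[8]))
            name = attrs.get("gene_name") or attrs.get("gene_id")
            biotype = attrs.get("gene_biotype") or attrs.get("gene_type")
            if name is None or biotype is None:
                n_missing += 1
                continue
            biotypes[name.upper()] = biotype
    if n_gene_rows == 0:
        raise ValueError(f"{path}: no 'gene' feature records found in GTF")
    if n_missing:
        logger.info("read_gtf_biotypes: %d gene records lacked a biotype", n_missing)
    if not biotypes:
        raise ValueError(f"{path}: no gene records with usable attributes")
    return biotypes


def read_biotype_table(path) -> dict:
    """Two-column TSV (gene, biotype) alternative to a GTF."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: biotype table needs two columns")
    return {str(g).upper(): str(b) for g, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_gene_list(path) -> set:
    """Plain-text gene list, one symbol per line (ImmPort-style)."""
    with _open_text(path) as fh:
        symbols = {line.strip().upper() for line in fh if line.strip()}
    if not symbols:
        raise ValueError(f"{path}: empty gene list")
    return symbols


_SEX_CODES = {"female": 0, "f": 0, "0": 0, "male": 1, "m": 1, "1": 1}


def read_clinical(path, time_unit="days") -> ClinicalTable:
    """Read the clinical TSV; drop rows with missing survival data.

    Required columns: ``sample_id``, ``os_time``, ``os_event``.  Sex is
    recoded female=0 / male=1; grade and stage are kept as given (the
    pipeline expects ordinal integer coding).  Rows missing os_time or
    os_event are dropped and counted; an os_event outside {0,1} is a
    hard error.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    n0 = len(df)
    df = df.dropna(subset=["os_time", "os_event"])
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("read_clinical: dropped %d rows with incomplete survival", n_dropped)
    if len(df) == 0:
        raise ValueError(f"{path}: zero rows with complete survival data")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if "sex" in df.columns:
        sex = df["sex"].astype(str).str.strip().str.lower().map(_SEX_CODES)
        if sex.isna().any():
            bad = sorted(set(df.loc[sex.isna(), "sex"].astype(str)))
            raise ValueError(f"{path}: unrecognized sex codes {bad}")
        df["sex"] = sex.astype(int)
    df["os_time"] = df["os_time"].astype(float)
    ev = df["os_event"]
    if not ev.isin([0, 1, 0.0, 1.0]).all():
        bad = sorted(set(ev[~ev.isin([0, 1, 0.0, 1.0])]))
        raise ValueError(f"{path}: os_event must be 0/1, found {bad}")
    df["os_event"] = ev.astype(int)
    return ClinicalTable(data=df, time_unit=time_unit, n_dropped_incomplete=n_dropped)


def attach_biotypes(expr: ExpressionMatrix, biotype_map: dict) -> ExpressionMatrix:
    """Return a copy of ``expr`` annotated with biotypes; unmatched genes logged."""
    matched = {g: biotype_map[g] for g in expr.values.index if g in biotype_map}
    n_unmatched = len(expr.values.index) - len(matched)
    if n_unmatched:
        logger.info("attach_biotypes: %d genes without annotation", n_unmatched)
    return ExpressionMatrix(
        values=expr.values,
        gene_biotype=matched,
        sample_condition=expr.sample_condition,
    )


# ---------------------------------------------------------------------------
# writers


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def write_condition_map(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcondition\n")
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.sample_condition[s]}\n")


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.data.to_csv(path, sep="\t", index_label="sample_id")
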