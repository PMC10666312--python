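"""Reading, writing, filtering and normalising the model's inputs.

All on-disk formats are plain text: FASTA for sequences, tab-separated
tables for everything else.  The TSV dialects are:

* TSS table          — columns ``chrom, tss, strand, gene_id`` (0-based TSS).
* expression matrix  — first column the entity ID, header row = sample IDs,
                       values are nonnegative raw counts.
* half-life features — ``gene_id`` + the eight named covariate columns
                       (:data:`HALFLIFE_COLUMNS`) + a ``y`` column holding the
                       log-normalised target expression.
* target table       — ``mirna_id, gene_id, cwcs``.
* split file         — ``gene_id, partition`` with partition in
                       {train, val, test}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HALFLIFE_COLUMNS",
    "WindowSpec",
    "GeneRecord",
    "GeneFeatures",
    "ExpressionMatrix",
    "TargetRecord",
    "SplitSpec",
    "WindowError",
    "reverse_complement",
    "extract_window",
    "lognorm",
    "mean_expression",
    "filter_genes",
    "read_targets",
    "write_targets",
    "read_fasta",
    "write_fasta",
    "read_tss_table",
    "read_gene_features",
    "write_gene_features",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_split",
    "write_split",
]

#: Canonical order of the eight mRNA half-life covariates: lengths and CG
#: content of the 5'UTR, ORF and 3'UTR, total intron length, and
#: exon-junction density.
HALFLIFE_COLUMNS = (
    "utr5_len",
    "utr5_gc",
    "orf_len",
    "orf_gc",
    "utr3_len",
    "utr3_gc",
    "intron_len",
    "exon_junction_density",
)

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class WindowError(ValueError):
    """A TSS-centered window does not fit inside its chromosome."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class WindowSpec:
    """Half-open TSS-centered window: ``upstream`` bases before the TSS and
    ``downstream`` bases from the TSS onward, total width ``upstream +
    downstream`` (defaults give the standard 10,500-base window)."""

    upstream: int = 3000
    downstream: int = 7500

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be nonnegative")
        if self.upstream + self.downstream < 1:
            raise ValueError("window must contain at least one base")

    @property
    def width(self) -> int:
        return self.upstream + self.downstream


@dataclass(frozen=True)
class GeneRecord:
    """One gene's TSS-centered sequence window, read 5'→3' along the
    transcript."""

    gene_id: str
    sequence: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        bad = set(self.sequence.upper()) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.gene_id}: sequence contains invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class GeneFeatures:
    """Eight half-life covariates plus the log-normalised target expression."""

    gene_id: str
    halflife: tuple
    y: float

    def __post_init__(self) -> None:
        if len(self.halflife) != 8:
            raise ValueError(
                f"{self.gene_id}: expected 8 half-life values, got {len(self.halflife)}"
            )
        if not all(math.isfinite(v) for v in self.halflife) or not math.isfinite(self.y):
            raise ValueError(f"{self.gene_id}: non-finite feature or target value")


@dataclass(frozen=True)
class TargetRecord:
    """One (miRNA, gene) pair with its Cumulative Weighted Context++ Score.

    More negative CWCS means stronger predicted repression.
    """

    mirna_id: str
    gene_id: str
    cwcs: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.cwcs):
            raise ValueError(f"({self.mirna_id}, {self.gene_id}): CWCS not finite")


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation/test gene-ID partitions."""

    train_ids: tuple
    val_ids: tuple
    test_ids: tuple

    def __post_init__(self) -> None:
        tr, va, te = map(set, (self.train_ids, self.val_ids, self.test_ids))
        if tr & va or tr & te or va & te:
            raise ValueError("split partitions must be pairwise disjoint")

    @property
    def all_ids(self) -> tuple:
        return tuple(self.train_ids) + tuple(self.val_ids) + tuple(self.test_ids)


class ExpressionMatrix:
    """Raw-count matrix (genes or miRNAs × samples), thin wrapper around a
    pandas DataFrame enforcing nonnegativity and unique labels."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            raise ValueError("duplicate row IDs in expression matrix")
        if frame.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in expression matrix")
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("expression matrix contains negative counts")
        self.frame = frame.astype(float)

    @property
    def row_ids(self) -> list:
        return list(self.frame.index)

    @property
    def col_ids(self) -> list:
        return list(self.frame.columns)

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# core operations


def extract_window(
    genome_sequence: str,
    tss_position: int,
    strand: str,
    spec: WindowSpec,
    *,
    pad: bool = False,
    gene_id: str = "?",
) -> str:
    """Extract the TSS-centered window, reading 5'→3' along the transcript.

    Coordinates are 0-based half-open.  On the plus strand the window is
    ``[tss - upstream, tss + downstream)``.  On the minus strand the mirrored
    plus-strand interval ``[tss - downstream, tss + upstream)`` is taken and
    reverse-complemented, so upstream promoter sequence again precedes the
    TSS in the returned string.

    With ``pad=False`` a window extending past either chromosome end raises
    :class:`WindowError`; with ``pad=True`` the missing bases are filled
    with ``N``.
    """
    if strand == "+":
        start, end = tss_position - spec.upstream, tss_position + spec.downstream
    elif strand == "-":
        start, end = tss_position - spec.downstream, tss_position + spec.upstream
    else:
        raise ValueError(f"{gene_id}: strand must be '+' or '-', got {strand!r}")

    n = len(genome_sequence)
    left_deficit = max(0, -start)
    right_deficit = max(0, end - n)
    if (left_deficit or right_deficit) and not pad:
        raise WindowError(
            f"window for gene {gene_id} ([{start}, {end}) on a {n}-base sequence) "
            f"is out of bounds by {left_deficit} base(s) on the left and "
            f"{right_deficit} on the right"
        )
    core = genome_sequence[max(start, 0) : min(end, n)]
    window = "N" * left_deficit + core + "N" * right_deficit
    if strand == "-":
        window = reverse_complement(window)
    return window.upper()


def lognorm(x):
    """Log-normalisation applied to raw counts: ``log10(x + 0.1)``.

    Accepts scalars or arrays; negative input is an error.
    """
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("lognorm requires nonnegative input")
    out = np.log10(arr + 0.1)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def mean_expression(
    m: ExpressionMatrix,
    sample_groups: Mapping[str, Sequence[str]],
    *,
    include_overall: bool = True,
) -> dict:
    """Arithmetic mean of raw counts per (group, row).

    ``sample_groups`` maps a group name (e.g. a cancer subtype) to its sample
    IDs.  With ``include_overall=True`` an ``"overall"`` group is added whose
    mean pools every sample appearing in any group (not the mean of the
    per-group means).
    """
    groups = {g: list(samples) for g, samples in sample_groups.items()}
    if include_overall:
        pooled: list = []
        seen: set = set()
        for samples in groups.values():
            for s in samples:
                if s not in seen:
                    seen.add(s)
                    pooled.append(s)
        groups["overall"] = pooled
    out: dict = {}
    for group, samples in groups.items():
        if not samples:
            raise ValueError(f"sample group {group!r} is empty")
        missing = [s for s in samples if s not in m.frame.columns]
        if missing:
            raise KeyError(f"group {group!r} references unknown samples {missing}")
        means = m.frame[samples].mean(axis=1)
        for row_id, value in means.items():
            out[(group, row_id)] = float(value)
    return out


def filter_genes(
    gene_ids: Sequence[str],
    exclusion_lists: Mapping[str, Iterable[str]] | None = None,
    keep_list: Iterable[str] | None = None,
) -> list:
    """Restrict ``gene_ids`` to ``keep_list`` and drop any gene appearing in
    any exclusion list (e.g. histone genes, Y-chromosome genes), preserving
    the input order.  Used to retain protein-coding genes only."""
    excluded: set = set()
    for ids in (exclusion_lists or {}).values():
        excluded.update(ids)
    keep = None if keep_list is None else set(keep_list)
    result = [
        g for g in gene_ids if g not in excluded and (keep is None or g in keep)
    ]
    if not result:
        warnings.warn("gene filtering removed every gene", stacklevel=2)
    return result


# ---------------------------------------------------------------------------
# file readers/writers


def read_fasta(path) -> list:
    """Read a FASTA of gene windows into :class:`GeneRecord` objects.

    The strand may be stored in the record description as ``strand=+`` /
    ``strand=-``; it defaults to ``+`` (windows are already written in
    transcript orientation)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        strand = "+"
        for token in rec.description.split():
            if token.startswith("strand="):
                strand = token.split("=", 1)[1]
        records.append(GeneRecord(rec.id, str(rec.seq).upper(), strand))
    return records

def write_fasta(records: Sequence[GeneRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description=f"strand={r.strand}")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_tss_table(path) -> pd.DataFrame:
    """TSV with columns chrom, tss (0-based), strand, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    required = {"chrom", "tss", "strand", "gene_id"}
    if missing := required - set(df.columns):
        raise ValueError(f"TSS table {path} is missing columns {sorted(missing)}")
    return df


def read_gene_features(path) -> dict:
    """Half-life feature table → map gene_id → :class:`GeneFeatures`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "y", *HALFLIFE_COLUMNS}
    if missing := required - set(df.columns):
        raise ValueError(f"feature table {path} is missing columns {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        hl = tuple(float(getattr(row, c)) for c in HALFLIFE_COLUMNS)
        out[row.gene_id] = GeneFeatures(row.gene_id, hl, float(row.y))
    return out

def write_gene_features(features: Mapping[str, GeneFeatures], path) -> None:
    rows = [
        {"gene_id": f.gene_id, **dict(zip(HALFLIFE_COLUMNS, f.halflife)), "y": f.y}
        for f in features.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)

def write_expression_matrix(m: ExpressionMatrix, path, id_label: str = "id") -> None:
    m.frame.rename_axis(id_label).to_csv(path, sep="\t")


def read_targets(path, *, duplicate_rule: str = "min") -> list:
    """Parse the miRNA→gene target table.

    Duplicate (miRNA, gene) pairs are collapsed by ``duplicate_rule``:
    ``"min"`` (default — keep the most negative score, i.e. the strongest
    predicted repression), ``"max"``, or ``"mean"``.
    """
    if duplicate_rule not in ("min", "max", "mean"):
        raise ValueError(f"unknown duplicate rule {duplicate_rule!r}")
    pairs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["mirna_id", "gene_id"]:
                continue  # header
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            mirna_id, gene_id, raw = parts
            try:
                cwcs = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unparseable CWCS value {raw!r}"
                ) from None
            pairs.setdefault((mirna_id, gene_id), []).append(cwcs)
    reduce = {"min": min, "max": max, "mean": lambda v: sum(v) / len(v)}[duplicate_rule]
    return [
        TargetRecord(mirna, gene, reduce(scores))
        for (mirna, gene), scores in pairs.items()
    ]

def write_targets(records: Sequence[TargetRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\tcwcs\n")
        for r in records:
            fh.write(f"{r.mirna_id}\t{r.gene_id}\t{r.cwcs!r}\n")


def read_split(path) -> SplitSpec:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if missing := {"gene_id", "partition"} - set(df.columns):
        raise ValueError(f"split file {path} is missing columns {sorted(missing)}")
    bad = set(df["partition"]) - {"train", "val", "test"}
    if bad:
        raise ValueError(f"split file {path}: unknown partitions {sorted(bad)}")
    part = lambda p: tuple(df.loc[df["partition"] == p, "gene_id"])
    return SplitSpec(part("train"), part("val"), part("test"))

def write_split(split: SplitSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tpartition\n")
        for name, ids in (("train", split.train_ids), ("val", split.val_ids), ("test", split.test_ids)):
            for g in ids:
                fh.write(f"{g}\t{name}\n")
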