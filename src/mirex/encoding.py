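"""Numeric encodings: one-hot sequence matrices, per-gene miRNA expression
vectors, and assembly of model-ready train/val/test batches."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneFeatures, GeneRecord, SplitSpec, TargetRecord

__all__ = [
    "BASE_ORDER",
    "one_hot",
    "decode_one_hot",
    "MiRNAFeatureVector",
    "build_mirna_vector",
    "Batch",
    "ModelData",
    "assemble_dataset",
]

#: Fixed column order of the one-hot encoding.
BASE_ORDER = "ACGT"

_ONE_HOT_LUT = np.zeros(256, dtype=np.int64)  # 0..3 = A,C,G,T; 4 = N (zero row)
_ONE_HOT_LUT[:] = -1
for _i, _b in enumerate(BASE_ORDER):
    _ONE_HOT_LUT[ord(_b)] = _i
    _ONE_HOT_LUT[ord(_b.lower())] = _i
_ONE_HOT_LUT[ord("N")] = 4
_ONE_HOT_LUT[ord("n")] = 4

_ROWS = np.vstack([np.eye(4, dtype=np.float32), np.zeros((1, 4), dtype=np.float32)])


def one_hot(sequence: str) -> np.ndarray:
    """Encode a DNA sequence as a W×4 matrix, columns ordered A,C,G,T.

    Case-insensitive; ``N`` (unknown base) maps to the all-zero row.  Any
    other character raises ``ValueError`` naming its position.
    """
    codes = _ONE_HOT_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"invalid character {sequence[pos]!r} at position {pos} "
            f"(alphabet is A/C/G/T/N)"
        )
    return _ROWS[codes]


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; zero rows decode to ``N``."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError("expected a W×4 matrix")
    letters = np.array(list(BASE_ORDER + "N"))
    codes = np.where(matrix.sum(axis=1) == 0, 4, matrix.argmax(axis=1))
    return "".join(letters[codes])


@dataclass(frozen=True)
class MiRNAFeatureVector:
    """Per-gene miRNA feature vector x: x_i is the expression level of
    miRNA i if that miRNA targets the gene, and exactly 0 otherwise.

    The targeting strength (CWCS) is deliberately *not* encoded here; it is
    consumed only by the selection procedure.
    """

    gene_id: str
    values: np.ndarray


def build_mirna_vector(
    gene_id: str,
    mirna_order: Sequence[str],
    targets: Sequence[TargetRecord],
    mirna_expr: Mapping[str, float],
) -> MiRNAFeatureVector:
    """Build the miRNA feature vector for one gene.

    ``mirna_order`` fixes the (documented) column order.  Every ordered
    miRNA must have an expression value in ``mirna_expr``.
    """
    missing = [m for m in mirna_order if m not in mirna_expr]
    if missing:
        raise KeyError(f"no expression value for ordered miRNA(s) {missing}")
    targeting = {t.mirna_id for t in targets if t.gene_id == gene_id}
    values = np.array(
        [mirna_expr[m] if m in targeting else 0.0 for m in mirna_order],
        dtype=np.float32,
    )
    return MiRNAFeatureVector(gene_id, values)


@dataclass
class Batch:
    """One model-ready partition: aligned arrays over the same genes."""

    gene_ids: list
    X: np.ndarray  # (N, W, 4) one-hot sequence
    H: np.ndarray  # (N, 8) half-life covariates
    M: np.ndarray  # (N, K) miRNA feature vectors (K may be 0)
    y: np.ndarray  # (N,) log-normalised expression targets

    def __len__(self) -> int:
        return len(self.gene_ids)

    def subset_mirnas(self, column_idx: Sequence[int]) -> "Batch":
        """A view of this batch restricted to the given miRNA columns."""
        return Batch(self.gene_ids, self.X, self.H, self.M[:, list(column_idx)], self.y)


@dataclass
class ModelData:
    """The three partitions plus the miRNA column order they share."""

    train: Batch
    val: Batch
    test: Batch
    mirna_order: list

    def subset_mirnas(self, mirna_ids: Sequence[str]) -> "ModelData":
        """Restrict the miRNA block to ``mirna_ids`` (in the given order);
        an empty list yields K=0 batches (the baseline configuration)."""
        idx = [self.mirna_order.index(m) for m in mirna_ids]
        return ModelData(
            self.train.subset_mirnas(idx),
            self.val.subset_mirnas(idx),
            self.test.subset_mirnas(idx),
            list(mirna_ids),
        )

    @property
    def k_mirnas(self) -> int:
        return len(self.mirna_order)

    @property
    def window(self) -> int:
        return self.train.X.shape[1]


def assemble_dataset(
    records: Sequence[GeneRecord],
    features: Mapping[str, GeneFeatures],
    vectors: Mapping[str, MiRNAFeatureVector],
    split: SplitSpec,
    mirna_order: Sequence[str] = (),
) -> ModelData:
    """Assemble deterministic train/val/test batches.

    Genes within each partition are sorted by gene ID, so the result is
    invariant to the input record order.  A gene named by the split but
    missing its sequence, features, or (when K>0) miRNA vector is an error.
    """
    by_id = {r.gene_id: r for r in records}
    k = len(mirna_order)

    def build(ids: Sequence[str]) -> Batch:
        ordered = sorted(ids)
        missing_seq = [g for g in ordered if g not in by_id]
        missing_feat = [g for g in ordered if g not in features]
        missing_vec = [g for g in ordered if k > 0 and g not in vectors]
        if missing_seq or missing_feat or missing_vec:
            raise KeyError(
                "split references genes with missing blocks: "
                f"sequence={missing_seq}, features={missing_feat}, "
                f"mirna_vector={missing_vec}"
            )
        X = np.stack([one_hot(by_id[g].sequence) for g in ordered]) if ordered else np.zeros((0, 0, 4), np.float32)
        H = np.array([features[g].halflife for g in ordered], dtype=np.float32).reshape(len(ordered), 8)
        if k:
            M = np.stack([np.asarray(vectors[g].values, dtype=np.float32) for g in ordered])
            if M.shape[1] != k:
                raise ValueError(f"miRNA vectors have {M.shape[1]} entries, expected {k}")
        else:
            M = np.zeros((len(ordered), 0), dtype=np.float32)
        y = np.array([features[g].y for g in ordered], dtype=np.float32)
        return Batch(ordered, X, H, M, y)

    return ModelData(
        build(split.train_ids), build(split.val_ids), build(split.test_ids), list(mirna_order)
    )
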