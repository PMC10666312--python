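"""Residual-correlation miRNA selection.

The sequence+half-life baseline cannot see post-transcriptional repression,
so genes repressed by an active miRNA should sit below its prediction:
their residuals (truth − predicted) should be negative, and more negative
where TargetScan's CWCS is more negative (stronger predicted binding).
For each miRNA we therefore compute the Spearman rank correlation between
the residuals of its target genes and the corresponding CWCS values, and
select the top-k miRNAs by that correlation.

Two modes exist: ``signed`` correlates the residuals themselves (direct
repression); ``absolute`` correlates |residual| with CWCS, catching
indirect regulation that can push expression in either direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import TargetRecord

__all__ = [
    "SelectionResult",
    "spearman",
    "rank_mirnas",
    "select_top_k",
    "residuals_from_baseline",
    "selection_to_tsv",
]


def spearman(a, b) -> float:
    """Spearman rank correlation (average ranks for ties), in [−1, 1].

    Vectors must have equal length ≥ 3.  If either vector has zero rank
    variance the correlation is undefined and ``ValueError`` is raised;
    callers treat such miRNAs as ineligible.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("spearman expects two equal-length 1-D vectors")
    if a.size < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("spearman undefined: zero rank variance")
    rho = stats.spearmanr(a, b).statistic
    if not np.isfinite(rho):  # pragma: no cover - guarded above
        raise ValueError("spearman correlation is undefined for this input")
    return float(rho)


@dataclass
class SelectionResult:
    """Ranking of miRNAs by residual–CWCS correlation.

    ``ranked`` holds ``(mirna_id, rho, n_target_genes)`` sorted by rho
    descending (ties broken by lexicographic miRNA ID); ``selected`` is the
    chosen top-k."""

    mode: str
    ranked: list
    selected: list
    k: int


def rank_mirnas(
    residuals: Mapping[str, float],
    targets: Sequence[TargetRecord],
    *,
    mode: str = "signed",
    min_targets: int = 10,
    k: int = 10,
) -> SelectionResult:
    """Rank every miRNA by the Spearman correlation between its target
    genes' residuals (or |residuals| in ``absolute`` mode) and their CWCS.

    Only target genes present in ``residuals`` count; miRNAs with fewer
    than ``min_targets`` usable genes, or with an undefined correlation,
    are ineligible.  Returns the full ranking plus the top-``k`` selection.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown selection mode {mode!r}")
    if min_targets < 3:
        raise ValueError("min_targets must be >= 3 (Spearman needs 3 points)")
    if not targets:
        warnings.warn("empty target table; nothing to rank", stacklevel=2)
        return SelectionResult(mode, [], [], k)

    by_mirna: dict = {}
    for t in targets:
        if t.gene_id in residuals:
            by_mirna.setdefault(t.mirna_id, []).append((t.gene_id, t.cwcs))

    ranked = []
    for mirna_id in sorted(by_mirna):
        pairs = by_mirna[mirna_id]
        if len(pairs) < min_targets:
            continue
        res = np.array([residuals[g] for g, _ in pairs])
        if mode == "absolute":
            res = np.abs(res)
        cwcs = np.array([c for _, c in pairs])
        try:
            rho = spearman(res, cwcs)
        except ValueError:
            continue  # undefined correlation -> ineligible
        ranked.append((mirna_id, rho, len(pairs)))
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return SelectionResult(mode, ranked, select_top_k_ranked(ranked, k), k)


def select_top_k_ranked(ranked: Sequence[tuple], k: int) -> list:
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} eligible miRNAs for a top-{k} selection",
            stacklevel=2,
        )
    return [mirna_id for mirna_id, _, _ in ranked[:k]]


def select_top_k(result: SelectionResult, k: int = 10) -> list:
    """First ``k`` miRNA IDs of the ranking (all of them, with a warning,
    if fewer are eligible)."""
    return select_top_k_ranked(result.ranked, k)


def residuals_from_baseline(run, partitions: Sequence[str] = ("train", "val")) -> dict:
    """Residual map (gene → truth − predicted) of a baseline run restricted
    to the given partitions.  Test genes are excluded by default so the
    selection never sees held-out information."""
    res = run.residual_map(partitions)
    if not res:
        raise ValueError(f"baseline run has no residuals in partitions {partitions}")
    return res


def selection_to_tsv(result: SelectionResult, path) -> None:
    """Export the ranking (mirna_id, rho, n_targets, selected flag)."""
    chosen = set(result.selected)
    with open(path, "w") as fh:
        fh.write("mirna_id\trho\tn_targets\tselected\n")
        for mirna_id, rho, n in result.ranked:
            fh.write(f"{mirna_id}\t{rho:.6f}\t{n}\t{int(mirna_id in chosen)}\n")
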