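"""Synthetic data with known ground truth.

The generator emulates the statistical structure the expression model
assumes, at desk scale and with every causal component recorded:

* promoter windows of i.i.d. uniform bases, a subset of which carry a
  planted motif (sampled from a PWM) that adds a fixed coefficient to the
  gene's log-expression;
* eight half-life covariates, standard normal, contributing linearly;
* a panel of miRNAs with raw-count expression across samples.  A planted
  subset represses its target genes: each (planted miRNA, gene) pair gets
  a TargetScan-like CWCS drawn as −|Normal|, and subtracts
  ``repression_scale · |CWCS| · (miRNA log-expression)`` from the gene's
  log-expression.  Decoy miRNAs receive target records with CWCS drawn from
  the same distribution but have no causal effect;
* Gaussian noise on the log scale.

Everything is reproducible from the seed, and all outputs are written in
the package's standard text formats so they re-parse losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import (
    ExpressionMatrix,
    GeneFeatures,
    GeneRecord,
    SplitSpec,
    TargetRecord,
    WindowSpec,
    lognorm,
)

__all__ = ["SimConfig", "SyntheticTruth", "SimOutput", "default_pwm", "generate", "truth_eval", "write_dir", "load_dir"]

_BASES = np.array(list("ACGT"))


def default_pwm(consensus: str = "TGACGTCA", strength: float = 0.85) -> np.ndarray:
    """A position weight matrix concentrated on ``consensus``: probability
    ``strength`` on the consensus base, the rest spread uniformly."""
    pwm = np.full((len(consensus), 4), (1.0 - strength) / 3.0)
    for i, base in enumerate(consensus):
        pwm[i, "ACGT".index(base)] = strength
    return pwm


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen.

    Defaults give a desk-scale dataset: 1,200 genes with 1,000-base windows
    (300 upstream + 700 downstream of the TSS), 20 miRNAs of which 5 are
    planted repressors with 50 target genes each, one planted motif, and
    log-scale Gaussian noise of SD 0.3.
    """

    n_genes: int = 1200
    window: WindowSpec = field(default_factory=lambda: WindowSpec(300, 700))
    n_mirnas: int = 20
    n_planted: int = 5
    targets_per_mirna: int = 50
    motif_effects: tuple = ((None, 0.5),)  # None -> default_pwm()
    motif_prob: float = 0.3
    halflife_coeffs: tuple = (0.5, -0.3, 0.4, 0.2, -0.2, 0.3, -0.4, 0.1)
    repression_scale: float = 1.5
    noise_sd: float = 0.3
    n_samples: int = 8
    split_fracs: tuple = (0.7, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_mirnas:
            raise ValueError("n_planted cannot exceed n_mirnas")
        if self.targets_per_mirna > self.n_genes:
            raise ValueError("targets_per_mirna cannot exceed n_genes")
        if self.noise_sd < 0 or self.repression_scale < 0:
            raise ValueError("noise_sd and repression_scale must be nonnegative")
        if len(self.halflife_coeffs) != 8:
            raise ValueError("halflife_coeffs must have 8 entries")
        if abs(sum(self.split_fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: the planted miRNA set and every
    gene's deterministic expression components (``y = motif + halflife +
    repression + noise``, repression signed ≤ 0)."""

    planted_mirnas: list
    motif_term: dict
    halflife_term: dict
    repression_term: dict
    noise: dict
    y: dict
    pair_contributions: dict  # mirna_id -> {gene_id: signed contribution to y}


@dataclass
class SimOutput:
    records: list
    features: dict
    mirna_expr: ExpressionMatrix
    targets: list
    split: SplitSpec
    truth: SyntheticTruth
    config: SimConfig


def generate(cfg: SimConfig) -> SimOutput:
    """Generate a complete synthetic dataset; deterministic in ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    W = cfg.window.width
    n = cfg.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    mirna_ids = [f"mir{i:03d}" for i in range(cfg.n_mirnas)]
    planted = sorted(rng.choice(mirna_ids, size=cfg.n_planted, replace=False).tolist())
    decoys = [m for m in mirna_ids if m not in planted]

    # sequences + planted motifs
    seq_codes = rng.integers(0, 4, size=(n, W))
    motif_term = np.zeros(n)
    for pwm, coeff in cfg.motif_effects:
        pwm = default_pwm() if pwm is None else np.asarray(pwm, dtype=float)
        carriers = rng.random(n) < cfg.motif_prob
        positions = rng.integers(0, W - pwm.shape[0] + 1, size=n)
        for g in np.nonzero(carriers)[0]:
            for j in range(pwm.shape[0]):
                seq_codes[g, positions[g] + j] = rng.choice(4, p=pwm[j])
        motif_term[carriers] += coeff
    records = [
        GeneRecord(gene_ids[i], "".join(_BASES[seq_codes[i]]), "+") for i in range(n)
    ]

    # half-life covariates, linear contribution
    H = rng.standard_normal((n, 8))
    hl_term = H @ np.asarray(cfg.halflife_coeffs)

    # miRNA expression: raw Poisson counts whose log-normalised mean sits on
    # a log10 scale comparable to real panels (≈ 0.9–1.5)
    target_log_expr = rng.normal(1.2, 0.3, size=cfg.n_mirnas)
    lam = np.maximum(10.0**target_log_expr - 0.1, 0.0)
    counts = rng.poisson(lam[:, None], size=(cfg.n_mirnas, cfg.n_samples)).astype(float)
    mirna_expr = ExpressionMatrix(
        pd.DataFrame(counts, index=mirna_ids, columns=[f"s{j:02d}" for j in range(cfg.n_samples)])
    )
    realized_log_expr = {
        m: lognorm(float(counts[i].mean())) for i, m in enumerate(mirna_ids)
    }

    # targeting: planted miRNAs repress; decoys get look-alike records
    targets: list = []
    repression = np.zeros(n)
    pair_contrib: dict = {}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for m in mirna_ids:
        chosen = rng.choice(gene_ids, size=cfg.targets_per_mirna, replace=False)
        cwcs = -np.abs(rng.normal(0.0, 0.4, size=cfg.targets_per_mirna))
        for g, c in zip(chosen, cwcs):
            targets.append(TargetRecord(m, g, float(c)))
        if m in planted:
            contrib = cfg.repression_scale * cwcs * realized_log_expr[m]  # signed <= 0
            pair_contrib[m] = {g: float(v) for g, v in zip(chosen, contrib)}
            for g, v in zip(chosen, contrib):
                repression[gene_index[g]] += v

    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    y = motif_term + hl_term + repression + noise

    features = {
        g: GeneFeatures(g, tuple(float(v) for v in H[i]), float(y[i]))
        for i, g in enumerate(gene_ids)
    }

    order = rng.permutation(n)
    n_train = int(round(cfg.split_fracs[0] * n))
    n_val = int(round(cfg.split_fracs[1] * n))
    shuffled = [gene_ids[i] for i in order]
    split = SplitSpec(
        tuple(shuffled[:n_train]),
        tuple(shuffled[n_train : n_train + n_val]),
        tuple(shuffled[n_train + n_val :]),
    )

    truth = SyntheticTruth(
        planted_mirnas=planted,
        motif_term={g: float(motif_term[i]) for i, g in enumerate(gene_ids)},
        halflife_term={g: float(hl_term[i]) for i, g in enumerate(gene_ids)},
        repression_term={g: float(repression[i]) for i, g in enumerate(gene_ids)},
        noise={g: float(noise[i]) for i, g in enumerate(gene_ids)},
        y={g: float(y[i]) for i, g in enumerate(gene_ids)},
        pair_contributions=pair_contrib,
    )
    return SimOutput(records, features, mirna_expr, targets, split, truth, cfg)


def truth_eval(selection, truth: SyntheticTruth) -> tuple:
    """(recovered count, precision, recall) of a selection against the
    planted miRNA set."""
    selected = list(selection.selected if hasattr(selection, "selected") else selection)
    planted = set(truth.planted_mirnas)
    recovered = sum(1 for m in selected if m in planted)
    precision = recovered / len(selected) if selected else 0.0
    recall = recovered / len(planted) if planted else 0.0
    return recovered, precision, recall


def write_dir(sim: SimOutput, out_dir) -> Path:
    """Write a self-contained dataset directory (sequences.fa, halflife.tsv,
    mirna_expr.tsv, targets.tsv, split.tsv, truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iof.write_fasta(sim.records, out / "sequences.fa")
    iof.write_gene_features(sim.features, out / "halflife.tsv")
    iof.write_expression_matrix(sim.mirna_expr, out / "mirna_expr.tsv", id_label="mirna_id")
    iof.write_targets(sim.targets, out / "targets.tsv")
    iof.write_split(sim.split, out / "split.tsv")
    cfg = asdict(sim.config)
    cfg["window"] = {"upstream": sim.config.window.upstream, "downstream": sim.config.window.downstream}
    cfg["motif_effects"] = [
        [None if pwm is None else np.asarray(pwm).tolist(), coeff]
        for pwm, coeff in sim.config.motif_effects
    ]
    with open(out / "truth.json", "w") as fh:
        json.dump({"config": cfg, **asdict(sim.truth)}, fh, indent=1, sort_keys=True)
    return out


def load_dir(data_dir):
    """Re-read a dataset directory written by :func:`write_dir` (truth is
    returned as a :class:`SyntheticTruth` when truth.json is present)."""
    d = Path(data_dir)
    records = iof.read_fasta(d / "sequences.fa")
    features = iof.read_gene_features(d / "halflife.tsv")
    mirna_expr = iof.read_expression_matrix(d / "mirna_expr.tsv")
    targets = iof.read_targets(d / "targets.tsv")
    split = iof.read_split(d / "split.tsv")
    truth = None
    truth_path = d / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            payload = json.load(fh)
        payload.pop("config", None)
        truth = SyntheticTruth(**payload)
    return records, features, mirna_expr, targets, split, truth
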