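"""Residual-CWCS Spearman ranking and top-k miRNA selection."""

import numpy as np
import pytest

from mirex.io_formats import TargetRecord
from mirex.selection import (
    rank_mirnas,
    residuals_from_baseline,
    select_top_k,
    selection_to_tsv,
    spearman,
)
from .conftest import make_stub_run


def brute_force_spearman(a, b):
    """Average-rank Spearman via explicit rank construction + the Pearson
    sum formula; independent of scipy."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                ranks[order[t]] = mean_rank
            i = j + 1
        return ranks

    ra, rb = avg_ranks(list(a)), avg_ranks(list(b))
    n = len(ra)
    ma, mb = sum(ra) / n, sum(rb) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = (sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb)) ** 0.5
    return num / den


class TestSpearman:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 2, 3), (10, 20, 30), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3), (3, 1, 2), -0.5),
        ],
    )
    def test_known_triples(self, a, b, expected):
        assert spearman(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            a = rng.integers(0, 6, size=n).astype(float)  # many ties
            b = rng.normal(size=n)
            if np.unique(a).size < 2:
                continue
            assert spearman(a, b) == pytest.approx(brute_force_spearman(a, b), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3"):
            spearman([1, 2], [3, 4])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 1, 1], [1, 2, 3])


def _screen(seed=0, n_mirnas=20, n_planted=5, n_targets=50, slope=0.8, noise=0.05):
    """Synthetic ranking fixture: planted miRNAs' residuals follow their
    CWCS, decoys' residuals are independent."""
    rng = np.random.default_rng(seed)
    mirnas = [f"m{i:02d}" for i in range(n_mirnas)]
    planted = mirnas[:n_planted]
    residuals, targets = {}, []
    gid = 0
    for m in mirnas:
        for _ in range(n_targets):
            g = f"g{gid:04d}"
            gid += 1
            cwcs = -abs(rng.normal(0, 0.5))
            if m in planted:
                residuals[g] = slope * cwcs + rng.normal(0, noise)
            else:
                residuals[g] = rng.normal(0, 0.5)
            targets.append(TargetRecord(m, g, cwcs))
    return residuals, targets, planted, mirnas


class TestRankMirnas:
    def test_monotone_residuals_rank_first(self):
        cwcs = [-0.9, -0.5, -0.3, -0.1]
        targets = [TargetRecord("mA", f"g{i}", c) for i, c in enumerate(cwcs)]
        targets += [TargetRecord("mB", f"g{i}", c) for i, c in enumerate(cwcs)]
        residuals = {f"g{i}": c for i, c in enumerate(cwcs)}  # increasing in cwcs
        result = rank_mirnas(residuals, targets, min_targets=3, k=1)
        assert result.ranked[0][1] == pytest.approx(1.0)

    def test_min_targets_eligibility(self):
        targets = [TargetRecord("small", "g0", -0.5), TargetRecord("small", "g1", -0.2)]
        targets += [TargetRecord("big", f"g{i}", -0.1 * (i + 1)) for i in range(5)]
        residuals = {f"g{i}": float(i) for i in range(5)}
        result = rank_mirnas(residuals, targets, min_targets=3, k=10)
        assert [m for m, _, _ in result.ranked] == ["big"]

    def test_planted_screen_recovers_all_planted_in_top5(self):
        residuals, targets, planted, _ = _screen(seed=1)
        result = rank_mirnas(residuals, targets, mode="signed", min_targets=10, k=5)
        assert set(result.selected) == set(planted)

    def test_every_rho_matches_brute_force_oracle(self):
        residuals, targets, _, mirnas = _screen(seed=2)
        result = rank_mirnas(residuals, targets, mode="signed", min_targets=10, k=10)
        assert len(result.ranked) == len(mirnas)
        by_mirna = {}
        for t in targets:
            by_mirna.setdefault(t.mirna_id, []).append((residuals[t.gene_id], t.cwcs))
        for mirna_id, rho, n in result.ranked:
            res, cw = zip(*by_mirna[mirna_id])
            assert n == len(res)
            assert rho == pytest.approx(brute_force_spearman(res, cw), abs=1e-12)

    def test_ranking_sorted_non_increasing(self):
        residuals, targets, _, _ = _screen(seed=3)
        result = rank_mirnas(residuals, targets, min_targets=10, k=10)
        rhos = [r for _, r, _ in result.ranked]
        assert rhos == sorted(rhos, reverse=True)

    def test_signed_and_absolute_agree_for_nonnegative_residuals(self):
        residuals, targets, _, _ = _screen(seed=4)
        residuals = {g: abs(r) for g, r in residuals.items()}
        signed = rank_mirnas(residuals, targets, mode="signed", min_targets=10, k=10)
        absolute = rank_mirnas(residuals, targets, mode="absolute", min_targets=10, k=10)
        assert signed.ranked == absolute.ranked

    def test_empty_target_table_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            result = rank_mirnas({"g": 1.0}, [], k=10)
        assert result.ranked == [] and result.selected == []

    def test_export_tsv(self, tmp_path):
        residuals, targets, _, _ = _screen(seed=5)
        result = rank_mirnas(residuals, targets, min_targets=10, k=10)
        path = tmp_path / "sel.tsv"
        selection_to_tsv(result, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "mirna_id\trho\tn_targets\tselected"
        assert sum(line.endswith("\t1") for line in lines[1:]) == 10


class TestSelectTopK:
    def test_exact_tie_broken_lexicographically(self):
        cwcs = [-0.8, -0.6, -0.4, -0.2]
        residuals = {f"g{i}": c for i, c in enumerate(cwcs)}
        # zeta and alpha have identical (gene, cwcs) pairs -> identical rho
        targets = [TargetRecord("zeta", f"g{i}", c) for i, c in enumerate(cwcs)]
        targets += [TargetRecord("alpha", f"g{i}", c) for i, c in enumerate(cwcs)]
        targets += [TargetRecord("mid", f"g{i}", -c) for i, c in enumerate(cwcs)]
        result = rank_mirnas(residuals, targets, min_targets=3, k=1)
        assert result.ranked[0][0] == "alpha" and result.ranked[1][0] == "zeta"
        assert result.selected == ["alpha"]

    def test_k_larger_than_eligible_returns_all(self):
        residuals, targets, _, mirnas = _screen(seed=6, n_mirnas=4, n_planted=1)
        result = rank_mirnas(residuals, targets, min_targets=10, k=10)
        with pytest.warns(UserWarning, match="eligible"):
            chosen = select_top_k(result, 10)
        assert sorted(chosen) == sorted(mirnas)

    def test_top_k_is_prefix_of_ranking(self):
        residuals, targets, _, _ = _screen(seed=7)
        result = rank_mirnas(residuals, targets, min_targets=10, k=10)
        assert select_top_k(result, 3) == [m for m, _, _ in result.ranked[:3]]


class TestResidualsFromBaseline:
    def test_perfect_predictions_give_zero_residuals(self):
        run = make_stub_run({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
        assert residuals_from_baseline(run) == {"a": 0.0, "b": 0.0}

    def test_residual_definition(self):
        run = make_stub_run({"a": 2.0, "b": 0.0}, {"a": 1.0, "b": 1.0})
        assert residuals_from_baseline(run) == {"a": 1.0, "b": -1.0}

    def test_test_partition_excluded_by_default(self):
        run = make_stub_run(
            {"a": 1.0, "b": 2.0}, {"a": 0.5, "b": 0.5},
            partition={"a": "train", "b": "test"},
        )
        assert residuals_from_baseline(run) == {"a": 0.5}

    def test_averaging_runs_equals_residuals_of_averaged_predictions(self):
        y = {"a": 1.0, "b": -1.0, "c": 0.5}
        preds = [
            {"a": 0.2, "b": -0.1, "c": 0.0},
            {"a": 0.4, "b": -0.6, "c": 1.0},
            {"a": 0.9, "b": 0.1, "c": 0.2},
        ]
        runs = [make_stub_run(y, p) for p in preds]
        maps = [residuals_from_baseline(r) for r in runs]
        averaged = {g: np.mean([m[g] for m in maps]) for g in y}
        mean_pred = {g: np.mean([p[g] for p in preds]) for g in y}
        expected = {g: y[g] - mean_pred[g] for g in y}
        for g in y:
            assert averaged[g] == pytest.approx(expected[g], abs=1e-12)
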