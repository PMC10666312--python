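"""Model evaluation: R², best-run aggregation with t confidence intervals,
and the four-variant comparison with Welch significance tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VARIANTS",
    "r_squared",
    "VariantReport",
    "aggregate_runs",
    "compare_variants",
    "plot_variant_reports",
]

#: Canonical variant order: sequence+half-life baseline, all miRNAs, the
#: signed-correlation selection, the absolute-correlation selection.
VARIANTS = ("baseline", "all_mirna", "mirex", "abs_corr")


def r_squared(y, y_hat) -> float:
    """Coefficient of determination, R² = 1 − RSS/TSS.

    RSS = Σ(yᵢ − ŷᵢ)², TSS = Σ(yᵢ − ȳ)².  Requires at least two
    observations and a non-constant ``y`` (TSS > 0).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    if y.size < 2:
        raise ValueError("R^2 requires at least 2 observations")
    rss = float(np.sum((y - y_hat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("R^2 undefined: y is constant (TSS = 0)")
    return 1.0 - rss / tss


@dataclass
class VariantReport:
    """Aggregated result for one model variant: the retained per-run test
    R² values, their mean, a 95% Student-t confidence interval, and (after
    :func:`compare_variants`) Welch p-values against the other variants."""

    variant: str
    r2_runs: list
    mean_r2: float
    ci95: tuple
    pairwise_p: dict = field(default_factory=dict)
    degenerate: bool = False

    @property
    def n_runs(self) -> int:
        return len(self.r2_runs)


def aggregate_runs(
    runs: Sequence,
    *,
    variant: str = "baseline",
    top_n: int = 10,
    rank_by: str = "val_r2",
) -> VariantReport:
    """Keep the best ``top_n`` runs by validation performance and summarise
    their test R².

    ``rank_by`` is ``"val_r2"`` (higher is better, default) or
    ``"val_loss"`` (lower best validation MSE is better).  The 95%
    confidence interval is Student-t with ``n − 1`` degrees of freedom; a
    single retained run gets a degenerate (mean, mean) interval.
    """
    if not runs:
        raise ValueError("aggregate_runs needs at least one run")
    if rank_by == "val_r2":
        key = lambda r: -r.r2_val
    elif rank_by == "val_loss":
        key = lambda r: r.best_val_loss
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    if len(runs) < top_n:
        warnings.warn(
            f"only {len(runs)} runs available; aggregating all of them",
            stacklevel=2,
        )
    kept = sorted(runs, key=key)[:top_n]
    r2 = np.array([r.r2_test for r in kept], dtype=float)
    mean = float(r2.mean())
    if len(r2) > 1:
        sem = float(r2.std(ddof=1) / np.sqrt(len(r2)))
        half = float(stats.t.ppf(0.975, df=len(r2) - 1)) * sem
    else:
        half = 0.0
    return VariantReport(variant, [float(v) for v in r2], mean, (mean - half, mean + half))


def compare_variants(reports: Sequence[VariantReport]) -> dict:
    """Two-sided Welch t-tests on the retained R² samples for every variant
    pair.  P-values are reported raw (no multiple-testing correction).
    Returns ``{(a, b): p}`` and also fills each report's ``pairwise_p``.
    """
    for rep in reports:
        if rep.n_runs < 2:
            raise ValueError(f"variant {rep.variant!r} has fewer than 2 retained runs")
    table: dict = {}
    for i, a in enumerate(reports):
        for b in reports[i + 1 :]:
            xa, xb = np.asarray(a.r2_runs), np.asarray(b.r2_runs)
            if np.ptp(xa) == 0 and np.ptp(xb) == 0:
                p = 1.0 if np.allclose(xa.mean(), xb.mean()) else float("nan")
                if np.isnan(p):
                    warnings.warn(
                        f"degenerate zero variance in both {a.variant} and {b.variant}; "
                        "p-value undefined",
                        stacklevel=2,
                    )
            else:
                p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
            table[(a.variant, b.variant)] = p
            table[(b.variant, a.variant)] = p
            a.pairwise_p[b.variant] = p
            b.pairwise_p[a.variant] = p
    return table


def plot_variant_reports(reports: Sequence[VariantReport], path=None, title=None):
    """Bar plot of mean test R² per variant with 95% CI whiskers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    names = [r.variant for r in reports]
    means = [r.mean_r2 for r in reports]
    errs = [
        [r.mean_r2 - r.ci95[0] for r in reports],
        [r.ci95[1] - r.mean_r2 for r in reports],
    ]
    ax.bar(names, means, yerr=errs, capsize=4, color="#4878a8")
    ax.set_ylabel("test $R^2$ (mean of retained runs)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
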