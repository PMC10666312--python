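"""The expression regressor: model and results objects.

:class:`ExpressionCNN` wraps a dataset (:class:`~mirex.encoding.ModelData`)
and an architecture (:class:`ModelConfig`); :meth:`ExpressionCNN.fit` trains
it with SGD on the mean-squared error under early stopping and returns a
:class:`CNNResults` carrying predictions, residuals, the validation-loss
curve and test R².

The architecture is the standard promoter-sequence backbone: stacked
convolution/ReLU/max-pool blocks over the one-hot TSS window, whose
flattened output is concatenated with the eight mRNA half-life covariates
and the per-gene miRNA expression vector before two dense layers produce
the scalar log-expression prediction.  With ``k_mirnas = 0`` the network is
exactly the sequence+half-life baseline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np

from ._nn import SGD, Net
from .encoding import Batch, ModelData
from .evaluation import r_squared

__all__ = ["ModelConfig", "TrainConfig", "ExpressionCNN", "CNNResults"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_blocks`` is a sequence of ``(filters, kernel_width, dilation,
    pool_width)`` tuples; pooling is non-overlapping max-pooling.  The
    defaults follow the published promoter backbone (two conv blocks, a
    64-unit dense layer); :meth:`toy` gives a small single-block preset
    whose training finishes in seconds on one CPU core.
    """

    window: int = 10500
    conv_blocks: tuple = ((128, 6, 1, 30), (32, 9, 1, 10))
    dense_units: int = 64
    dropout: float = 0.0
    k_mirnas: int = 0
    standardize_halflife: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.k_mirnas < 0:
            raise ValueError("k_mirnas must be >= 0")
        self.pooled_length()  # validates conv geometry

    def pooled_length(self) -> int:
        """Sequence length after all conv/pool blocks (must be >= 1)."""
        L = self.window
        for filters, kernel, dilation, pool in self.conv_blocks:
            L_conv = L - (kernel - 1) * dilation
            L = L_conv // pool
            if L_conv < 1 or L < 1:
                raise ValueError(
                    f"conv block (filters={filters}, kernel={kernel}, "
                    f"dilation={dilation}, pool={pool}) reduces the sequence "
                    "below length 1"
                )
        return L

    @classmethod
    def toy(cls, window: int = 1000, k_mirnas: int = 0, **kw) -> "ModelConfig":
        """Small desk-scale preset: one conv block over a 1,000-base window."""
        kw.setdefault("conv_blocks", ((8, 8, 1, 25),))
        kw.setdefault("dense_units", 32)
        kw.setdefault("standardize_halflife", True)
        return cls(window=window, k_mirnas=k_mirnas, **kw)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.  The defaults are the published configuration
    (batch 32, learning rate 5e-4, at most 100 epochs, early-stopping
    patience 20).  :meth:`toy` rescales the optimiser for the small preset,
    where the dataset and network are an order of magnitude smaller."""

    batch_size: int = 32
    learning_rate: float = 0.0005
    max_epochs: int = 100
    patience: int = 20
    seed: int = 0
    momentum: float = 0.0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.patience) < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, max_epochs, patience and learning_rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")

    @classmethod
    def toy(cls, seed: int = 0, **kw) -> "TrainConfig":
        kw.setdefault("learning_rate", 0.01)
        kw.setdefault("max_epochs", 50)
        kw.setdefault("patience", 8)
        return cls(seed=seed, **kw)


# cache the first conv block's patch matrices only below this many floats
# (the one-hot input is static, so the patches are reusable every epoch)
_COLS_CACHE_MAX_FLOATS = 150_000_000


class ExpressionCNN:
    """Model object binding a dataset to an architecture.

    Parameters
    ----------
    data
        Assembled train/val/test batches; the miRNA block width must match
        ``config.k_mirnas``.
    config
        Architecture; defaults to the full-size backbone with ``k_mirnas``
        and ``window`` inferred from the data.
    """

    def __init__(self, data: ModelData, config: ModelConfig | None = None):
        if config is None:
            config = ModelConfig(window=data.window, k_mirnas=data.k_mirnas)
        if config.k_mirnas != data.k_mirnas:
            raise ValueError(
                f"config expects {config.k_mirnas} miRNAs but data carries {data.k_mirnas}"
            )
        if config.window != data.window:
            raise ValueError(
                f"config window {config.window} does not match data window {data.window}"
            )
        if len(data.train) == 0:
            raise ValueError("training partition is empty")
        if len(data.val) == 0:
            raise ValueError("validation partition is empty")
        self.data = data
        self.config = config
        self._h_shift = np.zeros(8, dtype=np.float32)
        self._h_scale = np.ones(8, dtype=np.float32)

    # -- helpers -------------------------------------------------------

    def _halflife(self, batch: Batch) -> np.ndarray:
        return (batch.H - self._h_shift) / self._h_scale

    def _predict_net(self, net: Net, batch: Batch, block: int = 512) -> np.ndarray:
        """Deterministic (dropout-off) predictions, in row blocks to bound
        memory."""
        H = self._halflife(batch)
        out = np.empty(len(batch), dtype=np.float32)
        for lo in range(0, len(batch), block):
            hi = min(lo + block, len(batch))
            out[lo:hi] = net.forward(batch.X[lo:hi], H[lo:hi], batch.M[lo:hi])[0]
        return out

    def _validation_loss(self, net: Net) -> float:
        """Mean-squared error on the validation partition (evaluation mode).

        Isolated as a method so a test harness can substitute a stub
        objective when exercising the early-stopping contract.
        """
        pred = self._predict_net(net, self.data.val)
        return float(np.mean((pred - self.data.val.y) ** 2))

    # -- fitting -------------------------------------------------------

    def fit(self, train_config: TrainConfig | None = None) -> "CNNResults":
        """Train with SGD on the MSE under early stopping.

        Training halts when the validation loss has not improved for
        ``patience`` consecutive epochs (or at ``max_epochs``); the weights
        of the best validation epoch are restored before predictions are
        computed.  Fully reproducible for a fixed ``train_config.seed``.
        """
        tcfg = train_config or TrainConfig()
        rng = np.random.default_rng(tcfg.seed)
        cfg = self.config

        if cfg.standardize_halflife:
            mu = self.data.train.H.mean(axis=0)
            sd = self.data.train.H.std(axis=0)
            self._h_shift = mu.astype(np.float32)
            self._h_scale = np.where(sd > 0, sd, 1.0).astype(np.float32)

        net = Net(cfg.window, cfg.conv_blocks, cfg.dense_units, cfg.dropout, cfg.k_mirnas, rng)
        opt = SGD(net.params, tcfg.learning_rate, tcfg.momentum)

        train = self.data.train
        H_train = self._halflife(train)
        cols_train = None
        k0, d0 = cfg.conv_blocks[0][1], cfg.conv_blocks[0][2]
        cache_floats = len(train) * (cfg.window - (k0 - 1) * d0) * k0 * 4
        if cache_floats <= _COLS_CACHE_MAX_FLOATS:
            cols_train = net.im2col_first(train.X)

        n = len(train)
        val_curve: list[float] = []
        best_loss = np.inf
        best_epoch = 0
        best_params = net.snapshot()
        for epoch in range(1, tcfg.max_epochs + 1):
            order = rng.permutation(n)
            for lo in range(0, n, tcfg.batch_size):
                idx = order[lo : lo + tcfg.batch_size]
                cols = cols_train[idx] if cols_train is not None else None
                yhat, cache = net.forward(
                    train.X[idx], H_train[idx], train.M[idx],
                    train=True, rng=rng, cols_first=cols,
                )
                err = yhat - train.y[idx]
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(learning rate {tcfg.learning_rate} may be too large)"
                    )
                opt.step(net.backward(cache, (2.0 / len(idx)) * err))
            vloss = self._validation_loss(net)
            if not np.isfinite(vloss):
                raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
            val_curve.append(vloss)
            if vloss < best_loss:
                best_loss, best_epoch = vloss, epoch
                best_params = net.snapshot()
            if epoch - best_epoch >= tcfg.patience:
                break
        net.restore(best_params)

        predictions: dict[str, float] = {}
        partition: dict[str, str] = {}
        y_true: dict[str, float] = {}
        for name, batch in (("train", train), ("val", self.data.val), ("test", self.data.test)):
            if len(batch) == 0:
                continue
            pred = self._predict_net(net, batch)
            for g, p, yt in zip(batch.gene_ids, pred, batch.y):
                predictions[g] = float(p)
                partition[g] = name
                y_true[g] = float(yt)
        residuals = {g: y_true[g] - predictions[g] for g in predictions}

        test, val = self.data.test, self.data.val
        r2_test = (
            r_squared(test.y, np.array([predictions[g] for g in test.gene_ids]))
            if len(test) >= 2 else float("nan")
        )
        r2_val = r_squared(val.y, np.array([predictions[g] for g in val.gene_ids])) if len(val) >= 2 else float("nan")
        return CNNResults(
            model=self,
            net=net,
            best_epoch=best_epoch,
            val_loss_curve=val_curve,
            predictions=predictions,
            residuals=residuals,
            partition=partition,
            r2_test=float(r2_test),
            r2_val=float(r2_val),
            seed=tcfg.seed,
            train_config=tcfg,
        )


@dataclass
class CNNResults:
    """Results of one training run.

    ``predictions`` and ``residuals`` map every gene (all three partitions)
    to its predicted log-expression and residual (ground truth − predicted);
    ``r2_test`` is the coefficient of determination on the test partition.
    """

    model: ExpressionCNN
    net: Net
    best_epoch: int
    val_loss_curve: list
    predictions: dict
    residuals: dict
    partition: dict
    r2_test: float
    r2_val: float
    seed: int
    train_config: TrainConfig

    @property
    def epochs_run(self) -> int:
        return len(self.val_loss_curve)

    @property
    def best_val_loss(self) -> float:
        return self.val_loss_curve[self.best_epoch - 1]

    def predict(self, batch: Batch) -> np.ndarray:
        """Deterministic predictions (dropout disabled) for a new batch."""
        if batch.X.shape[1:] != (self.model.config.window, 4):
            raise ValueError(
                f"batch sequence block has shape {batch.X.shape[1:]}, "
                f"expected ({self.model.config.window}, 4)"
            )
        if batch.M.shape[1] != self.model.config.k_mirnas:
            raise ValueError(
                f"batch has {batch.M.shape[1]} miRNA columns, expected {self.model.config.k_mirnas}"
            )
        return self.model._predict_net(self.net, batch)

    def residual_map(self, partitions: Sequence[str] = ("train", "val")) -> dict:
        """Residuals restricted to the given partitions (default train+val,
        keeping test genes out of downstream feature selection)."""
        wanted = set(partitions)
        return {g: r for g, r in self.residuals.items() if self.partition[g] in wanted}

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Expression CNN regression results",
            "=" * 41,
            f"{'window (bases)':<28}{cfg.window:>13}",
            f"{'conv blocks':<28}{len(cfg.conv_blocks):>13}",
            f"{'miRNA features (K)':<28}{cfg.k_mirnas:>13}",
            f"{'parameters':<28}{self.net.n_params:>13}",
            f"{'seed':<28}{self.seed:>13}",
            f"{'epochs run':<28}{self.epochs_run:>13}",
            f"{'best epoch':<28}{self.best_epoch:>13}",
            f"{'best val MSE':<28}{self.best_val_loss:>13.5f}",
            f"{'validation R2':<28}{self.r2_val:>13.4f}",
            f"{'test R2':<28}{self.r2_test:>13.4f}",
            "=" * 41,
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        """Persist the run's predictions and metrics (not the weights) so a
        pipeline can resume aggregation without retraining."""
        payload = {
            "best_epoch": self.best_epoch,
            "val_loss_curve": self.val_loss_curve,
            "predictions": self.predictions,
            "residuals": self.residuals,
            "partition": self.partition,
            "r2_test": self.r2_test,
            "r2_val": self.r2_val,
            "seed": self.seed,
            "train_config": asdict(self.train_config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CNNResults":
        with open(path) as fh:
            payload = json.load(fh)
        payload["train_config"] = TrainConfig(**payload["train_config"])
        return cls(model=None, net=None, **payload)
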