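"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from mirex.encoding import Batch, ModelData
from mirex.model import CNNResults, ModelConfig, TrainConfig
from mirex.synthetic import SimConfig, generate


@pytest.fixture(scope="session")
def tiny_sim():
    """A miniature simulated dataset: 120 genes, 60-base windows, 8 miRNAs
    (3 planted, 12 targets each)."""
    from mirex.io_formats import WindowSpec

    cfg = SimConfig(
        n_genes=120,
        window=WindowSpec(20, 40),
        n_mirnas=8,
        n_planted=3,
        targets_per_mirna=12,
        noise_sd=0.2,
        seed=7,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def tiny_model_data(tiny_sim):
    from mirex.pipeline import prepare_model_data

    sim = tiny_sim
    return prepare_model_data(sim.records, sim.features, sim.mirna_expr, sim.targets, sim.split)


@pytest.fixture()
def tiny_model_config():
    return ModelConfig(window=60, conv_blocks=((4, 5, 1, 8),), dense_units=8, k_mirnas=0)


@pytest.fixture()
def tiny_train_config():
    return TrainConfig(batch_size=16, learning_rate=0.01, max_epochs=5, patience=3, seed=0)


def make_stub_run(y_true: dict, y_pred: dict, partition=None, r2_val=0.0, val_curve=(1.0,), seed=0):
    """Build a CNNResults carrying given predictions without any training."""
    partition = partition or {g: "train" for g in y_true}
    return CNNResults(
        model=None,
        net=None,
        best_epoch=int(np.argmin(val_curve)) + 1,
        val_loss_curve=list(val_curve),
        predictions=dict(y_pred),
        residuals={g: y_true[g] - y_pred[g] for g in y_true},
        partition=partition,
        r2_test=0.0,
        r2_val=r2_val,
        seed=seed,
        train_config=TrainConfig(seed=seed),
    )
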