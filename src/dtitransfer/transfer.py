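"""Stage-I pre-training and the Stage-II transfer modes.

A source model is first trained on a large related family (Stage I). Stage II
then adapts it to a small target-family dataset in one of three ways:

* Mode 1 (full fine-tuning): all layers initialized from the source model and
  re-trained; at epoch 0 the model is exactly the source model.
* Mode 2 (feature transformer): both hidden layers frozen; only the output
  layer is re-trained on target data.
* Mode 3 (shallow classifier): the output layer is replaced by an SVM fit on
  the frozen second-hidden-layer features; source parameters are untouched.

The zero-shot baseline applies the source model to target data unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .models import (
    FNNConfig,
    FNNParams,
    ShallowHyper,
    ShallowModel,
    TrainRecord,
    extract_features,
    fit_shallow,
    init_fnn,
    predict_fnn,
    predict_shallow,
    shallow_scores,
    train_fnn,
)

FROZEN_FEATURE_LAYERS = ("L1", "L2")


class TransferMode(str, Enum):
    MODE1_FULL_FINETUNE = "mode1_full_finetune"
    MODE2_FEATURE_TRANSFORMER = "mode2_feature_transformer"
    MODE3_SHALLOW = "mode3_shallow"
    ZERO_SHOT = "zero_shot"
    SCRATCH_REFERENCE = "scratch_reference"
    SCRATCH_BASE = "scratch_base"


@dataclass
class TransferResult:
    """A trained target-family predictor plus how it was obtained."""

    mode: TransferMode
    params: FNNParams | None = None
    shallow: ShallowModel | None = None
    record: TrainRecord | None = None
    source_family: str = ""
    target_family: str = ""

    def predict(self, vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and ranking scores (probabilities for FNN heads, margins for SVM)."""
        if self.mode in (TransferMode.MODE3_SHALLOW, TransferMode.SCRATCH_BASE):
            feats = (extract_features(self.params, vectors)
                     if self.mode is TransferMode.MODE3_SHALLOW else np.asarray(vectors))
            return predict_shallow(self.shallow, feats), shallow_scores(self.shallow, feats)
        return predict_fnn(self.params, vectors)


def _check_two_classes(y: np.ndarray, what: str) -> None:
    if len(np.unique(np.asarray(y).ravel())) < 2:
        raise ValueError(f"{what} must contain both classes")


def pretrain_source(
    source_train: tuple[np.ndarray, np.ndarray], config: FNNConfig
) -> FNNParams:
    """Stage I: full training from seeded scratch initialization on the source family."""
    X, y = source_train
    _check_two_classes(y, "source training data")
    params, _ = train_fnn(init_fnn(config), (X, y), config)
    params.provenance = "pretrained"
    return params


def mode1_full_finetune(
    source: FNNParams,
    target_train: tuple[np.ndarray, np.ndarray],
    config: FNNConfig,
    source_family: str = "",
    target_family: str = "",
) -> TransferResult:
    """Mode 1: continue training every layer from the source model's weights.

    With ``config.epochs == 0`` the result is bit-identical to the source
    model, i.e. equivalent to the zero-shot baseline.
    """
    params, record = train_fnn(source, target_train, config)
    return TransferResult(TransferMode.MODE1_FULL_FINETUNE, params=params, record=record,
                          source_family=source_family, target_family=target_family)


def mode2_feature_transformer(
    source: FNNParams,
    target_train: tuple[np.ndarray, np.ndarray],
    config: FNNConfig,
    source_family: str = "",
    target_family: str = "",
) -> TransferResult:
    """Mode 2: hidden layers frozen bit-exactly; only the output layer is re-trained."""
    params, record = train_fnn(source, target_train, config, freeze=FROZEN_FEATURE_LAYERS)
    return TransferResult(TransferMode.MODE2_FEATURE_TRANSFORMER, params=params,
                          record=record, source_family=source_family,
                          target_family=target_family)


def mode3_shallow(
    source: FNNParams,
    target_train: tuple[np.ndarray, np.ndarray],
    svm_hyper: ShallowHyper | None = None,
    source_family: str = "",
    target_family: str = "",
) -> TransferResult:
    """Mode 3: SVM head fit on frozen penultimate-layer features of the source model."""
    X, y = target_train
    _check_two_classes(y, "target training data")
    feats = extract_features(source, X)
    shallow = fit_shallow(feats, y, svm_hyper)
    return TransferResult(TransferMode.MODE3_SHALLOW, params=source, shallow=shallow,
                          source_family=source_family, target_family=target_family)


def zero_shot(
    source: FNNParams, source_family: str = "", target_family: str = ""
) -> TransferResult:
    """The unmodified source model used directly as the target predictor."""
    return TransferResult(TransferMode.ZERO_SHOT, params=source,
                          source_family=source_family, target_family=target_family)


def train_scratch_reference(
    target_train: tuple[np.ndarray, np.ndarray],
    config: FNNConfig,
    target_family: str = "",
) -> TransferResult:
    """The same FNN trained from random initialization on the target data only."""
    X, y = target_train
    _check_two_classes(y, "target training data")
    params, record = train_fnn(init_fnn(config), (X, y), config)
    return TransferResult(TransferMode.SCRATCH_REFERENCE, params=params, record=record,
                          target_family=target_family)


def train_scratch_base(
    target_train: tuple[np.ndarray, np.ndarray],
    svm_hyper: ShallowHyper | None = None,
    target_family: str = "",
) -> TransferResult:
    """The base model: an SVM trained directly on the raw compound vectors."""
    X, y = target_train
    _check_two_classes(y, "target training data")
    shallow = fit_shallow(np.asarray(X), y, svm_hyper)
    return TransferResult(TransferMode.SCRATCH_BASE, shallow=shallow,
                          target_family=target_family)
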