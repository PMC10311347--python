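"""The evaluation grid: modes x training-set sizes x repeats, MCC-centric metrics.

Within a repeat every competing model sees the identical balanced subset draw
(a paired design), and all are evaluated on the same fixed target test set.
The Matthews correlation coefficient is the headline metric; AUROC,
precision, recall, F1 and accuracy are reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .models import FNNConfig, FNNParams, LabeledVectors, ShallowHyper, scratch_config
from .split import SubsetSpec, balanced_indices
from .transfer import (
    TransferMode,
    TransferResult,
    mode1_full_finetune,
    mode2_feature_transformer,
    mode3_shallow,
    pretrain_source,
    train_scratch_base,
    train_scratch_reference,
    zero_shot,
)

logger = logging.getLogger(__name__)

DEFAULT_MODES = (
    TransferMode.MODE1_FULL_FINETUNE,
    TransferMode.MODE2_FEATURE_TRANSFORMER,
    TransferMode.MODE3_SHALLOW,
    TransferMode.ZERO_SHOT,
    TransferMode.SCRATCH_REFERENCE,
    TransferMode.SCRATCH_BASE,
)


@dataclass(frozen=True)
class MetricSet:
    mcc: float
    auroc: float
    precision: float
    recall: float
    f1: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class RunRecord:
    """One grid cell: a (source, target, mode, size, repeat) evaluation."""

    source_family: str
    target_family: str
    mode: TransferMode
    size: int
    repeat: int
    seed: int
    metrics: MetricSet
    loss_curve: tuple[float, ...] = ()


@dataclass
class ExperimentResult:
    records: list[RunRecord] = field(default_factory=list)

    def to_frame(self, include_losses: bool = False) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "source_family": r.source_family,
                "target_family": r.target_family,
                "mode": r.mode.value,
                "size": r.size,
                "repeat": r.repeat,
                "seed": r.seed,
                **r.metrics.as_dict(),
            }
            if include_losses:
                row["loss_curve"] = ";".join(f"{v:.6g}" for v in r.loss_curve)
            rows.append(row)
        return pd.DataFrame(rows)


def matthews_corrcoef_binary(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """MCC from the 2x2 confusion matrix, with 0 when the denominator vanishes."""
    t = np.asarray(y_true).ravel().astype(int)
    p = np.asarray(y_pred).ravel().astype(int)
    tp = int(np.sum((t == 1) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray
) -> MetricSet:
    """Confusion-matrix metrics plus rank-based AUROC.

    AUROC needs both classes among the true labels; with a single-class test
    set it is undefined and reported as 0.5.
    """
    t = np.asarray(y_true).ravel()
    p = np.asarray(y_pred).ravel()
    s = np.asarray(scores).ravel()
    if len(t) == 0:
        raise ValueError("empty evaluation set")
    if not (len(t) == len(p) == len(s)):
        raise ValueError("labels, predictions and scores must have equal length")
    if not set(np.unique(t)) <= {0, 1} or not set(np.unique(p)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    auroc = roc_auc_score(t, s) if len(np.unique(t)) == 2 else 0.5
    return MetricSet(
        mcc=float(matthews_corrcoef_binary(t, p)),
        auroc=float(auroc),
        precision=float(precision_score(t, p, zero_division=0)),
        recall=float(recall_score(t, p, zero_division=0)),
        f1=float(f1_score(t, p, zero_division=0)),
        accuracy=float(accuracy_score(t, p)),
    )


def derive_seed(master_seed: int, *key: int) -> int:
    """A reproducible 31-bit child seed for a grid coordinate."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_benchmark(
    source_train: LabeledVectors,
    target_train: LabeledVectors,
    target_test: LabeledVectors,
    spec: SubsetSpec,
    modes: Sequence[TransferMode] = DEFAULT_MODES,
    config: FNNConfig | None = None,
    svm_hyper: ShallowHyper | None = None,
    source_params: FNNParams | None = None,
) -> ExperimentResult:
    """Run the full grid: for each repeat and size, train every requested mode
    on the same balanced subset and evaluate on the fixed target test set.

    ``spec.seed`` is the master seed; all subset draws, initializations and
    shuffles derive from it, so identical calls reproduce every record
    exactly. Sizes infeasible for the target training pool are skipped with a
    warning. A pre-trained ``source_params`` may be supplied to avoid
    repeating Stage I across grids.
    """
    config = config or FNNConfig()
    modes = [TransferMode(m) for m in modes]
    needs_source = any(m not in (TransferMode.SCRATCH_REFERENCE, TransferMode.SCRATCH_BASE)
                       for m in modes)
    if needs_source and source_params is None:
        pre_cfg = scratch_config(config, derive_seed(spec.seed, 0))
        source_params = pretrain_source((source_train.X, source_train.y), pre_cfg)

    y_train = np.asarray(target_train.y)
    n_pos = int(np.sum(y_train == 1))
    n_neg = int(np.sum(y_train == 0))
    feasible = []
    for size in spec.sizes:
        if size // 2 <= n_pos and size // 2 <= n_neg:
            feasible.append(size)
        else:
            logger.warning(
                "size %d skipped: target train pool has %d active / %d inactive",
                size, n_pos, n_neg,
            )

    zs_eval: MetricSet | None = None
    if TransferMode.ZERO_SHOT in modes:
        zs = zero_shot(source_params, target_family=target_test.family)
        labels, scores = zs.predict(target_test.X)
        zs_eval = compute_metrics(target_test.y, labels, scores)

    result = ExperimentResult()
    for repeat in range(spec.repeats):
        for si, size in enumerate(feasible):
            cell_seed = derive_seed(spec.seed, 1, repeat, si)
            rng = np.random.default_rng(cell_seed)
            idx = balanced_indices(y_train, size, rng)
            subset = (target_train.X[idx], y_train[idx])
            for mode in modes:
                trained = _run_mode(mode, source_params, subset, config, svm_hyper,
                                    cell_seed, source_train.family, target_train.family)
                if mode is TransferMode.ZERO_SHOT:
                    metrics = zs_eval
                else:
                    labels, scores = trained.predict(target_test.X)
                    metrics = compute_metrics(target_test.y, labels, scores)
                losses = tuple(trained.record.losses) if trained.record else ()
                result.records.append(
                    RunRecord(
                        source_family=source_train.family,
                        target_family=target_train.family,
                        mode=mode,
                        size=size,
                        repeat=repeat,
                        seed=cell_seed,
                        metrics=metrics,
                        loss_curve=losses,
                    )
                )
    return result


def _run_mode(
    mode: TransferMode,
    source_params: FNNParams | None,
    subset: tuple[np.ndarray, np.ndarray],
    config: FNNConfig,
    svm_hyper: ShallowHyper | None,
    cell_seed: int,
    source_family: str,
    target_family: str,
) -> TransferResult:
    cfg = scratch_config(config, cell_seed)
    if mode is TransferMode.MODE1_FULL_FINETUNE:
        return mode1_full_finetune(source_params, subset, cfg,
                                   source_family, target_family)
    if mode is TransferMode.MODE2_FEATURE_TRANSFORMER:
        return mode2_feature_transformer(source_params, subset, cfg,
                                         source_family, target_family)
    if mode is TransferMode.MODE3_SHALLOW:
        return mode3_shallow(source_params, subset, svm_hyper,
                             source_family, target_family)
    if mode is TransferMode.ZERO_SHOT:
        return zero_shot(source_params, source_family, target_family)
    if mode is TransferMode.SCRATCH_REFERENCE:
        return train_scratch_reference(subset, cfg, target_family)
    if mode is TransferMode.SCRATCH_BASE:
        return train_scratch_base(subset, svm_hyper, target_family)
    raise ValueError(f"unknown mode {mode!r}")


def aggregate(result: ExperimentResult) -> pd.DataFrame:
    """Mean and sample sd of every metric per (mode, size), plus the repeat count.

    With a single repeat the sample sd is undefined; it is reported as 0.0 and
    the ``sd_well_defined`` column is False.
    """
    df = result.to_frame()
    if df.empty:
        raise ValueError("no records to aggregate")
    metric_cols = [f.name for f in fields(MetricSet)]
    grouped = df.groupby(["mode", "size"], sort=True)
    out = grouped[metric_cols].agg(["mean", "std"])
    out.columns = [f"{m}_{stat}" for m, stat in out.columns]
    out["n_repeats"] = grouped.size()
    out["sd_well_defined"] = out["n_repeats"] > 1
    sd_cols = [c for c in out.columns if c.endswith("_std")]
    out[sd_cols] = out[sd_cols].fillna(0.0)
    return out.reset_index()


def write_results(result: ExperimentResult, out_dir) -> dict[str, Path]:
    """Write the long per-repeat table, the (mode, size) summary, and loss curves."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out_dir / "records.csv",
        "summary": out_dir / "summary.csv",
        "losses": out_dir / "loss_curves.csv",
    }
    result.to_frame().to_csv(paths["records"], index=False)
    aggregate(result).to_csv(paths["summary"], index=False)
    loss_rows = []
    for r in result.records:
        for epoch, loss in enumerate(r.loss_curve, start=1):
            loss_rows.append({"mode": r.mode.value, "size": r.size, "repeat": r.repeat,
                              "epoch": epoch, "loss": loss})
    pd.DataFrame(loss_rows).to_csv(paths["losses"], index=False)
    return paths


def plot_loss_curves(result: ExperimentResult, path, size: int | None = None) -> None:
    """Mean per-epoch training-loss curves per mode (convergence comparison)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for mode in sorted({r.mode for r in result.records}, key=lambda m: m.value):
        curves = [r.loss_curve for r in result.records
                  if r.mode == mode and r.loss_curve
                  and (size is None or r.size == size)]
        if not curves:
            continue
        mean_curve = np.mean(np.asarray(curves), axis=0)
        ax.plot(np.arange(1, len(mean_curve) + 1), mean_curve, label=mode.value)
    ax.set_xlabel("epoch")
    ax.set_ylabel("mean training loss")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
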