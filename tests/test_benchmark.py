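"""Metric computation against brute-force oracles; grid mechanics; aggregation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dtitransfer.benchmark import (
    ExperimentResult,
    MetricSet,
    RunRecord,
    aggregate,
    compute_metrics,
    matthews_corrcoef_binary,
    run_benchmark,
    write_results,
)
from dtitransfer.models import FNNConfig, LabeledVectors
from dtitransfer.split import SubsetSpec
from dtitransfer.synthetic import SyntheticConfig, generate_families
from dtitransfer.transfer import TransferMode


def oracle_confusion_metrics(y_true, y_pred):
    """Independent brute-force confusion-matrix evaluation."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    acc = (tp + tn) / len(y_true)
    prec = 0.0 if tp + fp == 0 else tp / (tp + fp)
    rec = 0.0 if tp + fn == 0 else tp / (tp + fn)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return mcc, acc, prec, rec, f1


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        m = compute_metrics(y, y, y.astype(float))
        assert m.mcc == 1.0 and m.accuracy == 1.0 and m.auroc == 1.0

    def test_balanced_coin_is_zero_mcc(self):
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.array([1, 0, 1, 0])  # TP=TN=FP=FN=1
        assert compute_metrics(y_true, y_pred, y_pred.astype(float)).mcc == 0.0

    def test_hand_computed_confusion(self):
        # TP=40, TN=35, FP=13, FN=8
        y_true = np.array([1] * 48 + [0] * 48)
        y_pred = np.array([1] * 40 + [0] * 8 + [1] * 13 + [0] * 35)
        expected = (40 * 35 - 13 * 8) / math.sqrt((40 + 13) * (40 + 8) * (35 + 13) * (35 + 8))
        m = compute_metrics(y_true, y_pred, y_pred.astype(float))
        assert m.mcc == pytest.approx(expected)

    def test_exhaustive_8_item_labelings_match_oracle(self):
        y_true = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        for bits in itertools.product([0, 1], repeat=8):
            y_pred = np.array(bits)
            m = compute_metrics(y_true, y_pred, y_pred.astype(float))
            mcc, acc, prec, rec, f1 = oracle_confusion_metrics(y_true, y_pred)
            assert m.mcc == pytest.approx(mcc)
            assert m.accuracy == pytest.approx(acc)
            assert m.precision == pytest.approx(prec)
            assert m.recall == pytest.approx(rec)
            assert m.f1 == pytest.approx(f1)

    def test_auroc_rankings(self):
        y = np.array([0, 0, 1, 1])
        assert compute_metrics(y, y, np.array([0.1, 0.2, 0.8, 0.9])).auroc == 1.0
        assert compute_metrics(y, y, np.array([0.9, 0.8, 0.2, 0.1])).auroc == 0.0

    def test_auroc_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 2000)
        scores = rng.random(2000)
        m = compute_metrics(y, y, scores)
        assert abs(m.auroc - 0.5) < 0.05

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0, 1]), np.array([0]), np.array([0.1]))
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError):
            compute_metrics(np.array([0, 2]), np.array([0, 1]), np.array([0.0, 1.0]))

    def test_mcc_range_random(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.integers(0, 2, 12)
            p = rng.integers(0, 2, 12)
            assert -1.0 <= matthews_corrcoef_binary(t, p) <= 1.0


@pytest.fixture(scope="module")
def mini_bench():
    """A deliberately small benchmark setup (low dimension, few epochs)."""
    cfg = FNNConfig(input_dim=16, hidden_sizes=(24, 8), epochs=8,
                    batch_size=32, learning_rate=1e-3, seed=0)
    fams = generate_families(
        SyntheticConfig(families=("src", "tgt"), n_per_family=300, dimension=16,
                        overlap=0.8, label_noise=0.1, seed=21)
    )
    src = fams["src"].as_vectors()
    tgt = fams["tgt"]
    train = LabeledVectors(tgt.X[:200], tgt.y[:200], "tgt")
    test = LabeledVectors(tgt.X[200:], tgt.y[200:], "tgt")
    return cfg, src, train, test


class TestRunBenchmark:
    def test_record_counting(self, mini_bench):
        cfg, src, train, test = mini_bench
        spec = SubsetSpec(sizes=(2,), repeats=3, seed=5)
        result = run_benchmark(src, train, test, spec,
                               modes=(TransferMode.MODE1_FULL_FINETUNE,
                                      TransferMode.SCRATCH_REFERENCE),
                               config=cfg)
        assert len(result.records) == 6  # 2 modes x 3 repeats

    def test_infeasible_size_skipped_not_crashed(self, mini_bench, caplog):
        cfg, src, train, test = mini_bench
        spec = SubsetSpec(sizes=(2, 4000), repeats=2, seed=5)
        with caplog.at_level("WARNING"):
            result = run_benchmark(src, train, test, spec,
                                   modes=(TransferMode.SCRATCH_REFERENCE,),
                                   config=cfg)
        assert {r.size for r in result.records} == {2}
        assert any("4000" in m for m in caplog.messages)

    def test_paired_design_same_subset_seed_per_cell(self, mini_bench):
        cfg, src, train, test = mini_bench
        spec = SubsetSpec(sizes=(6,), repeats=2, seed=5)
        result = run_benchmark(src, train, test, spec,
                               modes=(TransferMode.MODE1_FULL_FINETUNE,
                                      TransferMode.SCRATCH_REFERENCE),
                               config=cfg)
        by_repeat = {}
        for r in result.records:
            by_repeat.setdefault(r.repeat, set()).add(r.seed)
        assert all(len(seeds) == 1 for seeds in by_repeat.values())

    def test_exact_reproducibility(self, mini_bench):
        cfg, src, train, test = mini_bench
        spec = SubsetSpec(sizes=(2, 6), repeats=2, seed=17)
        modes = (TransferMode.MODE1_FULL_FINETUNE, TransferMode.MODE3_SHALLOW,
                 TransferMode.ZERO_SHOT, TransferMode.SCRATCH_REFERENCE)
        a = run_benchmark(src, train, test, spec, modes=modes, config=cfg)
        b = run_benchmark(src, train, test, spec, modes=modes, config=cfg)
        assert a.records == b.records

    def test_loss_curves_recorded_for_gradient_models(self, mini_bench):
        cfg, src, train, test = mini_bench
        spec = SubsetSpec(sizes=(6,), repeats=1, seed=2)
        result = run_benchmark(src, train, test, spec,
                               modes=(TransferMode.MODE1_FULL_FINETUNE,
                                      TransferMode.MODE3_SHALLOW),
                               config=cfg)
        by_mode = {r.mode: r for r in result.records}
        assert len(by_mode[TransferMode.MODE1_FULL_FINETUNE].loss_curve) == cfg.epochs
        assert by_mode[TransferMode.MODE3_SHALLOW].loss_curve == ()


def _record(mode, size, repeat, mcc):
    ms = MetricSet(mcc=mcc, auroc=0.5, precision=0.5, recall=0.5, f1=0.5, accuracy=0.5)
    return RunRecord("s", "t", mode, size, repeat, 0, ms)


class TestAggregate:
    def test_hand_computed_mean_and_sd(self):
        vals = [0.2, 0.5, 0.8]
        result = ExperimentResult(
            [_record(TransferMode.ZERO_SHOT, 2, i, v) for i, v in enumerate(vals)]
        )
        row = aggregate(result).iloc[0]
        assert row["mcc_mean"] == pytest.approx(np.mean(vals))
        assert row["mcc_std"] == pytest.approx(np.std(vals, ddof=1))
        assert row["n_repeats"] == 3

    def test_single_repeat_sd_flagged(self):
        result = ExperimentResult([_record(TransferMode.ZERO_SHOT, 2, 0, 0.4)])
        row = aggregate(result).iloc[0]
        assert row["mcc_std"] == 0.0
        assert not row["sd_well_defined"]

    def test_identical_repeats_zero_sd(self):
        result = ExperimentResult(
            [_record(TransferMode.ZERO_SHOT, 2, i, 0.4) for i in range(5)]
        )
        assert aggregate(result).iloc[0]["mcc_std"] == 0.0

    def test_order_invariance(self):
        records = [_record(TransferMode.ZERO_SHOT, s, i, 0.1 * i)
                   for s in (2, 6) for i in range(3)]
        a = aggregate(ExperimentResult(records))
        b = aggregate(ExperimentResult(records[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate(ExperimentResult([]))


class TestWriteResults:
    def test_files_written_and_readable(self, tmp_path, mini_bench):
        cfg, src, train, test = mini_bench
        spec = SubsetSpec(sizes=(2,), repeats=2, seed=1)
        result = run_benchmark(src, train, test, spec,
                               modes=(TransferMode.MODE1_FULL_FINETUNE,),
                               config=cfg)
        paths = write_results(result, tmp_path / "out")
        records = pd.read_csv(paths["records"])
        assert len(records) == 2
        summary = pd.read_csv(paths["summary"])
        assert "mcc_mean" in summary.columns
        losses = pd.read_csv(paths["losses"])
        assert len(losses) == 2 * cfg.epochs

    def test_loss_curve_plot_written(self, tmp_path, mini_bench):
        from dtitransfer.benchmark import plot_loss_curves

        cfg, src, train, test = mini_bench
        spec = SubsetSpec(sizes=(6,), repeats=1, seed=4)
        result = run_benchmark(src, train, test, spec,
                               modes=(TransferMode.MODE1_FULL_FINETUNE,
                                      TransferMode.SCRATCH_REFERENCE),
                               config=cfg)
        out = tmp_path / "losses.png"
        plot_loss_curves(result, out)
        assert out.stat().st_size > 0
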