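"""Micro-averaged multilabel metrics and the two-cohort comparison harness.

Counts are pooled over every (sample, label) cell — micro-averaging — and
accuracy/precision/recall/F1 derived from the pooled confusion counts.
``run_comparison`` reproduces the cross-cohort experimental design: for each
direction it trains every architecture on one cohort (early-stopping on that
cohort's validation split), then reports metrics on the training cohort's
held-out test split ("within") and on the entire other cohort ("cross"),
with the other cohort preprocessed using the training cohort's hold times,
Tukey fences and normalization statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import reference_ranges
from .models import LabForecaster, ModelSpec, TrainConfig
from .preprocessing import PreprocessingPipeline
from .synthetic import RawCohort
from .windowing import build_dataset, extract_windows

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion_counts", "micro_metrics",
    "run_comparison", "plot_history",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled confusion counts over all samples and labels."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Micro-averaged metrics with the counts they derive from.

    ``zero_division_flags`` names any metric whose denominator was empty
    (reported as 0 by convention).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    arm: str = ""
    zero_division_flags: tuple[str, ...] = ()


def confusion_counts(predicted: np.ndarray, truth: np.ndarray
                     ) -> ConfusionCounts:
    """Pool TP/FP/TN/FN over every cell of two binary matrices."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    for arr, name in ((p, "predicted"), (t, "truth")):
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} matrix has non-binary entries")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
    )


def micro_metrics(counts: ConfusionCounts, arm: str = "") -> MetricsReport:
    """Accuracy, precision, recall, F1 from pooled counts.

    Empty denominators yield 0 with a flag rather than NaN.
    """
    if counts.total == 0:
        raise ValueError("no cells to evaluate")
    flags = []
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision, _ = 0.0, flags.append("precision")
    if counts.tp + counts.fn:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall, _ = 0.0, flags.append("recall")
    if precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, _ = 0.0, flags.append("f1")
    return MetricsReport(accuracy=accuracy, precision=precision,
                         recall=recall, f1=f1, counts=counts, arm=arm,
                         zero_division_flags=tuple(flags))


def _report_row(rep: MetricsReport, direction: str, architecture: str,
                test_set: str) -> dict:
    return {
        "train_cohort": direction, "architecture": architecture,
        "test_set": test_set, "accuracy": rep.accuracy,
        "precision": rep.precision, "recall": rep.recall, "f1": rep.f1,
        "tp": rep.counts.tp, "fp": rep.counts.fp,
        "tn": rep.counts.tn, "fn": rep.counts.fn,
    }


def run_comparison(
    cohort_a: RawCohort,
    cohort_b: RawCohort,
    architectures: list[str] | None = None,
    window: int = 6,
    threshold: float = 0.5,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    split_fractions: tuple[float, float, float] = (0.68, 0.12, 0.20),
    preprocess_kwargs: dict | None = None,
    model_hyperparameters: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Train-on-one, test-on-both comparison over architectures.

    Returns one row per (train cohort, architecture, test set) triple with
    micro-averaged metrics; an architecture that fails to train loses only
    its own rows (the failure is recorded in an ``error`` column).
    """
    if architectures is None:
        architectures = ["lstm", "cnn", "mcnn", "transformer", "tcn", "gbm"]
    base_cfg = train_config or TrainConfig(threshold=threshold)
    hp = model_hyperparameters or {}
    ss = np.random.SeedSequence(seed)
    rows: list[dict] = []
    directions = ((cohort_a, cohort_b), (cohort_b, cohort_a))
    dir_seeds = ss.spawn(len(directions))
    for (train_cohort, other_cohort), dseed in zip(directions, dir_seeds):
        split_seed, train_seed = [int(s.generate_state(1)[0] % 2**31)
                                  for s in dseed.spawn(2)]
        pipe = PreprocessingPipeline(**(preprocess_kwargs or {}))
        train_stays = pipe.fit_transform(train_cohort)
        other_stays = pipe.transform(other_cohort)
        ranges = reference_ranges(train_cohort.channel_specs)
        ds = build_dataset(train_stays, window, ranges,
                           split_fractions=split_fractions, seed=split_seed)
        other_samples = [s for stay in other_stays
                         for s in extract_windows(stay, window, ranges)]
        for arch in architectures:
            spec = ModelSpec(arch, window, ds.n_channels,
                             hyperparameters=hp.get(arch, {}))
            cfg = TrainConfig(**{**base_cfg.__dict__,
                                 "threshold": threshold,
                                 "seed": train_seed})
            try:
                res = LabForecaster(ds, spec, cfg).fit()
                within = res.evaluate("test")
                cross = res.evaluate(other_samples)
            except Exception as exc:  # noqa: BLE001 - row-level isolation
                rows.append({"train_cohort": train_cohort.name,
                             "architecture": arch, "test_set": "error",
                             "error": str(exc)})
                continue
            rows.append(_report_row(within, train_cohort.name, arch, "within"))
            rows.append(_report_row(cross, train_cohort.name, arch, "cross"))
    return pd.DataFrame(rows)


def plot_history(history: pd.DataFrame, out_path: str, title: str = "") -> None:
    """Write loss/accuracy/F1-versus-epoch training curves to an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    axes[0].plot(history["epoch"], history["train_loss"], label="train")
    if "val_loss" in history:
        axes[0].plot(history["epoch"], history["val_loss"], label="validation")
    axes[0].set_ylabel("BCE loss")
    axes[0].legend()
    for ax, col, label in ((axes[1], "val_accuracy", "micro accuracy"),
                           (axes[2], "val_f1", "micro F1")):
        if col in history:
            ax.plot(history["epoch"], history[col])
        ax.set_ylabel(label)
    for ax in axes:
        ax.set_xlabel("epoch")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
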