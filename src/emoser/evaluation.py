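"""Speaker-independent evaluation: UAR/ACC, confusion matrices,
cross-validation and the ablation harness.

The headline metric is unweighted average recall (UAR), the mean of
per-class recalls TP/(TP+FN), which is robust to class imbalance; plain
accuracy (ACC) is reported alongside.  Folds partition *speakers*, never
clips, so no speaker contributes to both the training and the test side
of any fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .features import CHANNEL_NAMES, FeatureConfig, extract_features
from .model import ModelConfig, TrainConfig, train

__all__ = [
    "EvalReport", "FoldPlan", "confusion_matrix", "uar", "accuracy",
    "speaker_folds", "cross_validate", "ablation", "SpeakerLeakageError",
]


class SpeakerLeakageError(RuntimeError):
    """A speaker appears on both sides of a fold."""


@dataclass
class EvalReport:
    classes: list
    per_class_recall: dict
    uar: float
    acc: float
    confusion_pct: np.ndarray  # row-normalized percentages
    counts: np.ndarray
    per_fold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "per_class_recall": {str(k): v for k, v in
                                 self.per_class_recall.items()},
            "uar": self.uar,
            "acc": self.acc,
            "confusion_pct": np.asarray(self.confusion_pct).tolist(),
            "counts": np.asarray(self.counts).tolist(),
            "per_fold": [r.to_dict() for r in self.per_fold],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion_pct, index=self.classes,
                            columns=self.classes)


@dataclass
class FoldPlan:
    folds: list  # list of (train_speakers, test_speakers) tuples
    k: int

    def __post_init__(self) -> None:
        seen = set()
        for tr, te in self.folds:
            tr, te = set(tr), set(te)
            if tr & te:
                raise SpeakerLeakageError(f"speakers {tr & te} in both sides")
            if seen & te:
                raise ValueError("test speaker sets must be disjoint")
            seen |= te


def confusion_matrix(y_true, y_pred, classes) -> tuple[np.ndarray, np.ndarray]:
    """Counts and row-normalized percentage confusion matrices.

    Row i, column j of the percentage matrix is the share (in %) of
    true-class-i samples predicted as class j; rows with no true samples
    are NaN and flagged with a warning.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    counts = _sk_confusion(y_true, y_pred, labels=list(classes))
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / row_sums
    empty = row_sums[:, 0] == 0
    if empty.any():
        warnings.warn(f"classes with no true samples: "
                      f"{[c for c, e in zip(classes, empty) if e]}")
    return counts, pct


def _recalls(counts: np.ndarray) -> np.ndarray:
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(row_sums > 0, np.diag(counts) / row_sums, np.nan)


def uar(y_true, y_pred, classes) -> float:
    """Unweighted average recall: mean over classes of TP/(TP+FN)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts, _ = confusion_matrix(y_true, y_pred, classes)
    rec = _recalls(counts)
    if np.isnan(rec).any():
        raise ValueError("every class must be present in y_true for UAR")
    return float(rec.mean())


def accuracy(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(list(y_true)), np.asarray(list(y_pred))
    return float((y_true == y_pred).mean())


def _report(y_true, y_pred, classes) -> EvalReport:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts, pct = confusion_matrix(y_true, y_pred, classes)
    rec = _recalls(counts)
    present = ~np.isnan(rec)
    if not present.all():
        warnings.warn("classes absent from this evaluation excluded from UAR")
    return EvalReport(
        classes=list(classes),
        per_class_recall={c: (float(r) if np.isfinite(r) else float("nan"))
                          for c, r in zip(classes, rec)},
        uar=float(rec[present].mean()),
        acc=accuracy(y_true, y_pred),
        confusion_pct=pct, counts=counts)


def speaker_folds(speakers, k: int, seed: int = 0) -> FoldPlan:
    """Partition speakers into k disjoint test groups (shuffled by seed).

    With 10 speakers and k=10 this is leave-one-speaker-out.
    """
    uniq = sorted(set(speakers))
    if len(uniq) < k:
        raise ValueError(f"{len(uniq)} speakers cannot form {k} folds")
    rng = np.random.default_rng(seed)
    order = [uniq[i] for i in rng.permutation(len(uniq))]
    groups = [list(g) for g in np.array_split(np.array(order, dtype=object), k)]
    folds = []
    for gi, g in enumerate(groups):
        test = tuple(sorted(g))
        tr = tuple(sorted(s for s in uniq if s not in set(test)))
        folds.append((tr, test))
    return FoldPlan(folds=folds, k=k)


def cross_validate(clips, model_cfg: ModelConfig,
                   feature_cfg: FeatureConfig | None = None,
                   plan: FoldPlan | None = None, k: int = 10,
                   train_cfg: TrainConfig | None = None,
                   channels=(0, 1, 2), seed: int = 0) -> EvalReport:
    """Speaker-independent k-fold cross-validation.

    Trains one model per fold and pools all held-out predictions into a
    single report (per-fold reports are attached as ``per_fold``).
    ``channels`` selects a subset of the three feature channels for the
    ablation harness.
    """
    if feature_cfg is None:
        feature_cfg = FeatureConfig(n_mels=model_cfg.n_mels)
    if train_cfg is None:
        train_cfg = TrainConfig()
    channels = list(channels)
    if not channels:
        raise ValueError("channel subset must be non-empty")
    classes = sorted({c.label for c in clips})
    if None in classes:
        raise ValueError("all clips must be labeled")
    cls_to_idx = {c: i for i, c in enumerate(classes)}
    feats = [extract_features(c, feature_cfg) for c in clips]
    values = [f.values[:, :, channels] for f in feats]
    labels = np.array([cls_to_idx[c.label] for c in clips])
    speakers = np.array([c.speaker_id for c in clips], dtype=object)
    if plan is None:
        plan = speaker_folds(speakers, k, seed=seed)
    mc = replace(model_cfg, in_channels=len(channels),
                 n_classes=len(classes), n_mels=feature_cfg.n_mels)

    pooled_true: list = []
    pooled_pred: list = []
    fold_reports = []
    for fold_i, (train_spk, test_spk) in enumerate(plan.folds):
        train_set, test_set = set(train_spk), set(test_spk)
        if train_set & test_set:
            raise SpeakerLeakageError(
                f"fold {fold_i}: speakers {train_set & test_set} leak")
        tr_idx = [i for i, s in enumerate(speakers) if s in train_set]
        te_idx = [i for i, s in enumerate(speakers) if s in test_set]
        if not te_idx:
            continue
        fold_tc = replace(train_cfg, seed=train_cfg.seed + fold_i)
        model, _ = train([values[i] for i in tr_idx], labels[tr_idx],
                         mc, fold_tc)
        preds = [model.predict(values[i]).label for i in te_idx]
        truth = labels[te_idx].tolist()
        pooled_true += truth
        pooled_pred += preds
        fold_reports.append(_report(truth, preds, list(range(len(classes)))))

    report = _report(pooled_true, pooled_pred, list(range(len(classes))))
    report = EvalReport(
        classes=classes,
        per_class_recall={classes[i]: v for i, v in
                          enumerate(report.per_class_recall.values())},
        uar=report.uar, acc=report.acc,
        confusion_pct=report.confusion_pct, counts=report.counts,
        per_fold=fold_reports)
    return report


def ablation(clips, model_cfg: ModelConfig,
             feature_cfg: FeatureConfig | None = None,
             block_counts=None, channel_subsets=None, k: int = 2,
             train_cfg: TrainConfig | None = None,
             seed: int = 0) -> pd.DataFrame:
    """Ablation harness over residual-block count and feature channels.

    ``block_counts`` (e.g. (1, 2, 3)) yields one cross-validation per
    block count; ``channel_subsets=True`` runs all seven non-empty
    subsets of {static, deltas, delta-deltas}.  Returns a table with one
    row per configuration and its pooled UAR.
    """
    rows = []
    if block_counts:
        for nb in block_counts:
            mc = replace(model_cfg, n_blocks=nb)
            rep = cross_validate(clips, mc, feature_cfg, k=k,
                                 train_cfg=train_cfg, seed=seed)
            plural = "s" if nb != 1 else ""
            rows.append({"axis": "blocks",
                         "configuration": f"{nb} residual block{plural}",
                         "uar": rep.uar, "acc": rep.acc})
    if channel_subsets:
        if channel_subsets is True:
            subsets = [[i for i in range(3) if mask >> i & 1]
                       for mask in range(1, 8)]
            subsets.sort(key=lambda s: (len(s), s))
        else:
            subsets = [list(s) for s in channel_subsets]
        for sub in subsets:
            if not sub:
                raise ValueError("channel subset must be non-empty")
            rep = cross_validate(clips, model_cfg, feature_cfg, k=k,
                                 train_cfg=train_cfg, channels=sub, seed=seed)
            name = " + ".join(CHANNEL_NAMES[i] for i in sub)
            rows.append({"axis": "channels", "configuration": name,
                         "uar": rep.uar, "acc": rep.acc})
    if not rows:
        raise ValueError("no ablation axis requested")
    return pd.DataFrame(rows)


def plot_confusion(report: EvalReport, path: str | Path) -> None:
    """Render the row-normalized confusion matrix to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(report.classes) + 2, 4))
    im = ax.imshow(report.confusion_pct, cmap="Blues", vmin=0, vmax=100)
    ax.set_xticks(range(len(report.classes)), report.classes, rotation=45)
    ax.set_yticks(range(len(report.classes)), report.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(report.classes)):
        for j in range(len(report.classes)):
            ax.text(j, i, f"{report.confusion_pct[i, j]:.1f}",
                    ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="% of true class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
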