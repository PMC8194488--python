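"""Expert-label aggregation and group-emotion association analysis.

Pipeline: per-utterance majority vote over (up to) three expert labels,
person-level emotion assignment (any non-neutral emotion overrides
neutral; the most frequent non-neutral emotion wins), a group x emotion
contingency table, and a Pearson chi-square association test with an
optional Monte-Carlo exact p-value.

The chi-square test itself goes beyond the original descriptive
analysis, which reported the contingency table only; results are tagged
accordingly.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnotatedUtterance", "ContingencyTable", "AssociationResult",
    "majority_vote", "person_label", "build_contingency", "association_test",
]

log = logging.getLogger(__name__)

UNRESOLVED = None


@dataclass
class AnnotatedUtterance:
    clip_id: str
    expert_labels: tuple
    model_label: str | None = None
    resolved_label: str | None = None

    def resolve(self, threshold: int = 2) -> str | None:
        self.resolved_label = majority_vote(self.expert_labels, threshold)
        return self.resolved_label


@dataclass
class ContingencyTable:
    groups: list
    emotions: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.groups), len(self.emotions)):
            raise ValueError("counts shape must be groups x emotions")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.groups,
                            columns=self.emotions)


@dataclass
class AssociationResult:
    statistic: float
    dof: int
    p_value: float
    residuals: np.ndarray  # Pearson residuals (obs - exp)/sqrt(exp)
    method: str
    note: str = ("chi-square association test added on top of the "
                 "descriptive contingency analysis")

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "dof": self.dof,
                "p_value": self.p_value,
                "residuals": np.asarray(self.residuals).tolist(),
                "method": self.method, "note": self.note}


def majority_vote(expert_labels, threshold: int = 2):
    """Label held by >= ``threshold`` experts, else ``None`` (unresolved).

    The default threshold of 2 (of 3) implements majority labeling.
    """
    labels = [l for l in expert_labels if l is not None]
    if not labels:
        raise ValueError("need at least one expert label")
    label, count = Counter(labels).most_common(1)[0]
    return label if count >= threshold else UNRESOLVED


def person_label(utterance_labels) -> str:
    """Person-level emotion from resolved utterance labels.

    Any non-neutral emotion overrides neutral; among non-neutral
    emotions the most frequent wins, remaining ties broken by earliest
    occurrence (logged).  Unresolved (None) labels are ignored; raises
    if none are resolved.
    """
    labels = [l for l in utterance_labels if l is not None]
    if not labels:
        raise ValueError("all utterances unresolved; cannot label person")
    non_neutral = [l for l in labels if l != "neutral"]
    if not non_neutral:
        return "neutral"
    counts = Counter(non_neutral)
    top = max(counts.values())
    tied = [l for l, c in counts.items() if c == top]
    if len(tied) > 1:
        winner = min(tied, key=non_neutral.index)
        log.info("person-label tie among %s broken to %s (earliest)",
                 tied, winner)
        return winner
    return tied[0]


def build_contingency(person_labels, group_flags, groups=None,
                      emotions=None) -> ContingencyTable:
    """Cross-tabulate person-level emotions by group."""
    person_labels = list(person_labels)
    group_flags = list(group_flags)
    if len(person_labels) != len(group_flags):
        raise ValueError("one group flag per person required")
    if groups is None:
        groups = sorted(set(group_flags))
    if emotions is None:
        emotions = sorted(set(person_labels))
    counts = np.zeros((len(groups), len(emotions)), dtype=int)
    g_idx = {g: i for i, g in enumerate(groups)}
    e_idx = {e: i for i, e in enumerate(emotions)}
    for lab, grp in zip(person_labels, group_flags):
        counts[g_idx[grp], e_idx[lab]] += 1
    return ContingencyTable(list(groups), list(emotions), counts)


def association_test(table: ContingencyTable, method: str = "auto",
                     n_resamples: int = 9999,
                     seed: int = 0) -> AssociationResult:
    """Pearson chi-square test of group-emotion association.

    ``method``: "chi2" (asymptotic, no continuity correction),
    "monte-carlo" (exact p by resampling tables with fixed margins), or
    "auto" (Monte-Carlo when any expected cell count is below 5).
    """
    counts = np.asarray(table.counts, dtype=float)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero-margin row or column; drop it first")
    expected = np.outer(row, col) / counts.sum()
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    residuals = (counts - expected) / np.sqrt(expected)
    if method == "auto":
        method = "monte-carlo" if (expected < 5).any() else "chi2"
    if method == "chi2":
        return AssociationResult(float(stat), int(dof), float(p), residuals,
                                 "pearson-chi2")
    if method == "monte-carlo":
        rng = np.random.default_rng(seed)
        dist = stats.random_table(row.astype(int), col.astype(int))
        reps = dist.rvs(n_resamples, random_state=rng)
        rep_stats = (((reps - expected) ** 2) / expected).sum(axis=(1, 2))
        p_mc = (1 + np.sum(rep_stats >= stat - 1e-12)) / (1 + n_resamples)
        return AssociationResult(float(stat), int(dof), float(p_mc),
                                 residuals, "monte-carlo")
    raise ValueError(f"unknown method {method!r}")


def analyze_manifest(manifest: str | Path, threshold: int = 2,
                     method: str = "auto",
                     seed: int = 0) -> tuple[ContingencyTable,
                                             AssociationResult]:
    """Full chain from a trial manifest CSV to table + test.

    Expected columns: clip_id, defendant_id, group, expert1..expert3.
    """
    df = pd.read_csv(manifest)
    expert_cols = [c for c in df.columns if c.startswith("expert")]
    if not expert_cols:
        raise ValueError("manifest has no expert label columns")
    person_labels, group_flags = [], []
    for (defendant, group), sub in df.groupby(["defendant_id", "group"],
                                              sort=True):
        resolved = [majority_vote(tuple(r), threshold)
                    for r in sub[expert_cols].itertuples(index=False)]
        person_labels.append(person_label(resolved))
        group_flags.append(group)
    table = build_contingency(person_labels, group_flags)
    return table, association_test(table, method=method, seed=seed)
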