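"""Coverage/accuracy metrics: Classified fraction, accuracy-on-classified,
confusion matrices, and threshold sweeps.

The two headline metrics per level mirror how rejection classifiers are
reported: *classified fraction* — how many sequences receive a prediction at
that level — and *accuracy* over the classified sequences only.  A sequence
counts as classified at Order level if its accepted level is Order or
Superfamily; at Superfamily level only if a Superfamily was accepted.
Truths known only to Order depth are excluded from Superfamily denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationRow
from .network import NodeProbabilities, greedy_predict
from .taxonomy import TaxonomyNode, TaxonomyTree

__all__ = [
    "EvaluationReport",
    "evaluate",
    "confusion",
    "threshold_sweep",
    "compare_unknown_reduction",
    "write_report_csv",
    "write_confusion_csv",
]

UNKNOWN = "Unknown"


def write_report_csv(reports: Sequence["EvaluationReport"], path) -> None:
    """One CSV row per level: n_total, n_classified, classified %, accuracy %."""
    rows = []
    for rep in reports:
        rows.append(
            {
                "level": rep.level,
                "n_total": rep.n_total,
                "n_classified": rep.n_classified,
                "n_correct": rep.n_correct,
                "classified_pct": 100 * rep.classified_fraction,
                "accuracy_pct": 100 * rep.accuracy,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_confusion_csv(matrix: pd.DataFrame, path) -> None:
    """Confusion matrix with labeled header row and column."""
    matrix.to_csv(path)


@dataclass
class EvaluationReport:
    level: str
    n_total: int
    n_classified: int
    n_correct: int
    classified_fraction: float
    accuracy: float  # NaN when nothing is classified
    confusion: pd.DataFrame


def _truth_label(truth: TaxonomyNode, level: str) -> str | None:
    """Truth label at ``level``; None if the truth is too shallow for it."""
    if level == "type":
        return truth.path if truth.level == "type" else truth.parent.path
    if truth.level == "subtype":
        return truth.path
    return None


def _pred_label(row: ClassificationRow, level: str) -> str | None:
    """Predicted label at ``level``; None when unclassified at that level."""
    if level == "type":
        if row.accepted_level == "type":
            return row.accepted_label
        if row.accepted_level == "subtype":
            return row.accepted_label.split("/", 1)[0]
        return None
    return row.accepted_label if row.accepted_level == "subtype" else None


def _check(rows: Sequence[ClassificationRow], truths: Sequence[TaxonomyNode], tree: TaxonomyTree):
    if len(rows) != len(truths):
        raise ValueError("rows and truths differ in length")
    for t in truths:
        if t not in tree:
            raise ValueError(f"truth label {t.path!r} not in tree")


def evaluate(
    rows: Sequence[ClassificationRow],
    truths: Sequence[TaxonomyNode],
    tree: TaxonomyTree,
    level: str,
) -> EvaluationReport:
    """Classified fraction and accuracy-on-classified at ``level``."""
    _check(rows, truths, tree)
    n_total = n_classified = n_correct = 0
    for row, truth in zip(rows, truths):
        tl = _truth_label(truth, level)
        if tl is None:
            continue  # truth too shallow for this level's denominator
        n_total += 1
        pl = _pred_label(row, level)
        if pl is not None:
            n_classified += 1
            n_correct += pl == tl
    frac = n_classified / n_total if n_total else float("nan")
    acc = n_correct / n_classified if n_classified else float("nan")
    return EvaluationReport(
        level=level,
        n_total=n_total,
        n_classified=n_classified,
        n_correct=n_correct,
        classified_fraction=frac,
        accuracy=acc,
        confusion=confusion(rows, truths, tree, level),
    )


def confusion(
    rows: Sequence[ClassificationRow],
    truths: Sequence[TaxonomyNode],
    tree: TaxonomyTree,
    level: str,
) -> pd.DataFrame:
    """Counts over truth labels (rows) x predicted labels plus an Unknown column.

    Only items whose truth reaches ``level`` are tallied, so the matrix total
    equals that level's ``n_total``.
    """
    _check(rows, truths, tree)
    if level == "type":
        labels = [t.path for t in tree.type_nodes]
    else:
        labels = [s.path for s in tree.subtype_nodes]
    mat = pd.DataFrame(
        0, index=pd.Index(labels, name="truth"),
        columns=pd.Index(labels + [UNKNOWN], name="predicted"), dtype=int
    )
    for row, truth in zip(rows, truths):
        tl = _truth_label(truth, level)
        if tl is None:
            continue
        pl = _pred_label(row, level)
        mat.loc[tl, pl if pl is not None else UNKNOWN] += 1
    return mat


def threshold_sweep(
    joints: np.ndarray,
    truths: Sequence[TaxonomyNode],
    tree: TaxonomyTree,
    thresholds: Sequence[float],
    level: str,
) -> list[tuple[float, float, float]]:
    """Re-apply the greedy threshold rule per threshold over joint-probability rows.

    Returns ``(threshold, classified_fraction, accuracy)`` triples; the
    classified fraction is nonincreasing in the threshold.
    """
    if len(thresholds) == 0:
        raise ValueError("empty threshold list")
    joints = np.atleast_2d(joints)
    out = []
    for thr in thresholds:
        rows = []
        for b in range(joints.shape[0]):
            probs = NodeProbabilities(conditional=joints[b], joint=joints[b])
            pred = greedy_predict(probs, tree, thr)
            rows.append(
                ClassificationRow(
                    seq_id=str(b),
                    accepted_label=pred.accepted_label,
                    accepted_level=pred.accepted_level,
                    joint=joints[b],
                )
            )
        rep = evaluate(rows, truths, tree, level)
        out.append((float(thr), rep.classified_fraction, rep.accuracy))
    return out


def compare_unknown_reduction(
    before_labels: Sequence[str],
    after_rows: Sequence[ClassificationRow],
) -> tuple[float, float]:
    """Unknown fraction among inputs vs after classifying the Unknown subset.

    ``before_labels`` are RepeatModeler-style ``Type/SubType`` strings or
    ``Unknown``; ``after_rows`` are the classifier's outputs for exactly the
    Unknown subset of the inputs.
    """
    n = len(before_labels)
    n_unknown_before = sum(1 for lab in before_labels if lab == UNKNOWN)
    if n == 0:
        return 0.0, 0.0
    if n_unknown_before == 0:
        return 0.0, 0.0
    if len(after_rows) != n_unknown_before:
        raise ValueError("after_rows must cover exactly the Unknown inputs")
    still_unknown = sum(1 for r in after_rows if r.accepted_level == "unknown")
    return n_unknown_before / n, still_unknown / n
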