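"""End-user inference: FASTA in, per-sequence classifications out.

Output conventions follow downstream RepeatMasker usage: the annotated
FASTA rewrites each header to ``>seq_id#Type/SubType`` (or ``#Type`` /
``#Unknown``), replacing any pre-existing ``#`` classification suffix, so
the file can drop straight into a RepeatModeler -> RepeatMasker workflow.
The CSV carries the accepted label plus the joint probability of every
taxonomy node (joint, not conditional, because the threshold rule operates
on joints; conditionals are recoverable by division).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .network import (
    ConvHierarchicalNet,
    HierarchicalPrediction,
    NodeProbabilities,
    batch_joint_probabilities,
    greedy_predict,
    load_model,
)
from .sequence_data import SeqRecord, encode, read_fasta

__all__ = [
    "ClassificationRow",
    "classify_records",
    "classify_fasta",
    "write_csv",
    "write_annotated_fasta",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.7


@dataclass
class ClassificationRow:
    """One classified sequence: accepted label/level plus all joint probabilities."""

    seq_id: str
    accepted_label: str  # "Unknown", "Type" or "Type/SubType"
    accepted_level: str  # "unknown" | "type" | "subtype"
    joint: np.ndarray  # per non-root node, logit-index order


def _predict_row(
    seq_id: str, joint: np.ndarray, net: ConvHierarchicalNet, threshold: float
) -> ClassificationRow:
    cond = joint.copy()
    for t in net.tree.type_nodes:
        pj = joint[t.logit_index]
        for c in t.children:
            cond[c.logit_index] = joint[c.logit_index] / pj if pj > 0 else 0.0
    probs = NodeProbabilities(conditional=cond, joint=joint)
    pred: HierarchicalPrediction = greedy_predict(probs, net.tree, threshold)
    return ClassificationRow(
        seq_id=seq_id,
        accepted_label=pred.accepted_label,
        accepted_level=pred.accepted_level,
        joint=joint,
    )


def classify_records(
    records: Sequence[SeqRecord],
    net: ConvHierarchicalNet,
    threshold: float = DEFAULT_THRESHOLD,
    batch_size: int = 32,
) -> list[ClassificationRow]:
    """Classify in-memory records; one output row per record, order preserved."""
    rows: list[ClassificationRow] = []
    for i in range(0, len(records), batch_size):
        chunk = records[i : i + batch_size]
        encoded = []
        for rec in chunk:
            try:
                encoded.append(encode(rec.sequence))
            except ValueError as exc:
                raise ValueError(f"record {rec.id!r}: {exc}") from exc
        batch, lengths = net.pad_batch(encoded)
        logits = net.forward(batch, lengths)
        joints = batch_joint_probabilities(logits, net.tree)
        for rec, joint in zip(chunk, joints):
            rows.append(_predict_row(rec.id, joint, net, threshold))
    return rows


def classify_fasta(
    fasta_path: str | Path,
    model: str | Path | ConvHierarchicalNet,
    threshold: float = DEFAULT_THRESHOLD,
    batch_size: int = 32,
) -> tuple[list[SeqRecord], list[ClassificationRow]]:
    """Classify every record of a FASTA file.

    ``model`` may be a loaded network or a path to a model archive.  Returns
    the parsed records and one classification row per record.
    """
    net = model if isinstance(model, ConvHierarchicalNet) else load_model(model)
    records = read_fasta(fasta_path)
    return records, classify_records(records, net, threshold, batch_size)


def write_csv(rows: Sequence[ClassificationRow], net: ConvHierarchicalNet, path: str | Path) -> None:
    """RFC-4180 CSV: seq_id, accepted label/level, then one joint-probability
    column per taxonomy node in logit-index order (6 significant digits)."""
    node_names = [n.path for n in net.tree.nodes()]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["seq_id", "accepted_label", "accepted_level", *node_names])
        for row in rows:
            writer.writerow(
                [row.seq_id, row.accepted_label, row.accepted_level]
                + [f"{p:.6g}" for p in row.joint]
            )


def _strip_annotation(seq_id: str) -> str:
    return seq_id.split("#", 1)[0]


def write_annotated_fasta(
    records: Sequence[SeqRecord],
    rows: Sequence[ClassificationRow],
    path: str | Path,
    width: int = 60,
) -> None:
    """Write records with headers rewritten to ``>id#Classification``.

    Any pre-existing ``#...`` suffix on the id is replaced; sequence bodies
    are unchanged.  Records and rows must align by seq_id.
    """
    if len(records) != len(rows):
        raise ValueError("records and rows differ in length")
    with open(path, "w", encoding="utf-8") as fh:
        for rec, row in zip(records, rows):
            if rec.id != row.seq_id:
                raise ValueError(f"id mismatch: record {rec.id!r} vs row {row.seq_id!r}")
            fh.write(f">{_strip_annotation(rec.id)}#{row.accepted_label}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
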