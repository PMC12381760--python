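"""FASTA I/O, nucleotide encoding, a binary sequence store, and stratified folds.

Sequences are encoded over a five-symbol alphabet (A, C, G, T/U, ambiguous)
with 0 reserved for padding; repeat consensus libraries routinely contain
IUPAC ambiguity codes, which all collapse onto the fifth symbol rather than
spending embedding capacity on rare codes.  Soft-masked (lowercase) bases are
treated as sequence, not annotation.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .taxonomy import TaxonomyNode

__all__ = [
    "SeqRecord",
    "FastaError",
    "EncodingError",
    "LabeledFamily",
    "read_fasta",
    "write_fasta",
    "encode",
    "decode",
    "PAD_INDEX",
    "VOCAB_SIZE",
    "SequenceStore",
    "stratified_partition",
]

#: Padding index; never appears inside a real encoded sequence.
PAD_INDEX = 0
#: Embedding vocabulary size: pad + {A, C, G, T/U, ambiguous}.
VOCAB_SIZE = 6

_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "U": 4}
_AMBIGUOUS = set("NRYSWKMBDHV")
_DECODE = {1: "A", 2: "C", 3: "G", 4: "T", 5: "N"}


class FastaError(ValueError):
    """Malformed FASTA input."""


class EncodingError(ValueError):
    """Sequence contains characters outside the IUPAC nucleotide codes."""


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence: id, rest-of-header description, residues."""

    id: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass
class LabeledFamily:
    """A repeat family with its deepest known taxonomy node and optional fold."""

    record: SeqRecord
    node: TaxonomyNode
    fold: int | None = None


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Parse a (multi-line) FASTA file into records, preserving order.

    Raises :class:`FastaError` for content before the first header, or a
    header with no sequence lines.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    with open(path, encoding="utf-8") as fh:
        # reject leading non-FASTA content (SimpleFastaParser silently skips it)
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaError(f"{path}: non-FASTA content before first '>' header")
            break
        fh.seek(0)
        for title, seq in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            if not parts:
                raise FastaError(f"{path}: record with empty header")
            seq_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if not seq:
                raise FastaError(f"{path}: record {seq_id!r} has a header but no sequence")
            records.append(SeqRecord(id=seq_id, description=desc, sequence=seq))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string to small integers (A→1 C→2 G→3 T/U→4, other IUPAC→5).

    Case-insensitive.  Gaps and non-IUPAC characters raise
    :class:`EncodingError` listing the offending characters and 1-based
    positions.
    """
    if not sequence:
        raise EncodingError("cannot encode an empty sequence")
    out = np.empty(len(sequence), dtype=np.uint8)
    bad: list[tuple[int, str]] = []
    for i, ch in enumerate(sequence):
        u = ch.upper()
        code = _CODE.get(u)
        if code is None:
            if u in _AMBIGUOUS:
                code = 5
            else:
                bad.append((i + 1, ch))
                continue
        out[i] = code
    if bad:
        shown = ", ".join(f"{c!r}@{p}" for p, c in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise EncodingError(f"invalid nucleotide characters: {shown}{more}")
    return out


def decode(symbols: Sequence[int]) -> str:
    """Inverse of :func:`encode` on the canonical five-letter alphabet."""
    try:
        return "".join(_DECODE[int(s)] for s in symbols)
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]} outside the 1..5 alphabet") from exc


class SequenceStore:
    """Single-file binary store of encoded sequences with random access by id.

    Layout: 8 magic bytes ``b"RCSEQ001"``, then raw uint8 sequence payloads
    back to back, then a JSON index mapping id -> [offset, length], then the
    little-endian uint64 offset of the index.  Open in mode ``"w"`` to build
    (call :meth:`close` or use as a context manager to finalize), ``"r"`` to
    read.
    """

    MAGIC = b"RCSEQ001"

    def __init__(self, path: str | Path, mode: str = "r"):
        self.path = Path(path)
        self.mode = mode
        self._index: dict[str, tuple[int, int]] = {}
        if mode == "w":
            self._fh = open(self.path, "wb")
            self._fh.write(self.MAGIC)
        elif mode == "r":
            self._fh = open(self.path, "rb")
            if self._fh.read(8) != self.MAGIC:
                raise ValueError(f"{self.path}: not a sequence store (bad magic)")
            self._fh.seek(-8, 2)
            (index_offset,) = struct.unpack("<Q", self._fh.read(8))
            self._fh.seek(index_offset)
            end = self._fh.seek(0, 2) - 8
            self._fh.seek(index_offset)
            raw = self._fh.read(end - index_offset)
            self._index = {k: (v[0], v[1]) for k, v in json.loads(raw).items()}
        else:
            raise ValueError("mode must be 'r' or 'w'")

    def put(self, seq_id: str, encoded: np.ndarray) -> None:
        if self.mode != "w":
            raise IOError("store opened read-only")
        if seq_id in self._index:
            raise KeyError(f"duplicate id {seq_id!r}")
        data = np.asarray(encoded, dtype=np.uint8).tobytes()
        offset = self._fh.tell()
        self._fh.write(data)
        self._index[seq_id] = (offset, len(data))

    def get(self, seq_id: str) -> np.ndarray:
        if seq_id not in self._index:
            raise KeyError(f"id {seq_id!r} not in store")
        offset, length = self._index[seq_id]
        self._fh.seek(offset)
        return np.frombuffer(self._fh.read(length), dtype=np.uint8).copy()

    def ids(self) -> list[str]:
        return list(self._index)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __len__(self) -> int:
        return len(self._index)

    def close(self) -> None:
        if self.mode == "w" and not self._fh.closed:
            index_offset = self._fh.tell()
            payload = json.dumps(
                {k: list(v) for k, v in self._index.items()}, separators=(",", ":")
            ).encode()
            self._fh.write(payload)
            self._fh.write(struct.pack("<Q", index_offset))
        self._fh.close()

    def content_hash(self) -> str:
        """SHA-256 of the finalized file (reproducibility check)."""
        h = hashlib.sha256()
        with open(self.path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        return h.hexdigest()

    def __enter__(self) -> "SequenceStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def stratified_partition(
    items: Sequence[LabeledFamily], n_folds: int, seed: int
) -> np.ndarray:
    """Assign items to folds, stratifying by the deepest taxonomy label.

    Items are grouped by full node path (Type/SubType where known, Type
    otherwise); within each group a seeded shuffle is dealt round-robin to the
    folds, so per-group fold counts differ by at most one.  Returns the fold
    id per item (also written onto each item's ``fold`` field).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    groups: dict[str, list[int]] = {}
    for i, item in enumerate(items):
        groups.setdefault(item.node.path, []).append(i)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(items), dtype=np.int64)
    next_fold = 0
    for key in sorted(groups):
        idx = np.array(groups[key])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[i] = (next_fold + j) % n_folds
        # rotate the starting fold so small groups don't all pile onto fold 0
        next_fold = (next_fold + len(idx)) % n_folds
    for i, item in enumerate(items):
        item.fold = int(folds[i])
    return folds
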