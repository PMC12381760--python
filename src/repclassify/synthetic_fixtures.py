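"""Synthetic Repbase-like corpora with planted, taxonomy-aligned motifs.

Real repeat superfamilies are recognizable by conserved sequence domains;
the generator emulates that with a toy taxonomy whose leaves each carry a
set of fixed random motifs planted into i.i.d. background sequence, plus
per-base substitution noise.  Because the signal is exact motifs, a trivial
motif-counting oracle bounds what a trained network should approach, giving
an independent non-neural reference.  The generator does not attempt real
TE structure (terminal inverted repeats, LTR ends, ORFs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import numpy as np

from .sequence_data import LabeledFamily, SeqRecord, stratified_partition
from .taxonomy import TaxonomyNode, TaxonomyTree, TranslationTable, build_tree

__all__ = [
    "FixtureSpec",
    "FixtureCorpus",
    "make_toy_taxonomy",
    "generate",
    "default_benchmark",
    "motif_oracle_predict",
]

_ALPHABET = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    n_types: int
    subtypes_per_type: int
    n_seqs_per_leaf: int
    length_range: tuple[int, int]
    motif_length: int = 12
    n_motifs_per_leaf: int = 3
    substitution_rate: float = 0.05
    background_gc: float = 0.42
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if not (0 <= self.substitution_rate < 0.5):
            raise ValueError("substitution_rate must be in [0, 0.5)")
        if not (0 < self.background_gc < 1):
            raise ValueError("background_gc must be in (0, 1)")


@dataclass
class FixtureCorpus:
    records: list[SeqRecord]
    truth: list[TaxonomyNode]
    tree: TaxonomyTree
    table: TranslationTable
    manifest: dict = field(default_factory=dict)

    def labeled(self) -> list[LabeledFamily]:
        return [LabeledFamily(r, n) for r, n in zip(self.records, self.truth)]


def make_toy_taxonomy(
    n_types: int, subtypes_per_type: int
) -> tuple[TaxonomyTree, TranslationTable]:
    """Toy taxonomy with types T01.. and subtypes T01/S01.. plus its table."""
    entries: dict[str, tuple[str, str | None]] = {}
    for t in range(1, n_types + 1):
        tname = f"T{t:02d}"
        if subtypes_per_type == 0:
            entries[tname] = (tname, None)
        for s in range(1, subtypes_per_type + 1):
            sname = f"S{s:02d}"
            entries[f"{tname}-{sname}"] = (tname, sname)
    table = TranslationTable(entries)
    return build_tree(table), table


def _leaves(tree: TaxonomyTree) -> list[TaxonomyNode]:
    out = []
    for t in tree.type_nodes:
        out.extend(t.children if t.children else [t])
    return out


def generate(spec: FixtureSpec) -> FixtureCorpus:
    """Generate a labeled corpus according to ``spec`` (deterministic per seed).

    Per leaf, ``n_motifs_per_leaf`` motifs are drawn once; every sequence is
    i.i.d. background at the requested GC content with each motif planted at
    a random non-overlapping position, then per-base substitution noise.
    """
    tree, table = make_toy_taxonomy(spec.n_types, spec.subtypes_per_type)
    rng = np.random.default_rng(spec.seed)
    # independent substream: the pre-noise corpus for a given seed is the
    # same whatever the substitution rate
    noise_rng = np.random.default_rng((spec.seed, 7919))
    lo, hi = spec.length_range
    if lo > hi or lo < 1:
        raise ValueError("invalid length_range")
    if spec.n_motifs_per_leaf * spec.motif_length > lo:
        raise ValueError(
            "length_range too small to place "
            f"{spec.n_motifs_per_leaf} non-overlapping motifs of length {spec.motif_length}"
        )
    gc = spec.background_gc
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    leaves = _leaves(tree)
    motifs: dict[str, list[str]] = {}
    records: list[SeqRecord] = []
    truth: list[TaxonomyNode] = []
    for leaf in leaves:
        motifs[leaf.path] = [
            "".join(rng.choice(_ALPHABET, size=spec.motif_length))
            for _ in range(spec.n_motifs_per_leaf)
        ]
    counter = 0
    for leaf in leaves:
        for _ in range(spec.n_seqs_per_leaf):
            counter += 1
            L = int(rng.integers(lo, hi + 1))
            seq = rng.choice(_ALPHABET, size=L, p=base_p)
            # non-overlapping placement: partition the sequence into
            # n_motifs blocks and place one motif per block
            block = L // spec.n_motifs_per_leaf
            for m_i, motif in enumerate(motifs[leaf.path]):
                start_lo = m_i * block
                start_hi = start_lo + block - spec.motif_length
                start = int(rng.integers(start_lo, max(start_lo, start_hi) + 1))
                seq[start : start + spec.motif_length] = list(motif)
            if spec.substitution_rate > 0:
                # substituted bases are redrawn from the three other bases, so
                # the observed mismatch rate equals the nominal rate
                hit = np.flatnonzero(noise_rng.random(L) < spec.substitution_rate)
                cur = seq[hit]
                offsets = noise_rng.integers(1, 4, size=hit.size)
                cur_idx = np.searchsorted(_ALPHABET, cur)
                seq[hit] = _ALPHABET[(cur_idx + offsets) % 4]
            records.append(
                SeqRecord(
                    id=f"fx-{counter:05d}",
                    description=leaf.path,
                    sequence="".join(seq),
                )
            )
            truth.append(leaf)
    manifest = {"spec": asdict(spec), "motifs": motifs}
    return FixtureCorpus(records, truth, tree, table, manifest)


def default_benchmark(seed: int = 20240101) -> tuple[FixtureCorpus, np.ndarray]:
    """The standard benchmark fixture plus an 80/20 stratified split.

    8 leaves (4 types x 2 subtypes), 200 sequences per leaf of 300-700 bp,
    3 planted 12-mers per leaf, 5% substitution noise, GC 0.42.  Returns the
    corpus and a boolean mask that is True for validation items (one of five
    stratified folds, ~20%).
    """
    spec = FixtureSpec(
        n_types=4,
        subtypes_per_type=2,
        n_seqs_per_leaf=200,
        length_range=(300, 700),
        motif_length=12,
        n_motifs_per_leaf=3,
        substitution_rate=0.05,
        background_gc=0.42,
        seed=seed,
    )
    corpus = generate(spec)
    folds = stratified_partition(corpus.labeled(), n_folds=5, seed=seed)
    return corpus, folds == 0


def motif_oracle_predict(
    corpus: FixtureCorpus, sequence: str
) -> TaxonomyNode:
    """Non-neural reference classifier: argmax of exact motif hit counts."""
    best, best_leaf = -1, None
    for leaf in _leaves(corpus.tree):
        hits = sum(sequence.count(m) for m in corpus.manifest["motifs"][leaf.path])
        if hits > best:
            best, best_leaf = hits, leaf
    return best_leaf


def write_truth_tsv(corpus: FixtureCorpus, path) -> None:
    """Truth table companion to the FASTA: seq_id, type, subtype."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("seq_id\ttype\tsubtype\n")
        for rec, node in zip(corpus.records, corpus.truth):
            t = node.label if node.level == "type" else node.parent.label
            s = node.label if node.level == "subtype" else ""
            fh.write(f"{rec.id}\t{t}\t{s}\n")


def write_manifest(corpus: FixtureCorpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(corpus.manifest, fh, indent=2)
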