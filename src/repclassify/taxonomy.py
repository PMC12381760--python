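"""Repeat classification taxonomy and the Repbase -> RepeatMasker translation layer.

The classifier predicts over a rooted two-level tree: *Type* nodes (RepeatMasker
Orders such as ``LTR``, ``LINE``, ``DNA``) and *SubType* nodes (Superfamilies
such as ``LTR/Gypsy`` or ``DNA/hAT``).  Repbase annotates families with its own
category strings; the translation table maps each Repbase category onto the
deepest RepeatMasker node it corresponds to.  The packaged default table maps
156 Repbase categories onto 9 Types and 44 SubTypes.

``Unknown`` is deliberately *not* a node of the tree: it denotes the absence of
an accepted prediction under the probability-threshold fallback rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

__all__ = [
    "TaxonomyNode",
    "TaxonomyTree",
    "TranslationTable",
    "TranslationError",
    "UNMAPPED",
    "load_translation_table",
    "load_default_table",
    "build_tree",
    "tree_from_paths",
    "translate",
    "count_nodes",
]

DEFAULT_TABLE_RESOURCE = "repbase_to_repeatmasker.tsv"

_WS = re.compile(r"\s+")


class TranslationError(ValueError):
    """Raised for malformed or inconsistent translation tables."""


class _Unmapped:
    """Sentinel for a source label absent from the translation table."""

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "UNMAPPED"

    def __bool__(self) -> bool:
        return False


#: Returned by :func:`translate` for labels the table does not cover.
UNMAPPED = _Unmapped()


@dataclass
class TaxonomyNode:
    """A node of the two-level repeat taxonomy.

    ``level`` is one of ``"root"``, ``"type"`` or ``"subtype"``.  Every
    non-root node carries a ``logit_index`` into the classifier's output
    vector; indices are assigned alphabetically by full path so that two
    builds of the same table agree.
    """

    label: str
    level: str
    parent: "TaxonomyNode | None" = None
    children: list["TaxonomyNode"] = field(default_factory=list)
    logit_index: int | None = None

    @property
    def path(self) -> str:
        """Full path string: ``"LTR"`` for a Type, ``"LTR/Gypsy"`` for a SubType."""
        if self.level == "root":
            return ""
        if self.level == "type":
            return self.label
        return f"{self.parent.label}/{self.label}"

    def __repr__(self) -> str:
        return f"TaxonomyNode({self.path!r}, level={self.level!r}, idx={self.logit_index})"

    # dataclass with mutable fields: identity hashing is what we want for
    # dict keys (nodes are unique per tree).
    def __hash__(self) -> int:
        return id(self)

    def __eq__(self, other: object) -> bool:
        return self is other


class TaxonomyTree:
    """Rooted 2-level tree of Type and SubType nodes with stable logit indices."""

    def __init__(self, root: TaxonomyNode):
        self.root = root
        self._by_path: dict[str, TaxonomyNode] = {}
        self._by_index: list[TaxonomyNode] = []
        nodes = [c for t in root.children for c in (t, *t.children)]
        for node in nodes:
            self._by_path[node.path] = node
        self._by_index = sorted(nodes, key=lambda n: n.logit_index)
        indices = [n.logit_index for n in self._by_index]
        if indices != list(range(len(indices))):
            raise ValueError("logit indices must form a contiguous 0..N-1 range")

    @property
    def n_nodes(self) -> int:
        """Number of non-root nodes (the classifier's logit dimension)."""
        return len(self._by_index)

    @property
    def type_nodes(self) -> list[TaxonomyNode]:
        return list(self.root.children)

    @property
    def subtype_nodes(self) -> list[TaxonomyNode]:
        return [c for t in self.root.children for c in t.children]

    def node(self, path: str) -> TaxonomyNode:
        """Look a node up by its full path string (``"LINE"`` or ``"LINE/L1"``)."""
        return self._by_path[path]

    def get(self, path: str) -> TaxonomyNode | None:
        return self._by_path.get(path)

    def by_index(self, i: int) -> TaxonomyNode:
        return self._by_index[i]

    def nodes(self) -> list[TaxonomyNode]:
        """All non-root nodes in logit-index order."""
        return list(self._by_index)

    def __contains__(self, node: TaxonomyNode) -> bool:
        return self._by_path.get(node.path) is node

    def __repr__(self) -> str:
        return (
            f"TaxonomyTree({count_nodes(self, 'type')} types, "
            f"{count_nodes(self, 'subtype')} subtypes)"
        )


@dataclass(frozen=True)
class TranslationTable:
    """Mapping from Repbase source categories to (type, subtype) targets.

    ``entries`` maps a normalized source label to a ``(type_label,
    subtype_label-or-None)`` pair.  Order of first appearance is preserved.
    """

    entries: dict[str, tuple[str, str | None]]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def type_labels(self) -> list[str]:
        return sorted({t for t, _ in self.entries.values()})

    @property
    def subtype_paths(self) -> list[str]:
        return sorted({f"{t}/{s}" for t, s in self.entries.values() if s})


def _normalize(label: str) -> str:
    return _WS.sub(" ", label.strip())


def load_translation_table(source: Union[str, Path, IO[str], Iterable[str]]) -> TranslationTable:
    """Load and validate a translation table from a TSV resource.

    Each record has ``source_label<TAB>type_label[<TAB>subtype_label]``;
    lines starting with ``#`` and blank lines are ignored.  Duplicate source
    labels (after whitespace normalization) are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            lines = fh.readlines()
    elif hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = list(source)

    entries: dict[str, tuple[str, str | None]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise TranslationError(
                f"line {lineno}: expected source_label<TAB>type_label, got {line!r}"
            )
        src = _normalize(parts[0])
        typ = _normalize(parts[1])
        sub = _normalize(parts[2]) if len(parts) > 2 and parts[2].strip() else None
        if not src or not typ:
            raise TranslationError(f"line {lineno}: empty source or type label")
        if src in entries:
            raise TranslationError(f"duplicate source label {src!r}")
        entries[src] = (typ, sub)
    if not entries:
        raise TranslationError("translation table resource contains no records")
    return TranslationTable(entries)


def load_default_table() -> TranslationTable:
    """The packaged 156-category Repbase -> RepeatMasker table."""
    ref = resources.files("repclassify.data").joinpath(DEFAULT_TABLE_RESOURCE)
    with ref.open("r", encoding="utf-8") as fh:
        return load_translation_table(fh)


def build_tree(table: TranslationTable) -> TaxonomyTree:
    """Build the taxonomy tree whose nodes are the distinct targets of ``table``.

    Logit indices are assigned alphabetically over full paths, giving a
    stable bijection onto ``0..N-1``.
    """
    root = TaxonomyNode(label="", level="root")
    type_labels = sorted({t for t, _ in table.entries.values()})
    types: dict[str, TaxonomyNode] = {}
    for t in type_labels:
        node = TaxonomyNode(label=t, level="type", parent=root)
        root.children.append(node)
        types[t] = node
    for t, s in sorted({(t, s) for t, s in table.entries.values() if s}):
        parent = types[t]
        parent.children.append(TaxonomyNode(label=s, level="subtype", parent=parent))
    all_nodes = sorted(
        (c for t in root.children for c in (t, *t.children)), key=lambda n: n.path
    )
    for i, node in enumerate(all_nodes):
        node.logit_index = i
    return TaxonomyTree(root)


def translate(
    table: TranslationTable, tree: TaxonomyTree, source_label: str
) -> TaxonomyNode | _Unmapped:
    """Resolve a Repbase category to the deepest taxonomy node it maps to.

    Unmapped labels return :data:`UNMAPPED` (a falsy sentinel, not an error):
    the caller decides whether to drop the record.
    """
    target = table.entries.get(_normalize(source_label))
    if target is None:
        return UNMAPPED
    typ, sub = target
    path = f"{typ}/{sub}" if sub else typ
    node = tree.get(path)
    if node is None:  # pragma: no cover - build_tree covers all targets
        raise TranslationError(f"table target {path!r} missing from tree")
    return node


def tree_from_paths(paths: Sequence[str]) -> TaxonomyTree:
    """Rebuild a taxonomy tree from full node paths listed in logit-index order.

    Used when deserializing a model file: the stored path list fixes the
    logit indices, whatever ordering produced them.
    """
    root = TaxonomyNode(label="", level="root")
    types: dict[str, TaxonomyNode] = {}
    nodes: list[TaxonomyNode] = []
    for path in paths:
        if "/" in path:
            nodes.append(None)  # placeholder; resolved after all types exist
        else:
            node = TaxonomyNode(label=path, level="type", parent=root)
            root.children.append(node)
            types[path] = node
            nodes.append(node)
    for i, path in enumerate(paths):
        if nodes[i] is None:
            t, s = path.split("/", 1)
            if t not in types:
                raise ValueError(f"subtype path {path!r} has no type node {t!r}")
            node = TaxonomyNode(label=s, level="subtype", parent=types[t])
            types[t].children.append(node)
            nodes[i] = node
        nodes[i].logit_index = i
    return TaxonomyTree(root)


def count_nodes(tree: TaxonomyTree, level: str) -> int:
    """Number of nodes at ``level`` ("type" or "subtype")."""
    if level == "type":
        return len(tree.type_nodes)
    if level == "subtype":
        return len(tree.subtype_nodes)
    raise ValueError(f"unknown level {level!r}")
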