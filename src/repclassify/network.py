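"""Convolutional repeat classifier with a hierarchical softmax head.

Architecture: each nucleotide symbol is embedded into an ``e``-dimensional
vector; ``n`` convolutional blocks follow, each a same-padded stride-1
convolution of kernel size ``k`` -> ReLU -> dropout(``d``) -> max-pool by 2.
The first block has ``f`` output features, growing by a factor ``g`` per
block (rounded half-away-from-zero).  A masked global average over the
real-sequence positions feeds a penultimate dense layer of size ``p`` (ReLU)
and a final linear map to one logit per non-root taxonomy node.

The head is a hierarchical softmax: an independent softmax over each node's
children, with joint probabilities given by path products.  The loss is the
cross-entropy of the true Type plus ``phi`` times the cross-entropy of the
true SubType among its siblings (when the truth is known to SubType depth).
At prediction time a SubType is accepted only if its joint probability
surpasses a user threshold; otherwise the prediction falls back to the Type
level, and below the threshold at Type level the sequence is left Unknown.

Everything here is plain NumPy, forward and backward; model capacity is
budgeted in multiply-accumulate operations (MACC) at a fixed reference
sequence length, which is how the first-layer feature count ``f`` is chosen.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_data import PAD_INDEX, VOCAB_SIZE
from .taxonomy import TaxonomyNode, TaxonomyTree, tree_from_paths

__all__ = [
    "Hyperparameters",
    "NodeProbabilities",
    "HierarchicalPrediction",
    "features_at_layer",
    "macc_count",
    "scale_features_to_budget",
    "node_probabilities",
    "hierarchical_loss",
    "greedy_predict",
    "ConvHierarchicalNet",
    "save_model",
    "load_model",
    "DEFAULT_MACC_BUDGET",
    "DEFAULT_MACC_REF_LENGTH",
]

#: MACC budget used to scale the first-layer feature count.
DEFAULT_MACC_BUDGET = 2e10
#: Reference sequence length for the MACC budget (a documented convention;
#: recorded in every model file).
DEFAULT_MACC_REF_LENGTH = 4096


@dataclass
class Hyperparameters:
    """Architecture hyperparameters; defaults are the tuned values.

    ``f`` (first-layer features) defaults to None, meaning "derive from the
    MACC budget" via :func:`scale_features_to_budget`.
    """

    e: int = 18
    n: int = 4
    k: int = 7
    d: float = 0.248
    g: float = 1.96
    p: int = 1953
    phi: float = 1.02
    f: int | None = None

    def __post_init__(self):
        if self.e < 1 or self.n < 1 or self.p < 1:
            raise ValueError("e, n and p must be positive")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("kernel size k must be an odd positive integer")
        if not (0 <= self.d < 1):
            raise ValueError("dropout d must be in [0, 1)")
        if self.g < 1:
            raise ValueError("growth factor g must be >= 1")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.f is not None and self.f < 1:
            raise ValueError("f must be positive when given")


def features_at_layer(f: int, g: float, i: int) -> int:
    """Feature count of conv block ``i``: f·gⁱ rounded half-away-from-zero, min 1."""
    x = f * g**i
    return max(1, int(math.floor(x + 0.5)))


def macc_count(h: Hyperparameters, L: int, n_nodes: int) -> int:
    """Multiply-accumulate count of one forward pass at sequence length ``L``.

    Stride-1 same-padded convolutions contribute ``floor(L/2^i)·k·c_in·c_out``
    per block; the penultimate and head dense layers contribute their weight
    counts; embedding lookups are free.
    """
    if h.f is None:
        raise ValueError("f must be resolved before counting MACCs")
    if L < 2**h.n:
        raise ValueError(f"L={L} shorter than 2^n={2 ** h.n}")
    total = 0
    for i in range(h.n):
        c_in = h.e if i == 0 else features_at_layer(h.f, h.g, i - 1)
        c_out = features_at_layer(h.f, h.g, i)
        total += (L // 2**i) * h.k * c_in * c_out
    c_last = features_at_layer(h.f, h.g, h.n - 1)
    total += c_last * h.p
    total += h.p * n_nodes
    return total


def scale_features_to_budget(
    h: Hyperparameters,
    budget: float = DEFAULT_MACC_BUDGET,
    L: int = DEFAULT_MACC_REF_LENGTH,
    n_nodes: int = 53,
) -> int:
    """Largest first-layer feature count ``f`` whose MACC count fits ``budget``."""

    def cost(f: int) -> int:
        trial = Hyperparameters(**{**asdict(h), "f": f})
        return macc_count(trial, L, n_nodes)

    if cost(1) > budget:
        raise ValueError(f"budget {budget:g} below the cost of f=1 ({cost(1)})")
    lo, hi = 1, 2
    while cost(hi) <= budget:
        lo, hi = hi, hi * 2
    # invariant: cost(lo) <= budget < cost(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if cost(mid) <= budget:
            lo = mid
        else:
            hi = mid
    return lo


# ---------------------------------------------------------------------------
# Hierarchical softmax head
# ---------------------------------------------------------------------------


@dataclass
class NodeProbabilities:
    """Conditional (given parent) and joint probabilities per non-root node."""

    conditional: np.ndarray
    joint: np.ndarray


@dataclass
class HierarchicalPrediction:
    """Threshold-accepted node (or Unknown) plus the full probability vectors."""

    accepted_node: TaxonomyNode | None
    accepted_level: str  # "unknown" | "type" | "subtype"
    probabilities: NodeProbabilities

    @property
    def accepted_label(self) -> str:
        return "Unknown" if self.accepted_node is None else self.accepted_node.path


def _sibling_groups(tree: TaxonomyTree) -> list[np.ndarray]:
    """Index arrays of each softmax group: the types, then each type's children."""
    groups = [np.array([t.logit_index for t in tree.type_nodes])]
    for t in tree.type_nodes:
        if t.children:
            groups.append(np.array([c.logit_index for c in t.children]))
    return groups


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def node_probabilities(logits: np.ndarray, tree: TaxonomyTree) -> NodeProbabilities:
    """Softmax over each sibling set; joints are root-to-node path products."""
    logits = np.asarray(logits, dtype=np.float64)
    if logits.shape != (tree.n_nodes,):
        raise ValueError(f"expected {tree.n_nodes} logits, got {logits.shape}")
    cond = np.empty_like(logits)
    for group in _sibling_groups(tree):
        cond[group] = _softmax(logits[group])
    joint = cond.copy()
    for t in tree.type_nodes:
        for c in t.children:
            joint[c.logit_index] = cond[c.logit_index] * joint[t.logit_index]
    return NodeProbabilities(conditional=cond, joint=joint)


def batch_joint_probabilities(logits: np.ndarray, tree: TaxonomyTree) -> np.ndarray:
    """Joint probabilities for a (B, n_nodes) logit matrix (vectorized)."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    cond = np.empty_like(logits)
    for group in _sibling_groups(tree):
        cond[:, group] = _softmax(logits[:, group], axis=1)
    joint = cond.copy()
    for t in tree.type_nodes:
        idx = [c.logit_index for c in t.children]
        if idx:
            joint[:, idx] = cond[:, idx] * joint[:, [t.logit_index]]
    return joint


def hierarchical_loss(
    logits: np.ndarray, tree: TaxonomyTree, truth: TaxonomyNode, phi: float
) -> float:
    """Type cross-entropy plus ``phi`` × SubType cross-entropy (if truth is a SubType)."""
    if truth not in tree:
        raise ValueError(f"truth node {truth!r} is not in the tree")
    logits = np.asarray(logits, dtype=np.float64)
    type_node = truth if truth.level == "type" else truth.parent
    tgroup = np.array([t.logit_index for t in tree.type_nodes])
    tlog = logits[tgroup]
    loss = float(np.logaddexp.reduce(tlog) - logits[type_node.logit_index])
    if truth.level == "subtype":
        sgroup = np.array([c.logit_index for c in type_node.children])
        slog = logits[sgroup]
        loss += phi * float(np.logaddexp.reduce(slog) - logits[truth.logit_index])
    return loss


def greedy_predict(
    probs: NodeProbabilities, tree: TaxonomyTree, threshold: float
) -> HierarchicalPrediction:
    """Accept the best Type if its joint surpasses ``threshold``; descend to its
    best SubType when that joint also surpasses the threshold; else Unknown."""
    type_idx = np.array([t.logit_index for t in tree.type_nodes])
    best_t = tree.type_nodes[int(np.argmax(probs.joint[type_idx]))]
    if probs.joint[best_t.logit_index] <= threshold:
        return HierarchicalPrediction(None, "unknown", probs)
    if best_t.children:
        child_idx = np.array([c.logit_index for c in best_t.children])
        best_s = best_t.children[int(np.argmax(probs.joint[child_idx]))]
        if probs.joint[best_s.logit_index] > threshold:
            return HierarchicalPrediction(best_s, "subtype", probs)
    return HierarchicalPrediction(best_t, "type", probs)


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------


class ConvHierarchicalNet:
    """The classifier: embedding, conv blocks, masked pooling, dense head.

    Forward and backward are implemented with im2col convolutions so all the
    heavy lifting is BLAS matrix products.  Global average pooling is masked:
    only positions derived from real (non-padding) input enter the average,
    which makes logits independent of how much a batch is padded.
    """

    #: Embedding-vs-first-conv scale split of the input-scaled initialization.
    EMB_INIT_GAIN = 64.0

    def __init__(
        self,
        h: Hyperparameters,
        tree: TaxonomyTree,
        seed: int = 0,
        macc_ref_length: int = DEFAULT_MACC_REF_LENGTH,
    ):
        if h.f is None:
            f = scale_features_to_budget(
                h, DEFAULT_MACC_BUDGET, macc_ref_length, tree.n_nodes
            )
            h = Hyperparameters(**{**asdict(h), "f": f})
        self.h = h
        self.tree = tree
        self.macc_ref_length = macc_ref_length
        self.channels = [features_at_layer(h.f, h.g, i) for i in range(h.n)]
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        # Input-scaled initialization: the embedding is drawn at a large scale
        # and the first convolution is shrunk by the same factor, so the
        # function at initialization is the standard He-initialized one but
        # the first-layer filters sit at a small norm.  Adam's step size is
        # scale-free per coordinate, so the filters that must reorganize the
        # most (the motif detectors of block 0) reach their solution in far
        # fewer steps on short training budgets.  Purely a conditioning
        # choice: it changes where in weight space training starts, not the
        # model family.
        self.params["emb"] = rng.normal(0.0, self.EMB_INIT_GAIN, (VOCAB_SIZE, h.e))
        self.params["emb"][PAD_INDEX] = 0.0
        c_in = h.e
        for i, c_out in enumerate(self.channels):
            scale = math.sqrt(2.0 / (h.k * c_in))
            if i == 0:
                scale /= self.EMB_INIT_GAIN
            self.params[f"conv_w{i}"] = rng.normal(0.0, scale, (h.k * c_in, c_out))
            self.params[f"conv_b{i}"] = np.zeros(c_out)
            c_in = c_out
        self.params["dense_w"] = rng.normal(
            0.0, math.sqrt(2.0 / c_in), (c_in, h.p)
        )
        self.params["dense_b"] = np.zeros(h.p)
        self.params["out_w"] = rng.normal(
            0.0, math.sqrt(1.0 / h.p), (h.p, tree.n_nodes)
        )
        self.params["out_b"] = np.zeros(tree.n_nodes)
        self._groups = _sibling_groups(tree)

    # -- batching helpers ---------------------------------------------------

    def pad_batch(self, seqs: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Right-pad encoded sequences to a common length (multiple of 2^n)."""
        if len(seqs) == 0:
            raise ValueError("empty batch")
        block = 2**self.h.n
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        L = int(max(lengths.max(), block))
        L = ((L + block - 1) // block) * block
        batch = np.full((len(seqs), L), PAD_INDEX, dtype=np.int64)
        for i, s in enumerate(seqs):
            batch[i, : len(s)] = s
        return batch, np.maximum(lengths, block)

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """(B, L, C) -> (B, L, k*C) patches of a same-padded width-k window."""
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # win: (B, L, C, k) -> (B, L, k, C)
        win = win.transpose(0, 1, 3, 2)
        B, L, _, C = win.shape
        return np.ascontiguousarray(win).reshape(B, L, k * C)

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        batch: np.ndarray,
        lengths: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        want_cache: bool = False,
    ):
        """Compute logits (B, n_nodes); optionally keep a cache for backward."""
        h = self.h
        if batch.ndim != 2 or batch.shape[0] == 0:
            raise ValueError("batch must be a non-empty (B, L) integer array")
        if training and h.d > 0 and rng is None:
            raise ValueError("training forward with dropout needs an rng")
        B, L = batch.shape
        valid = lengths.astype(np.int64).copy()
        pos = np.arange(L)
        mask = (pos[None, :] < valid[:, None]).astype(np.float64)
        x = self.params["emb"][batch] * mask[:, :, None]
        cache = {"batch": batch, "masks": [mask], "valids": [valid.copy()], "layers": []}
        for i in range(h.n):
            w, b = self.params[f"conv_w{i}"], self.params[f"conv_b{i}"]
            cols = self._im2col(x, h.k)
            pre = cols @ w + b
            pre *= mask[:, :, None]
            relu_mask = pre > 0
            act = pre * relu_mask
            if training and h.d > 0:
                keep = rng.random(act.shape) >= h.d
                act = act * keep / (1.0 - h.d)
            else:
                keep = None
            Lp = act.shape[1] // 2
            windows = act[:, : 2 * Lp].reshape(B, Lp, 2, -1)
            argmax = windows.argmax(axis=2)
            pooled = np.take_along_axis(windows, argmax[:, :, None, :], axis=2)[
                :, :, 0, :
            ]
            valid = valid // 2
            pos = np.arange(Lp)
            new_mask = (pos[None, :] < valid[:, None]).astype(np.float64)
            pooled = pooled * new_mask[:, :, None]
            if want_cache:
                cache["layers"].append(
                    {
                        "cols": cols,
                        "relu_mask": relu_mask,
                        "keep": keep,
                        "argmax": argmax,
                        "in_len": act.shape[1],
                        "mask_in": mask,
                    }
                )
            x, mask = pooled, new_mask
            cache["masks"].append(mask)
            cache["valids"].append(valid.copy())
        # masked global average
        denom = np.maximum(valid, 1).astype(np.float64)
        avg = x.sum(axis=1) / denom[:, None]
        dense_pre = avg @ self.params["dense_w"] + self.params["dense_b"]
        dense_relu = dense_pre > 0
        dense_act = dense_pre * dense_relu
        logits = dense_act @ self.params["out_w"] + self.params["out_b"]
        if want_cache:
            cache.update(
                {
                    "x_final": x,
                    "denom": denom,
                    "avg": avg,
                    "dense_relu": dense_relu,
                    "dense_act": dense_act,
                }
            )
            return logits, cache
        return logits

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the summed loss w.r.t. every parameter."""
        h = self.h
        grads: dict[str, np.ndarray] = {}
        grads["out_w"] = cache["dense_act"].T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        ddense = (dlogits @ self.params["out_w"].T) * cache["dense_relu"]
        grads["dense_w"] = cache["avg"].T @ ddense
        grads["dense_b"] = ddense.sum(axis=0)
        davg = ddense @ self.params["dense_w"].T
        x = cache["x_final"]
        B, Lp, C = x.shape
        dx = np.broadcast_to(
            (davg / cache["denom"][:, None])[:, None, :], (B, Lp, C)
        ) * cache["masks"][h.n][:, :, None]
        for i in reversed(range(h.n)):
            layer = cache["layers"][i]
            in_len = layer["in_len"]
            Lp = dx.shape[1]
            dwindows = np.zeros((B, Lp, 2, dx.shape[2]))
            np.put_along_axis(dwindows, layer["argmax"][:, :, None, :], dx[:, :, None, :], axis=2)
            dact = np.zeros((B, in_len, dx.shape[2]))
            dact[:, : 2 * Lp] = dwindows.reshape(B, 2 * Lp, -1)
            if layer["keep"] is not None:
                dact = dact * layer["keep"] / (1.0 - h.d)
            dpre = dact * layer["relu_mask"] * layer["mask_in"][:, :, None]
            w = self.params[f"conv_w{i}"]
            cols = layer["cols"]
            grads[f"conv_w{i}"] = np.tensordot(cols, dpre, axes=([0, 1], [0, 1]))
            grads[f"conv_b{i}"] = dpre.sum(axis=(0, 1))
            # grad w.r.t. conv input: correlate dpre with the flipped kernel
            c_in = w.shape[0] // h.k
            c_out = w.shape[1]
            w_k = w.reshape(h.k, c_in, c_out)[::-1]  # flip taps
            w_rot = w_k.transpose(0, 2, 1).reshape(h.k * c_out, c_in)
            dcols = self._im2col(dpre, h.k)
            dx = dcols @ w_rot
            dx *= layer["mask_in"][:, :, None]
        demb = np.zeros_like(self.params["emb"])
        np.add.at(demb, cache["batch"].reshape(-1), dx.reshape(-1, dx.shape[2]))
        demb[PAD_INDEX] = 0.0
        grads["emb"] = demb
        return grads

    # -- loss over a batch --------------------------------------------------

    def loss_and_grad_logits(
        self, logits: np.ndarray, truth_indices: np.ndarray, truth_is_subtype: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Mean hierarchical loss over the batch and its gradient w.r.t. logits.

        ``truth_indices`` holds each sample's truth logit index;
        ``truth_is_subtype`` flags truths known to SubType depth.
        """
        h = self.h
        B = logits.shape[0]
        dlogits = np.zeros_like(logits)
        total = 0.0
        tgroup = self._groups[0]
        tlog = logits[:, tgroup]
        tsm = _softmax(tlog, axis=1)
        by_index = {n.logit_index: n for n in self.tree.nodes()}
        for b in range(B):
            truth = by_index[int(truth_indices[b])]
            type_node = truth if truth.level == "type" else truth.parent
            ti = list(tgroup).index(type_node.logit_index)
            total += float(np.log(np.sum(np.exp(tlog[b] - tlog[b].max()))) + tlog[b].max() - tlog[b, ti])
            grad_t = tsm[b].copy()
            grad_t[ti] -= 1.0
            dlogits[b, tgroup] += grad_t
            if truth_is_subtype[b]:
                sgroup = np.array([c.logit_index for c in type_node.children])
                slog = logits[b, sgroup]
                ssm = _softmax(slog)
                si = list(sgroup).index(truth.logit_index)
                total += h.phi * float(
                    np.log(np.sum(np.exp(slog - slog.max()))) + slog.max() - slog[si]
                )
                grad_s = h.phi * ssm
                grad_s[si] -= h.phi
                dlogits[b, sgroup] += grad_s
        return total / B, dlogits / B


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------


def save_model(net: ConvHierarchicalNet, path: str | Path) -> None:
    """Write a self-describing model archive (weights + hyperparameters +
    taxonomy + vocabulary + MACC reference length)."""
    meta = {
        "format": "repclassify-model-1",
        "hyperparameters": asdict(net.h),
        "taxonomy_paths": [n.path for n in net.tree.nodes()],
        "vocabulary": {"pad": PAD_INDEX, "size": VOCAB_SIZE,
                       "codes": {"A": 1, "C": 2, "G": 3, "T": 4, "U": 4, "other_iupac": 5}},
        "macc_ref_length": net.macc_ref_length,
    }
    arrays = {f"param/{k}": v for k, v in net.params.items()}
    with open(path, "wb") as fh:  # keep the caller's filename, whatever suffix
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_model(path: str | Path) -> ConvHierarchicalNet:
    """Load a model archive written by :func:`save_model`."""
    with np.load(path) as data:
        if "__meta__" not in data:
            raise ValueError(f"{path}: not a repclassify model archive")
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != "repclassify-model-1":
            raise ValueError(f"{path}: unsupported model format {meta.get('format')!r}")
        tree = tree_from_paths(meta["taxonomy_paths"])
        h = Hyperparameters(**meta["hyperparameters"])
        net = ConvHierarchicalNet(h, tree, macc_ref_length=meta["macc_ref_length"])
        for key in data.files:
            if key.startswith("param/"):
                net.params[key[len("param/"):]] = data[key]
    return net
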