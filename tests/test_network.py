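import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repclassify.network import (
    ConvHierarchicalNet,
    Hyperparameters,
    batch_joint_probabilities,
    features_at_layer,
    greedy_predict,
    hierarchical_loss,
    load_model,
    macc_count,
    node_probabilities,
    save_model,
    scale_features_to_budget,
    NodeProbabilities,
)
from repclassify.sequence_data import encode
from repclassify.synthetic_fixtures import make_toy_taxonomy

SMALL = Hyperparameters(e=4, n=2, k=3, d=0.0, g=1.5, p=8, phi=1.0, f=3)


# -- feature growth and MACC accounting -------------------------------------


@pytest.mark.parametrize(
    "f,g,i,expected",
    [(16, 2.0, 2, 64), (10, 1.96, 1, 20), (10, 1.96, 0, 10), (1, 1.0, 5, 1)],
)
def test_features_at_layer(f, g, i, expected):
    assert features_at_layer(f, g, i) == expected


def test_macc_closed_form():
    h = Hyperparameters(e=2, n=1, k=3, d=0.0, g=1.0, p=5, phi=1.0, f=4)
    assert macc_count(h, L=8, n_nodes=3) == 8 * 3 * 2 * 4 + 4 * 5 + 5 * 3


def test_macc_linearity_in_length():
    h = Hyperparameters(e=6, n=3, k=5, d=0.0, g=1.7, p=64, phi=1.0, f=8)
    conv_l = macc_count(h, 256, 10) - (features_at_layer(8, 1.7, 2) * 64 + 64 * 10)
    assert macc_count(h, 512, 10) - macc_count(h, 256, 10) == conv_l


def test_macc_rejects_too_short():
    h = Hyperparameters(e=2, n=3, k=3, d=0.0, g=1.0, p=4, phi=1.0, f=2)
    with pytest.raises(ValueError):
        macc_count(h, L=7, n_nodes=3)


def _brute_force_macc(h, L, n_nodes):
    """Independent loop-nest multiply counter."""
    total = 0
    length = L
    c_in = h.e
    for i in range(h.n):
        c_out = max(1, int(math.floor(h.f * h.g**i + 0.5)))
        for _pos in range(length):
            total += h.k * c_in * c_out
        c_in = c_out
        length //= 2
    total += c_in * h.p
    total += h.p * n_nodes
    return total


def test_macc_matches_brute_force_counter():
    rng = np.random.default_rng(5)
    for _ in range(20):
        h = Hyperparameters(
            e=int(rng.integers(2, 24)),
            n=int(rng.integers(1, 5)),
            k=int(rng.choice([3, 5, 7, 9])),
            d=0.0,
            g=float(rng.uniform(1.0, 2.5)),
            p=int(rng.integers(8, 512)),
            phi=1.0,
            f=int(rng.integers(1, 40)),
        )
        L = int(rng.integers(2**h.n, 600))
        n_nodes = int(rng.integers(2, 60))
        assert macc_count(h, L, n_nodes) == _brute_force_macc(h, L, n_nodes)


def test_scale_features_linear_scan():
    base = Hyperparameters(e=8, n=3, k=7, d=0.0, g=1.5, p=128, phi=1.0, f=1)
    for budget in [1e6, 1e7, 1e8, 1e10]:
        f = scale_features_to_budget(base, budget, L=1024, n_nodes=20)
        costs = [
            macc_count(
                Hyperparameters(e=8, n=3, k=7, d=0.0, g=1.5, p=128, phi=1.0, f=ff),
                1024,
                20,
            )
            for ff in range(1, f + 2)
        ]
        assert all(costs[i] <= costs[i + 1] for i in range(len(costs) - 1))
        assert costs[f - 1] <= budget < costs[f]


def test_scale_features_exact_and_tiny_budget():
    base = Hyperparameters(e=4, n=2, k=3, d=0.0, g=2.0, p=16, phi=1.0, f=1)
    exact = macc_count(
        Hyperparameters(e=4, n=2, k=3, d=0.0, g=2.0, p=16, phi=1.0, f=7), 64, 5
    )
    assert scale_features_to_budget(base, exact, 64, 5) == 7
    with pytest.raises(ValueError):
        scale_features_to_budget(base, 10, 64, 5)


# -- hierarchical softmax ----------------------------------------------------


def test_equal_logits_give_uniform_conditionals(toy_tree):
    probs = node_probabilities(np.zeros(toy_tree.n_nodes), toy_tree)
    for t in toy_tree.type_nodes:
        assert probs.conditional[t.logit_index] == pytest.approx(1 / 3)
        for c in t.children:
            assert probs.conditional[c.logit_index] == pytest.approx(0.5)


def test_sole_child_conditional_is_one():
    tree, _ = make_toy_taxonomy(2, 1)
    probs = node_probabilities(np.random.default_rng(0).normal(size=tree.n_nodes), tree)
    for t in tree.type_nodes:
        (child,) = t.children
        assert probs.conditional[child.logit_index] == pytest.approx(1.0)


def test_probability_invariants_random_draws(toy_tree, rng):
    """Per-parent conditionals sum to 1; type joints sum to 1; child <= parent."""
    for _ in range(200):
        probs = node_probabilities(rng.normal(scale=3, size=toy_tree.n_nodes), toy_tree)
        type_sum = sum(probs.joint[t.logit_index] for t in toy_tree.type_nodes)
        assert type_sum == pytest.approx(1.0, abs=1e-9)
        for t in toy_tree.type_nodes:
            if t.children:
                cond_sum = sum(probs.conditional[c.logit_index] for c in t.children)
                assert cond_sum == pytest.approx(1.0, abs=1e-9)
                for c in t.children:
                    assert 0 <= probs.joint[c.logit_index] <= probs.joint[t.logit_index] + 1e-12


def test_loss_uniform_closed_forms():
    tree, _ = make_toy_taxonomy(4, 2)
    logits = np.zeros(tree.n_nodes)
    t = tree.node("T01")
    s = tree.node("T01/S01")
    assert hierarchical_loss(logits, tree, t, phi=1.0) == pytest.approx(math.log(4))
    assert hierarchical_loss(logits, tree, s, phi=1.0) == pytest.approx(
        math.log(4) + math.log(2)
    )


def test_loss_phi_zero_is_type_only(toy_tree, rng):
    s = toy_tree.node("T02/S01")
    t = toy_tree.node("T02")
    for _ in range(20):
        logits = rng.normal(size=toy_tree.n_nodes)
        assert hierarchical_loss(logits, toy_tree, s, phi=0.0) == pytest.approx(
            hierarchical_loss(logits, toy_tree, t, phi=1.0)
        )


def test_loss_equals_neg_log_joint_at_phi_one(rng):
    for _ in range(100):
        tree, _ = make_toy_taxonomy(int(rng.integers(2, 5)), int(rng.integers(1, 4)))
        logits = rng.normal(scale=2, size=tree.n_nodes)
        node = tree.subtype_nodes[int(rng.integers(len(tree.subtype_nodes)))]
        probs = node_probabilities(logits, tree)
        assert hierarchical_loss(logits, tree, node, phi=1.0) == pytest.approx(
            -math.log(probs.joint[node.logit_index]), abs=1e-6
        )


def test_loss_rejects_foreign_node(toy_tree):
    other, _ = make_toy_taxonomy(2, 1)
    with pytest.raises(ValueError):
        hierarchical_loss(np.zeros(toy_tree.n_nodes), toy_tree, other.node("T01"), 1.0)


# -- greedy thresholded prediction ------------------------------------------


def _handmade_probs(tree):
    """P(A)=0.9, P(B)=0.1, P(A1|A)=0.6, P(A2|A)=0.4 on a 2-type/2-subtype tree."""
    joint = np.zeros(tree.n_nodes)
    cond = np.zeros(tree.n_nodes)
    a, b = tree.node("T01"), tree.node("T02")
    a1, a2 = tree.node("T01/S01"), tree.node("T01/S02")
    cond[a.logit_index], cond[b.logit_index] = 0.9, 0.1
    cond[a1.logit_index], cond[a2.logit_index] = 0.6, 0.4
    joint[:] = cond
    joint[a1.logit_index] = 0.54
    joint[a2.logit_index] = 0.36
    joint[tree.node("T02/S01").logit_index] = 0.06
    joint[tree.node("T02/S02").logit_index] = 0.04
    return NodeProbabilities(conditional=cond, joint=joint)


@pytest.mark.parametrize(
    "threshold,label,level",
    [(0.7, "T01", "type"), (0.5, "T01/S01", "subtype"), (0.95, "Unknown", "unknown")],
)
def test_greedy_predict_threshold_cases(threshold, label, level):
    tree, _ = make_toy_taxonomy(2, 2)
    pred = greedy_predict(_handmade_probs(tree), tree, threshold)
    assert pred.accepted_label == label
    assert pred.accepted_level == level


def test_greedy_predict_monotone_in_threshold(toy_tree, rng):
    order = {"subtype": 2, "type": 1, "unknown": 0}
    for _ in range(50):
        probs = node_probabilities(rng.normal(scale=2, size=toy_tree.n_nodes), toy_tree)
        levels = [
            order[greedy_predict(probs, toy_tree, t).accepted_level]
            for t in np.linspace(0, 1, 11)
        ]
        assert all(a >= b for a, b in zip(levels, levels[1:]))


# -- forward pass ------------------------------------------------------------


def test_forward_deterministic_and_batch_equivariant(toy_tree):
    net = ConvHierarchicalNet(SMALL, toy_tree, seed=3)
    seqs = [encode("ACGTACGTACGT"), encode("GGTTAACCGGTTAACC"), encode("ACGTACGTACGT")]
    batch, lengths = net.pad_batch(seqs)
    logits = net.forward(batch, lengths)
    assert np.allclose(logits[0], logits[2])
    perm = [1, 2, 0]
    logits_p = net.forward(batch[perm], lengths[perm])
    assert np.allclose(logits_p, logits[perm])
    assert np.isfinite(logits).all()


def test_forward_padding_invariance(toy_tree):
    net = ConvHierarchicalNet(SMALL, toy_tree, seed=3)
    short = encode("ACGTACGTACG")
    long = encode("A" * 64)
    b1, l1 = net.pad_batch([short])
    single = net.forward(b1, l1)
    b2, l2 = net.pad_batch([short, long])
    batched = net.forward(b2, l2)
    assert np.abs(single[0] - batched[0]).max() < 1e-4


def test_forward_handmade_convolution():
    """One block, hand-set +-1/0 weights, length-6 input vs pencil arithmetic."""
    tree, _ = make_toy_taxonomy(2, 0)
    h = Hyperparameters(e=2, n=1, k=3, d=0.0, g=1.0, p=2, phi=1.0, f=1)
    net = ConvHierarchicalNet(h, tree, seed=0)
    # embedding: A=(1,0), C=(0,1), others 0
    emb = np.zeros((6, 2))
    emb[1] = [1, 0]
    emb[2] = [0, 1]
    net.params["emb"] = emb
    # conv: detects A at the center tap: w[center, dim0] = 1
    w = np.zeros((3 * 2, 1))
    w[2] = 1.0  # tap index 1 (center), channel 0
    net.params["conv_w0"] = w
    net.params["conv_b0"][:] = 0.0
    net.params["dense_w"] = np.ones((1, 2))
    net.params["dense_b"][:] = 0.0
    net.params["out_w"] = np.array([[1.0, -1.0], [0.0, 0.0]])
    net.params["out_b"][:] = 0.0
    # input ACACAA -> conv output per position = [1,0,1,0,1,1] (A detector)
    # ReLU same; maxpool pairs -> [1,1,1]; masked average = 1 -> dense=[1,1]
    # logits = [1, -1]
    batch, lengths = net.pad_batch([encode("ACACAA")])
    logits = net.forward(batch, lengths)
    assert np.allclose(logits[0], [1.0, -1.0])


def test_forward_gradients_match_numerical(toy_tree):
    net = ConvHierarchicalNet(SMALL, toy_tree, seed=1)
    seqs = [encode("ACGTACGTACGTAAA"), encode("GGGTTTAACCGG")]
    batch, lengths = net.pad_batch(seqs)
    ti = np.array(
        [toy_tree.node("T01/S01").logit_index, toy_tree.node("T02").logit_index]
    )
    ts = np.array([True, False])
    logits, cache = net.forward(batch, lengths, want_cache=True)
    _, dlogits = net.loss_and_grad_logits(logits, ti, ts)
    grads = net.backward(cache, dlogits)
    rng = np.random.default_rng(0)
    eps = 1e-6
    for name, p in net.params.items():
        flat = p.reshape(-1)
        for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = net.loss_and_grad_logits(net.forward(batch, lengths), ti, ts)
            flat[idx] = orig - eps
            lm, _ = net.loss_and_grad_logits(net.forward(batch, lengths), ti, ts)
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name].reshape(-1)[idx] == pytest.approx(num, abs=1e-6, rel=1e-4)


def test_batch_joint_matches_single(toy_tree, rng):
    logits = rng.normal(size=(4, toy_tree.n_nodes))
    joint = batch_joint_probabilities(logits, toy_tree)
    for b in range(4):
        single = node_probabilities(logits[b], toy_tree)
        assert np.allclose(joint[b], single.joint)


def test_empty_batch_rejected(toy_tree):
    net = ConvHierarchicalNet(SMALL, toy_tree, seed=0)
    with pytest.raises(ValueError):
        net.pad_batch([])


# -- model archive -----------------------------------------------------------


def test_model_save_load_roundtrip(tmp_path, toy_tree):
    net = ConvHierarchicalNet(SMALL, toy_tree, seed=11)
    path = tmp_path / "model.rcm"
    save_model(net, path)
    loaded = load_model(path)
    assert loaded.h == net.h
    assert [n.path for n in loaded.tree.nodes()] == [n.path for n in net.tree.nodes()]
    seqs = [encode("ACGTACGTACGTACGT")]
    b, l = net.pad_batch(seqs)
    assert np.allclose(net.forward(b, l), loaded.forward(b, l))


def test_load_model_rejects_garbage(tmp_path):
    p = tmp_path / "junk.rcm"
    np.savez(open(p, "wb"), x=np.arange(3))
    with pytest.raises(ValueError):
        load_model(p)
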