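# repclassify

Deep-learning classification of repeat consensus sequences under the
RepeatMasker schema.

De novo repeat discovery tools (RepeatModeler and friends) emit libraries of
consensus sequences in which a large fraction of families — often most of
them in non-model taxa — are labelled `Unknown`. `repclassify` assigns those
families a RepeatMasker *Order* ("Type": LTR, LINE, SINE, DNA, RC,
Retroposon, Satellite, rRNA, tRNA) and, where confident, a *Superfamily*
("SubType": `LTR/Gypsy`, `LINE/L1`, `DNA/hAT`, ...), so that the library can
drop straight into a RepeatModeler → RepeatMasker annotation workflow. It is
aimed at genome-annotation practitioners working on repeat-rich, poorly
represented genomes.

## The model

A 1-D convolutional network over embedded nucleotides with a hierarchical
softmax head. Nucleotides (A, C, G, T/U, ambiguous) are embedded in an
`e`-dimensional space; `n` blocks of (same-padded convolution, kernel `k` →
ReLU → dropout `d` → max-pool /2) follow, with `round(f·gⁱ)` features at
block `i`; a masked global average feeds a dense layer of size `p` and a
linear map to one logit per taxonomy node. The head applies an independent
softmax over each node's children; joint probabilities are path products

    P(Order o) = softmax_orders(z)_o ,   P(o/s) = P(o) · softmax_children(o)(z)_s

and the loss is `CE(Order) + φ·CE(Superfamily)`. A prediction is accepted at
a level only when its joint probability surpasses a user threshold
(default 0.7), falling back Superfamily → Order → `Unknown`; raising the
threshold trades coverage for accuracy. A Repbase → RepeatMasker translation
layer (156 source categories → 9 Types / 44 SubTypes) maps Repbase-style
labels onto the prediction tree. Model capacity is budgeted in
multiply-accumulate operations (2×10¹⁰ at a 4096-bp reference length), which
fixes the first-layer feature count `f`.

See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

Train a small model on a generated motif-planted corpus and classify with
it:

```python
from repclassify.network import Hyperparameters, save_model
from repclassify.sequence_data import encode, write_fasta
from repclassify.synthetic_fixtures import FixtureSpec, generate
from repclassify.training import TrainConfig, TrainItem, train
from repclassify.classify import classify_fasta

spec = FixtureSpec(n_types=3, subtypes_per_type=2, n_seqs_per_leaf=40,
                   length_range=(150, 300), substitution_rate=0.02,
                   background_gc=0.45, seed=42)
corpus = generate(spec)
items = [TrainItem(encode(r.sequence), n)
         for r, n in zip(corpus.records, corpus.truth)]
net, hist = train(items[::2], items[1::2],
                  Hyperparameters(e=6, n=2, k=7, d=0.0, g=1.5, p=64, phi=1.0, f=12),
                  corpus.tree, TrainConfig(epochs=60, batch_size=16, seed=0))
print(f"held-out Order accuracy:       {max(hist.order_accuracy):.3f}")
print(f"held-out Superfamily accuracy: {max(hist.superfamily_accuracy):.3f}")

write_fasta(corpus.records[:3], "example.fa")
save_model(net, "example_model.rcm")
records, rows = classify_fasta("example.fa", "example_model.rcm", threshold=0.7)
for row in rows:
    best = max(row.joint[[t.logit_index for t in net.tree.type_nodes]])
    print(row.seq_id, row.accepted_label, f"P={best:.3f}")
```

Output:

```
held-out Order accuracy:       0.750
held-out Superfamily accuracy: 0.633
fx-00001 T01 P=0.932
fx-00002 T01/S01 P=0.898
fx-00003 T01/S01 P=0.784
```

The accuracies are argmax (threshold-free) metrics on the held-out half of
the corpus. In the per-record lines, `fx-00001` cleared the 0.7 threshold at
the Order level only (its best Superfamily joint stayed below 0.7), while
the other two were confidently assigned a Superfamily; all three truly
belong to `T01`.

The same inference is available from the shell:

```bash
repclassify classify consensi.fa --model model.rcm --threshold 0.7 \
    --output-csv classified.csv --output-fasta consensi.classified.fa
```

The CSV has one row per input with the accepted label and the joint
probability of every taxonomy node; the FASTA rewrites each header to
`>id#Type/SubType` (or `#Type`, `#Unknown`) for downstream RepeatMasker use.

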