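# Methods

## The model

`repclassify` classifies repeat consensus sequences (for example the entries
of a RepeatModeler `consensi.fa`) into the RepeatMasker two-level schema:
an *Order* ("Type": LTR, LINE, SINE, DNA, RC, Retroposon, Satellite, rRNA,
tRNA) and, within an Order, a *Superfamily* ("SubType": LTR/Gypsy, LINE/L1,
DNA/hAT, ...).

The classifier is a one-dimensional convolutional network over embedded
nucleotides. Each symbol of the five-letter alphabet {A, C, G, T/U,
ambiguous} is embedded in an `e`-dimensional space (index 0 is reserved for
padding and contributes nothing). `n` convolutional blocks follow; block
`i` applies a stride-1, same-padded convolution with kernel size `k` and
`round(f·gⁱ)` output features, then ReLU, dropout with probability `d`, and
max-pooling by a factor of 2. The resulting feature maps are averaged
globally — over positions derived from real input only, so results do not
depend on batch padding — and passed through a penultimate dense layer of
size `p` (ReLU) to a final linear map with one logit per taxonomy node.

The output head is a hierarchical softmax over the label tree: an
independent softmax over the Orders, and one over each Order's
Superfamilies. Joint probabilities are path products,

    P(Order o) = softmax_orders(z)_o
    P(o/s)     = P(o) · softmax_children(o)(z)_s

The training loss for a sequence whose truth is Superfamily `s` under Order
`o` is

    L = CE(orders, o) + φ · CE(children(o), s)

with `φ` the Superfamily loss weight; truths known only to Order depth
contribute the first term alone. With φ = 1 the loss is exactly
−log P(truth path), which the test suite asserts against the probability
head.

At inference a user threshold `t` governs a coverage/accuracy trade-off:
the best Order is accepted only if its joint probability exceeds `t`
(strictly); its best Superfamily is then accepted only if that joint also
exceeds `t`; otherwise the prediction falls back to the Order, or to
`Unknown`. Raising `t` can therefore only move a prediction from
Superfamily to Order to Unknown, never the reverse, and classified counts
are nonincreasing in `t`. The default threshold is 0.7.

## Hyperparameters

Defaults are the tuned values for full-corpus training:

| parameter | meaning | default |
|---|---|---|
| `e` | embedding size | 18 |
| `n` | conv blocks | 4 |
| `k` | kernel size (odd) | 7 |
| `d` | dropout probability | 0.248 |
| `g` | feature growth per block | 1.96 |
| `p` | penultimate layer size | 1953 |
| `φ` | Superfamily loss weight | 1.02 |
| `f` | first-layer features | derived from the MACC budget |

`f` is not tuned directly: it is set to the largest value whose
multiply-accumulate (MACC) count per forward pass stays within a budget of
2×10¹⁰ at a reference length of 4096 bp (the reference length is a package
convention, recorded in every model archive). Rounding of `f·gⁱ` is
half-away-from-zero, fixed for reproducibility.

Training uses Adam (moments 0.9/0.99, no weight decay) with a 1cycle
learning-rate schedule: a cosine rise from `peak/25` to the peak (10⁻³ by
default) over the first 25% of steps, then a cosine anneal to
`peak/(25·10⁵)`. Batches of 32 are formed after bucketing sequences by
length inside the seeded shuffle, limiting padding waste on corpora whose
lengths span orders of magnitude. The checkpoint with the best validation
Superfamily accuracy is retained. Hyperparameter search is a seeded random
search (validation Superfamily accuracy objective) over documented ranges;
`f` is re-derived from the budget per trial.

## Numerical and design choices

- **Encoding.** IUPAC ambiguity codes all collapse onto one "ambiguous"
  symbol rather than receiving embedding capacity; T and U share a code;
  soft-masking (case) is ignored. Gaps are rejected with positions listed.
- **Padding.** Sequences shorter than 2ⁿ are right-padded to 2ⁿ; pooling
  uses floor division and the valid length is tracked per block, so the
  masked global average sees only real-sequence positions. Appending
  padding to a batched sequence leaves its logits unchanged.
- **Initialization.** Weights are He-initialized, except that the embedding
  is drawn at a large scale (64) with the first convolution shrunk by the
  same factor. The function at initialization is unchanged, but the
  first-layer filters — the ones that must reorganize into motif detectors —
  sit at a small norm, and since Adam's per-coordinate step is scale-free
  they converge in far fewer steps. This conditioning choice matters on
  short training budgets and is neutral on long ones.
- **Threshold semantics.** The threshold applies at the Order level too
  (strict inequality), so a maximally uncertain model classifies nothing.
  "Unknown" is the absence of an accepted prediction, not a taxonomy node.
- **Tie-breaking.** Logit indices are assigned alphabetically by full node
  path; two builds of the same translation table agree exactly.
- **Determinism.** A single integer seed fixes initialization, shuffling,
  bucketing, and dropout; identical seeds give identical training
  histories. Dropout is inference-disabled.
- **No strand handling.** Input orientation is used as given; there is no
  reverse-complement averaging.

## The translation layer

Repbase names families with its own category strings; the packaged table
(`repclassify/data/repbase_to_repeatmasker.tsv`) maps 156 such categories
onto 9 RepeatMasker Types and 44 SubTypes. The table is reconstructed from
publicly documented RepeatMasker classification conventions (Gypsy →
LTR/Gypsy, Mariner/Tc1 → DNA/TcMar, Helitron → RC/Helitron, ...); the
header of the resource states this provenance. Unmapped categories
translate to a distinguished unmapped value, and the caller decides whether
to drop such records.

## The synthetic fixture

Real repeat superfamilies are recognizable partly by conserved sequence
domains. The fixture generator emulates that: a toy taxonomy whose leaves
each carry a few fixed random motifs, planted at non-overlapping positions
into i.i.d. background sequence of controlled GC content, with per-base
substitution noise (substituted bases are redrawn from the three other
bases, so the observed mismatch rate equals the nominal rate). Because the
signal is exact motifs, a trivial motif-counting oracle gives a non-neural
upper reference: at zero noise it exceeds 99% Order accuracy.

The standard benchmark corpus is 4 Types × 2 SubTypes, 200 sequences per
leaf (1,600 total) of 300–700 bp, three 12-bp motifs per leaf, 5%
substitution noise, GC 0.42, with an 80/20 stratified train/validation
split. What the fixture does **not** emulate: real TE structure (terminal
inverted repeats, LTR ends, ORFs), length distributions spanning tens of
kilobases, shared homology between related superfamilies, and database
label noise. Passing fixture benchmarks therefore demonstrates that the
pipeline learns planted taxonomic signal end to end, not that a model
trained on it classifies real repeat libraries.

## Benchmark scale and known limitations

The parameter-recovery benchmark trains a deliberately small configuration
(e=8, n=3, k=7, f=16, g=1.5, p=128, φ=1, dropout 0) for 25 epochs at batch
32 with 1cycle peak 10⁻³ — about 1,000 optimizer steps on one CPU core, a
few minutes of wall time. This step budget is the binding constraint: the
cumulative learning rate over a 1,000-step 1cycle at peak 10⁻³ is ≈0.5
weight-units per coordinate, which under-resolves the convolutional motif
detectors. With the same data and twice the epochs the held-out Order
accuracy rises from roughly 0.7 to roughly 0.9; corpus-scale training runs
(hundreds of thousands of steps) do not face this limit. The benchmark
numbers reported by `scripts/acceptance.py` are therefore conservative
lower bounds set by the fixed step budget, not by the model family.

Full-scale training on licensed Repbase, and the published accuracy of the
original study design (mean cross-validation accuracy ≈95% Order / ≈94%
Superfamily; test-library accuracies at thresholds 0.7/0.9), are out of
scope here: they require the licensed corpus and GPU-scale compute. The
package reproduces the method — architecture, loss, schedule, partitioning,
capacity budgeting, metrics — and validates it at fixture scale.
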