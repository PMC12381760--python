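import numpy as np
import pytest

from repclassify.synthetic_fixtures import FixtureSpec, generate, make_toy_taxonomy


@pytest.fixture(scope="session")
def toy_tree():
    tree, table = make_toy_taxonomy(3, 2)
    return tree


@pytest.fixture(scope="session")
def toy_tree_and_table():
    return make_toy_taxonomy(3, 2)


@pytest.fixture(scope="session")
def small_corpus():
    """A tiny noiseless corpus: 2 types x 2 subtypes, 12 sequences per leaf."""
    spec = FixtureSpec(
        n_types=2,
        subtypes_per_type=2,
        n_seqs_per_leaf=12,
        length_range=(120, 200),
        motif_length=10,
        n_motifs_per_leaf=2,
        substitution_rate=0.0,
        background_gc=0.5,
        seed=7,
    )
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
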