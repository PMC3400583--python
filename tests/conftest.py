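import numpy as np
import pytest

from fflnet import (EdgeStore, NodeCatalog, RELATIONS, RegulomeSimSpec,
                    gen_regulome, make_edge)


@pytest.fixture
def small_catalog():
    return NodeCatalog(
        genes=frozenset({"g1", "g2", "g3", "g4"}),
        mirnas=frozenset({"m1", "m2"}),
        tfs=frozenset({"t1", "t2"}),
    )


@pytest.fixture
def tf_ffl_store(small_catalog):
    """Minimal store holding one TF-FFL (t1, m1, g1)."""
    store = EdgeStore(small_catalog)
    store.add(make_edge("t1", "g1", "TF-gene"))
    store.add(make_edge("m1", "g1", "miRNA-gene"))
    store.add(make_edge("t1", "m1", "TF-miRNA"))
    return store


def random_store(seed: int, n_tf=4, n_mirna=4, n_gene=4, density=0.2):
    """Seeded random EdgeStore for oracle comparisons."""
    spec = RegulomeSimSpec(
        n_tf=n_tf, n_mirna=n_mirna, n_gene=n_gene,
        background_density={r: density for r in RELATIONS},
        planted={}, seed=seed)
    store, _ = gen_regulome(spec)
    return store
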