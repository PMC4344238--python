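import numpy as np
import pandas as pd
import pytest

from trninfer import motif_engine
from trninfer.genome_io import GeneRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def uniform_bg():
    """Order-0 uniform background."""
    return motif_engine.BackgroundModel(order=0, cond=[np.full((1, 4), 0.25)])


@pytest.fixture(scope="session")
def trained_bg():
    """Order-3 background trained on seeded random sequence."""
    r = np.random.default_rng(7)
    seqs = ["".join(r.choice(list("ACGT"), 3000)) for _ in range(5)]
    return motif_engine.train_background(seqs, order=3)


def make_genes(rows, genome="g0"):
    """rows: (gene_id, replicon, start, end, strand, gene_index)"""
    return [
        GeneRecord(gene_id=r[0], genome_id=genome, replicon_id=r[1], start=r[2], end=r[3], strand=r[4], gene_index=r[5])
        for r in rows
    ]


@pytest.fixture(scope="session")
def expression_with_module(rng):
    """100 genes x 100 conditions; genes m0..m4 share a latent profile on 40
    planted conditions with noise sd 0.3."""
    r = np.random.default_rng(202)
    n, c = 100, 100
    x = r.normal(size=(n, c))
    active = r.choice(c, 40, replace=False)
    latent = r.normal(size=c)
    for g in range(5):
        x[g, active] = latent[active] + 0.3 * r.normal(size=40)
    names = [f"m{i}" for i in range(5)] + [f"n{i}" for i in range(n - 5)]
    df = pd.DataFrame(x, index=names, columns=[f"c{j}" for j in range(c)])
    return df, {f"c{j}" for j in active}
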