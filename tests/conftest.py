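import numpy as np
import pytest

from startseq import (
    SimConfig,
    assign_ribo_density,
    assign_rna_density,
    build_genome,
    quantify_genes,
    simulate_riboseq,
    simulate_rnaseq,
)


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(n_operons=12, ribo_depth=30_000, rna_depth=30_000, seed=7)


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return build_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_tracks(tiny_genome):
    """Density tracks for both conditions of the tiny simulation."""
    g = tiny_genome
    out = {}
    for cond in ("control", "drug"):
        ribo = simulate_riboseq(g, cond)
        rna = simulate_rnaseq(g, condition=cond)
        out[cond] = {
            "ribo": assign_ribo_density(ribo, g.replicon_lengths),
            "rna": assign_rna_density(rna, g.replicon_lengths),
        }
    return out


@pytest.fixture(scope="session")
def tiny_quant(tiny_genome, tiny_tracks):
    g = tiny_genome
    return {
        cond: quantify_genes(t["ribo"], t["rna"], g.genes)
        for cond, t in tiny_tracks.items()
    }
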