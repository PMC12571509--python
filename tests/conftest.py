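import numpy as np
import pandas as pd
import pytest

from triohap3d import simulate, phasing
from triohap3d.pipeline import _trio_variant_sets


@pytest.fixture(scope="session")
def small_spec():
    return simulate.GenomeSpec(
        chromosomes=(("chr1", 2_000_000), ("chr21", 1_000_000)),
        snp_rate=1e-3,
        trisomy_chrom="chr21",
        trisomy_origin="maternal",
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    truth = simulate.simulate_trio_genomes(small_spec)
    simulate.simulate_expression(truth, n_genes=60, noise_sd=0.0, seed=12)
    return truth


@pytest.fixture(scope="session")
def small_fragments(small_truth):
    return simulate.simulate_fragments(small_truth, coverage=8, frag_len=150, seed=13)


@pytest.fixture(scope="session")
def phase_table(small_truth):
    father, mother, child = _trio_variant_sets(small_truth)
    return phasing.classify_snps(father, mother, child)


def poisson_matrix(n=60, loop=None, tad_blocks=(), comp_labels=None, scale=40, seed=0):
    """Synthetic cis matrix: distance decay + optional structure layers."""
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    grid = 1.0 / (1 + np.abs(idx[:, None] - idx[None, :]))
    if comp_labels is not None:
        comp_labels = np.asarray(comp_labels)
        grid = grid * np.where(comp_labels[:, None] == comp_labels[None, :], 3.0, 1.0)
    for s, e in tad_blocks:
        grid[s:e, s:e] *= 5.0
    if loop is not None:
        i, j, strength = loop
        grid[i, j] *= strength
        grid[j, i] *= strength
    counts = rng.poisson(grid * scale).astype(float)
    return np.triu(counts) + np.triu(counts, 1).T
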