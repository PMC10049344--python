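import numpy as np
import pytest

from mtrkit import synthetic_data as sd
from mtrkit.variant_model import GeneModel


@pytest.fixture
def small_gene() -> GeneModel:
    """A fixed 60-codon gene used across structure/mapping tests."""
    return sd.generate_gene(60, seed=11, gene_id="GTEST")


@pytest.fixture
def medium_gene() -> GeneModel:
    return sd.generate_gene(200, seed=7, gene_id="GMED")


def naive_mtr(gene, variant_set, window_size):
    """Pure-python per-window MTR recount; the oracle for compute_mtr.

    Recomputes, for every focal codon, the observed and expected counts by
    direct iteration, then forms the ratio in the same published order:
    observed proportion over expected proportion.
    """
    from mtrkit.variant_model import MISSENSE, SYNONYMOUS, enumerate_codon_snvs

    half = window_size // 2
    L = len(gene)
    values = np.full(L, np.nan)
    for focal in range(1, L + 1):
        lo, hi = max(1, focal - half), min(L, focal + half)
        n_mis = n_syn = 0
        for pos in range(lo, hi + 1):
            counts = enumerate_codon_snvs(gene.codons[pos - 1])
            n_mis += counts["n_missense"]
            n_syn += counts["n_synonymous"]
        o_mis = o_syn = 0
        for v in variant_set:
            if v.gene_id != gene.gene_id or not (lo <= v.codon_index <= hi):
                continue
            if v.consequence == MISSENSE:
                o_mis += 1
            elif v.consequence == SYNONYMOUS:
                o_syn += 1
        if o_mis + o_syn > 0:
            values[focal - 1] = (o_mis / (o_mis + o_syn)) / (n_mis / (n_mis + n_syn))
    return values
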