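import numpy as np
import pandas as pd
import pytest

from breakome.io_core import BreakSample, GenomeMask, MappableSpace, TssTable
from breakome import intervals as iv
from breakome.synthetic_data import SyntheticConfig, generate_all


def make_sample(records, sample_id="s1", tissue="t"):
    """records: iterable of (chrom, pos, strand, depth)."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "strand", "depth"])
    return BreakSample(sample_id=sample_id, tissue=tissue, df=df)


def full_mask(chrom_lengths, role="non_repeat"):
    return GenomeMask(role=role, by_chrom={
        c: iv.as_intervals([(0, L)]) for c, L in chrom_lengths.items()})


def empty_mask(role="polyA_excluded"):
    return GenomeMask(role=role, by_chrom={})


@pytest.fixture(scope="session")
def tiny_ds():
    """Small planted-structure dataset shared by integration tests."""
    cfg = SyntheticConfig(genome_length=400_000, n_genes=40,
                          breaks_per_sample=4000, hot_pool_size=200,
                          rng_seed=11)
    return generate_all(cfg)


@pytest.fixture(scope="session")
def null_ds():
    """Same scale with every planted effect switched off."""
    cfg = SyntheticConfig(genome_length=400_000, n_genes=40,
                          breaks_per_sample=4000, hot_fraction=0.0,
                          hot_pool_size=0, tss_enrichment_factor=1.0,
                          template_bias=1.0, upstream_c_bias=None,
                          ap_purine_bias=None, ap_coupling=0.0,
                          expression_effect=1.0, rng_seed=7)
    return generate_all(cfg)


@pytest.fixture()
def simple_tss():
    return TssTable(pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "transcript_id": ["gA.t0", "gB.t0"],
        "chrom": ["chr1", "chr1"],
        "tss_pos": [1000, 5000],
        "strand": ["+", "-"],
    }))


@pytest.fixture()
def uniform_space():
    """Fully mappable single 10 kb chromosome."""
    return MappableSpace({"chr1": 10_000}, full_mask({"chr1": 10_000}),
                         empty_mask())
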