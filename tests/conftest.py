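import numpy as np
import pytest

from symbiopop.containers import MISSING, PopulationPanel, VariantTable
from symbiopop.synthetic_data import HostSimConfig, simulate_host_populations


def make_table(
    genotypes,
    pos=None,
    chrom=None,
    ref=None,
    alt=None,
    qual=None,
    info=None,
    depths=None,
    is_indel=None,
    n_alleles=None,
    sample_ids=None,
    ploidy=2,
):
    """Build a VariantTable from a dense dosage matrix with sane defaults."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    return VariantTable(
        chrom=np.asarray(
            chrom if chrom is not None else ["chr1"] * n_sites, dtype=object
        ),
        pos=np.asarray(
            pos if pos is not None else np.arange(1, n_sites + 1) * 10, dtype=np.int64
        ),
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites, dtype=object),
        alt=np.asarray(alt if alt is not None else ["G"] * n_sites, dtype=object),
        qual=np.asarray(qual if qual is not None else [100.0] * n_sites, dtype=float),
        info=list(info) if info is not None else [{} for _ in range(n_sites)],
        is_indel=np.asarray(
            is_indel if is_indel is not None else [False] * n_sites, dtype=bool
        ),
        n_alleles=np.asarray(
            n_alleles if n_alleles is not None else [2] * n_sites, dtype=np.int32
        ),
        genotypes=g,
        depths=np.asarray(
            depths if depths is not None else np.full(g.shape, 30), dtype=np.int32
        ),
        sample_ids=(
            list(sample_ids)
            if sample_ids is not None
            else [f"s{i}" for i in range(n_samples)]
        ),
        ploidy=ploidy,
    )


def two_pop_panel(sample_ids, n1):
    return PopulationPanel(
        {s: ("pop1" if i < n1 else "pop2") for i, s in enumerate(sample_ids)}
    )


@pytest.fixture(scope="session")
def host_sim():
    """Small two-population simulation shared across tests (seeded)."""
    cfg = HostSimConfig(
        n_genes=40,
        gene_len_codons=100,
        n_samples_pop1=10,
        n_samples_pop2=10,
        theta=0.008,
        divergence=0.02,
        selected_genes=frozenset(range(4)),
        nonsyn_fix_multiplier=8.0,
        seed=11,
    )
    return simulate_host_populations(cfg)
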