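import numpy as np
import pytest

from apobec_smoke.catalog import Mutation, MutationCatalog, annotate_context
from apobec_smoke.simulate import SiteInventory, simulate_reference


@pytest.fixture(scope="session")
def refseq():
    """50 kb synthetic reference at 45% GC shared across tests."""
    return simulate_reference(50_000, 0.45, seed=123)


@pytest.fixture(scope="session")
def ref_handle(refseq):
    return {"chr1": refseq}


@pytest.fixture(scope="session")
def sites(refseq):
    return SiteInventory(refseq)


def make_catalog(mutations, sample_id="s1", genome_length=1_000_000, metadata=None):
    """Build a catalog from (chrom, pos, ref, alt[, ccf]) tuples."""
    muts = []
    for rec in mutations:
        chrom, pos, ref, alt = rec[:4]
        ccf = rec[4] if len(rec) > 4 else None
        muts.append(Mutation(chrom=chrom, pos=pos, ref=ref, alt=alt, ccf=ccf))
    return MutationCatalog(sample_id=sample_id, mutations=muts,
                           genome_length=genome_length, metadata=metadata or {})


@pytest.fixture
def catalog_factory():
    return make_catalog
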