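import numpy as np
import pandas as pd
import pytest

from hydroxyscan.annotate import Transcript
from hydroxyscan.digest import SiteMap, find_ccgg_sites
from hydroxyscan.simulate import SimDesign, SimEffects, simulate_counts, simulate_genome


def make_sitemap(entries):
    """SiteMap from [(chrom, pos), ...] without motif constraints (annotation tests)."""
    return SiteMap(entries=pd.DataFrame(entries, columns=["chrom", "pos"]))


@pytest.fixture(scope="session")
def small_genome():
    """Deterministic 2x50 kb synthetic genome with CGIs and gene models."""
    seqs, cgis, tx = simulate_genome(
        n_chrom=2, length=50_000, ccgg_rate=0.002, cgi_density=1e-4,
        gene_density=5e-5, seed=11,
    )
    return seqs, cgis, tx


@pytest.fixture(scope="session")
def small_sitemap(small_genome):
    seqs, _, _ = small_genome
    return find_ccgg_sites(seqs)


@pytest.fixture(scope="session")
def paired_dataset(small_sitemap):
    """Counts + sample sheet + truth for the default paired design."""
    design = SimDesign(n_sites=len(small_sitemap), seed=11)
    effects = SimEffects(planted_dhmrs=[("chr1", 10, 9, -2.0)])
    scm, sheet, truth, libf = simulate_counts(small_sitemap, design, effects, seed=12)
    return scm, sheet, truth, libf


@pytest.fixture
def forward_transcript():
    """Coding transcript on the + strand: exons 1001-1500 and 2001-3000, CDS 1101-2900."""
    return Transcript(
        tx_id="T1.1", gene_id="G1", chrom="chr1", strand="+",
        start=1001, end=3000, exons=[(1001, 1500), (2001, 3000)], cds=(1101, 2900),
    )


@pytest.fixture
def reverse_transcript():
    """Coding transcript on the - strand mirroring the forward fixture."""
    return Transcript(
        tx_id="T2.1", gene_id="G2", chrom="chr2", strand="-",
        start=1001, end=3000, exons=[(1001, 2000), (2501, 3000)], cds=(1101, 2900),
    )
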