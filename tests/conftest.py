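import numpy as np
import pytest

from spliceshift.gene_models import Exon, GeneModel, Transcript


def make_tx(tid, chain, strand="+", chrom="chr1"):
    return Transcript(tid, tuple(Exon(chrom, s, e) for s, e in chain), strand)


def make_gene(gene_id, chains, strand="+", chrom="chr1"):
    txs = tuple(make_tx(f"{gene_id}.{i + 1}", c, strand, chrom)
                for i, c in enumerate(chains))
    return GeneModel(gene_id, txs, strand, chrom)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_924)


@pytest.fixture
def six_isoform_gene():
    """Six splice forms of one gene realising one event of each of SE/RI/A3/A5.

    Modelled on a MADS-box flowering gene whose four splicing events produce
    six distinct isoforms.  The four event regions are separated by
    constitutive exons, so every pairwise isoform comparison resolves into
    clean single-class events.
    """
    e1, e2, e3, e4 = (1, 100), (201, 300), (401, 500), (601, 700)
    e5, e6, e7 = (801, 900), (1001, 1100), (1201, 1300)
    base = [e1, e2, e3, e4, e5, e6, e7]
    se = [e1, e3, e4, e5, e6, e7]                      # skips exon 2
    ri = [e1, e2, (401, 700), e5, e6, e7]              # retains intron 3-4
    a5 = [e1, e2, e3, e4, (801, 950), e6, e7]          # longer donor exon 5
    a3 = [e1, e2, e3, e4, e5, e6, (1251, 1300)]        # shifted acceptor exon 7
    combo = [e1, e3, e4, e5, e6, (1251, 1300)]         # SE + A3
    return make_gene("maf_like", [base, se, ri, a5, a3, combo])
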