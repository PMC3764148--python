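import numpy as np
import pytest

from circkit.genome import Exon, GeneModel, Transcript


def make_transcript(gene_id, tid, strand, exon_ivals, chrom="chr1"):
    """exon_ivals are genomic (start, end) in transcription order."""
    exons = tuple(
        Exon(chrom=chrom, start=s, end=e, index=i)
        for i, (s, e) in enumerate(exon_ivals)
    )
    return Transcript(id=tid, gene_id=gene_id, strand=strand, exons=exons)


def make_gene(transcript):
    gm = GeneModel(
        gene_id=transcript.gene_id,
        chrom=transcript.chrom,
        strand=transcript.strand,
    )
    gm.add(transcript)
    return gm


@pytest.fixture(scope="session")
def toy_genome():
    """A deterministic 2 kb sequence: position i holds a base derived from i,
    so any slice is easy to recompute by hand in a failing test."""
    rng = np.random.default_rng(20130905)
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=6000))}


@pytest.fixture
def plus_gene(toy_genome):
    """4-exon gene on '+': exons of 100, 80, 120, 90 nt with 150-nt introns."""
    ivals, pos = [], 100
    for ln in (100, 80, 120, 90):
        ivals.append((pos, pos + ln))
        pos += ln + 150
    t = make_transcript("GPLUS", "GPLUS.t1", "+", ivals)
    return make_gene(t)


@pytest.fixture
def minus_gene(toy_genome):
    """3-exon gene on '-': transcription order right to left."""
    ivals_genomic = [(3000, 3100), (3250, 3330), (3500, 3620)]
    t = make_transcript("GMINUS", "GMINUS.t1", "-", ivals_genomic[::-1])
    return make_gene(t)
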