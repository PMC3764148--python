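"""Classification of aligned read pairs into circle evidence and decoys.

Read 1 and read 2 are deliberately asymmetric, following the directional
library protocol: read 1 is the junction-defining read and must align to a
scrambled-junction database entry overlapping the junction midpoint by at
least ``overhang`` nt on both sides; read 2 need not be junctional and is
placed anywhere within the same gene.

A pair is circle-consistent when read 2 lies within the genomic span of
exons y..x implied by read 1's junction (or maps to the same junction) and
the two reads are on opposite strands. A pair whose read 2 maps to the same
gene but outside that span cannot derive from the circle — it is a decoy,
and decoys build the empirical null for FDR assignment. Same-strand pairs,
short overhangs and cross-gene pairs are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .align import Alignment
from .genome import GeneModel
from .junctions import JunctionEntry


@dataclass(frozen=True)
class ClassifyConfig:
    overhang: int = 10
    # 'read1_antisense' is the directional protocol in which a sense circle
    # yields read 1 in '-' orientation on the junction entry and read 2 in
    # '+' orientation on the gene.
    strandness: str = "read1_antisense"

    def __post_init__(self) -> None:
        if self.overhang < 1:
            raise ValueError("overhang must be >= 1")
        if self.strandness not in ("read1_antisense", "read1_sense"):
            raise ValueError(f"unknown strandness {self.strandness!r}")

    @property
    def sense_read1_orientation(self) -> str:
        return "-" if self.strandness == "read1_antisense" else "+"


@dataclass(frozen=True)
class ReadPairEvidence:
    junction_id: str
    gene_id: str
    donor_coord: int
    acceptor_coord: int
    chrom: str
    strand: str
    read1_score: int
    read2_score: int
    read1_orientation: str
    read2_orientation: str
    read2_target: str  # within-circle | upstream-of-acceptor | downstream-of-donor | same-junction | other-gene | unaligned | same-strand | short-overhang | other-junction
    klass: str         # circle_consistent | decoy | discarded
    sense: bool
    intronic: bool = False
    sample: str = "sample"


def _span_ref_gene(ref_name: str) -> str | None:
    return ref_name.removeprefix("span::") if ref_name.startswith("span::") else None


def _tx_ref_id(ref_name: str) -> str | None:
    return ref_name.removeprefix("tx::") if ref_name.startswith("tx::") else None


def _genomic_interval_on_span(
    gene: GeneModel, aln: Alignment
) -> tuple[int, int]:
    """Genomic interval of an alignment to the gene-sense span reference."""
    lo, hi = gene.span
    if gene.strand == "+":
        return lo + aln.ref_start, lo + aln.ref_end
    return hi - aln.ref_end, hi - aln.ref_start


def transcript_genomic_interval(
    transcript, tstart: int, tend: int
) -> tuple[int, int]:
    """Genomic extent [lo, hi) of transcript-coordinate interval [tstart,
    tend); spliced alignments crossing exon boundaries span the intervening
    intron genomically."""
    lo = hi = None
    c = 0
    for e in transcript.exons:
        elen = len(e)
        s, t = max(tstart, c), min(tend, c + elen)
        if s < t:
            off0, off1 = s - c, t - c
            if transcript.strand == "+":
                g0, g1 = e.start + off0, e.start + off1
            else:
                g0, g1 = e.end - off1, e.end - off0
            lo = g0 if lo is None else min(lo, g0)
            hi = g1 if hi is None else max(hi, g1)
        c += elen
    if lo is None:
        raise ValueError("alignment interval outside transcript")
    return lo, hi


def _discard(entry: JunctionEntry | None, r1: Alignment | None, r2: Alignment | None,
             reason: str, sample: str) -> ReadPairEvidence:
    return ReadPairEvidence(
        junction_id=entry.entry_id if entry else "",
        gene_id=entry.gene_id if entry else "",
        donor_coord=entry.donor_coord if entry else -1,
        acceptor_coord=entry.acceptor_coord if entry else -1,
        chrom=entry.chrom if entry else "",
        strand=entry.strand if entry else ".",
        read1_score=r1.score if r1 else 0,
        read2_score=r2.score if r2 else 0,
        read1_orientation=r1.orientation if r1 else ".",
        read2_orientation=r2.orientation if r2 else ".",
        read2_target=reason,
        klass="discarded",
        sense=False,
        sample=sample,
    )


def circle_genomic_span(entry: JunctionEntry, genes: Mapping[str, GeneModel]) -> tuple[int, int]:
    """Genomic interval covered by exons y..x of the junction's transcript."""
    gm = genes[entry.gene_id]
    t = gm.transcripts[entry.transcript_ids[0]]
    exons = t.exons[entry.acceptor_index : entry.donor_index + 1]
    return min(e.start for e in exons), max(e.end for e in exons)


def classify_pair(
    read1_aln: Alignment | None,
    read2_aln: Alignment | None,
    junction_meta: Mapping[str, JunctionEntry],
    genes: Mapping[str, GeneModel],
    config: ClassifyConfig = ClassifyConfig(),
    sample: str = "sample",
    tx_to_gene: Mapping[str, str] | None = None,
) -> ReadPairEvidence:
    """Classify one aligned pair.

    ``read1_aln`` must target a junction entry (reference name = entry id);
    ``read2_aln`` may target a spliced transcript (``tx::<id>``), a gene
    span (``span::<gene>``) or a junction entry.
    """
    if read1_aln is None or read1_aln.ref_name not in junction_meta:
        return _discard(None, read1_aln, read2_aln, "unaligned", sample)
    entry = junction_meta[read1_aln.ref_name]
    if read2_aln is None:
        return _discard(entry, read1_aln, None, "unaligned", sample)

    # junction midpoint sits at offset flank on the entry
    left = entry.flank - read1_aln.ref_start
    right = read1_aln.ref_end - entry.flank
    if left < config.overhang or right < config.overhang:
        return _discard(entry, read1_aln, read2_aln, "short-overhang", sample)

    r2_span_gene = _span_ref_gene(read2_aln.ref_name)
    r2_tx = _tx_ref_id(read2_aln.ref_name)
    if r2_span_gene is None and r2_tx is None:  # read 2 on a junction entry
        other = junction_meta.get(read2_aln.ref_name)
        if other is None or other.gene_id != entry.gene_id:
            return _discard(entry, read1_aln, read2_aln, "other-gene", sample)
        if read2_aln.ref_name != read1_aln.ref_name:
            return _discard(entry, read1_aln, read2_aln, "other-junction", sample)
        target = "same-junction"
        intronic = False
    else:
        gm = genes[entry.gene_id]
        if r2_tx is not None:
            if tx_to_gene is None:
                tx_to_gene = {
                    tid: gid for gid, g in genes.items() for tid in g.transcripts
                }
            if tx_to_gene.get(r2_tx) != entry.gene_id:
                return _discard(entry, read1_aln, read2_aln, "other-gene", sample)
            t2 = gm.transcripts[r2_tx]
            g2lo, g2hi = transcript_genomic_interval(
                t2, read2_aln.ref_start, read2_aln.ref_end
            )
            exonic = True
        else:
            if r2_span_gene != entry.gene_id:
                return _discard(entry, read1_aln, read2_aln, "other-gene", sample)
            g2lo, g2hi = _genomic_interval_on_span(gm, read2_aln)
            exonic = False
        clo, chi = circle_genomic_span(entry, genes)
        if g2hi <= clo or g2lo >= chi:
            # outside the implied circle: impossible for a true circle
            before = g2hi <= clo
            if gm.strand == "+":
                target = "upstream-of-acceptor" if before else "downstream-of-donor"
            else:
                target = "downstream-of-donor" if before else "upstream-of-acceptor"
            intronic = False
        else:
            target = "within-circle"
            if exonic:
                intronic = False
            else:
                t = gm.transcripts[entry.transcript_ids[0]]
                exons = t.exons[entry.acceptor_index : entry.donor_index + 1]
                covered = any(g2lo >= e.start and g2hi <= e.end for e in exons)
                intronic = not covered

    if read1_aln.orientation == read2_aln.orientation:
        return _discard(entry, read1_aln, read2_aln, "same-strand", sample)

    sense = read1_aln.orientation == config.sense_read1_orientation
    klass = "decoy" if target in ("upstream-of-acceptor", "downstream-of-donor") else "circle_consistent"
    return ReadPairEvidence(
        junction_id=entry.entry_id,
        gene_id=entry.gene_id,
        donor_coord=entry.donor_coord,
        acceptor_coord=entry.acceptor_coord,
        chrom=entry.chrom,
        strand=entry.strand,
        read1_score=read1_aln.score,
        read2_score=read2_aln.score,
        read1_orientation=read1_aln.orientation,
        read2_orientation=read2_aln.orientation,
        read2_target=target,
        klass=klass,
        sense=sense,
        intronic=intronic,
        sample=sample,
    )


def evidence_table(evidence: Iterable[ReadPairEvidence]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in evidence])


def aggregate_candidates(evidence: Iterable[ReadPairEvidence]):
    """Aggregate classified evidence into per-junction candidates.

    Returns (candidates, decoys): circle-consistent and decoy evidence are
    aggregated separately by (gene, donor coordinate, acceptor coordinate).
    Each aggregate carries the junctional count and three averages, exported
    as score1info/score2info/score12info: mean read-1 score, mean read-2
    score, and the mean per-pair score product (the last stored
    nonnegative since both scores are <= 0; it is reported but not used for
    the FDR).
    """
    from .fdr import CircleCandidate

    groups: dict[tuple, list[ReadPairEvidence]] = {}
    for ev in evidence:
        if ev.klass not in ("circle_consistent", "decoy"):
            continue
        key = (ev.klass, ev.gene_id, ev.donor_coord, ev.acceptor_coord)
        groups.setdefault(key, []).append(ev)

    out = {"circle_consistent": [], "decoy": []}
    for (klass, gene, donor, acceptor) in sorted(groups):
        evs = groups[(klass, gene, donor, acceptor)]
        n = len(evs)
        per_sample: dict[str, int] = {}
        for ev in evs:
            per_sample[ev.sample] = per_sample.get(ev.sample, 0) + 1
        cand = CircleCandidate(
            gene_id=gene,
            donor_coord=donor,
            acceptor_coord=acceptor,
            chrom=evs[0].chrom,
            strand=evs[0].strand,
            count=n,
            mean_read1_score=sum(e.read1_score for e in evs) / n,
            mean_read2_score=sum(e.read2_score for e in evs) / n,
            mean_product_score=sum(e.read1_score * e.read2_score for e in evs) / n,
            n_sense=sum(e.sense for e in evs),
            n_intronic=sum(e.intronic for e in evs),
            per_sample_counts=per_sample,
        )
        out[klass].append(cand)
    return out["circle_consistent"], out["decoy"]
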