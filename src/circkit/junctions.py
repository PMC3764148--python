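"""Scrambled exon-exon junction database construction.

A circular RNA joining the donor (RNA 3') site of exon x to the acceptor
(RNA 5') site of exon y with y <= x produces a diagnostic back-splice
junction absent from any linear isoform. For every transcript we enumerate
all such (y, x) pairs — n(n+1)/2 of them for n exons, including y == x
single-exon circles — and emit a reference entry of length 2*flank
(default 132 nt) with the junction at the midpoint.

Entry sequences are cut from the circle treated as a periodic string: the
flank nt of circular sequence ending at the donor site, followed by the
flank nt beginning at the acceptor site, wrapping around the circle as
needed. This one rule covers long flanking exons (plain flank
concatenation), short exons (neighbouring exons within the circle are
walked into), and circles shorter than the entry (in-silico rolling
circle tiling).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

from .genome import GeneModel, Transcript, spliced_sequence

DEFAULT_FLANK = 66


@dataclass(frozen=True)
class JunctionEntry:
    gene_id: str
    transcript_ids: tuple[str, ...]
    acceptor_index: int  # y
    donor_index: int     # x, x >= y
    chrom: str
    strand: str
    donor_coord: int     # genomic boundary of exon x donor site
    acceptor_coord: int  # genomic boundary of exon y acceptor site
    seq: str
    circle_length: int
    rolling_circle: bool
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.donor_index < self.acceptor_index:
            raise ValueError("donor exon index must be >= acceptor exon index")
        if len(self.seq) != 2 * self.flank:
            raise ValueError(
                f"entry sequence length {len(self.seq)} != 2*flank ({2 * self.flank})"
            )

    @property
    def entry_id(self) -> str:
        return "|".join(
            [
                self.gene_id,
                self.transcript_ids[0],
                str(self.acceptor_index),
                str(self.donor_index),
                str(self.donor_coord),
                str(self.acceptor_coord),
            ]
        )


def parse_entry_id(entry_id: str) -> dict:
    gene, tx, y, x, donor, acceptor = entry_id.split("|")
    return {
        "gene_id": gene,
        "transcript_id": tx,
        "acceptor_index": int(y),
        "donor_index": int(x),
        "donor_coord": int(donor),
        "acceptor_coord": int(acceptor),
    }


def enumerate_scrambled_pairs(transcript: Transcript | int) -> list[tuple[int, int]]:
    """All (acceptor y, donor x) index pairs with y <= x, sorted.

    Accepts a Transcript or a bare exon count.
    """
    n = transcript if isinstance(transcript, int) else transcript.n_exons
    return [(y, x) for y in range(n) for x in range(y, n)]


def junction_entry(
    transcript: Transcript,
    y: int,
    x: int,
    genome: Mapping[str, object],
    flank: int = DEFAULT_FLANK,
) -> JunctionEntry:
    """Build the junction-database entry for the circle of exons y..x."""
    circle = spliced_sequence(transcript, y, x, genome, circular=True)
    L = len(circle)
    if L == 0:
        raise ValueError("empty circle sequence")
    # Position 0 of the circle string is the acceptor site, position L the
    # donor site; the junction window is [L - flank, L + flank) on the tiling.
    seq = "".join(circle[(L - flank + i) % L] for i in range(2 * flank))
    return JunctionEntry(
        gene_id=transcript.gene_id,
        transcript_ids=(transcript.id,),
        acceptor_index=y,
        donor_index=x,
        chrom=transcript.chrom,
        strand=transcript.strand,
        donor_coord=transcript.donor_coord(x),
        acceptor_coord=transcript.acceptor_coord(y),
        seq=seq,
        circle_length=L,
        rolling_circle=L < 2 * flank,
        flank=flank,
    )


def build_db(
    genemodels: Mapping[str, GeneModel] | Iterable[GeneModel],
    genome: Mapping[str, object],
    flank: int = DEFAULT_FLANK,
) -> list[JunctionEntry]:
    """Enumerate junction entries for all genes.

    Duplicate transcripts (identical exon chains) are collapsed first;
    junctions identical at genomic (donor, acceptor) coordinates across the
    remaining transcripts of a gene are merged with a provenance list of
    transcript ids. Output is sorted by (gene, transcript, y, x).
    """
    if isinstance(genemodels, Mapping):
        genes = [genemodels[k] for k in sorted(genemodels)]
    else:
        genes = sorted(genemodels, key=lambda g: g.gene_id)

    out: list[JunctionEntry] = []
    for gm in genes:
        by_coord: dict[tuple[int, int], JunctionEntry] = {}
        for t in gm.unique_transcripts():
            for (yy, xx) in enumerate_scrambled_pairs(t):
                e = junction_entry(t, yy, xx, genome, flank=flank)
                key = (e.donor_coord, e.acceptor_coord)
                prev = by_coord.get(key)
                if prev is None:
                    by_coord[key] = e
                else:
                    merged_ids = tuple(
                        sorted(set(prev.transcript_ids) | set(e.transcript_ids))
                    )
                    keep = min(
                        prev,
                        e,
                        key=lambda j: (
                            j.transcript_ids[0],
                            j.acceptor_index,
                            j.donor_index,
                        ),
                    )
                    by_coord[key] = replace(keep, transcript_ids=merged_ids)
        out.extend(
            sorted(
                by_coord.values(),
                key=lambda e: (
                    e.gene_id,
                    e.transcript_ids[0],
                    e.acceptor_index,
                    e.donor_index,
                ),
            )
        )
    return out


def metadata_table(entries: Iterable[JunctionEntry]) -> pd.DataFrame:
    cols = [
        "entry_id", "gene_id", "transcript_ids", "acceptor_index", "donor_index",
        "chrom", "strand", "donor_coord", "acceptor_coord", "circle_length",
        "rolling_circle", "flank",
    ]
    rows = [
        {
            "entry_id": e.entry_id,
            "gene_id": e.gene_id,
            "transcript_ids": ",".join(e.transcript_ids),
            "acceptor_index": e.acceptor_index,
            "donor_index": e.donor_index,
            "chrom": e.chrom,
            "strand": e.strand,
            "donor_coord": e.donor_coord,
            "acceptor_coord": e.acceptor_coord,
            "circle_length": e.circle_length,
            "rolling_circle": e.rolling_circle,
            "flank": e.flank,
        }
        for e in entries
    ]
    return pd.DataFrame(rows, columns=cols)


def write_db(
    entries: list[JunctionEntry], fasta_path: str, metadata_path: str
) -> None:
    """Write the junction FASTA and its metadata TSV."""
    with open(fasta_path, "w") as fh:
        for e in entries:
            fh.write(f">{e.entry_id}\n{e.seq}\n")
    metadata_table(entries).to_csv(metadata_path, sep="\t", index=False)
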