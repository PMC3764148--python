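"""Gene models and spliced-sequence extraction.

Coordinates are 0-based half-open internally; GTF input (1-based inclusive)
is converted at the parsing boundary. Exons of a transcript are indexed in
transcription order (index 0 is the 5'-most exon of the RNA), so on the
minus strand index 0 is the genomically rightmost exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Seq import reverse_complement


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    index: int  # ordinal in transcription order, 0-based

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"exon start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """An ordered exon chain on one strand.

    The donor site of exon i is its 3' boundary in RNA orientation (genomic
    end on '+', genomic start on '-'); the acceptor site is its 5' boundary.
    """

    id: str
    gene_id: str
    strand: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.id}: strand must be '+' or '-'")
        if not self.exons:
            raise AnnotationError(f"{self.id}: transcript needs >=1 exon")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start - a.end < 1:
                raise AnnotationError(
                    f"{self.id}: exons overlap or abut at {a.end}..{b.start}"
                )
        expect = genomic if self.strand == "+" else genomic[::-1]
        if tuple(e.index for e in self.exons) != tuple(range(len(self.exons))):
            raise AnnotationError(f"{self.id}: exon indices must be 0..n-1")
        if tuple(self.exons) != tuple(expect):
            raise AnnotationError(
                f"{self.id}: exons not in transcription order for strand {self.strand}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def donor_coord(self, i: int) -> int:
        """Genomic boundary coordinate of exon i's donor (RNA 3') site."""
        e = self.exons[i]
        return e.end if self.strand == "+" else e.start

    def acceptor_coord(self, i: int) -> int:
        """Genomic boundary coordinate of exon i's acceptor (RNA 5') site."""
        e = self.exons[i]
        return e.start if self.strand == "+" else e.end

    def intron_lengths(self) -> list[int]:
        """Intron lengths in transcription order (n_exons - 1 values)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(b.start - a.end)
            else:
                out.append(a.start - b.end)
        return out

    def exon_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def add(self, t: Transcript) -> None:
        if t.chrom != self.chrom or t.strand != self.strand:
            raise AnnotationError(
                f"{self.gene_id}: transcript {t.id} on different chrom/strand"
            )
        self.transcripts[t.id] = t

    @property
    def span(self) -> tuple[int, int]:
        starts = [e.start for t in self.transcripts.values() for e in t.exons]
        ends = [e.end for t in self.transcripts.values() for e in t.exons]
        return min(starts), max(ends)

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged genomic exon intervals across all transcripts."""
        ivals = sorted(
            (e.start, e.end) for t in self.transcripts.values() for e in t.exons
        )
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def unique_transcripts(self) -> list[Transcript]:
        """Transcripts deduplicated by exon chain (keeps lexicographically
        smallest id), so identical isoforms under different ids are not
        enumerated twice."""
        seen: dict[tuple, Transcript] = {}
        for tid in sorted(self.transcripts):
            t = self.transcripts[tid]
            seen.setdefault(t.exon_chain(), t)
        return [seen[k] for k in sorted(seen)]


# ---------------------------------------------------------------------------
# sequence access

def fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] as an uppercase string.

    Works with a plain dict of strings and with pyfaidx.Fasta.
    """
    try:
        seq = genome[chrom][start:end]
    except KeyError as exc:
        raise AnnotationError(f"sequence {chrom!r} not in genome") from exc
    return str(seq).upper()


def spliced_sequence(
    transcript: Transcript,
    acceptor_exon: int,
    donor_exon: int,
    genome: Mapping[str, object],
    circular: bool = False,
) -> str:
    """RNA-sense sequence of exons acceptor_exon..donor_exon (inclusive,
    transcription order).

    ``circular`` is informational: the returned string is the circle body and
    callers apply wraparound semantics themselves.
    """
    n = transcript.n_exons
    if not (0 <= acceptor_exon <= donor_exon < n):
        raise IndexError(
            f"exon range {acceptor_exon}..{donor_exon} out of bounds for "
            f"{transcript.id} with {n} exons"
        )
    exons = transcript.exons[acceptor_exon : donor_exon + 1]
    genomic = sorted(exons, key=lambda e: e.start)
    seq = "".join(fetch(genome, e.chrom, e.start, e.end) for e in genomic)
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# annotation I/O

def _parse_gtf(path: str) -> dict[str, GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises several parser exceptions
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc

    per_tx: dict[str, list] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.features_of_type("exon"):
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"GTF exon at {feat.seqid}:{feat.start} missing {exc} attribute"
            ) from exc
        # gffutils keeps GTF 1-based inclusive; convert to 0-based half-open
        per_tx.setdefault(tid, []).append((feat.seqid, feat.start - 1, feat.end))
        tx_meta[tid] = (gid, feat.seqid, feat.strand)
    return _assemble(per_tx, tx_meta)


def _parse_bed12(path: str) -> dict[str, GeneModel]:
    per_tx: dict[str, list] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: BED12 needs 12 fields, got {len(f)}"
                )
            try:
                chrom, cstart = f[0], int(f[1])
                name, strand = f[3], f[5]
                nblocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != nblocks or len(starts) != nblocks:
                raise AnnotationError(
                    f"{path}:{lineno}: blockCount={nblocks} does not match block lists"
                )
            exons = [
                (chrom, cstart + st, cstart + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            # BED has no separate gene id; use the name as both
            per_tx[name] = exons
            tx_meta[name] = (name, chrom, strand)
    return _assemble(per_tx, tx_meta)


def _assemble(per_tx, tx_meta) -> dict[str, GeneModel]:
    genes: dict[str, GeneModel] = {}
    for tid in sorted(per_tx):
        gid, chrom, strand = tx_meta[tid]
        ivals = sorted(set(per_tx[tid]), key=lambda x: x[1])
        if strand == "-":
            ivals = ivals[::-1]
        exons = tuple(
            Exon(chrom=c, start=s, end=e, index=i)
            for i, (c, s, e) in enumerate(ivals)
        )
        t = Transcript(id=tid, gene_id=gid, strand=strand, exons=exons)
        gm = genes.setdefault(gid, GeneModel(gene_id=gid, chrom=chrom, strand=strand))
        gm.add(t)
    return genes


def load_annotation(path: str, dialect: str = "gtf") -> dict[str, GeneModel]:
    """Load gene models from a GTF or BED12 file, keyed by gene id."""
    if dialect == "gtf":
        return _parse_gtf(path)
    if dialect == "bed12":
        return _parse_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "circkit") -> None:
    """Write gene models back to ensembl-style GTF (exon features only)."""
    with open(path, "w") as fh:
        for gm in sorted(genes, key=lambda g: g.gene_id):
            for tid in sorted(gm.transcripts):
                t = gm.transcripts[tid]
                for e in t.exons:
                    attrs = (
                        f'gene_id "{gm.gene_id}"; transcript_id "{t.id}"; '
                        f'exon_number "{e.index + 1}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                e.chrom,
                                source,
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                t.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )
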