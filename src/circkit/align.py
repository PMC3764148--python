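"""Alignment scoring and a small internal ungapped aligner.

Scores follow the convention that a perfect alignment scores 0 and every
penalty is subtracted: a mismatch costs between ``mismatch_min`` (at base
quality 0) and ``mismatch_max`` (at quality >= ``quality_cap``), linearly
interpolated and floored, so a high-quality mismatch costs 6 by default.
Gaps cost open + extend per gap base; N bases cost a flat penalty.

The internal aligner is deterministic seed-and-extend without gaps: it is
the primary path for aligning synthetic reads to the junction database and
to gene/transcript sequences, and it reports scores under the same scheme
used to re-score external SAM records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Seq import reverse_complement


@dataclass(frozen=True)
class ScoringScheme:
    mismatch_min: int = 2
    mismatch_max: int = 6
    n_penalty: int = 1
    gap_open: int = 5
    gap_extend: int = 3
    quality_cap: int = 40
    # reporting threshold: alignments scoring below
    # min_score_const + min_score_per_base * read_length are treated as
    # unaligned (the end-to-end default of the reference aligner)
    min_score_const: float = -0.6
    min_score_per_base: float = -0.6

    def __post_init__(self) -> None:
        if self.mismatch_max < self.mismatch_min:
            raise ValueError("mismatch_max must be >= mismatch_min")

    def mismatch_penalty(self, quality: int) -> int:
        q = min(max(quality, 0), self.quality_cap)
        span = self.mismatch_max - self.mismatch_min
        return self.mismatch_min + (span * q) // self.quality_cap

    def min_score(self, read_length: int) -> float:
        return self.min_score_const + self.min_score_per_base * read_length


DEFAULT_SCHEME = ScoringScheme()


def phred(qual_char: str) -> int:
    return ord(qual_char) - 33


def score_ungapped(read: str, ref: str, quals: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Score a gap-free alignment of ``read`` against the same-length ``ref``."""
    if len(read) != len(ref):
        raise ValueError("read and reference segments differ in length")
    if len(quals) != len(read):
        raise ValueError("quality string length does not match read")
    score = 0
    for b, r, q in zip(read.upper(), ref.upper(), quals):
        if b == "N" or r == "N":
            score -= scheme.n_penalty
        elif b != r:
            score -= scheme.mismatch_penalty(phred(q))
    return score


def alignment_score(
    aligned_read,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    trust_tag: bool = False,
) -> int:
    """Score a pysam AlignedSegment under the scheme.

    With ``trust_tag`` the aligner-reported AS tag is returned when present;
    otherwise the score is recomputed from the aligned pairs (requires the
    MD tag for reference bases) plus CIGAR gaps and the base qualities.
    """
    if trust_tag and aligned_read.has_tag("AS"):
        return int(aligned_read.get_tag("AS"))
    quals = aligned_read.query_qualities
    if quals is None:
        raise ValueError(
            f"read {aligned_read.query_name}: base qualities required to recompute score"
        )
    seq = aligned_read.query_sequence
    score = 0
    try:
        pairs = aligned_read.get_aligned_pairs(with_seq=True)
    except ValueError as exc:
        raise ValueError(
            f"read {aligned_read.query_name}: MD tag required to recompute score"
        ) from exc
    gap_run = None
    for qpos, rpos, rbase in pairs:
        if qpos is None or rpos is None:
            kind = "del" if qpos is None else "ins"
            if gap_run != kind:
                score -= scheme.gap_open
                gap_run = kind
            score -= scheme.gap_extend
            continue
        gap_run = None
        rb = (rbase or "N").upper()
        qb = seq[qpos].upper()
        if qb == "N" or rb == "N":
            score -= scheme.n_penalty
        elif qb != rb:
            score -= scheme.mismatch_penalty(quals[qpos])
    return score


@dataclass(frozen=True)
class Alignment:
    ref_name: str
    ref_start: int      # 0-based on the reference, forward coordinates
    orientation: str    # '+' read as given, '-' reverse complement aligned
    score: int
    read_length: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.read_length


@dataclass
class SeqIndex:
    """Exact k-mer index over a set of reference sequences.

    Gap-free seed-and-extend: seeds are sampled at a few read offsets, each
    seed hit proposes a diagonal, and every distinct placement fully
    contained in a reference is scored. Best score wins; ties break on
    (ref name, position, orientation) so results are deterministic.
    ``tie_prefer`` is an ordered tuple of reference-name prefixes that win
    ties (e.g. spliced transcripts, then gene spans, then junction entries
    for the non-junctional mate).
    """

    refs: dict[str, str]
    k: int = 20
    tie_prefer: tuple[str, ...] = ()
    _index: dict[str, list[tuple[str, int]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name in sorted(self.refs):
            seq = self.refs[name].upper()
            self.refs[name] = seq
            for i in range(len(seq) - self.k + 1):
                kmer = seq[i : i + self.k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((name, i))

    def _candidates(self, read: str) -> set[tuple[str, int]]:
        L = len(read)
        offsets = {0, max(0, (L - self.k) // 2), max(0, L - self.k)}
        hits: set[tuple[str, int]] = set()
        for off in offsets:
            kmer = read[off : off + self.k]
            for name, pos in self._index.get(kmer, ()):
                start = pos - off
                if start >= 0 and start + L <= len(self.refs[name]):
                    hits.add((name, start))
        return hits

    def align(
        self, read: str, quals: str, scheme: ScoringScheme = DEFAULT_SCHEME
    ) -> Alignment | None:
        """Best gap-free alignment of the read or its reverse complement."""
        read = read.upper()
        best: tuple | None = None
        for orient, seq, q in (
            ("+", read, quals),
            ("-", reverse_complement(read), quals[::-1]),
        ):
            for name, start in self._candidates(seq):
                ref_seg = self.refs[name][start : start + len(seq)]
                s = score_ungapped(seq, ref_seg, q, scheme)
                rank = len(self.tie_prefer)
                for i, prefix in enumerate(self.tie_prefer):
                    if name.startswith(prefix):
                        rank = i
                        break
                key = (-s, rank, name, start, orient)
                if best is None or key < best[0]:
                    best = (key, Alignment(name, start, orient, s, len(seq)))
        if best is None or best[1].score < scheme.min_score(len(read)):
            return None
        return best[1]


def build_gene_span_refs(
    genes: Mapping[str, object], genome: Mapping[str, object]
) -> dict[str, str]:
    """Gene-sense sequences of each gene's genomic span, named span::<gene>.

    Spans include introns so that reads from intron-retained circles and
    decoy mates landing in introns can be placed.
    """
    from .genome import fetch

    refs = {}
    for gid in sorted(genes):
        gm = genes[gid]
        lo, hi = gm.span
        seq = fetch(genome, gm.chrom, lo, hi)
        if gm.strand == "-":
            seq = reverse_complement(seq)
        refs[f"span::{gid}"] = seq
    return refs


def build_transcript_refs(
    genes: Mapping[str, object], genome: Mapping[str, object]
) -> dict[str, str]:
    """Spliced RNA-sense transcript sequences, named tx::<transcript>.

    These are the linear transcript models the non-junctional mate aligns
    to; mates crossing canonical splice junctions place contiguously here
    where the intron-containing gene span cannot accommodate them.
    """
    from .genome import spliced_sequence

    refs = {}
    for gid in sorted(genes):
        for t in genes[gid].unique_transcripts():
            refs[f"tx::{t.id}"] = spliced_sequence(t, 0, t.n_exons - 1, genome)
    return refs
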