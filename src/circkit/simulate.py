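"""Seeded synthetic fixtures: genome, annotation, planted circles, and
directional 76-nt paired-end reads with quality-dependent errors.

The generator emulates the structure of a directional poly(A)-depleted
paired-end library: fragments are sampled from linear transcripts and from
planted circular isoforms (uniformly over circular positions, wrapping
across the back-splice junction), read 2 is the sense end of the fragment
and read 1 the reverse complement of the antisense end. Base qualities come
from a two-state (high/low quality) profile with state-specific error
rates, so quality-interpolated mismatch penalties are exercised at both
ends of their range.

Two confounder classes are simulated:

* gene-level paralogs — with probability ``paralog_rate`` a gene is
  duplicated elsewhere on the chromosome with controlled divergence,
  creating multi-mapping pressure;
* artifact read pairs — the sequencing-error / boundary-degeneracy
  confounder: read 1 mimics a scrambled-junction read (a window across a
  junction of the gene's own scrambled-pair space, carrying an elevated
  mismatch rate) while read 2 sits at a uniform position on the linear
  transcript. Depending on where the mate lands these become decoy pairs
  (mate outside the implied circle) or false circle-consistent candidates
  (mate inside); their alignment quality is independent of the mate's
  position, which is what lets the decoy-derived empirical null stand in
  for the false-candidate score distribution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .genome import GeneModel

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedCircle:
    gene: str
    acceptor_index: int  # y
    donor_index: int     # x
    abundance: float     # molar units; 1.0 ~ one RPKM-equivalent molecule
    intron_retained: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 20
    min_exons: int = 4
    max_exons: int = 8
    min_exon_len: int = 45
    max_exon_len: int = 250
    min_intron_len: int = 80
    max_intron_len: int = 800
    intergenic_gap: int = 500
    paralog_rate: float = 0.3        # per-gene whole-gene duplication prob.
    paralog_divergence: float = 0.03
    read_length: int = 76
    fragment_mean: float = 250.0
    fragment_sd: float = 35.0
    high_q: int = 40
    low_q: int = 12
    low_q_fraction: float = 0.15
    high_q_error: float = 0.001
    low_q_error: float = 0.02
    # expected fragments per molecule = abundance * depth * length/1000
    depth: float = 1.0
    linear_abundance_mean: float = 30.0   # lognormal median of linear molarity
    linear_abundance_sigma: float = 0.8
    # artifact (decoy-generating) read pairs
    artifact_junctions_per_gene: float = 2.0   # Poisson mean
    artifact_rate: float = 0.1                 # reads per junction, as a
                                               # fraction of the gene's
                                               # linear fragment rate
    artifact_mismatch_rate: float = 0.06
    circles: tuple[PlantedCircle, ...] = ()

    def __post_init__(self) -> None:
        for r in (self.paralog_rate, self.paralog_divergence,
                  self.low_q_fraction, self.high_q_error, self.low_q_error,
                  self.artifact_mismatch_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.min_exons < 1 or self.max_exons < self.min_exons:
            raise ValueError("infeasible exon count range")
        if self.min_exon_len < 1 or self.max_exon_len < self.min_exon_len:
            raise ValueError("infeasible exon length range")
        if self.min_intron_len < 1 or self.max_intron_len < self.min_intron_len:
            raise ValueError("infeasible intron length range")


@dataclass
class Reference:
    genome: dict[str, str]
    genes: dict[str, GeneModel]
    gene_table: pd.DataFrame       # gene, strand, n_exons, paralog_of
    linear_abundance: dict[str, float]

    def write(self, fasta_path: str, gtf_path: str) -> None:
        from .genome import write_gtf

        with open(fasta_path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_gtf(self.genes.values(), gtf_path)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def make_reference(config: SimulationConfig) -> Reference:
    """Build a deterministic toy genome + annotation from the config.

    One chromosome; genes laid out left to right with intergenic gaps;
    random strands. Paralog copies (divergence
    ``paralog_divergence``) are appended after the base genes with ids
    ``<gene>p``. The GTF written by :meth:`Reference.write` round-trips
    through the annotation loader.
    """
    rng = np.random.default_rng(config.seed)

    # structural plan for the base genes
    plans = []  # (gid, strand, [exon seqs], [intron seqs], paralog_of)
    for gi in range(config.n_genes):
        gid = f"G{gi:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.min_exons, config.max_exons + 1))
        exon_seqs = [
            _random_seq(rng, int(rng.integers(config.min_exon_len, config.max_exon_len + 1)))
            for _ in range(n_exons)
        ]
        intron_seqs = [
            _random_seq(rng, int(rng.integers(config.min_intron_len, config.max_intron_len + 1)))
            for _ in range(n_exons - 1)
        ]
        plans.append((gid, strand, exon_seqs, intron_seqs, ""))
    for gid, strand, exon_seqs, intron_seqs, _ in list(plans):
        if rng.random() < config.paralog_rate:
            plans.append(
                (
                    f"{gid}p",
                    strand,
                    [_mutate(rng, s, config.paralog_divergence) for s in exon_seqs],
                    [_mutate(rng, s, config.paralog_divergence) for s in intron_seqs],
                    gid,
                )
            )

    chrom = "chr1"
    pieces: list[str] = []
    pos = 0
    gtf_rows = []
    gene_rows = []
    abundances: dict[str, float] = {}
    for gid, strand, exon_seqs, intron_seqs, paralog_of in plans:
        tid = f"{gid}.t1"
        n_exons = len(exon_seqs)
        gap = _random_seq(rng, config.intergenic_gap)
        pieces.append(gap)
        pos += len(gap)
        exon_ivals = []  # genomic order, left to right
        for j, es in enumerate(exon_seqs):
            exon_ivals.append((pos, pos + len(es)))
            pieces.append(es)
            pos += len(es)
            if j < n_exons - 1:
                pieces.append(intron_seqs[j])
                pos += len(intron_seqs[j])
        tx_order = range(n_exons) if strand == "+" else range(n_exons - 1, -1, -1)
        for tx_idx, gidx in enumerate(tx_order):
            s, e = exon_ivals[gidx]
            gtf_rows.append((gid, tid, chrom, strand, s, e, tx_idx))
        gene_rows.append(
            {"gene": gid, "strand": strand, "n_exons": n_exons, "paralog_of": paralog_of}
        )
        abundances[gid] = float(
            rng.lognormal(np.log(config.linear_abundance_mean), config.linear_abundance_sigma)
        )
    pieces.append(_random_seq(rng, config.intergenic_gap))
    genome = {chrom: "".join(pieces)}

    from .genome import Exon, Transcript

    genes: dict[str, GeneModel] = {}
    per_tx: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    for gid, tid, c, strand, s, e, tx_idx in gtf_rows:
        per_tx.setdefault(tid, []).append((c, s, e, tx_idx))
        meta[tid] = (gid, c, strand)
    for tid, rows in per_tx.items():
        gid, c, strand = meta[tid]
        rows.sort(key=lambda r: r[3])
        exons = tuple(
            Exon(chrom=c, start=s, end=e, index=i) for i, (c, s, e, _) in enumerate(rows)
        )
        t = Transcript(id=tid, gene_id=gid, strand=strand, exons=exons)
        genes.setdefault(gid, GeneModel(gene_id=gid, chrom=c, strand=strand)).add(t)

    return Reference(
        genome=genome,
        genes=genes,
        gene_table=pd.DataFrame(gene_rows),
        linear_abundance=abundances,
    )


def plant_circles(
    reference: Reference,
    n: int,
    abundance: float,
    seed: int,
    min_exon_span: int = 1,
) -> tuple[PlantedCircle, ...]:
    """Choose ``n`` circles on distinct genes, deterministically for a seed.

    Genes involved in a paralog duplication (either copy) are skipped: a
    back-splice junction duplicated elsewhere in the genome is not uniquely
    mappable even in principle, so planted ground truth is placed on
    identifiable junctions while the paralogs keep supplying multi-mapping
    pressure.
    """
    rng = np.random.default_rng(seed)
    gt = reference.gene_table
    in_paralogy = set(gt.loc[gt["paralog_of"] != "", "gene"]) | set(
        gt.loc[gt["paralog_of"] != "", "paralog_of"]
    )
    gids = [g for g in sorted(reference.genes) if g not in in_paralogy]
    if n > len(gids):
        raise ValueError("more circles requested than eligible genes available")
    chosen = rng.choice(len(gids), size=n, replace=False)
    circles = []
    for gi in sorted(chosen):
        gid = gids[gi]
        t = next(iter(reference.genes[gid].transcripts.values()))
        ne = t.n_exons
        y = int(rng.integers(0, ne - min_exon_span))
        x = int(rng.integers(y + min_exon_span, ne))
        circles.append(PlantedCircle(gid, y, x, abundance))
    return tuple(circles)


@dataclass(frozen=True)
class SimulatedPair:
    pair_id: str
    read1: str
    qual1: str
    read2: str
    qual2: str
    gene: str
    molecule: str            # linear | circle | artifact
    donor_coord: int         # -1 for linear molecules
    acceptor_coord: int
    read1_spans_junction: bool
    sample: str


def _circle_sequence(reference: Reference, pc: PlantedCircle) -> tuple[str, int, int]:
    from .genome import fetch, spliced_sequence

    gm = reference.genes[pc.gene]
    t = next(iter(gm.transcripts.values()))
    if pc.intron_retained:
        exons = t.exons[pc.acceptor_index : pc.donor_index + 1]
        lo = min(e.start for e in exons)
        hi = max(e.end for e in exons)
        seq = fetch(reference.genome, t.chrom, lo, hi)
        if t.strand == "-":
            seq = reverse_complement(seq)
    else:
        seq = spliced_sequence(
            t, pc.acceptor_index, pc.donor_index, reference.genome, circular=True
        )
    return seq, t.donor_coord(pc.donor_index), t.acceptor_coord(pc.acceptor_index)


def _apply_errors(
    rng: np.random.Generator, seq: str, config: SimulationConfig
) -> tuple[str, str]:
    n = len(seq)
    low = rng.random(n) < config.low_q_fraction
    quals = np.where(low, config.low_q, config.high_q)
    err_p = np.where(low, config.low_q_error, config.high_q_error)
    errs = rng.random(n) < err_p
    out = list(seq)
    for i in np.flatnonzero(errs):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    qstr = "".join(chr(q + 33) for q in quals)
    return "".join(out), qstr


def simulate_readpairs(
    config: SimulationConfig,
    reference: Reference,
    sample: str = "synthA:r1",
) -> list[SimulatedPair]:
    """Simulate directional paired-end reads: linear fragments, circle
    fragments (with back-splice wraparound) and artifact pairs.
    Deterministic for a fixed config seed and sample name."""
    sample_tag = zlib.crc32(sample.encode()) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, sample_tag]))
    from .genome import spliced_sequence

    rl = config.read_length
    pairs: list[SimulatedPair] = []
    counter = 0

    def emit(frag_r1: str, frag_r2: str, gene: str, molecule: str, donor: int,
             acceptor: int, spans: bool, extra_mm: float = 0.0) -> None:
        nonlocal counter
        read1_t = reverse_complement(frag_r1[-rl:])
        read2_t = frag_r2[:rl]
        if extra_mm:
            read1_t = _mutate(rng, read1_t, extra_mm)
        read1, q1 = _apply_errors(rng, read1_t, config)
        read2, q2 = _apply_errors(rng, read2_t, config)
        pairs.append(
            SimulatedPair(
                pair_id=f"{sample}:{counter}",
                read1=read1,
                qual1=q1,
                read2=read2,
                qual2=q2,
                gene=gene,
                molecule=molecule,
                donor_coord=donor,
                acceptor_coord=acceptor,
                read1_spans_junction=spans,
                sample=sample,
            )
        )
        counter += 1

    def fragment_length(upper: int | None = None) -> int:
        fl = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
        fl = max(fl, rl)
        if upper is not None:
            fl = min(fl, upper)
        return fl

    planted = {(pc.gene, pc.acceptor_index, pc.donor_index) for pc in config.circles}

    for gid in sorted(reference.genes):
        gm = reference.genes[gid]
        t = next(iter(gm.transcripts.values()))
        seq = spliced_sequence(t, 0, t.n_exons - 1, reference.genome)
        L = len(seq)
        if L < rl:
            continue
        lam = reference.linear_abundance[gid] * config.depth * L / 1000.0

        # linear fragments
        for _ in range(rng.poisson(lam)):
            fl = fragment_length(upper=L)
            start = int(rng.integers(0, L - fl + 1))
            frag = seq[start : start + fl]
            emit(frag, frag, gid, "linear", -1, -1, False)

        # artifact pairs at degenerate scrambled junctions of this gene
        n_art = rng.poisson(config.artifact_junctions_per_gene)
        ne = t.n_exons
        for _ in range(n_art):
            y = int(rng.integers(0, ne))
            x = int(rng.integers(y, ne))
            if (gid, y, x) in planted:
                continue
            cseq = spliced_sequence(t, y, x, reference.genome, circular=True)
            Lc = len(cseq)
            tiled = cseq * (rl // Lc + 2)
            donor = t.donor_coord(x)
            acceptor = t.acceptor_coord(y)
            for _ in range(rng.poisson(config.artifact_rate * lam)):
                # read 1 crosses the junction with a uniform overhang
                o = int(rng.integers(10, min(66, rl - 10) + 1))
                w_start = (Lc - (rl - o)) % Lc
                frag_r1 = tiled[w_start : w_start + rl]
                m_start = int(rng.integers(0, L - rl + 1))
                frag_r2 = seq[m_start : m_start + rl]
                emit(
                    frag_r1, frag_r2, gid, "artifact", donor, acceptor, True,
                    extra_mm=config.artifact_mismatch_rate,
                )

    # circular molecules
    for pc in config.circles:
        cseq, donor, acceptor = _circle_sequence(reference, pc)
        L = len(cseq)
        lam = pc.abundance * config.depth * L / 1000.0
        tiled_reps = max(3, (int(config.fragment_mean + 5 * config.fragment_sd) // L) + 2)
        tiled = cseq * tiled_reps
        for _ in range(rng.poisson(lam)):
            fl = fragment_length()
            start = int(rng.integers(0, L))
            frag = tiled[start : start + fl]
            # does read 1 span the back-splice junction with the default
            # 10 nt overhang? read 1 covers circle positions
            # [start + fl - rl, start + fl); junction boundaries sit at
            # multiples of L.
            r1_lo = start + fl - rl
            r1_hi = start + fl
            spans = any(
                r1_lo + 10 <= m * L <= r1_hi - 10
                for m in range(1, (r1_hi // L) + 2)
            )
            emit(frag, frag, pc.gene, "circle", donor, acceptor, spans)

    return pairs


def truth_table(pairs: list[SimulatedPair]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pairs])[
        [
            "pair_id", "gene", "molecule", "donor_coord", "acceptor_coord",
            "read1_spans_junction", "sample",
        ]
    ]


def write_fastq(pairs: list[SimulatedPair], path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.read1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.read2}\n+\n{p.qual2}\n")
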