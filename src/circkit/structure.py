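"""Structural analyses of circular isoforms.

Covers within-gene intron-length statistics around circularizing splice
sites, the combinatorial index of splice-site pairing, strand-orientation
summaries, and microRNA seed-match window profiles around the back-splice
junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from scipy.stats import rankdata

from .genome import Transcript


# ---------------------------------------------------------------------------
# intron-length statistics

def intron_quantile(
    lengths: Sequence[float], target_index: int, convention: str = "rank"
) -> float:
    """Within-gene quantile of one intron's length.

    ``rank`` (default): descending rank of the target divided by the number
    of introns, times 100 — the second-largest of 5 introns scores
    2/5 * 100 = 40. Ties share the mean rank. ``fig4``: shortest = 0,
    longest = 100, linear in ascending mean rank.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty intron length list")
    if not (0 <= target_index < arr.size):
        raise IndexError("target intron index out of range")
    if convention == "rank":
        desc = rankdata(-arr, method="average")
        return float(desc[target_index] / arr.size * 100.0)
    if convention == "fig4":
        if arr.size == 1:
            return 100.0
        asc = rankdata(arr, method="average")
        return float((asc[target_index] - 1) / (arr.size - 1) * 100.0)
    raise ValueError(f"unknown quantile convention {convention!r}")


def fraction_of_max(lengths: Sequence[float], target_index: int) -> float:
    """Target intron length as a fraction of the gene's longest intron."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty intron length list")
    if not (0 <= target_index < arr.size):
        raise IndexError("target intron index out of range")
    return float(arr[target_index] / arr.max())


def null_fraction_distribution(
    gene_intron_lengths: Iterable[Sequence[float]], variant: str = "to_max"
) -> pd.DataFrame:
    """Null distribution of second- and third-largest intron ratios.

    ``to_max``: (2nd largest)/(largest) and (3rd largest)/(largest) per gene;
    ``second_to_third``: (3rd largest)/(2nd largest). Both readings of the
    "second vs. third largest intron" null are provided; genes with too few
    introns are skipped.
    """
    rows = []
    for lens in gene_intron_lengths:
        arr = np.sort(np.asarray(lens, dtype=float))[::-1]
        if variant == "to_max":
            if arr.size >= 2:
                rows.append({"second_over_max": arr[1] / arr[0],
                             "third_over_max": arr[2] / arr[0] if arr.size >= 3 else np.nan})
        elif variant == "second_to_third":
            if arr.size >= 3:
                rows.append({"third_over_second": arr[2] / arr[1]})
        else:
            raise ValueError(f"unknown null variant {variant!r}")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FlankingIntrons:
    """Intron lengths flanking a circle's splice sites.

    flank5 is the intron upstream of the acceptor exon (None at the first
    exon); flank3 is the intron downstream of the donor exon (None at the
    last exon). Lengths are genomic; indices refer to the transcript's
    intron list in transcription order.
    """

    flank5: int | None
    flank3: int | None
    flank5_index: int | None
    flank3_index: int | None
    gene_intron_lengths: tuple[int, ...]


def flanking_introns(transcript: Transcript, y: int, x: int) -> FlankingIntrons:
    introns = transcript.intron_lengths()
    f5_idx = y - 1 if y >= 1 else None
    f3_idx = x if x < len(introns) else None
    return FlankingIntrons(
        flank5=introns[f5_idx] if f5_idx is not None else None,
        flank3=introns[f3_idx] if f3_idx is not None else None,
        flank5_index=f5_idx,
        flank3_index=f3_idx,
        gene_intron_lengths=tuple(introns),
    )


def flanking_intron_quantiles(
    isoforms: pd.DataFrame,
    weighting: str = "by_reads",
    min_count: int = 20,
    convention: str = "rank",
) -> pd.DataFrame:
    """Quantiles of circle-flanking introns over a set of isoforms.

    ``isoforms`` needs columns count, flank5_index, flank3_index and
    intron_lengths (a sequence per row). ``by_reads`` weights each isoform
    by its total read count; ``once_each`` counts each isoform once provided
    it has at least ``min_count`` reads. Returns one row per (isoform,
    flank) with the quantile and its weight.
    """
    if weighting not in ("by_reads", "once_each"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rows = []
    for _, r in isoforms.iterrows():
        count = int(r["count"])
        if weighting == "once_each" and count < min_count:
            continue
        weight = count if weighting == "by_reads" else 1
        lens = list(r["intron_lengths"])
        if not lens:
            continue
        for side, idx in (("flank5", r["flank5_index"]), ("flank3", r["flank3_index"])):
            if idx is None or (isinstance(idx, float) and np.isnan(idx)):
                continue
            rows.append(
                {
                    "gene": r.get("gene"),
                    "side": side,
                    "quantile": intron_quantile(lens, int(idx), convention),
                    "fraction_of_max": fraction_of_max(lens, int(idx)),
                    "weight": weight,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "side", "quantile", "fraction_of_max", "weight"])


# ---------------------------------------------------------------------------
# combinatorial index

@dataclass(frozen=True)
class CombinatorialSummary:
    gene: str
    detected: int
    n_acceptors: int
    n_donors: int
    min_possible: int
    max_possible: int
    index: float | None  # C; None when max_possible == min_possible


def combinatorial_index(
    isoforms: Iterable[tuple[int, int]], gene: str = ""
) -> CombinatorialSummary:
    """Combinatorial index C of detected circular isoforms of one gene.

    ``isoforms`` are (acceptor coordinate, donor coordinate) pairs oriented
    so the acceptor is upstream (coordinate-smaller or equal) of the donor;
    duplicates are collapsed. min possible = max(#acceptors, #donors);
    max possible = #{(a, d): a upstream of d} over detected sites, counting
    a == d (single-exon circles) as a valid pairing of that site with
    itself. C = (detected - min)/(max - min), undefined when max == min.
    """
    pairs = sorted(set((int(a), int(d)) for a, d in isoforms))
    if any(a > d for a, d in pairs):
        raise ValueError(
            "isoforms must be oriented acceptor-upstream-of-donor; "
            "remove mixed-orientation genes first"
        )
    acceptors = sorted({a for a, _ in pairs})
    donors = sorted({d for _, d in pairs})
    detected = len(pairs)
    min_possible = max(len(acceptors), len(donors))
    max_possible = sum(1 for a in acceptors for d in donors if a <= d)
    if max_possible == min_possible:
        c = None
    else:
        c = (detected - min_possible) / (max_possible - min_possible)
    return CombinatorialSummary(
        gene=gene,
        detected=detected,
        n_acceptors=len(acceptors),
        n_donors=len(donors),
        min_possible=min_possible,
        max_possible=max_possible,
        index=c,
    )


def orient_isoforms(
    isoforms: pd.DataFrame,
) -> pd.DataFrame:
    """Orient (acceptor_coord, donor_coord) pairs so acceptor <= donor;
    genes mixing both orientations are removed."""
    df = isoforms.copy()
    df["lo"] = df[["acceptor_coord", "donor_coord"]].min(axis=1)
    df["hi"] = df[["acceptor_coord", "donor_coord"]].max(axis=1)
    fwd = df["acceptor_coord"] <= df["donor_coord"]
    by_gene = df.assign(fwd=fwd).groupby("gene")["fwd"].agg(["all", "any"])
    mixed_genes = set(by_gene[(~by_gene["all"]) & by_gene["any"]].index)
    df = df[~df["gene"].isin(mixed_genes)]
    out = df[["gene"]].copy()
    out["acceptor_coord"] = df["lo"]
    out["donor_coord"] = df["hi"]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# strand orientation

def orientation_summary(
    counts: pd.DataFrame, config_sense_orientation: str = "-"
) -> pd.DataFrame:
    """Percent of circular isoforms in the sense orientation per cell type.

    ``counts`` follows the ``orientation`` groupby profile: one row per
    (cell_type, gene, donor_coord, acceptor_coord, read1_orientation), with
    same-strand pairs already discarded and replicates pooled. An isoform is
    sense when its read-1 orientation equals ``config_sense_orientation``
    (the directional-library expectation). Cell types without isoforms are
    reported as missing, not 0.
    """
    rows = []
    for ct, grp in counts.groupby("cell_type"):
        n = len(grp)
        if n == 0:
            continue
        sense = int((grp["read1_orientation"] == config_sense_orientation).sum())
        rows.append(
            {"cell_type": ct, "n_isoforms": n, "percent_sense": 100.0 * sense / n}
        )
    return pd.DataFrame(rows, columns=["cell_type", "n_isoforms", "percent_sense"])


# ---------------------------------------------------------------------------
# microRNA seed windows

def mirna_seeds(mature_sequences: Iterable[str]) -> set[str]:
    """6-mer seeds (nt 2-7) of mature miRNA sequences, as DNA."""
    seeds = set()
    for seq in mature_sequences:
        s = str(seq).upper().replace("U", "T")
        if len(s) >= 7:
            seeds.add(s[1:7])
    return seeds


def seed_match_profile(
    windows: Iterable[str], seeds: set[str], window_length: int = 132
) -> tuple[np.ndarray, int]:
    """Seed-site counts per offset across junction windows.

    A match at offset o means the reverse complement of some seed occupies
    window positions [o, o+6); each window contributes at most one match
    per offset. Returns (counts over the window_length - 5 offsets,
    number of windows).
    """
    targets = {reverse_complement(s) for s in seeds}
    n_offsets = window_length - 6 + 1
    counts = np.zeros(n_offsets, dtype=int)
    n_windows = 0
    for w in windows:
        w = str(w).upper()
        if len(w) != window_length:
            raise ValueError(
                f"junction window length {len(w)} != {window_length}"
            )
        n_windows += 1
        for o in range(n_offsets):
            if w[o : o + 6] in targets:
                counts[o] += 1
    return counts, n_windows


def seed_enrichment(
    windows: Sequence[str],
    seeds: set[str],
    ranks: Sequence[float],
    rank_threshold: float = 1000,
    window_length: int = 132,
) -> pd.DataFrame:
    """Per-offset seed-match enrichment of highly expressed junctions.

    Windows with rank < ``rank_threshold`` (best rank in any cell type) form
    the high set; all others the low set. The enrichment at each offset is
    the high-set match rate divided by the low-set match rate (NaN where the
    low set has no matches).
    """
    windows = list(windows)
    ranks = np.asarray(list(ranks), dtype=float)
    if len(windows) != len(ranks):
        raise ValueError("windows and ranks differ in length")
    high = [w for w, r in zip(windows, ranks) if r < rank_threshold]
    low = [w for w, r in zip(windows, ranks) if not (r < rank_threshold)]
    ch, nh = seed_match_profile(high, seeds, window_length)
    cl, nl = seed_match_profile(low, seeds, window_length)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_h = ch / nh if nh else np.full_like(ch, np.nan, dtype=float)
        rate_l = cl / nl if nl else np.full_like(cl, np.nan, dtype=float)
        ratio = np.where(rate_l > 0, rate_h / np.where(rate_l > 0, rate_l, 1), np.nan)
    return pd.DataFrame(
        {
            "offset": np.arange(window_length - 5),
            "high_matches": ch,
            "low_matches": cl,
            "high_rate": rate_h,
            "low_rate": rate_l,
            "ratio": ratio,
        }
    )
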