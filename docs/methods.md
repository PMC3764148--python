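# Methods

## Problem

Back-splicing covalently joins the donor (3′) splice site of a downstream
exon to the acceptor (5′) splice site of an upstream exon of the same
transcript, producing a circular RNA. The junction it creates — exon *x*
donor joined to exon *y* acceptor with *y* ≤ *x* — appears in no linear
isoform, so a sequencing read spanning it is diagnostic of a circle. The
hard part is not finding such reads but distinguishing them from reads that
merely *look* junctional because of sequencing errors and sequence
similarity between exons: in highly expressed genes almost all apparent
junction reads are artifacts. circkit implements detection built on two
ideas: score averaging instead of per-read thresholds, and an empirical
null built from read pairs that are self-contradictory as circle evidence.

## Junction database

For every transcript with *n* distinct exons, all *n(n+1)/2* ordered pairs
(*y*, *x*), *y* ≤ *x*, are enumerated, including *y* = *x* (single-exon
circles). Each pair yields a reference entry of length `2*flank` (default
132 nt, flank 66) with the back-splice junction at the midpoint. The entry
is cut from the circle treated as a periodic string: the 66 nt of spliced
circle sequence ending at the donor site followed by the 66 nt starting at
the acceptor site, wrapping around the circle as needed. This single
wraparound rule subsumes three situations that would otherwise need
special-casing: flanking exons ≥ 66 nt (plain flank concatenation), short
exons (the window walks into neighbouring exons of the circle), and whole
circles shorter than 132 nt (rolling-circle tiling, flagged
`rolling_circle`). A string oracle — cut the same window from the
triple-repeated circle — verifies the rule in the tests.

Duplicate transcripts (identical exon chains under different ids) are
collapsed before enumeration, and junctions identical at genomic (donor,
acceptor) coordinates across a gene's isoforms are merged with a
provenance list. Coordinates are 0-based half-open internally; GTF I/O
converts at the boundary. Exon indices are transcription-order ordinals
(index 0 is the 5′-most exon of the RNA on either strand).

## Alignment and scoring

Reads are scored so that a perfect alignment is 0 and each mismatch costs
between 2 (quality 0) and 6 (quality ≥ 40), linearly interpolated in the
base quality; gaps cost 5 to open plus 3 per base, N bases cost 1. These
are the reference aligner's end-to-end defaults, and the same scheme is
applied whether alignments come from the internal aligner or are re-scored
from SAM records (MD tag + qualities). Alignments scoring below
−0.6 − 0.6·L (L = read length) are treated as unaligned, again following
the reference aligner's reporting threshold; without it, chance seed
matches with 15+ mismatches would pollute both candidates and the null
with meaningless placements.

The internal aligner is deterministic gap-free seed-and-extend (exact
20-mers sampled at three read offsets, every proposed diagonal scored in
full, ties broken by reference name, position, orientation). It exists so
the pipeline is self-contained and exactly reproducible; pre-aligned
SAM/BAM ingestion is equally supported. Read 2 is aligned against spliced
transcript models first, then gene spans (introns included, for
intron-retained circles and intronic mates), then the junction database;
on score ties the linear placements win, because a mate explicable by the
linear transcript carries no junctional claim.

## Read-pair classification

Read 1 and read 2 are deliberately asymmetric, following the directional
library protocol: read 1 is the junction-defining read and must overlap
the entry midpoint by at least 10 nt on both sides (the minimum overhang a
76-nt read needs on a 132-nt entry); read 2 need not be junctional. With
the default `read1_antisense` strandness a sense circle yields read 1 in
− orientation on the junction entry and read 2 in + orientation.

A pair is **circle-consistent** when read 2 lies within the genomic span
of exons *y*..*x* implied by read 1's junction (or maps to the same
junction) and the reads are on opposite strands; intronic placements
inside the span are accepted and flagged (intron-retained circles). A pair
whose mate maps to the same gene but upstream of the acceptor exon or
downstream of the donor exon cannot derive from the circle: it is a
**decoy**. Same-strand pairs, overhang failures and cross-gene pairs are
discarded. Classification is a pure function of orientations, mate
placement and overhang; no alignment-quality threshold is applied at this
stage.

Evidence is aggregated by (gene, donor coordinate, acceptor coordinate):
the junctional count, the mean read-1 score, the mean read-2 score, and
the mean per-pair score product (reported for completeness but not used in
the FDR; it is stored non-negative since both factors are ≤ 0).

## Empirical FDR

Decoy aggregates supply one null point each — the pair (mean read-1 score,
mean read-2 score) — pooled genome-wide (decoys are too sparse per gene
for per-gene nulls, though that option exists). A candidate's FDR is the
add-one dominance tail

    fdr = (1 + #{(u1, u2) in null : u1 >= s1 and u2 >= s2}) / (1 + N),

the weakest combination rule that uses both score averages jointly;
add-one smoothing keeps the FDR in (0, 1]. Candidates pass at
fdr ≤ α = 0.025 (boundary inclusive). With an empty null the FDR is 1
with a warning — absence of decoys is absence of calibration, not
evidence of purity.

Two alternative referral rules are available: `marginal-min` (the smaller
of the two one-dimensional tails) and `calibrated`, a conformal variant
that refers the candidate's dominance count to the leave-one-out dominance
counts of the null points themselves. Raw two-dimensional dominance is a
depth, not a calibrated tail probability — points near the Pareto frontier
of the null have few dominators wherever the mass sits — so when the joint
null distribution is strongly two-dimensional the calibrated rule is the
statistically safer choice. In the regimes simulated here the two score
averages are highly concordant (the mate score is nearly always ≈ 0), the
problem is effectively one-dimensional, and the plain dominance rule is
calibrated in practice; it remains the default.

The FDR machinery presumes exchangeability between decoys and false
candidates: an artifact read's alignment quality must not depend on where
its mate happens to fall. That is true of error- and degeneracy-driven
artifacts (the dominant real sources), and the simulator is built to
respect it (below). It is *not* true of adversarial structures such as a
wholesale duplicated exon inside a gene, where junctions implying a circle
that starts at the first exon can never generate upstream decoys yet
produce abundant well-scoring false candidates; no decoy-based referral
can calibrate against such a source.

## Quantitation

Linear abundance is taken as RPKM from poly(A) analysis; circular
abundance is the junctional read-pair count (counting junction-spanning
reads normalizes by length automatically). The equivalence factor κ — the
junctional counts corresponding to a circle at the molar level of a 1-RPKM
linear transcript — is calibrated on reference genes as the geometric mean
of per-gene counts per RPKM-equivalent:

    kappa = 2 ** mean_g( log2 c_g − log2 R_g − log2 m_g ),

where m_g is the known circular:linear molecule ratio of calibration gene
g (m_g = 1 reduces to averaging log2-count minus log2-RPKM differences).
The genome-wide circular mass fraction is
100 · Σcounts / (κ · ΣRPKM), optionally restricted to circles with count
strictly greater than 5 (the conservative variant). Per-gene tables carry
both `rpkm_div_cir` (RPKM/count, the published ordering field) and the
molar ratio count/(κ·RPKM); genes with ratio > 1 are flagged
circle-dominant. A small utility converts RNase-R/mock qPCR cycle
thresholds to a fraction resistant, with both sign conventions exposed
because the published formula (2^(RNaseR Ct − Mock Ct)) is inverted
relative to the usual ΔCt reading; the printed form is the default.

Counting conventions differ between downstream analyses (summing over
replicates and/or cell types, keying isoforms with or without read
orientations). These are implemented as named `groupby` profiles
(`intron_lengths`, `by_cell_type`, `per_replicate_oriented`,
`orientation`) selected explicitly, never inferred.

## Regulation statistics

*Poisson model.* Per gene, circle counts across samples are modeled as
`cir ~ log(genexp) + celltype + totcircles − 1` with a log link, fitted by
IRLS (statsmodels GLM); rows are restricted to circles with ≥ 50 counts in
at least one sample and passing the FDR cut. Identically-zero covariates
are dropped rather than failing the rank check; genuinely collinear
designs raise an error naming the offending columns. An alternative
layout with per-isoform expression slopes plus replicate-type effects is
available as `model="isoform_interaction"`.

*Site-usage intervals.* For each donor and acceptor site, per cell type,
an exact (Clopper–Pearson) binomial interval at level .999 is computed for
the probability that a circle of the gene uses that site; x is the site's
count, n the gene's total. Sites enter when represented by > 50 counts in
some cell type and > 5 reads overall, with gene evidence in ≥ 2 cell
types; zero-usage rows are retained because all-or-none switching between
cell types is exactly the signal of interest. A site is flagged regulated
when any pair of cell types has non-overlapping intervals (no
multiple-testing correction, by design). Replicates are collapsed before
interval computation.

*Orthology conservation.* For the two-species contingency of circle
evidence, the expected joint count under independence is
E = round(rowTotal·colTotal/N) — rounded to the nearest integer, which is
what reproduces the published worked value (E = 35, residual 3.7 from
O = 57, margins 147 and 332, N = 1402); an unrounded mode is a flag away.
The residual (O−E)/√E is reported with a one-sided normal p-value.

## Structural statistics

*Intron quantiles.* The default transform ranks a gene's introns in
descending length and reports rank/n·100, ties sharing the mean rank — the
convention fixed by the in-text worked example (second largest of 5 → 40).
The figure-caption convention (shortest = 0, longest = 100) is exposed as
`fig4`; the two disagree and we do not guess which produced the published
heatmaps, so both are available and the worked-example convention is the
default. Fraction-of-max (target length / longest intron) comes with a
null-distribution helper offering both readings of the "second vs. third
largest intron" null.

*Combinatorial index.* For a gene's detected circle isoforms (deduplicated
acceptor/donor coordinate pairs, oriented acceptor-upstream; mixed-
orientation genes removed), C = (detected − min)/(max − min) with
min = max(#acceptors, #donors) and max = #{(a, d) : a upstream of d};
C is undefined when max = min.

*Orientation summary.* Isoforms are keyed per cell type with read-1
orientation (replicates pooled, same-strand pairs already discarded); the
percentage matching the annotated strand is reported per cell type, with
empty cell types reported as missing rather than 0%.

*Seed windows.* MicroRNA seeds are the 6-mers at nt 2–7 of mature
sequences; a match at offset o means the reverse complement of a seed
occupies window positions [o, o+6) of the 132-nt junction window — the
standard target-site definition, chosen because the source of the seeds
is the miRNA itself while the window is target sequence. Offsets run 0–126
(127 values). Enrichment is the match rate in highly expressed junction
windows (rank < 1000 in some cell type) over the rate in all others.

## Synthetic data

The simulator generates the full study scaffold deterministically from a
seed: a single-chromosome genome with `n_genes` multi-exon genes (4–8
exons of 45–250 nt, introns 80–800 nt, random strands, 500-nt gaps),
lognormal linear abundances (median 30, σ 0.8), and directional 76-nt
read pairs. Fragments are ~N(250, 35) nt; read 2 is the sense end, read 1
the reverse complement of the antisense end, matching the dUTP-style
protocol in which read 1 aligns antisense to the RNA. Base qualities come
from a two-state profile (85% at Q40 with error 0.001, 15% at Q12 with
error 0.02) so the quality-interpolated mismatch penalty is exercised at
both ends. Expected fragments per molecule are abundance · depth ·
length/1000; circle fragments are placed uniformly over circular
positions and wrap across the back-splice junction, which makes the
expected junctional read count per circle ≈ abundance · depth · 0.057,
independent of circle length. Planted circles (chosen exons y..x, molar
abundance, optional intron retention) are recorded in a truth table along
with per-pair provenance.

Two confounders are simulated. Gene-level paralogs: with probability
`paralog_rate` (0.3) a gene is duplicated elsewhere with 3% divergence,
creating multi-mapping pressure. Artifact pairs model the error/boundary-
degeneracy confounder directly: at a Poisson(2)-per-gene set of scrambled
junctions, reads are emitted whose read 1 is a junction-crossing window
carrying an elevated mismatch rate (6%) and whose read 2 sits at a
uniform position on the linear transcript. Because the mate's position is
independent of read 1's quality, these pairs split into decoys and false
candidates with identical score distributions — the exchangeability the
FDR referral relies on. The 6% rate places the null's perfect-score mass
(~0.7% per read) clearly below the 2.5% FDR threshold, which is the
operating regime the method requires: with a null of a few hundred
aggregates, perfect-decoy mass near the threshold would make passing it
arithmetically impossible for any candidate. Planted circles are placed
on genes outside any paralog relationship, since a junction duplicated
elsewhere in the genome is not uniquely mappable even in principle.

What the simulator does not model: coverage and GC bias, indels, adapter
read-through, rRNA contamination, unannotated splicing, and rolling-circle
reverse-transcription artifacts (a hook exists but is off by default).
Passing tests therefore demonstrate the statistical machinery under clean
homology/error confounding, not robustness to every failure mode of real
libraries.

## Problem sizes and numerical choices

The simulation-driven tests use 60–100 genes with ~7,000–11,000 read
pairs, giving nulls of 300–400 decoy aggregates and 20 planted circles at
abundance 400 (~23 expected junctional reads each); these sizes make the
binomial bound on the null passing fraction meaningful while keeping any
single scenario under a few seconds. GLM convergence follows statsmodels
defaults (IRLS, tolerance 1e-8, 50 iterations). All randomness flows from
explicit integer seeds; alignment, dedup and output orderings are
deterministic, so reruns are byte-identical.

## Known limitations

- Read 2 is placed by gap-free alignment; mates spanning two canonical
  junctions in one read (< 1% at these exon sizes) may fail to place and
  are discarded as unaligned rather than rescued by spliced alignment.
- De novo circles at unannotated boundaries are out of scope by design;
  so are antisense-specific junction databases and inter-gene fusions.
- The per-isoform FDR is thresholded per candidate and propagated to its
  reads; the alternative reading (thresholding reads directly) is not
  implemented.
- With very small decoy nulls (N < 39) no candidate can reach α = 0.025;
  the pipeline reports this honestly rather than interpolating the null.
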