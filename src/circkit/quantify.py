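"""Circular:linear abundance normalization and quantitation.

Linear abundance comes from poly(A) analysis in RPKM units; circular
abundance is the junctional read-pair count (counting junctional reads
inherently normalizes by gene length). The two scales are tied together by
an equivalence factor kappa — the junctional counts expected for a circle
expressed at the molar level of a 1-RPKM linear transcript — calibrated on
reference genes whose circular:linear molecule ratio m_g is known (e.g.
from qPCR):

    kappa = 2 ** mean_g( log2 c_g - log2 R_g - log2 m_g )

i.e. the geometric mean of per-gene counts per RPKM-equivalent. With
m_g = 1 this reduces to averaging log2-count minus log2-RPKM differences
and raising 2 to the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EquivalenceFactor:
    kappa: float
    calibration_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")


def equivalence_factor(
    calibration: Iterable[tuple[str, float, float, float]]
) -> EquivalenceFactor:
    """Calibrate kappa from (gene, circle counts, linear RPKM, molar ratio).

    The molar ratio m_g is the circular:linear molecule ratio of the
    calibration gene; pass 1.0 when counts and RPKM refer to equally
    abundant species.
    """
    rows = list(calibration)
    if not rows:
        raise ValueError("need at least one calibration gene")
    logs = []
    genes = []
    for gene, c, r, m in rows:
        if c <= 0 or r <= 0 or m <= 0:
            raise ValueError(f"calibration gene {gene}: inputs must be > 0")
        logs.append(math.log2(c) - math.log2(r) - math.log2(m))
        genes.append(gene)
    return EquivalenceFactor(
        kappa=2.0 ** (sum(logs) / len(logs)), calibration_genes=tuple(genes)
    )


def circular_mass_fraction(
    counts: Sequence[float],
    rpkms: Sequence[float],
    kappa: float | EquivalenceFactor,
    min_count_filter: int | None = None,
) -> float:
    """Percent of transcript molecules that are circular.

    100 * sum(junctional counts) / (kappa * sum(RPKM across all genes)).
    With ``min_count_filter`` only circles with count strictly greater than
    the filter contribute (the conservative variant).
    """
    k = kappa.kappa if isinstance(kappa, EquivalenceFactor) else float(kappa)
    total_rpkm = float(np.sum(rpkms))
    if total_rpkm <= 0:
        raise ValueError("total RPKM must be > 0")
    counts = np.asarray(counts, dtype=float)
    if min_count_filter is not None:
        counts = counts[counts > min_count_filter]
    return 100.0 * float(counts.sum()) / (k * total_rpkm)


def circle_linear_ratio(
    table: pd.DataFrame, kappa: float | EquivalenceFactor
) -> pd.DataFrame:
    """Per-gene circular:linear ratios.

    ``table`` needs columns gene, cir_count, rpkm. Adds:

    - ``rpkm_div_cir``: RPKM / junctional count (the published ordering
      field); equal molecule numbers occur at rpkm_div_cir == 1/kappa,
      since count == kappa * RPKM there;
    - ``molar_ratio``: count / (kappa * RPKM), >1 flagged circle-dominant.

    Rows with zero counts are retained with an ``undefined`` flag.
    """
    k = kappa.kappa if isinstance(kappa, EquivalenceFactor) else float(kappa)
    out = table.copy()
    counts = out["cir_count"].astype(float)
    rpkm = out["rpkm"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rpkm_div_cir"] = np.where(counts > 0, rpkm / counts, np.nan)
        out["molar_ratio"] = np.where(
            (rpkm > 0) & (counts >= 0), counts / (k * rpkm), np.nan
        )
    out["undefined"] = counts <= 0
    out["circle_dominant"] = (out["molar_ratio"] > 1).fillna(False)
    return out.sort_values(
        "rpkm_div_cir", kind="mergesort", na_position="last"
    ).reset_index(drop=True)


def fraction_resistant(
    ct_rnaser: float, ct_mock: float, sign: str = "printed"
) -> float:
    """Exonuclease-resistance fraction from qPCR cycle thresholds.

    ``printed`` returns 2**(ct_rnaser - ct_mock); ``standard`` returns
    2**(ct_mock - ct_rnaser), the usual delta-Ct reading in which a higher
    post-treatment Ct means less surviving template. Both are exposed
    because the two conventions disagree in sign.
    """
    if not (math.isfinite(ct_rnaser) and math.isfinite(ct_mock)):
        raise ValueError("Ct values must be finite")
    if sign == "printed":
        return 2.0 ** (ct_rnaser - ct_mock)
    if sign == "standard":
        return 2.0 ** (ct_mock - ct_rnaser)
    raise ValueError(f"unknown sign convention {sign!r}")


# ---------------------------------------------------------------------------
# counting profiles
#
# The downstream analyses each key "one circular isoform" differently; these
# named groupby profiles make the convention explicit instead of inferred.

GROUPBY_PROFILES: dict[str, dict] = {
    # intron-length analyses: summed across cell types and replicates
    "intron_lengths": {
        "keys": ["gene", "donor_coord", "acceptor_coord"],
        "sum_over": ["cell_type", "replicate"],
    },
    # per-cell-type expression: summed across replicates
    "by_cell_type": {
        "keys": ["cell_type", "gene", "donor_coord", "acceptor_coord"],
        "sum_over": ["replicate"],
    },
    # per-replicate totals: keyed with both read orientations
    "per_replicate_oriented": {
        "keys": [
            "cell_type", "replicate", "gene", "donor_coord", "acceptor_coord",
            "read1_orientation", "read2_orientation",
        ],
        "sum_over": [],
    },
    # strand-orientation analysis: replicates pooled, read-1 orientation kept
    "orientation": {
        "keys": [
            "cell_type", "gene", "donor_coord", "acceptor_coord",
            "read1_orientation",
        ],
        "sum_over": ["replicate"],
    },
}


def summarize_counts(counts: pd.DataFrame, profile: str) -> pd.DataFrame:
    """Aggregate a tidy per-read-pair (or finer) count table under a named
    profile; input needs a ``count`` column plus the profile's key columns."""
    try:
        spec = GROUPBY_PROFILES[profile]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; available: {sorted(GROUPBY_PROFILES)}"
        ) from None
    keys = spec["keys"]
    missing = [k for k in keys if k not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing} for {profile!r}")
    return (
        counts.groupby(keys, as_index=False)["count"].sum().sort_values(keys).reset_index(drop=True)
    )
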