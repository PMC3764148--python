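"""Regulation statistics: Poisson model of circle counts, exact binomial
confidence intervals for splice-site usage, and orthology-conservation
independence residuals.

The Poisson regression models junctional counts of one gene's circular
isoforms across samples as

    cir ~ log(genexp) + celltype + totcircles - 1      (log link)

where genexp is the linear gene expression (RPKM), celltype enters as
indicator columns (no intercept), and totcircles — the total circle counts
in the sample — absorbs sequencing-depth differences. Fitting is IRLS via
statsmodels GLM.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


# ---------------------------------------------------------------------------
# Poisson regulation model

@dataclass
class PoissonFit:
    coefficients: pd.Series
    fitted: np.ndarray
    deviance_residuals: np.ndarray
    deviance: float
    std_errors: pd.Series
    n_obs: int


def _design_matrix(rows: pd.DataFrame, model: str) -> pd.DataFrame:
    X = pd.DataFrame(index=rows.index)
    if model == "main":
        X["log_genexp"] = np.log(rows["genexp"].astype(float))
        for ct in sorted(rows["celltype"].unique()):
            X[f"celltype[{ct}]"] = (rows["celltype"] == ct).astype(float)
        X["totcircles"] = rows["totcircles"].astype(float)
    elif model == "isoform_interaction":
        # variant with per-isoform slopes for log expression plus
        # replicate-type effects (the alternative published layout)
        for iso in sorted(rows["iso"].unique()):
            ind = (rows["iso"] == iso).astype(float)
            X[f"iso[{iso}]"] = ind
            X[f"log_genexp:iso[{iso}]"] = ind * np.log(rows["genexp"].astype(float))
        for rt in sorted(rows["reptype"].unique())[1:]:
            X[f"reptype[{rt}]"] = (rows["reptype"] == rt).astype(float)
    else:
        raise ValueError(f"unknown model {model!r}")
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name columns implicated in the collinearity via the QR diagonal
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-10]
        raise ValueError(
            f"singular design: collinear columns {bad or list(X.columns)}"
        )


def filter_regulation_rows(rows: pd.DataFrame, min_count: int = 50) -> pd.DataFrame:
    """Keep circles represented by at least ``min_count`` counts in one
    sample (and passing the FDR cut when a ``passing`` column is present)."""
    df = rows
    if "passing" in df.columns:
        df = df[df["passing"]]
    ok = df.groupby("circle_id")["cir"].transform("max") >= min_count
    return df[ok]


def fit_poisson_regulation(
    rows: pd.DataFrame,
    min_count: int = 50,
    model: str = "main",
    apply_filter: bool = True,
) -> PoissonFit:
    """Fit the per-gene Poisson regulation model.

    ``rows`` is a tidy table with columns cir, genexp, celltype, totcircles
    (plus circle_id for the count filter; iso/reptype for the interaction
    variant). Returns coefficients, fitted means and deviance residuals.
    """
    df = filter_regulation_rows(rows, min_count) if apply_filter else rows
    if len(df) == 0:
        raise ValueError("no rows pass the count filter")
    if (df["genexp"] <= 0).any() and model == "main":
        raise ValueError("genexp must be > 0 for modeled rows")
    X = _design_matrix(df, model)
    # identically-zero covariates carry no information; drop them rather
    # than failing the rank check on degenerate designs
    X = X.loc[:, (X != 0).any(axis=0)]
    _check_full_rank(X)
    y = df["cir"].astype(float).to_numpy()
    glm = sm.GLM(y, X.to_numpy(dtype=float), family=sm.families.Poisson())
    res = glm.fit(maxiter=50, tol=1e-8)
    return PoissonFit(
        coefficients=pd.Series(res.params, index=X.columns),
        fitted=np.asarray(res.fittedvalues),
        deviance_residuals=np.asarray(res.resid_deviance),
        deviance=float(res.deviance),
        std_errors=pd.Series(res.bse, index=X.columns),
        n_obs=len(df),
    )


# ---------------------------------------------------------------------------
# exact binomial confidence intervals for site usage

@dataclass(frozen=True)
class SiteUsageCI:
    gene: str
    site_coord: int
    site_kind: str  # donor | acceptor
    cell_type: str
    x: int
    n: int
    mean: float
    lower: float
    upper: float
    level: float = 0.999


def site_usage_ci(x: int, n: int, level: float = 0.999) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a binomial proportion.

    lower solves P(X >= x | p) = alpha/2 (0 when x == 0); upper solves
    P(X <= x | p) = alpha/2 (1 when x == n); alpha = 1 - level.
    """
    if n < 1 or not (0 <= x <= n):
        raise ValueError(f"invalid binomial counts x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def site_usage_table(
    counts: pd.DataFrame,
    level: float = 0.999,
    min_site_count: int = 50,
    min_reads: int = 5,
    min_cell_types: int = 2,
) -> pd.DataFrame:
    """Per-site usage CIs by cell type from a by-cell-type count table.

    ``counts`` needs columns cell_type, gene, donor_coord, acceptor_coord,
    count (replicates already collapsed). Donor and acceptor sites are
    analyzed separately. A site enters the analysis when it is represented
    by more than ``min_site_count`` counts in at least one cell type and by
    more than ``min_reads`` reads in total, and its gene has circle
    evidence in at least ``min_cell_types`` cell types. Zero-usage rows
    (x = 0 in a cell type where the gene is observed) are retained — they
    are exactly what all-or-none regulated sites look like.
    """
    rows = []
    for kind, coord_col in (("donor", "donor_coord"), ("acceptor", "acceptor_coord")):
        site = (
            counts.groupby(["gene", coord_col, "cell_type"], as_index=False)["count"]
            .sum()
            .rename(columns={coord_col: "site_coord", "count": "x"})
        )
        totals = (
            counts.groupby(["gene", "cell_type"], as_index=False)["count"]
            .sum()
            .rename(columns={"count": "n"})
        )
        # every (site, cell type with gene evidence) pair, zeros included
        sites = site[["gene", "site_coord"]].drop_duplicates()
        full = sites.merge(totals, on="gene")
        site = full.merge(site, on=["gene", "site_coord", "cell_type"], how="left")
        site["x"] = site["x"].fillna(0).astype(int)
        site = site[site["n"] > 0]
        peak = site.groupby(["gene", "site_coord"])["x"].transform("max")
        total_x = site.groupby(["gene", "site_coord"])["x"].transform("sum")
        n_cts = site.groupby(["gene", "site_coord"])["n"].transform("size")
        keep = (
            (peak > min_site_count)
            & (total_x > min_reads)
            & (n_cts >= min_cell_types)
        )
        for _, r in site[keep].iterrows():
            lo, hi = site_usage_ci(int(r["x"]), int(r["n"]), level)
            rows.append(
                {
                    "type": r["cell_type"],
                    "method": "exact binomial CI",
                    "x": int(r["x"]),
                    "n": int(r["n"]),
                    "mean": r["x"] / r["n"],
                    "lower": lo,
                    "upper": hi,
                    "site_kind": kind,
                    "site_coord": int(r["site_coord"]),
                    "gene": r["gene"],
                }
            )
    cols = ["type", "method", "x", "n", "mean", "lower", "upper",
            "site_kind", "site_coord", "gene"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["gene", "site_kind", "site_coord", "type"]
    ).reset_index(drop=True)


def flag_regulated_sites(ci_table: pd.DataFrame) -> pd.DataFrame:
    """Sites with at least one pair of non-overlapping CIs across cell types.

    Returns one row per flagged (gene, site_kind, site_coord). The flag is
    symmetric in cell-type order: intervals [l1,u1], [l2,u2] are
    non-overlapping iff u1 < l2 or u2 < l1.
    """
    flagged = []
    for (gene, kind, coord), grp in ci_table.groupby(
        ["gene", "site_kind", "site_coord"]
    ):
        ivals = list(zip(grp["lower"], grp["upper"], grp["type"]))
        if len(ivals) < 2:
            continue
        for (l1, u1, c1), (l2, u2, c2) in combinations(ivals, 2):
            if u1 < l2 or u2 < l1:
                flagged.append(
                    {
                        "gene": gene,
                        "site_kind": kind,
                        "site_coord": coord,
                        "cell_type_a": min(c1, c2),
                        "cell_type_b": max(c1, c2),
                    }
                )
                break
    return pd.DataFrame(
        flagged, columns=["gene", "site_kind", "site_coord", "cell_type_a", "cell_type_b"]
    )


# ---------------------------------------------------------------------------
# orthology-conservation independence residual

@dataclass(frozen=True)
class ContingencyCounts:
    n_total: int
    row_total: int
    col_total: int
    observed: int

    def __post_init__(self) -> None:
        if not (0 <= self.observed <= min(self.row_total, self.col_total) <= self.n_total):
            raise ValueError("inconsistent contingency counts")


def independence_residual(
    counts: ContingencyCounts, round_expected: bool = True
) -> tuple[float, float]:
    """(E, (O-E)/sqrt(E)) under marginal independence.

    E = rowTotal * colTotal / N, rounded to the nearest integer by default.
    The chi-squared residual (O-E)/sqrt(E) measures over-representation of
    the joint class; a one-sided p-value from the normal upper tail is
    available via :func:`residual_pvalue`.
    """
    e = counts.row_total * counts.col_total / counts.n_total
    if round_expected:
        e = float(round(e))
    if e == 0:
        raise ValueError("expected count is zero")
    return e, (counts.observed - e) / np.sqrt(e)


def residual_pvalue(residual: float) -> float:
    """One-sided upper-tail normal p-value for an independence residual."""
    return float(stats.norm.sf(residual))
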