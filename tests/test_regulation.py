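import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circkit.regulation import (
    ContingencyCounts,
    fit_poisson_regulation,
    flag_regulated_sites,
    independence_residual,
    residual_pvalue,
    site_usage_ci,
    site_usage_table,
)


def brute_force_ci(x, n, level=0.999, step=1e-6):
    """Grid search for the exact binomial interval endpoints."""
    alpha = 1 - level
    grid = np.arange(step, 1.0, step)
    if x == 0:
        lower = 0.0
    else:
        upper_tail = stats.binom.sf(x - 1, n, grid)  # P(X >= x)
        lower = grid[np.searchsorted(upper_tail, alpha / 2, side="left")]
    if x == n:
        upper = 1.0
    else:
        lower_tail = stats.binom.cdf(x, n, grid)  # P(X <= x)
        upper = grid[len(lower_tail) - np.searchsorted(lower_tail[::-1], alpha / 2, side="left") - 1]
    return lower, upper


class TestSiteUsageCI:
    def test_boundaries(self):
        assert site_usage_ci(0, 10)[0] == 0.0
        assert site_usage_ci(10, 10)[1] == 1.0

    @pytest.mark.parametrize("x,n", [(5, 10), (1, 20), (19, 20), (30, 200)])
    def test_matches_brute_force_tail_search(self, x, n):
        lo, hi = site_usage_ci(x, n)
        blo, bhi = brute_force_ci(x, n)
        assert abs(lo - blo) < 1e-5
        assert abs(hi - bhi) < 1e-5

    def test_interval_ordering(self):
        lo, hi = site_usage_ci(5, 10)
        assert 0 <= lo <= 0.5 <= hi <= 1

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            site_usage_ci(5, 0)
        with pytest.raises(ValueError):
            site_usage_ci(-1, 10)

    def test_coverage_at_point_three(self):
        """Empirical coverage of the .999 interval across binomial draws."""
        rng = np.random.default_rng(2013)
        n, p, reps = 200, 0.3, 2000
        xs = rng.binomial(n, p, size=reps)
        alpha = 1 - 0.999
        lo = np.where(xs == 0, 0.0, stats.beta.ppf(alpha / 2, xs, n - xs + 1))
        hi = np.where(xs == n, 1.0, stats.beta.ppf(1 - alpha / 2, xs + 1, n - xs))
        coverage = np.mean((lo <= p) & (p <= hi))
        assert coverage >= 0.995


class TestSiteUsageTable:
    def counts(self):
        rows = []
        for ct, counts in (("A", (100, 2)), ("B", (3, 120))):
            for (donor, acc), c in zip(((500, 100), (700, 100)), counts):
                rows.append(
                    {
                        "cell_type": ct, "gene": "g", "donor_coord": donor,
                        "acceptor_coord": acc, "count": c,
                    }
                )
        return pd.DataFrame(rows)

    def test_filters_and_schema(self):
        tab = site_usage_table(self.counts())
        assert {"type", "method", "x", "n", "mean", "lower", "upper"} <= set(tab.columns)
        donors = tab[tab["site_kind"] == "donor"]
        assert set(donors["site_coord"]) == {500, 700}
        accs = tab[tab["site_kind"] == "acceptor"]
        # the single acceptor is used by 100% of circles in each cell type
        assert (accs["mean"] == 1.0).all()

    def test_flag_regulated_sites_on_switched_usage(self):
        tab = site_usage_table(self.counts())
        flagged = flag_regulated_sites(tab)
        assert set(flagged["site_coord"]) == {500, 700}
        assert (flagged["site_kind"] == "donor").all()

    def test_flag_symmetric_in_cell_type_order(self):
        tab = site_usage_table(self.counts())
        reordered = tab.iloc[::-1].reset_index(drop=True)
        a = flag_regulated_sites(tab)
        b = flag_regulated_sites(reordered)
        assert set(map(tuple, a[["gene", "site_kind", "site_coord"]].values)) == set(
            map(tuple, b[["gene", "site_kind", "site_coord"]].values)
        )


class TestFlagging:
    def _tab(self, i1, i2):
        return pd.DataFrame(
            {
                "gene": ["g", "g"],
                "site_kind": ["donor", "donor"],
                "site_coord": [10, 10],
                "type": ["A", "B"],
                "lower": [i1[0], i2[0]],
                "upper": [i1[1], i2[1]],
            }
        )

    def test_disjoint_intervals_flagged(self):
        assert len(flag_regulated_sites(self._tab((0, 0.2), (0.5, 1)))) == 1

    def test_overlapping_intervals_not_flagged(self):
        assert len(flag_regulated_sites(self._tab((0, 0.6), (0.5, 1)))) == 0

    def test_all_or_none_usage_flagged(self):
        # a site used by every circle in one cell type and none elsewhere,
        # at large n: intervals [~1] vs [~0] cannot overlap
        lo1, hi1 = site_usage_ci(200, 200)
        lo2, hi2 = site_usage_ci(0, 150)
        assert len(flag_regulated_sites(self._tab((lo1, hi1), (lo2, hi2)))) == 1


class TestPoissonRegulation:
    def test_saturated_single_cell_type_mean(self):
        rows = pd.DataFrame(
            {
                "circle_id": ["c"] * 3,
                "cir": [2, 2, 2],
                "genexp": [1.0, 1.0, 1.0],
                "celltype": ["A"] * 3,
                "totcircles": [0.0] * 3,
            }
        )
        fit = fit_poisson_regulation(rows, apply_filter=False)
        # log(genexp)=0 and totcircles=0: the A indicator carries the mean
        assert fit.coefficients["celltype[A]"] == pytest.approx(np.log(2), abs=1e-6)

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(42)
        n = 500
        genexp = rng.uniform(1, 100, n)
        celltype = rng.choice(["A", "B"], n)
        totc = rng.uniform(0, 2, n)
        beta = {"log_genexp": 0.8, "celltype[A]": 0.5, "celltype[B]": 1.2, "totcircles": 0.3}
        eta = (
            beta["log_genexp"] * np.log(genexp)
            + np.where(celltype == "A", beta["celltype[A]"], beta["celltype[B]"])
            + beta["totcircles"] * totc
        )
        y = rng.poisson(np.exp(eta))
        rows = pd.DataFrame(
            {
                "circle_id": "c",
                "cir": y,
                "genexp": genexp,
                "celltype": celltype,
                "totcircles": totc,
            }
        )
        fit = fit_poisson_regulation(rows, apply_filter=False)
        for name, truth in beta.items():
            est, se = fit.coefficients[name], fit.std_errors[name]
            assert abs(est - truth) < 3 * se, name

    def test_equals_group_means_on_categorical_design(self):
        rng = np.random.default_rng(9)
        rows = pd.DataFrame(
            {
                "circle_id": "c",
                "cir": rng.poisson(5, 60),
                "genexp": 1.0,  # log = 0: no slope contribution varies
                "celltype": ["A"] * 30 + ["B"] * 30,
                "totcircles": 0.0,
            }
        )
        # drop the constant-zero / constant columns to a purely categorical fit
        rows2 = rows.copy()
        fit = fit_poisson_regulation(rows2, apply_filter=False)
        for ct in ("A", "B"):
            grp = rows.loc[rows["celltype"] == ct, "cir"].mean()
            assert np.exp(fit.coefficients[f"celltype[{ct}]"]) == pytest.approx(
                grp, rel=1e-6
            )

    def test_min_count_filter(self):
        rows = pd.DataFrame(
            {
                "circle_id": ["lo"] * 2 + ["hi"] * 2,
                "cir": [5, 4, 60, 40],
                "genexp": [1.0] * 4,
                "celltype": ["A", "B"] * 2,
                "totcircles": [0.0] * 4,
            }
        )
        fit = fit_poisson_regulation(rows, min_count=50)
        assert fit.n_obs == 2

    def test_singular_design_names_columns(self):
        rows = pd.DataFrame(
            {
                "circle_id": "c",
                "cir": [1, 2, 3, 4],
                "genexp": [np.e] * 4,  # log(genexp) == 1, collinear with
                "celltype": ["A"] * 4,  # the single indicator
                "totcircles": [0.0] * 4,
            }
        )
        with pytest.raises(ValueError, match="singular design"):
            fit_poisson_regulation(rows, apply_filter=False)


class TestIndependenceResidual:
    def test_published_orthology_counts(self):
        # 1402 orthologous genes; 147 in the top-expressed circle set, 332
        # with circle evidence in the second species, 57 in both
        c = ContingencyCounts(n_total=1402, row_total=147, col_total=332, observed=57)
        e, resid = independence_residual(c)
        assert e == 35
        assert round(resid, 1) == 3.7

    def test_observed_equals_expected(self):
        c = ContingencyCounts(n_total=1000, row_total=100, col_total=100, observed=10)
        e, resid = independence_residual(c)
        assert (e, resid) == (10, 0.0)

    def test_hand_computed_case(self):
        c = ContingencyCounts(n_total=1000, row_total=100, col_total=100, observed=70)
        e, resid = independence_residual(c)
        assert e == 10
        assert resid == pytest.approx(60 / np.sqrt(10))

    def test_unrounded_mode(self):
        c = ContingencyCounts(n_total=1402, row_total=147, col_total=332, observed=57)
        e, resid = independence_residual(c, round_expected=False)
        assert e == pytest.approx(147 * 332 / 1402)
        assert resid == pytest.approx((57 - e) / np.sqrt(e))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyCounts(n_total=10, row_total=5, col_total=4, observed=6)

    def test_one_sided_pvalue(self):
        assert residual_pvalue(3.7) == pytest.approx(stats.norm.sf(3.7))
        assert 1e-5 < residual_pvalue(3.7) < 2e-4


class TestIsoformInteractionVariant:
    def test_per_isoform_slopes_recovered(self):
        rng = np.random.default_rng(13)
        n = 400
        iso = rng.choice(["i1", "i2"], n)
        genexp = rng.uniform(2, 60, n)
        reptype = rng.choice(["Ar1", "Ar2"], n)
        slope = np.where(iso == "i1", 0.5, 1.1)
        inter = np.where(iso == "i1", 0.3, -0.2)
        eta = inter + slope * np.log(genexp) + np.where(reptype == "Ar2", 0.25, 0.0)
        rows = pd.DataFrame(
            {
                "circle_id": "c",
                "cir": rng.poisson(np.exp(eta)),
                "genexp": genexp,
                "celltype": "A",
                "totcircles": 0.0,
                "iso": iso,
                "reptype": reptype,
            }
        )
        fit = fit_poisson_regulation(rows, apply_filter=False, model="isoform_interaction")
        assert abs(fit.coefficients["log_genexp:iso[i1]"] - 0.5) < 3 * fit.std_errors["log_genexp:iso[i1]"]
        assert abs(fit.coefficients["log_genexp:iso[i2]"] - 1.1) < 3 * fit.std_errors["log_genexp:iso[i2]"]
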