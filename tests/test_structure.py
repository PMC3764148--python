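import numpy as np
import pandas as pd
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from circkit.structure import (
    combinatorial_index,
    flanking_introns,
    fraction_of_max,
    intron_quantile,
    mirna_seeds,
    null_fraction_distribution,
    orient_isoforms,
    orientation_summary,
    seed_enrichment,
    seed_match_profile,
)

from conftest import make_transcript


def brute_quantile(lengths, idx):
    """Descending mean-rank of the target over the number of introns."""
    arr = list(lengths)
    ranks = []
    for v in arr:
        greater = sum(1 for w in arr if w > v)
        equal = sum(1 for w in arr if w == v)
        ranks.append(greater + (equal + 1) / 2)
    return ranks[idx] / len(arr) * 100


class TestIntronQuantile:
    def test_second_largest_of_five_is_forty(self):
        lengths = [10, 500, 200, 50, 30]  # second largest is 200 at index 2
        assert intron_quantile(lengths, 2) == pytest.approx(40.0)

    def test_largest_of_n(self):
        assert intron_quantile([5, 9, 1, 2], 1) == pytest.approx(100 / 4)

    def test_tied_introns_share_mean_rank(self):
        # two equal introns occupying descending ranks 2-3 of 4
        lengths = [100, 60, 60, 10]
        assert intron_quantile(lengths, 1) == pytest.approx(62.5)
        assert intron_quantile(lengths, 2) == pytest.approx(62.5)

    def test_fig4_convention_endpoints(self):
        lengths = [10, 500, 200, 50, 30]
        assert intron_quantile(lengths, 1, convention="fig4") == 100.0
        assert intron_quantile(lengths, 0, convention="fig4") == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_ranking(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(1, 30, size=rng.integers(1, 12)).tolist()
        idx = int(rng.integers(0, len(lengths)))
        assert intron_quantile(lengths, idx) == pytest.approx(
            brute_quantile(lengths, idx)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            intron_quantile([], 0)

    @settings(max_examples=200, derandomize=True)
    @given(
        lengths=st.lists(st.integers(1, 10**6), min_size=1, max_size=15),
        data=st.data(),
    )
    def test_quantile_properties_hold_for_arbitrary_genes(self, lengths, data):
        idx = data.draw(st.integers(0, len(lengths) - 1))
        q = intron_quantile(lengths, idx)
        assert 0 < q <= 100
        assert q == pytest.approx(brute_quantile(lengths, idx))
        assert fraction_of_max(lengths, idx) <= 1.0


class TestFractionOfMax:
    def test_longest_is_one(self):
        assert fraction_of_max([100, 300, 50], 1) == 1.0

    def test_half(self):
        assert fraction_of_max([100, 50], 1) == 0.5

    def test_null_distribution_variants(self):
        genes = [[100, 50, 25], [200, 100, 10], [9, 3]]
        to_max = null_fraction_distribution(genes, "to_max")
        assert to_max["second_over_max"].tolist() == pytest.approx([0.5, 0.5, 1 / 3])
        sec = null_fraction_distribution(genes, "second_to_third")
        assert sec["third_over_second"].tolist() == pytest.approx([0.5, 0.1])


class TestFlankingIntrons:
    def test_interior_circle(self, plus_gene):
        t = plus_gene.transcripts["GPLUS.t1"]
        fi = flanking_introns(t, 1, 2)
        assert fi.flank5 == t.intron_lengths()[0]
        assert fi.flank3 == t.intron_lengths()[2]

    def test_undefined_at_termini(self, plus_gene):
        t = plus_gene.transcripts["GPLUS.t1"]
        fi = flanking_introns(t, 0, t.n_exons - 1)
        assert fi.flank5 is None and fi.flank3 is None


class TestCombinatorialIndex:
    def brute(self, pairs):
        pairs = sorted(set(pairs))
        A = sorted({a for a, _ in pairs})
        D = sorted({d for _, d in pairs})
        max_poss = len([(a, d) for a in A for d in D if a <= d])
        min_poss = max(len(A), len(D))
        if max_poss == min_poss:
            return None
        return (len(pairs) - min_poss) / (max_poss - min_poss)

    def test_two_by_two_with_three_detected(self):
        pairs = [(10, 100), (10, 200), (20, 100)]
        s = combinatorial_index(pairs)
        assert (s.min_possible, s.max_possible) == (2, 4)
        assert s.index == 0.5

    def test_detected_equals_minimum(self):
        s = combinatorial_index([(10, 100), (20, 200)])
        assert s.index == 0.0

    def test_single_pair_undefined(self):
        assert combinatorial_index([(10, 100)]).index is None

    def test_duplicates_collapsed(self):
        s = combinatorial_index([(10, 100), (10, 100), (10, 200)])
        assert s.detected == 2

    def test_mixed_orientation_rejected(self):
        with pytest.raises(ValueError):
            combinatorial_index([(100, 10)])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        sites = sorted(rng.choice(200, size=8, replace=False))
        pairs = []
        for _ in range(rng.integers(1, 10)):
            a, d = sorted(rng.choice(sites, size=2, replace=True))
            pairs.append((int(a), int(d)))
        s = combinatorial_index(pairs)
        assert s.index == self.brute(pairs)
        if s.index is not None:
            assert 0 <= s.index <= 1

    def test_adding_isoform_never_decreases_index(self):
        base = [(10, 100), (10, 200), (20, 200)]
        s0 = combinatorial_index(base)
        s1 = combinatorial_index(base + [(20, 100)])
        assert s1.index >= s0.index

    def test_orient_isoforms_drops_mixed_genes(self):
        df = pd.DataFrame(
            {
                "gene": ["a", "a", "b", "b"],
                "acceptor_coord": [10, 300, 400, 500],
                "donor_coord": [100, 200, 450, 550],
            }
        )
        out = orient_isoforms(df)
        assert set(out["gene"]) == {"b"}


class TestOrientation:
    def counts(self):
        rows = [("A", "-", 24), ("A", "+", 1), ("B", "-", 10)]
        return pd.DataFrame(
            [
                {
                    "cell_type": ct,
                    "gene": f"g{i}",
                    "donor_coord": 100 + i,
                    "acceptor_coord": 50,
                    "read1_orientation": o,
                    "count": c,
                }
                for i, (ct, o, c) in enumerate(
                    [(ct, o, c) for ct, o, c in rows for _ in range(c)]
                )
            ]
        )

    def test_percent_sense(self):
        df = self.counts()
        out = orientation_summary(df).set_index("cell_type")
        assert out.loc["A", "percent_sense"] == pytest.approx(96.0)
        assert out.loc["B", "percent_sense"] == 100.0

    def test_all_sense_fixture(self):
        df = self.counts()
        df["read1_orientation"] = "-"
        out = orientation_summary(df)
        assert (out["percent_sense"] == 100.0).all()

    def test_empty_cell_type_missing_not_zero(self):
        out = orientation_summary(self.counts())
        assert "C" not in set(out["cell_type"])


def naive_scan(window, targets):
    return [1 if window[o : o + 6] in targets else 0 for o in range(len(window) - 5)]


class TestSeeds:
    def test_seed_extraction_nt_2_to_7(self):
        seeds = mirna_seeds(["UGAGGUAGUAGGUUGUAUAGUU"])
        assert seeds == {"GAGGTA"}

    def test_offset_count_is_127(self):
        counts, n = seed_match_profile(["A" * 132], {"TTTTTT"})
        assert len(counts) == 127 and n == 1

    def test_single_site_spanning_midpoint(self):
        seed = "GAGGTA"
        site = reverse_complement(seed)
        window = "A" * 63 + site + "A" * (132 - 63 - 6)
        counts, _ = seed_match_profile([window], {seed})
        assert counts[63] == 1
        assert counts.sum() == 1

    def test_matches_naive_scan_on_random_windows(self):
        rng = np.random.default_rng(8)
        seeds = {"".join("ACGU"[i] for i in rng.integers(0, 4, 6)) for _ in range(20)}
        seeds = mirna_seeds(["N" + s + "NNNN" for s in seeds])
        targets = {reverse_complement(s) for s in seeds}
        windows = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, 132)) for _ in range(50)
        ]
        counts, n = seed_match_profile(windows, seeds)
        expect = np.sum([naive_scan(w, targets) for w in windows], axis=0)
        assert n == 50
        assert counts.tolist() == expect.tolist()

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError):
            seed_match_profile(["ACGT"], {"AAAAAA"})

    def test_identical_high_low_sets_give_unit_ratio(self):
        rng = np.random.default_rng(9)
        windows = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, 132)) for _ in range(30)
        ]
        seeds = {"ACGTAC", "GGGTTT"}
        df = seed_enrichment(windows * 2, seeds, [1] * 30 + [5000] * 30)
        matched = df["ratio"].dropna()
        assert len(matched) > 0
        assert np.allclose(matched, 1.0)
        assert len(df) == 127
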