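"""Statistical tests and genomic summary statistics."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from temrkit.stats import (DepthProfile, annotate_genic, binom_two_tailed,
                           callable_density, depth_copy_number, fisher_exact_2x2,
                           gc_content, genic_enrichment, match_ancestral,
                           sample_control_windows, spearman, te_density, welch_t)


class TestWelchT:
    def test_identical_samples_degenerate(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res["p"] > 0.9 and abs(res["t"]) < 1e-12

    def test_constant_equal_samples_flagged(self):
        res = welch_t([2, 2, 2], [2, 2, 2])
        assert res == {"t": 0.0, "df": res["df"], "p": 1.0, "degenerate_variance": True}

    def test_textbook_example(self):
        # means 2.5 vs 3.5, equal variances 5/3; hand-computed Welch formula
        res = welch_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert res["t"] == pytest.approx(-1.0954451)
        assert res["df"] == pytest.approx(6.0)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1], [1, 2])


class TestBinomTwoTailed:
    @pytest.mark.parametrize("k,n,expected", [
        (1, 10, 0.021484375),       # 2 * 11/1024
        (5, 10, 1.0),
        (0, 10, 0.001953125),       # 2 * 1/1024 by direct enumeration
    ])
    def test_exact_values(self, k, n, expected):
        assert binom_two_tailed(k, n, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_small_p_method_by_enumeration(self):
        # sum of P(X=j) over j with point probability <= that of k
        for k, n in [(2, 11), (3, 15), (7, 9)]:
            probs = [comb(n, j) / 2 ** n for j in range(n + 1)]
            expected = sum(p for p in probs if p <= probs[k] + 1e-15)
            assert binom_two_tailed(k, n, 0.5) == pytest.approx(expected)

    def test_symmetry(self):
        for n in (7, 10, 13):
            for k in range(n + 1):
                assert binom_two_tailed(k, n, 0.5) == pytest.approx(
                    binom_two_tailed(n - k, n, 0.5))

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            binom_two_tailed(1, 0)


class TestFisherExact:
    def test_no_association(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_full_hypergeometric_enumeration(self):
        # table (1,9,9,1): p = 202/184756 by enumerating all tables with the
        # same margins and summing point probabilities <= that of the observed
        a, b, c, d = 1, 9, 9, 1
        n1, n2, m1 = a + b, c + d, a + c
        N = n1 + n2
        denom = comb(N, m1)
        probs = {}
        for k in range(max(0, m1 - n2), min(n1, m1) + 1):
            probs[k] = comb(n1, k) * comb(n2, m1 - k) / denom
        expected = sum(p for p in probs.values() if p <= probs[a] + 1e-15)
        assert expected == pytest.approx(202 / 184756)
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(expected)

    def test_unit_margin_reduces_to_bernoulli(self):
        # when one margin is 1, the hypergeometric is a Bernoulli draw whose
        # two-tailed small-p p-value is computed directly
        for c, d in [(9, 10), (3, 14), (1, 1)]:
            q = (1 + c) / (1 + c + d)          # P(success) for the single draw
            probs = [1 - q, q]
            for k in (0, 1):
                expected = sum(p for p in probs if p <= probs[k] + 1e-15)
                got = fisher_exact_2x2(k, 1 - k, c + 1 - k, d - (1 - k))
                assert got == pytest.approx(expected)

    def test_invariant_under_row_and_column_swap(self):
        for a, b, c, d in [(1, 9, 9, 1), (2, 3, 7, 5), (0, 4, 6, 2)]:
            base = fisher_exact_2x2(a, b, c, d)
            assert fisher_exact_2x2(d, c, b, a) == pytest.approx(base)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)


class TestSpearman:
    def test_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])["rho"] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [9, 7, 5, 3])["rho"] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_formula(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0]

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = np.array(v)[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]    # Pearson of average ranks
        assert spearman(x, y)["rho"] == pytest.approx(expected)

    def test_constant_vector_flagged(self):
        assert spearman([1, 1, 1], [1, 2, 3])["undefined"]


class TestGCContent:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 100.0), ("ATAT", 0.0),
                                              ("GCAT", 50.0)])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


def _annotation(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])


class TestTeDensity:
    def test_full_coverage(self):
        ann = _annotation([("chr1", 0, 200_000, "Alu")])
        assert te_density(("chr1", 90_000, 110_000), ann, "Alu") == 100.0

    def test_no_te(self):
        ann = _annotation([("chr1", 0, 100, "Alu")])
        assert te_density(("chr1", 400_000, 420_000), ann, "Alu") == 0.0

    def test_half_coverage(self):
        # [85k, 135k) window centred at 110k; Alu covers [85k, 110k)
        ann = _annotation([("chr1", 0, 110_000, "Alu")])
        assert te_density(("chr1", 100_000, 120_000), ann, "Alu") == 50.0

    def test_edge_clipping_renormalizes(self):
        ann = _annotation([("chr1", 0, 10_000, "Alu")])
        # midpoint at 10k: window clipped to [0, 35k); coverage 10k/35k
        d = te_density(("chr1", 5_000, 15_000), ann, "Alu",
                       genome_sizes={"chr1": 35_000})
        assert d == pytest.approx(100 * 10_000 / 35_000)

    def test_off_chromosome_rejected(self):
        ann = _annotation([("chr1", 0, 100, "Alu")])
        with pytest.raises(ValueError):
            te_density(("chr1", 60_000, 80_000), ann, "Alu",
                       genome_sizes={"chr1": 50_000})


class TestControlWindows:
    def test_fully_qualifying_genome(self):
        ann = _annotation([("chr1", i * 1000, i * 1000 + 300, "Alu")
                           for i in range(500)])
        dens = sample_control_windows(20, {"chr1": 500_000}, ann, "Alu",
                                      window=50_000, seed=3)
        assert len(dens) == 20
        assert all(25 < d < 35 for d in dens)   # ~30% coverage everywhere

    def test_family_absent_raises(self):
        ann = _annotation([("chr1", 0, 300, "Alu")])
        with pytest.raises(RuntimeError):
            sample_control_windows(5, {"chr1": 500_000}, ann, "LINE-1",
                                   window=50_000, seed=1, max_iter_factor=20)

    def test_mean_matches_genome_fraction(self):
        rng = np.random.default_rng(8)
        starts = np.sort(rng.choice(np.arange(0, 990_000, 600), 600, replace=False))
        ann = _annotation([("chr1", int(s), int(s) + 300, "Alu") for s in starts])
        frac = 600 * 300 / 1_000_000 * 100
        dens = sample_control_windows(60, {"chr1": 1_000_000}, ann, "Alu",
                                      window=50_000, seed=5)
        # sampling error at n=60 windows: generous 99% check
        assert abs(np.mean(dens) - frac) < 3.0


class TestCallableDensity:
    def test_arithmetic(self):
        callable_r = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 20_000_000}])
        events = pd.DataFrame([{"chrom": "chr1", "start": i * 1_000_000,
                                "end": i * 1_000_000 + 500} for i in range(10)])
        res = callable_density(events, callable_r)
        assert res["genome"]["density"] == pytest.approx(5.0)

    def test_zero_events(self):
        callable_r = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1_000_000}])
        res = callable_density(pd.DataFrame(columns=["chrom", "start", "end"]), callable_r)
        assert res["genome"]["density"] == 0.0

    def test_events_outside_callable_excluded(self):
        callable_r = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1_000_000}])
        events = pd.DataFrame([{"chrom": "chr1", "start": 2_000_000, "end": 2_000_500}])
        assert callable_density(events, callable_r)["genome"]["events"] == 0


class TestDepthCopyNumber:
    def test_diploid_baseline(self):
        prof = DepthProfile(100, np.full(1000, 30.0))
        res = depth_copy_number(prof, (10_000, 20_000))
        assert res["ratio"] == pytest.approx(1.0) and res["copy_number"] == 2

    def test_triplication(self):
        depth = np.full(1000, 30.0)
        depth[100:200] = 90.0
        prof = DepthProfile(100, depth, genome_mean=30.0)
        res = depth_copy_number(prof, (10_000, 20_000))
        assert res["ratio"] == pytest.approx(3.0) and res["copy_number"] == 6

    def test_low_unique_flag(self):
        prof = DepthProfile(100, np.full(1000, 30.0))
        ann = _annotation([("chr1", 10_000, 19_500, "Alu")])  # 95% repeat content
        res = depth_copy_number(prof, (10_000, 20_000), ann, "chr1")
        assert res["low_unique"]

    def test_recovers_planted_cn_with_noise(self):
        rng = np.random.default_rng(2)
        for cn in (2, 3, 4, 5, 6):
            depth = 30.0 * np.ones(2000) + rng.normal(0, 0.1 * 30, 2000)
            depth[500:700] *= cn / 2.0
            prof = DepthProfile(100, depth, genome_mean=float(np.mean(depth[:500])))
            res = depth_copy_number(prof, (50_000, 70_000))
            assert res["copy_number"] == cn

    def test_zero_genome_mean_rejected(self):
        prof = DepthProfile(100, np.zeros(10))
        with pytest.raises(ValueError):
            depth_copy_number(prof, (0, 500))


class TestMatchAncestral:
    def test_size_match_rule(self):
        dels = pd.DataFrame([{"chrom": "chr1", "start": 1000, "size": 1000}])
        ins_ok = pd.DataFrame([{"chrom": "chr1", "start": 1100, "size": 920}])
        ins_bad = pd.DataFrame([{"chrom": "chr1", "start": 1100, "size": 850}])
        assert len(match_ancestral(dels, ins_ok, window=300)) == 1
        assert len(match_ancestral(dels, ins_bad, window=300)) == 0

    def test_identical_records_match(self):
        dels = pd.DataFrame([{"chrom": "chr1", "start": 1000, "size": 700}])
        assert len(match_ancestral(dels, dels.copy(), window=300)) == 1

    def test_window_boundary(self):
        dels = pd.DataFrame([{"chrom": "chr1", "start": 1000, "size": 1000}])
        far = pd.DataFrame([{"chrom": "chr1", "start": 1000 + 301, "size": 1000}])
        assert len(match_ancestral(dels, far, window=300)) == 0


class TestAnnotateGenic:
    @pytest.fixture
    def gene_model(self):
        return pd.DataFrame([
            {"chrom": "chr1", "start": 10_000, "end": 30_000, "name": "g1", "feature": "gene"},
            {"chrom": "chr1", "start": 10_000, "end": 10_500, "name": "g1", "feature": "exon"},
            {"chrom": "chr1", "start": 29_000, "end": 30_000, "name": "g1", "feature": "exon"},
        ])

    @pytest.mark.parametrize("start,end,category", [
        (12_000, 13_000, "intronic"),
        (10_400, 12_000, "exonic"),      # overlaps one exon base or more
        (34_000, 34_500, "proximal"),    # 4 kbp downstream
        (50_000, 51_000, "intergenic"),
    ])
    def test_categories(self, gene_model, start, end, category):
        events = pd.DataFrame([{"chrom": "chr1", "start": start, "end": end}])
        out = annotate_genic(events, gene_model)
        assert out.genic_category.iloc[0] == category

    def test_partition(self, gene_model, rng):
        events = pd.DataFrame([{"chrom": "chr1",
                                "start": int(s), "end": int(s) + 500}
                               for s in rng.integers(0, 80_000, 50)])
        out = annotate_genic(events, gene_model)
        counts = out.genic_category.value_counts()
        assert counts.sum() == 50
        assert set(counts.index) <= {"exonic", "intronic", "proximal", "intergenic"}

    def test_enrichment_table(self):
        res = genic_enrichment(["exonic"] * 6 + ["intergenic"] * 4,
                               ["intronic"] * 3 + ["intergenic"] * 7)
        assert res["table"] == (6, 4, 3, 7)
        assert 0 < res["p"] <= 1
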