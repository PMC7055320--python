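"""Downstream statistics: exact tails against enumeration oracles, density
and correlation scans, and the permutation machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from paleomethyl.stats import (
    GenomeBins,
    beta_value,
    bh_adjust,
    chi_square_counts,
    correlation_scan_table,
    derived_cpg_density,
    matched_interval_permutation,
    methylation_expression_scan,
    nearest_feature_distance_test,
    phenotype_direction_binomial,
    term_enrichment,
)


class TestBetaValue:
    def test_examples(self):
        assert beta_value(3, 1) == 0.75
        assert beta_value(5, 0) == 1.0
        assert beta_value(2, 2) == 0.5

    def test_zero_signal_undefined(self):
        assert math.isnan(beta_value(0, 0))

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            beta_value(-1, 2)


class TestDensity:
    POS = {"chr1": np.arange(0, 200_000, 100)}

    def test_fully_covered_window(self):
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 200_000}])
        out = derived_cpg_density(dmrs, self.POS, mode="dmr_centered")
        assert out["fraction"].iloc[0] == 1.0

    def test_no_dmrs_gives_zero_everywhere(self):
        out = derived_cpg_density(pd.DataFrame(columns=["chrom", "start", "end"]),
                                  self.POS, mode="tiled")
        assert (out["fraction"].dropna() == 0).all()

    def test_matches_membership_oracle(self):
        dmrs = pd.DataFrame([
            {"chrom": "chr1", "start": 10_000, "end": 15_000},
            {"chrom": "chr1", "start": 120_000, "end": 121_000},
        ])
        out = derived_cpg_density(dmrs, self.POS, mode="tiled", window_size=50_000)
        pos = self.POS["chr1"]
        member = np.zeros(pos.size, bool)
        for _, r in dmrs.iterrows():
            member |= (pos >= r["start"]) & (pos < r["end"])
        for _, w in out.iterrows():
            sel = (pos >= w["start"]) & (pos < w["end"])
            if sel.sum():
                assert w["fraction"] == pytest.approx(member[sel].mean())

    def test_empty_window_reported_missing(self):
        pos = {"chr1": np.array([10, 20, 30])}
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100}])
        out = derived_cpg_density(dmrs, pos, mode="tiled", window_size=50,
                                  chrom_lengths={"chr1": 100})
        assert math.isnan(out["fraction"].iloc[1])


class TestCorrelationScan:
    def test_perfect_linear_relation(self):
        tissues = [f"t{i}" for i in range(8)]
        meth = pd.DataFrame(
            np.tile(np.linspace(0.1, 0.8, 8), (30, 1)), columns=tissues
        )
        expr = 5.0 - 3.0 * meth.iloc[0].to_numpy()
        s, r, p = methylation_expression_scan(meth, expr, window=25)
        assert r == pytest.approx(-1.0)
        assert p < 1e-10

    def test_constant_methylation_skipped(self):
        tissues = [f"t{i}" for i in range(6)]
        meth = pd.DataFrame(np.full((30, 6), 0.5), columns=tissues)
        assert methylation_expression_scan(meth, np.arange(6.0)) is None

    def test_too_few_tissues_skipped(self):
        meth = pd.DataFrame(np.random.default_rng(0).uniform(size=(30, 2)))
        assert methylation_expression_scan(meth, np.array([1.0, 2.0])) is None

    def test_planted_window_recovered(self):
        # one 25-CpG sub-window of a 40-CpG DMR carries the correlated signal
        rng = np.random.default_rng(1)
        tissues = [f"t{i}" for i in range(12)]
        rs = []
        for _ in range(20):
            expr = rng.uniform(0, 1, 12)
            meth = rng.uniform(0.3, 0.7, (40, 12))
            signal = 0.5 + 0.45 * (expr - 0.5)
            meth[10:35] = signal + rng.normal(0, 0.05, (25, 12))
            s, r, p = methylation_expression_scan(
                pd.DataFrame(meth, columns=tissues), expr, window=25
            )
            # chosen window covers >= 20 of the 25 signal CpGs
            assert min(s + 25, 35) - max(s, 10) >= 20
            rs.append(r)
        # planted correlation is strongly positive on average
        assert np.mean(rs) > 0.8

    def test_table_applies_bh_across_dmr_gene_pairs(self):
        rng = np.random.default_rng(2)
        tissues = [f"t{i}" for i in range(8)]
        expr = pd.DataFrame(rng.uniform(0, 1, (3, 8)),
                            index=["g1", "g2", "g3"], columns=tissues)
        dmr_meth = {
            "dmr1": pd.DataFrame(rng.uniform(0, 1, (30, 8)), columns=tissues),
            "dmr2": pd.DataFrame(rng.uniform(0, 1, (30, 8)), columns=tissues),
        }
        cands = {"dmr1": ["g1", "g2"], "dmr2": ["g3", "missing_gene"]}
        out = correlation_scan_table(dmr_meth, cands, expr)
        assert set(out["gene"]) <= {"g1", "g2", "g3"}
        assert (out["q"] >= out["p"] - 1e-12).all()


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by exact summation of hypergeometric pmf terms."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    return total


class TestTermEnrichment:
    def test_exact_tail_matches_enumeration(self):
        # printed instance: 100 query genes, 31 term hits, background 1789
        # genes of which 254 carry the term
        N, K, n, k = 1789, 254, 100, 31
        genes = [f"g{i}" for i in range(N)]
        table = pd.DataFrame({"gene": genes[:K], "term": "voice"})
        query = genes[:k] + genes[K : K + (n - k)]
        out = term_enrichment(query, genes, table)
        row = out[out["term"] == "voice"].iloc[0]
        assert row["query_hits"] == k
        assert row["p"] == pytest.approx(hypergeom_tail_oracle(k, N, K, n), abs=1e-12)
        assert row["fold"] == pytest.approx((k / n) / (K / N))

    def test_extreme_enrichment(self):
        genes = [f"g{i}" for i in range(50)]
        table = pd.DataFrame({"gene": genes[:5], "term": "t"})
        out = term_enrichment(genes[:5], genes, table)
        assert out.iloc[0]["fold"] == pytest.approx(10.0)
        assert out.iloc[0]["p"] == pytest.approx(hypergeom_tail_oracle(5, 50, 5, 5),
                                                 abs=1e-12)

    def test_random_queries_are_calibrated(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(400)]
        table = pd.DataFrame({"gene": genes[:120], "term": "t"})
        folds, small_p = [], 0
        reps = 300
        for _ in range(reps):
            query = list(rng.choice(genes, size=60, replace=False))
            out = term_enrichment(query, genes, table)
            folds.append(out.iloc[0]["fold"])
            small_p += out.iloc[0]["p"] < 0.05
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)
        assert small_p / reps < 0.1  # one-sided exact test is conservative

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment([], ["g1"], pd.DataFrame({"gene": ["g1"], "term": ["t"]}))

    def test_chi_square_wrapper(self):
        chi2, p = chi_square_counts([[30, 70], [10, 90]])
        assert p < 0.01


class TestMatchedPermutation:
    @staticmethod
    def _genome(length=100_000):
        pos = {"chr1": np.arange(0, length, 50)}
        return pos, GenomeBins.from_cpg_positions(pos, bin_size=1000,
                                                  chrom_lengths={"chr1": length})

    def test_reproducible_under_seed(self):
        pos, genome = self._genome()
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 10_000, "end": 11_000},
                             {"chrom": "chr1", "start": 50_000, "end": 52_000}])
        targets = pd.DataFrame([{"chrom": "chr1", "start": 40_000, "end": 60_000}])
        a = matched_interval_permutation(dmrs, targets, genome, n_perm=100, seed=5)
        b = matched_interval_permutation(dmrs, targets, genome, n_perm=100, seed=5)
        assert a == b
        assert a["p"] >= 1 / 101

    def test_null_overlap_matches_exact_placement_oracle(self):
        # uniform composition -> placements are uniform; the null overlap
        # rate equals the exact per-start-position overlap probability
        length = 100_000
        pos, genome = self._genome(length)
        L = 1_000
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": L}] * 20)
        targets = pd.DataFrame(
            [{"chrom": "chr1", "start": s, "end": s + 2_000}
             for s in range(0, length, 20_000)]
        )
        res = matched_interval_permutation(dmrs, targets, genome,
                                           n_perm=300, seed=6)
        covered = np.zeros(length, bool)
        for _, t in targets.iterrows():
            covered[max(t["start"] - L + 1, 0):t["end"]] = True
        p_overlap = covered[: length - L].mean()
        assert res["null_mean"] / len(dmrs) == pytest.approx(p_overlap, abs=0.05)

    def test_whole_genome_target_is_degenerate(self):
        pos, genome = self._genome()
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 500, "end": 700}])
        targets = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100_000}])
        res = matched_interval_permutation(dmrs, targets, genome, n_perm=50, seed=7)
        assert res["observed"] == 1
        assert res["p"] == 1.0  # every placement overlaps too


class TestNearestFeature:
    def test_features_at_midpoints_give_zero_distance(self):
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 1000, "end": 2000},
                             {"chrom": "chr1", "start": 5000, "end": 7000}])
        features = {"chr1": np.array([1500, 6000])}
        res = nearest_feature_distance_test(dmrs, features, {"chr1": 100_000},
                                            n_perm=200, seed=8)
        assert res["observed_median"] == 0
        assert res["p"] == pytest.approx(1 / 201)

    def test_single_pair_exact_distance(self):
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 2000}])
        features = {"chr1": np.array([1700])}
        res = nearest_feature_distance_test(dmrs, features, {"chr1": 10_000},
                                            n_perm=10, seed=9)
        assert res["observed_median"] == 700

    def test_uniform_features_give_fold_near_one(self):
        rng = np.random.default_rng(10)
        dmrs = pd.DataFrame(
            [{"chrom": "chr1", "start": int(s), "end": int(s) + 500}
             for s in rng.integers(0, 900_000, 40)]
        )
        features = {"chr1": rng.integers(0, 1_000_000, 200)}
        res = nearest_feature_distance_test(dmrs, features, {"chr1": 1_000_000},
                                            n_perm=300, seed=11)
        assert 0.5 < res["fold_closer"] < 2.0


def binomial_tail_oracle(k, n, p=0.5):
    return sum(math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(k, n + 1))


class TestDirectionBinomial:
    def test_all_matches_closed_form(self):
        assert phenotype_direction_binomial(9, 9) == pytest.approx(2**-9)

    def test_exact_tail_matches_enumeration(self):
        assert phenotype_direction_binomial(26, 31) == pytest.approx(
            binomial_tail_oracle(26, 31), abs=1e-12
        )
        assert phenotype_direction_binomial(18, 22) == pytest.approx(
            binomial_tail_oracle(18, 22), abs=1e-12
        )

    def test_half_matches_exceed_half(self):
        assert phenotype_direction_binomial(5, 10) > 0.5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            phenotype_direction_binomial(1, 0)
        with pytest.raises(ValueError):
            phenotype_direction_binomial(5, 4)


class TestBH:
    def test_q_values_monotone_in_p_rank(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()
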