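"""Interval engine and enrichment statistics."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strexpand import (
    annotate_region_category,
    closest_distance,
    density_profile,
    fisher_enrichment,
    overlaps,
    permutation_resample_test,
    random_effects_pool,
    two_proportion_test,
)

from oracles import brute_force_closest, brute_force_overlaps, fisher_two_sided


def _random_track(rng, n, chroms=("chr1", "chr2"), span=50_000):
    starts = rng.integers(0, span, n)
    lengths = rng.integers(1, 500, n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, n),
            "start": starts,
            "end": starts + lengths,
            "name": [f"iv{i}" for i in range(n)],
        }
    )


class TestOverlaps:
    def test_half_open_adjacency(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]})
        assert not overlaps(a, b)[0]

    def test_slop_bridges_gap(self):
        # enhancer-style 10-kb slop turns a 5-kb gap into an overlap
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [15], "end": [20]})
        assert not overlaps(a, b)[0]
        assert overlaps(a, b, slop=10_000)[0]

    def test_min_overlap(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [7], "end": [30]})
        assert overlaps(a, b, min_overlap=3)[0]
        assert not overlaps(a, b, min_overlap=4)[0]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_track(rng, 120)
        b = _random_track(rng, 120)
        slop = int(rng.integers(0, 300))
        got = overlaps(a, b, slop=slop)
        want = brute_force_overlaps(a, b, slop=slop)
        assert np.array_equal(got, want)

    def test_negative_slop_rejected(self):
        t = _random_track(np.random.default_rng(0), 3)
        with pytest.raises(ValueError):
            overlaps(t, t, slop=-1)


class TestClosestDistance:
    def test_examples(self):
        a = pd.DataFrame({"chrom": ["chr1", "chr1", "chr1"],
                          "start": [100, 0, 50], "end": [110, 10, 60]})
        b = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [100, 20],
                          "end": [110, 30]})
        d = closest_distance(a, b)
        assert d[0] == 0          # identical interval
        assert d[1] == 10         # [0,10) to [20,30)
        assert d[2] == 20         # [50,60) to [20,30)

    def test_absent_chromosome_is_inf(self):
        a = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [5]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5]})
        assert math.isinf(closest_distance(a, b)[0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(50 + seed)
        a = _random_track(rng, 100)
        b = _random_track(rng, 100)
        assert np.array_equal(closest_distance(a, b), brute_force_closest(a, b))


class TestRegionCategories:
    def _gene(self):
        # toy 3-exon gene on chr1: body [10000, 16000), TSS 10000
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "strand": ["+"],
             "tss": [10_000], "start": [10_000], "end": [16_000]}
        )
        exons = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [10_000, 12_000, 15_000],
             "end": [10_500, 12_400, 16_000]}
        )
        return genes, exons

    def test_upstream_promoter(self):
        genes, exons = self._gene()
        strs = pd.DataFrame({"chrom": ["chr1"], "start": [8_000], "end": [8_050]})
        assert annotate_region_category(strs, genes, exons)[0] == "promoter"

    def test_intron_of_toy_gene(self):
        genes, exons = self._gene()
        strs = pd.DataFrame({"chrom": ["chr1"], "start": [14_000], "end": [14_040]})
        assert annotate_region_category(strs, genes, exons)[0] == "intron"

    def test_far_intergenic(self):
        genes, exons = self._gene()
        strs = pd.DataFrame({"chrom": ["chr1"], "start": [40_000], "end": [40_050]})
        assert annotate_region_category(strs, genes, exons)[0] == "intergenic"

    def test_every_str_gets_one_label(self, rng):
        genes, exons = self._gene()
        strs = _random_track(rng, 200, chroms=("chr1",), span=60_000)
        cats = annotate_region_category(strs, genes, exons)
        assert cats.isin(["promoter", "exon", "intron", "intergenic"]).all()
        assert len(cats) == len(strs)

    def test_bad_gene_rejected(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "tss": [5],
                              "start": [10], "end": [5]})
        strs = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1]})
        with pytest.raises(ValueError):
            annotate_region_category(strs, genes)


class TestFisherEnrichment:
    def test_balanced_table(self):
        res = fisher_enrichment(
            np.array([True] * 10 + [False] * 10), np.array([True] * 10 + [False] * 10)
        )
        assert res.odds_ratio == 1.0 and res.p_two_sided == pytest.approx(1.0)

    def test_spec_table(self):
        res = fisher_enrichment(
            np.array([True] * 8 + [False] * 2), np.array([True] * 2 + [False] * 8)
        )
        assert res.odds_ratio == pytest.approx(16.0)
        assert res.p_two_sided == pytest.approx(0.023, abs=5e-4)

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(0, 30, 4) + 1
            p1 = fisher_enrichment(
                np.r_[np.ones(a, bool), np.zeros(b, bool)],
                np.r_[np.ones(c, bool), np.zeros(d, bool)],
            ).p_two_sided
            p2 = fisher_enrichment(
                np.r_[np.ones(a, bool), np.zeros(c, bool)],
                np.r_[np.ones(b, bool), np.zeros(d, bool)],
            ).p_two_sided
            assert p1 == pytest.approx(p2, rel=1e-9)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 50, 4))
        if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
            a, b, c, d = a + 1, b + 1, c + 1, d + 1
        res = fisher_enrichment(
            np.r_[np.ones(a, bool), np.zeros(b, bool)],
            np.r_[np.ones(c, bool), np.zeros(d, bool)],
        )
        assert res.p_two_sided == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        res = fisher_enrichment(
            np.array([True] * 5), np.array([True] * 2 + [False] * 3)
        )
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx((5.5 * 3.5) / (0.5 * 2.5))

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(np.array([False] * 5), np.array([False] * 5))


class TestDensityProfile:
    def test_all_mass_at_centers(self):
        feats = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [1000, 5000, 9000],
                              "end": [1200, 5200, 9200]})
        strs = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [1080, 5080, 9080],
                             "end": [1120, 5120, 9120]})
        prof = density_profile(strs, feats, half_window=2000, n_bins=10)
        central = prof[(prof["bin_start"] >= -400) & (prof["bin_end"] <= 400)]
        assert prof["count"].sum() == 3
        assert central["count"].sum() == 3

    def test_empty_window(self):
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        strs = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [50_040]})
        prof = density_profile(strs, feats)
        assert (prof["count"] == 0).all()

    def test_requires_features_and_even_bins(self):
        strs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        with pytest.raises(ValueError):
            density_profile(strs, strs.iloc[:0])
        with pytest.raises(ValueError):
            density_profile(strs, strs, n_bins=7)

    def test_uniform_strs_flat_profile(self, rng):
        feats = pd.DataFrame({"chrom": "chr1",
                              "start": np.arange(10_000, 500_000, 25_000),
                              "end": np.arange(10_000, 500_000, 25_000) + 100})
        starts = rng.integers(0, 500_000, 3000)
        strs = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 20})
        prof = density_profile(strs, feats, half_window=2000, n_bins=8)
        n = prof["count"].sum()
        expected = n / 8
        se = math.sqrt(n * (1 / 8) * (7 / 8))
        assert (np.abs(prof["count"] - expected) <= 3.5 * se).all()


class TestPermutationTest:
    def test_extreme_observation_hits_formula_bound(self, rng):
        ids = [f"x{i}" for i in range(60)]
        stat = lambda sub: 0.0
        p = permutation_resample_test(1.0, ids[:10], ids, stat, n_perm=500, seed=1)
        assert p == pytest.approx(1 / 501)

    def test_null_median_observation_gives_half(self, rng):
        scores = {f"x{i}": v for i, v in enumerate(rng.normal(size=200))}
        ids = list(scores)
        stat = lambda sub: float(np.mean([scores[s] for s in sub]))
        null = [
            stat(list(np.random.default_rng(s).choice(ids, 20, replace=False)))
            for s in range(400)
        ]
        obs = float(np.median(null))
        p = permutation_resample_test(obs, ids[:20], ids, stat, n_perm=1000, seed=2)
        assert abs(p - 0.5) < 0.1

    def test_seeded_determinism(self):
        ids = [f"x{i}" for i in range(30)]
        stat = lambda sub: len([s for s in sub if s.endswith("1")])
        p1 = permutation_resample_test(2.0, ids[:5], ids, stat, n_perm=200, seed=9)
        p2 = permutation_resample_test(2.0, ids[:5], ids, stat, n_perm=200, seed=9)
        assert p1 == p2

    def test_validation(self):
        with pytest.raises(ValueError):
            permutation_resample_test(0.0, ["a"], ["a"], lambda s: 0, n_perm=10)
        with pytest.raises(ValueError):
            permutation_resample_test(0.0, ["a", "b"], ["a"], lambda s: 0, n_perm=200)


class TestTwoProportion:
    def test_equal_proportions(self):
        assert two_proportion_test(5, 50, 10, 100) == pytest.approx(1.0)

    def test_hand_computed_z(self):
        # k1=90/100 vs k2=10/100: pooled=0.5, z^2 = 0.64/(0.25*0.02) = 128
        p = two_proportion_test(90, 100, 10, 100)
        assert p == pytest.approx(float(stats.chi2.sf(128.0, 1)))

    def test_group_swap_symmetry(self):
        assert two_proportion_test(30, 40, 10, 60) == pytest.approx(
            two_proportion_test(10, 60, 30, 40)
        )

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            two_proportion_test(0, 0, 1, 10)


class TestRandomEffectsPool:
    def test_identical_studies_have_no_heterogeneity(self):
        out = random_effects_pool([0.5, 0.5], [0.2, 0.2])
        assert out["pooled_or"] == pytest.approx(math.exp(0.5))
        assert out["tau2"] == 0.0

    def test_hand_computed_example(self):
        out = random_effects_pool([0.5, 0.1], [0.2, 0.2])
        assert out["pooled_log_or"] == pytest.approx(0.3)
        assert out["tau2"] == pytest.approx(0.04)
        assert out["pooled_se"] == pytest.approx(0.2)

    def test_single_study_passthrough(self):
        out = random_effects_pool([0.7], [0.3])
        assert out["pooled_log_or"] == pytest.approx(0.7)
        assert out["tau2"] == 0.0

    def test_pooled_within_study_range(self, rng):
        for _ in range(20):
            y = rng.normal(0, 1, 5)
            se = rng.uniform(0.1, 0.5, 5)
            out = random_effects_pool(y, se)
            assert y.min() - 1e-9 <= out["pooled_log_or"] <= y.max() + 1e-9

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_matches_metafor_dersimonian_laird(self):
        y = [0.42, -0.1, 0.75, 0.3]
        se = [0.21, 0.35, 0.28, 0.15]
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({','.join(map(str, y))}), sei=c({','.join(map(str, se))}),"
            " method='DL');"
            "cat(sprintf('%.10f %.10f %.10f', r$beta, r$se, r$tau2))"
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        beta, se_r, tau2 = map(float, res.stdout.split())
        out = random_effects_pool(y, se)
        assert out["pooled_log_or"] == pytest.approx(beta, abs=1e-8)
        assert out["pooled_se"] == pytest.approx(se_r, abs=1e-8)
        assert out["tau2"] == pytest.approx(tau2, abs=1e-8)
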