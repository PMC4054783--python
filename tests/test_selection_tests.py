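import math

import numpy as np
import pandas as pd
import pytest

from esekit.motif_sets import HexamerSet, composition
from esekit.selection_tests import (
    divergence_by_distance,
    divergence_counts_per_exon,
    net_selection_estimate,
    paired_distance_test,
    percent_difference,
    pseudo_ese_sets,
    snp_counts_per_exon,
    snp_profile,
    summarize_profile,
)
from esekit.synthetic_data import (
    SyntheticSpec,
    gen_genome,
    gen_ortholog_pairs,
    gen_snps,
)


@pytest.fixture(scope="module")
def genome_with_pairs():
    spec = SyntheticSpec(seed=88, n_exons=600)
    exons, truth = gen_genome(spec)
    pool = HexamerSet.from_iterable("pool", truth["params"]["pool"])
    return spec, exons, pool


class TestDivergence:
    def test_identical_sequences_have_zero_divergence(self, genome_with_pairs):
        spec, exons, pool = genome_with_pairs
        pairs = gen_ortholog_pairs(exons[:100], pool, d=0.0, r=1.0, seed=1)
        prof = divergence_by_distance(pairs, pool)
        assert prof["subs_ese"].sum() == 0
        assert prof["subs_non"].sum() == 0

    def test_neutral_multiplier_gives_equal_rates(self, genome_with_pairs):
        spec, exons, pool = genome_with_pairs
        pairs = gen_ortholog_pairs(exons, pool, d=0.35, r=1.0, seed=2)
        counts = divergence_counts_per_exon(pairs, pool).sum(axis=(0, 1))
        p_ese = counts[1] / counts[0]
        p_non = counts[3] / counts[2]
        se = math.sqrt(0.35 * 0.65 * (1 / counts[0] + 1 / counts[2]))
        assert abs(p_ese - p_non) < 3 * se

    def test_rate_deficit_recovered(self, genome_with_pairs):
        spec, exons, pool = genome_with_pairs
        pairs = gen_ortholog_pairs(exons, pool, d=0.35, r=0.85, seed=3)
        prof = divergence_by_distance(pairs, pool)
        summary = summarize_profile(prof, min_sites=50)
        assert summary["median_ese"] < summary["median_non"]
        assert -25 < summary["pct_difference"] < -5
        assert summary["p_paired"] < 0.01

    def test_profiles_independent_of_exon_order(self, genome_with_pairs):
        spec, exons, pool = genome_with_pairs
        pairs = gen_ortholog_pairs(exons[:80], pool, d=0.3, r=0.8, seed=4)
        a = divergence_by_distance(pairs, pool)
        b = divergence_by_distance(list(reversed(pairs)), pool)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_profile_warns(self):
        with pytest.warns(UserWarning, match="no analysable"):
            divergence_by_distance([], HexamerSet.from_iterable("s", ["AAAAAA"]))


class TestSNPProfile:
    def test_no_snps_gives_zero_profile(self, genome_with_pairs):
        spec, exons, pool = genome_with_pairs
        snps = gen_snps(exons[:50], pool, s=0.0, q=1.0, seed=5)
        prof = snp_profile(exons[:50], snps, pool)
        assert prof["snp_sites_ese"].sum() == 0

    def test_imposed_deficit_recovered(self, genome_with_pairs):
        spec, exons, pool = genome_with_pairs
        snps = gen_snps(exons, pool, s=0.036, q=0.833, seed=6)
        counts = snp_counts_per_exon(exons, snps, pool).sum(axis=(0, 1))
        p_ese = counts[1] / counts[0]
        p_non = counts[3] / counts[2]
        se_ese = math.sqrt(0.03 * 0.97 / counts[0])
        se_non = math.sqrt(0.036 * 0.964 / counts[2])
        assert p_ese == pytest.approx(0.036 * 0.833, abs=3 * se_ese)
        assert p_non == pytest.approx(0.036, abs=3 * se_non)

    def test_duplicate_snp_records_count_once(self):
        from esekit.sequence_model import ExonRecord, SNPTable

        exon = ExonRecord("g", 1, "GAAGAAGAAGAA")
        snps = SNPTable({"g:1": [2, 2, 2]})
        counts = snp_counts_per_exon(
            [exon], snps, HexamerSet.from_iterable("s", ["GAAGAA"]), max_distance=10
        )
        assert counts[0, :, 1].sum() == 1  # one SNP-bearing ESE site

    def test_site_classification_agrees_with_divergence(self, genome_with_pairs):
        # the SNP and divergence pipelines must see the same ESE geometry
        spec, exons, pool = genome_with_pairs
        subset = exons[:60]
        pairs = gen_ortholog_pairs(subset, pool, d=0.0, r=1.0, seed=7)
        div_counts = divergence_counts_per_exon(pairs, pool).sum(axis=0)
        snps = gen_snps(subset, pool, s=0.0, q=1.0, seed=8)
        snp_counts = snp_counts_per_exon(subset, snps, pool).sum(axis=0)
        # every four-fold ESE site is an exonic ESE site
        assert (div_counts[:, 0] <= snp_counts[:, 0]).all()
        assert (div_counts[:, 2] <= snp_counts[:, 2]).all()


class TestPairedDistanceTest:
    def test_identical_profiles_give_p_one(self):
        s = pd.Series(np.linspace(0.2, 0.4, 40), index=range(1, 41))
        assert paired_distance_test(s, s) == 1.0

    def test_constant_shift_minimises_p(self):
        s = pd.Series(np.linspace(0.2, 0.4, 30), index=range(1, 31))
        p = paired_distance_test(s, s + 0.02)
        assert p < 1e-4

    def test_deficit_detected_in_simulation(self, rng):
        detections = 0
        runs = 30
        for i in range(runs):
            r = np.random.default_rng(1000 + i)
            a = pd.Series(0.30 + r.normal(0, 0.015, 50), index=range(1, 51))
            b = pd.Series(0.35 + r.normal(0, 0.015, 50), index=range(1, 51))
            if paired_distance_test(a, b) < 0.01:
                detections += 1
        assert detections >= int(0.95 * runs)

    def test_few_shared_distances_warns(self):
        a = pd.Series([0.1, 0.2, 0.3, 0.35], index=[1, 2, 3, 4])
        b = pd.Series([0.2, 0.3, 0.4, 0.25], index=[1, 2, 3, 4])
        with pytest.warns(UserWarning, match="shared distances"):
            paired_distance_test(a, b)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ese,non,expected",
        [(0.30, 0.36, -16.7), (0.38, 0.34, 11.8), (0.25, 0.25, 0.0)],
    )
    def test_values(self, ese, non, expected):
        assert percent_difference(ese, non) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.1, 0.0)


class TestPseudoSets:
    def test_degenerate_composition(self):
        sets = pseudo_ese_sets({"A": 1.0, "C": 0, "G": 0, "T": 0}, size=1,
                               replicates=3, seed=1)
        assert all(s.motifs == frozenset({"AAAAAA"}) for s in sets)

    def test_uniform_composition_recovered(self):
        sets = pseudo_ese_sets(
            {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
            size=100, replicates=50, seed=2,
        )
        base_counts = {b: 0 for b in "ACGT"}
        total = 0
        for s in sets:
            for m in s:
                for b in m:
                    base_counts[b] += 1
                total += 6
        se = math.sqrt(0.25 * 0.75 / total)
        for b in "ACGT":
            assert base_counts[b] / total == pytest.approx(0.25, abs=3 * se)

    def test_matches_target_set_composition(self):
        target = HexamerSet.from_iterable(
            "t", ["GAAGAA", "AAGAAG", "GGAAGG", "GATGCA", "CAAGTA"]
        )
        comp = composition(target)
        sets = pseudo_ese_sets(
            {b: comp[b] for b in "ACGT"}, size=50, replicates=40, seed=3
        )
        pooled_a = np.mean([composition(s)["A"] for s in sets])
        assert pooled_a == pytest.approx(comp["A"], abs=0.02)

    def test_unattainable_size_rejected(self):
        with pytest.raises(ValueError):
            pseudo_ese_sets({"A": 1.0, "C": 0, "G": 0, "T": 0}, size=2,
                            replicates=1, seed=1)

    def test_sets_are_distinct_hexamers(self):
        sets = pseudo_ese_sets(
            {"A": 0.7, "C": 0.1, "G": 0.1, "T": 0.1}, size=30, replicates=5, seed=4
        )
        assert all(len(s) == 30 for s in sets)

    def test_pseudo_contrast_attenuated_by_contamination(self, genome_with_pairs):
        # pseudo sets matched to the pool's composition contain true pool
        # motifs, so the ESE-vs-pseudo rate contrast is weaker than the
        # ESE-vs-non contrast
        spec, exons, pool = genome_with_pairs
        pairs = gen_ortholog_pairs(exons, pool, d=0.35, r=0.7, seed=9)
        real = divergence_by_distance(pairs, pool)
        comp = composition(pool)
        pseudo = pseudo_ese_sets(
            {b: comp[b] for b in "ACGT"}, size=len(pool), replicates=5, seed=10
        )
        pseudo_props = []
        for ps in pseudo:
            prof = divergence_by_distance(pairs, ps)
            pseudo_props.append(prof["prop_ese"])
        pseudo_median = pd.concat(pseudo_props, axis=1).median(axis=1)
        ok = (real["sites_ese"] >= 50) & (real["sites_non"] >= 50)
        real_gap = (real.loc[ok, "prop_non"] - real.loc[ok, "prop_ese"]).median()
        pseudo_gap = (
            pseudo_median[ok] - real.loc[ok, "prop_ese"]
        ).median()
        assert pseudo_gap < real_gap


class TestNetSelection:
    def test_published_style_rounding_chain(self):
        out = net_selection_estimate(0.15, 0.30, 0.80)
        assert out["local_reduction_pct"] == 5
        assert out["net_reduction_pct"] == 4

    def test_zero_deficit_gives_zero(self):
        out = net_selection_estimate(0.0, 0.5, 0.9)
        assert out["net_reduction_pct"] == 0

    @pytest.mark.parametrize("d", [0.04, 0.15, 0.5])
    def test_identity_limits(self, d):
        out = net_selection_estimate(d, 1.0, 1.0)
        assert out["net_reduction_pct"] == int(math.floor(100 * d + 0.5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            net_selection_estimate(1.5, 0.3, 0.8)
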