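import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from esekit.codon_metrics import (
    CodonUsage,
    SENSE_CODONS,
    codon_slopes,
    extract_frame_codons,
    fisher_combine,
    hpi,
    observed_codon_proportions,
    pair_concordance,
    sample_pair_indices,
    synonymous_pairs,
)
from esekit.motif_sets import HexamerSet
from esekit.sequence_model import STOP_CODONS
from esekit.synthetic_data import SyntheticSpec, gen_genome


class TestExtractFrameCodons:
    @pytest.mark.parametrize(
        "hexamer,expected",
        [
            ("GAAGAA", ["GAA", "AAG", "AGA", "GAA"]),
            ("AAAAAA", ["AAA", "AAA", "AAA", "AAA"]),
            ("TGATGA", ["TGA", "GAT", "ATG", "TGA"]),
        ],
    )
    def test_windowing(self, hexamer, expected):
        assert extract_frame_codons(hexamer) == expected

    def test_stop_triplets_dropped_at_counting(self):
        props = observed_codon_proportions(
            HexamerSet.from_iterable("s", ["TGATGA"])
        )
        nonzero = {SENSE_CODONS[i] for i in np.flatnonzero(props)}
        assert nonzero == {"GAT", "ATG"}
        assert props.sum() == pytest.approx(1.0)

    def test_malformed_input_rejected(self):
        with pytest.raises(ValueError):
            extract_frame_codons("GAAGA")


class TestCodonUsage:
    def test_normalises_and_removes_stops(self):
        usage = CodonUsage.human_genome()
        arr = usage.as_array()
        assert arr.sum() == pytest.approx(1.0)
        assert len(arr) == 61

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "usage.tsv"
        rows = "\n".join(f"{c}\t{f}" for c, f in CodonUsage.human_genome().items())
        p.write_text(rows + "\n")
        again = CodonUsage.from_tsv(p)
        assert np.allclose(again.as_array(), CodonUsage.human_genome().as_array())


def brute_force_hpi(hexamers, usage, reps, seed, sd_ddof=1):
    """Independent HPI implementation: dictionary counting on literal
    hexamer strings, sharing only the uniform-draw convention."""
    freq = dict(usage.items())
    codons = sorted(freq)  # == SENSE_CODONS order
    cum = []
    total = 0.0
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            total += freq[c1] * freq[c2]
            cum.append(total)
    cum[-1] = 1.0

    def spectrum(motifs):
        counts = Counter()
        for m in motifs:
            for f in (m[0:3], m[1:4], m[2:5], m[3:6]):
                if f not in STOP_CODONS:
                    counts[f] += 1
        tot = sum(counts.values())
        return [counts.get(c, 0) / tot for c in codons]

    obs = spectrum(sorted(hexamers.motifs))
    rng = np.random.default_rng(seed)
    u = rng.random((reps, len(hexamers)))
    null = []
    for row in u:
        motifs = []
        for x in row:
            k = 0
            while cum[k] <= x:
                k += 1
            i, j = divmod(k, 61)
            motifs.append(SENSE_CODONS[i] + SENSE_CODONS[j])
        null.append(spectrum(motifs))
    null_arr = np.array(null)
    mean = null_arr.mean(axis=0)
    sd = null_arr.std(axis=0, ddof=sd_ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.array(obs) - mean) / sd
    return pd.DataFrame(
        {"observed": obs, "null_mean": mean, "null_sd": sd, "hpi": z},
        index=pd.Index(codons, name="codon"),
    )


class TestHPI:
    def test_matches_brute_force_dual_implementation(self):
        motifs = ["GAAGAA", "ACGTAC", "TTCAAG", "CCCGGG", "ATGATG"]
        hexamers = HexamerSet.from_iterable("small", motifs)
        usage = CodonUsage.human_genome()
        fast = hpi(hexamers, usage, reps=200, seed=77)
        slow = brute_force_hpi(hexamers, usage, reps=200, seed=77)
        pd.testing.assert_frame_equal(fast, slow, atol=1e-12, rtol=0)

    def test_null_generated_set_is_calibrated(self):
        usage = CodonUsage.human_genome()
        rng = np.random.default_rng(5)
        idx = sample_pair_indices(rng, usage, 1, 300)[0]
        motifs = {
            SENSE_CODONS[i] + SENSE_CODONS[j]
            for i, j in (divmod(int(k), 61) for k in idx)
        }
        tab = hpi(HexamerSet.from_iterable("null", motifs), usage,
                  reps=2000, seed=6)
        z = tab["hpi"].dropna()
        frac = float((z.abs() > 1.96).mean())
        # Binomial(61, 0.05): accept up to ~9 exceedances
        assert frac <= 9 / 61

    def test_observed_and_null_proportions_sum_to_one(self):
        hexamers = HexamerSet.from_iterable("s", ["GAAGAA", "CCATGG"])
        tab = hpi(hexamers, reps=100, seed=3)
        assert tab["observed"].sum() == pytest.approx(1.0)
        assert tab["null_mean"].sum() == pytest.approx(1.0)

    def test_degenerate_sd_warns(self):
        usage_freq = {c: 0.0 for c in SENSE_CODONS}
        usage_freq["AAA"] = 1.0
        usage = CodonUsage(usage_freq)
        with pytest.warns(UserWarning, match="HPI undefined"):
            tab = hpi(HexamerSet.from_iterable("s", ["AAAAAA"]), usage,
                      reps=50, seed=1)
        assert tab.loc["AAA", "hpi"] != tab.loc["AAA", "hpi"] or np.isnan(
            tab.loc["AAA", "hpi"]
        )


class TestSynonymousPairs:
    def test_exactly_87_pairs(self):
        assert len(synonymous_pairs()) == 87

    def test_contains_glu_pair_and_no_stops(self):
        pairs = synonymous_pairs()
        assert ("GAA", "GAG") in pairs
        flat = {c for p in pairs for c in p}
        assert not flat & STOP_CODONS

    def test_no_cross_amino_acid_pairs(self):
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        fwd = unambiguous_dna_by_id[1].forward_table
        assert all(fwd[a] == fwd[b] for a, b in synonymous_pairs())


class TestCodonSlopes:
    def test_distance_independent_usage_has_null_slopes(self):
        spec = SyntheticSpec(seed=31, n_exons=800, embed_plateau=0.0,
                             embed_floor=0.0, pool_size=5)
        exons, _ = gen_genome(spec)
        table = codon_slopes(exons)
        sub = table.dropna()
        frac_large = float((sub["slope"].abs() > 3 * sub["stderr"]).mean())
        assert frac_large < 0.12

    def test_imposed_gradient_recovered(self):
        beta = -0.004
        spec = SyntheticSpec(
            seed=32, n_exons=1500, embed_plateau=0.0, embed_floor=0.0,
            pool_size=5, synonym_gradient={("GAA", "GAG"): beta},
        )
        exons, _ = gen_genome(spec)
        table = codon_slopes(exons)
        assert table.loc["GAA", "slope"] == pytest.approx(
            beta, abs=3 * table.loc["GAA", "stderr"]
        )

    def test_single_codon_family_slope_is_zero(self):
        spec = SyntheticSpec(seed=33, n_exons=300, embed_plateau=0.0,
                             embed_floor=0.0, pool_size=5)
        exons, _ = gen_genome(spec)
        table = codon_slopes(exons)
        assert table.loc["ATG", "slope"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["TGG", "slope"] == pytest.approx(0.0, abs=1e-12)


class TestPairConcordance:
    def test_published_binomial_and_fisher_values(self):
        # 66 negatives of 87 under a fair coin
        from scipy.stats import binomtest

        p = binomtest(66, 87, 0.5, alternative="greater").pvalue
        assert p == pytest.approx(7.10e-07, rel=0.01)
        chi2, _ = fisher_combine([0.016, 0.056])
        assert chi2 == pytest.approx(14.04, abs=0.01)
        chi2b, _ = fisher_combine([7.1e-7, 0.0031])
        assert chi2b == pytest.approx(39.9, abs=0.05)

    def test_fisher_statistic_identity(self, rng):
        ps = rng.uniform(1e-6, 1, 5)
        chi2, _ = fisher_combine(ps)
        assert chi2 == pytest.approx(-2 * np.log(ps).sum(), abs=1e-9)

    def test_all_negative_pairs_closed_form(self):
        pairs = synonymous_pairs()
        hpi_tab = pd.DataFrame(
            {"hpi": np.linspace(1, 2, 61)}, index=pd.Index(SENSE_CODONS, name="codon")
        )
        # slope anti-ordered with HPI: every oriented slope difference < 0
        slope_tab = pd.DataFrame(
            {"slope": -np.linspace(1, 2, 61)},
            index=pd.Index(SENSE_CODONS, name="codon"),
        )
        res = pair_concordance(hpi_tab, slope_tab)
        assert res["negatives"] == 87 and res["positives"] == 0
        assert res["p_binomial"] == pytest.approx(0.5 ** 87, rel=1e-9)

    def test_orientation_invariance(self, rng):
        vals = rng.normal(size=61)
        slopes = rng.normal(size=61)
        idx = pd.Index(SENSE_CODONS, name="codon")
        a = pair_concordance(
            pd.DataFrame({"hpi": vals}, index=idx),
            pd.DataFrame({"slope": slopes}, index=idx),
        )
        b = pair_concordance(
            pd.DataFrame({"hpi": vals}, index=idx[::-1][::-1]),
            pd.DataFrame({"slope": slopes}, index=idx),
        )
        assert a == b
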