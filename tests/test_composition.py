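"""Compositional signatures: dinucleotide odds, codon usage, UGA stats,
correlation clustering."""

import numpy as np
import pytest

from mitovir import composition
from mitovir.composition import (
    CODONS,
    DINUCLEOTIDES,
    CorrelationClustering,
    classify_dinucleotide_bias,
    cluster_by_correlation,
    codon_usage,
    dinucleotide_odds,
    profile_correlation,
    trp_codon_stats,
)
from mitovir.errors import EmptyInputError
from mitovir.seqcore import CdsRecord, CdsSet, GeneticCode
from mitovir.synthetic_data import gen_cds_set, gen_codon_table_family, gen_viral_genome


def brute_force_odds(s: str) -> dict:
    """Independent sliding-window oracle for dinucleotide odds ratios."""
    mono = {b: s.count(b) / len(s) for b in "ACGT"}
    wins = [s[i : i + 2] for i in range(len(s) - 1)]
    out = {}
    for d in DINUCLEOTIDES:
        f = wins.count(d) / len(wins)
        out[d] = f / (mono[d[0]] * mono[d[1]]) if mono[d[0]] * mono[d[1]] else float("nan")
    return out


class TestDinucleotideOdds:
    def test_homopolymer_has_unit_aa_odds(self):
        prof = dinucleotide_odds("A" * 1000, source_id="polyA")
        assert prof.odds["AA"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = "".join(rng.choice(list("ACGT"), size=200, p=[0.4, 0.1, 0.2, 0.3]))
        got = dinucleotide_odds(s).odds
        expect = brute_force_odds(s)
        for d in DINUCLEOTIDES:
            assert got[d] == pytest.approx(expect[d], nan_ok=True)

    def test_iid_sequence_converges_to_unit_ratios(self):
        rng = np.random.default_rng(7)
        s = "".join(rng.choice(list("ACGT"), size=100_000))
        prof = dinucleotide_odds(s)
        assert all(0.95 <= r <= 1.05 for r in prof.odds.values())

    def test_short_input_warns_and_empty_raises(self):
        with pytest.warns(UserWarning, match="noisy"):
            dinucleotide_odds("ACGTACGT")
        with pytest.raises(EmptyInputError):
            dinucleotide_odds("NNNN")


class TestBiasClassification:
    def test_boundaries_are_unbiased(self):
        prof = dinucleotide_odds("ACGT" * 100)
        fake = {d: 1.0 for d in DINUCLEOTIDES}
        fake["AA"], fake["CC"], fake["GG"] = 0.78, 1.25, 1.251
        prof = composition.DinucleotideProfile("x", fake)
        calls = classify_dinucleotide_bias(prof)
        assert calls["AA"] == "unbiased"  # exactly on the low cutoff
        assert calls["CC"] == "unbiased"  # exactly on the high cutoff
        assert calls["GG"] == "biased"

    def test_cc_gg_enriched_genome_is_flagged(self):
        rng = np.random.default_rng(3)
        # runs of C and G inflate CC/GG beyond mononucleotide expectation
        s = "".join(rng.choice(["CCCC", "GGGG", "AT", "TA", "AC", "GT"], size=3000))
        calls = classify_dinucleotide_bias(dinucleotide_odds(s))
        assert calls["CC"] == "biased" and calls["GG"] == "biased"


class TestCodonUsage:
    def test_single_cds_counts_and_per_1000(self, code1):
        table = codon_usage(CdsSet([CdsRecord("x", "ATGATGTAA", 1)]), code1)
        assert table.counts["ATG"] == 2 and table.counts["TAA"] == 1
        assert table.per_1000["ATG"] == pytest.approx(666.67, abs=0.01)
        assert table.synonymous_fraction["ATG"] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_per_1000_sums_to_1000(self, seed, code5):
        probs = gen_codon_table_family(0.7, 1, seed=seed)[0]
        cds = gen_cds_set(probs, 500, seed=seed)
        table = codon_usage(cds, code5)
        assert sum(table.per_1000.values()) == pytest.approx(1000, abs=0.5)

    def test_uniform_sense_codons_recovered_within_3_se(self, code5):
        sense = [c for c in CODONS if c not in ("TAA", "TAG")]
        probs = {c: 1 / len(sense) for c in sense}
        n = 60_000
        table = codon_usage(gen_cds_set(probs, n, seed=7), code5)
        p = 1 / len(sense)
        se = 1000 * np.sqrt(p * (1 - p) / n)
        for c in sense:
            assert abs(table.per_1000[c] - 1000 * p) < 3 * se

    def test_empty_set_raises(self, code5):
        with pytest.raises(EmptyInputError):
            codon_usage(CdsSet(), code5)


class TestTrpCodonStats:
    def test_internal_tga_vs_tgg_percent(self, code5):
        cds = CdsSet([CdsRecord("x", "ATG" + "TGA" * 3 + "TGG" + "TAA", 5)])
        got = trp_codon_stats(cds, code5)
        assert (got.uga_count, got.ugg_count) == (3, 1)
        assert got.uga_trp_percent == pytest.approx(75.0)

    def test_terminal_tga_is_a_stop_not_trp(self, code5):
        got = trp_codon_stats(CdsSet([CdsRecord("x", "ATGAAATGA", 5)]), code5)
        assert got.uga_count == 0
        assert got.uga_trp_percent is None

    def test_standard_code_requires_explicit_opt_in(self, code1):
        cds = CdsSet([CdsRecord("x", "ATGTGGTAA", 1)])
        with pytest.raises(ValueError, match="TGA as Trp"):
            trp_codon_stats(cds, code1)
        assert trp_codon_stats(cds, code1, allow_standard_code=True).ugg_count == 1

    @pytest.mark.parametrize("target", [0.0, 50.0, 73.3, 100.0])
    def test_generator_uga_fraction_recovered(self, target, code5):
        genome, truth = gen_viral_genome(
            orf_codons=600, code_id=5, at_target=65, trp_uga_frac=target, seed=11
        )
        cds_str = genome.residues[truth.orf_span[0] : truth.orf_span[1]]
        got = trp_codon_stats(CdsSet([CdsRecord("v", cds_str, 5)]), code5)
        n_trp = got.uga_count + got.ugg_count
        assert got.uga_trp_percent == pytest.approx(truth.trp_uga_fraction)
        # nearest achievable fraction given the drawn Trp count
        assert abs(got.uga_trp_percent - target) <= 100.0 / (2 * n_trp) + 1e-9


class TestCorrelationAndClustering:
    def test_identical_and_negated_vectors(self):
        v = np.array([1.0, 2, 3, 4, 5])
        cc = profile_correlation([("a", v), ("b", v), ("c", -v)])
        f = cc.r_frame()
        assert f.loc["a", "b"] == pytest.approx(1.0)
        assert f.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        x = np.array([1.0, 4, 2, 8, 5])
        y = np.array([2.0, 3, 7, 6, 9])

        def pearson(a, b):
            am, bm = a - a.mean(), b - b.mean()
            return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))

        cc = profile_correlation([("x", x), ("y", y)])
        assert cc.r_frame().loc["x", "y"] == pytest.approx(pearson(x, y))

    def test_zero_variance_vector_is_excluded(self):
        cc = profile_correlation([("a", [1.0, 2, 3]), ("b", [5.0, 5, 5]), ("c", [1.0, 2, 3.1])])
        assert np.isnan(cc.r_frame().loc["a", "b"])
        out = cluster_by_correlation(cc, 0.8)
        assert out.assignment["b"] is None
        assert out.assignment["a"] == out.assignment["c"] is not None

    def test_two_identical_plus_orthogonal(self):
        v = np.array([1.0, 0, 1, 0, 1, 0])
        w = np.array([0.0, 1, 0, 1, 0, 1])
        out = cluster_by_correlation(profile_correlation([("a", v), ("b", v), ("c", w)]))
        assert out.assignment["a"] == out.assignment["b"] is not None
        assert out.assignment["c"] is None

    def test_pair_just_below_threshold_not_clustered(self):
        r = np.array([[1.0, 0.79], [0.79, 1.0]])
        cc = CorrelationClustering(["a", "b"], r, None, {})
        assert cluster_by_correlation(cc, 0.8).assignment == {"a": None, "b": None}
        assert cluster_by_correlation(cc, 0.79).assignment == {"a": 1, "b": 1}

    def test_clustering_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        vecs = [("p%d" % i, rng.normal(size=8)) for i in range(6)]
        a = cluster_by_correlation(profile_correlation(vecs), 0.5).assignment
        b = cluster_by_correlation(profile_correlation(vecs[::-1]), 0.5).assignment
        assert a == b

    def test_two_codon_families_form_two_clusters(self, code5):
        insect = gen_codon_table_family(0.9, 4, seed=21)
        fungal = gen_codon_table_family(0.6, 4, seed=22)
        profiles = []
        for i, p in enumerate(insect):
            t = codon_usage(gen_cds_set(p, 2000, seed=100 + i, source_id=f"i{i}"), code5)
            profiles.append((f"insect{i}", t.vector()))
        for i, p in enumerate(fungal):
            t = codon_usage(gen_cds_set(p, 2000, seed=200 + i, source_id=f"f{i}"), code5)
            profiles.append((f"fungal{i}", t.vector()))
        out = cluster_by_correlation(profile_correlation(profiles), 0.8)
        groups = out.clusters()
        assert len(groups) == 2
        by_prefix = {lab[:6] for labs in groups.values() for lab in labs}
        for labs in groups.values():
            assert len({lab[:1] for lab in labs}) == 1  # no mixed cluster
        assert by_prefix == {"insect", "fungal"}
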