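"""Small-RNA pipeline: filtering, mapping, profiling, enrichment, KS,
classification, profile clustering."""

import numpy as np
import pytest

from mitovir import srna
from mitovir.errors import EmptyInputError
from mitovir.seqcore import NucSequence, reverse_complement
from mitovir.srna import (
    Alignment,
    AlignmentSet,
    ReadRecord,
    classify_signature,
    coverage_track,
    ecdf_ks_compare,
    filter_reads,
    five_prime_enrichment,
    map_reads,
    profile_cluster,
    read_fastq,
    size_profile,
    write_fastq,
)
from mitovir.synthetic_data import gen_srna_reads


def _read(seq, q=40, rid="r1"):
    return ReadRecord(rid, seq, (q,) * len(seq))


class TestFastqIO:
    def test_roundtrip(self, tmp_path):
        reads = [_read("ACGTACGTACGTACGTACGTA", rid=f"r{i}") for i in range(3)]
        p = tmp_path / "x.fastq"
        write_fastq(reads, p)
        assert read_fastq(p) == reads

    def test_malformed_record_reports_index(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r0\nACGT\n+\nIIII\nr1-no-at\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="index 1"):
            read_fastq(p)


class TestFilterReads:
    def test_quality_and_length_rules(self):
        keep = _read("A" * 25, q=30)
        short = _read("A" * 19, q=40)
        # 21 of 30 bases at Q>=20 is 70% < 80%
        lowq = ReadRecord("r", "A" * 30, (25,) * 21 + (10,) * 9)
        boundary = ReadRecord("r", "A" * 30, (25,) * 24 + (10,) * 6)  # exactly 80%
        got = filter_reads([keep, short, lowq, boundary])
        assert keep in got and boundary in got
        assert short not in got and lowq not in got


class TestMapReads:
    def test_exact_substring_maps_at_truth(self):
        ref = NucSequence("ref", "ACGTACGGTTCAGGCATTACGGATCCGTAGGCTA" * 3)
        read = _read(ref.residues[10:31])
        aln = map_reads([read], ref)
        assert len(aln) == 1
        a = aln.alignments[0]
        assert (a.start, a.strand, a.mismatches) == (10, "+", 0)

    def test_minus_strand_read_found(self):
        ref = NucSequence("ref", "ACGTACGGTTCAGGCATTACGGATCCGTAGGCTAGCTT")
        read = _read(reverse_complement(ref.residues[5:26]))
        a = map_reads([read], ref).alignments[0]
        assert (a.start, a.strand) == (5, "-")

    def test_two_mismatches_unmapped_at_max_mm_1(self):
        ref = NucSequence("ref", "ACGTACGGTTCAGGCATTACGGATCCGTAGGCTA")
        sub = list(ref.residues[5:26])
        sub[2], sub[15] = "T" if sub[2] != "T" else "A", "T" if sub[15] != "T" else "A"
        assert len(map_reads([_read("".join(sub))], ref, max_mm=1)) == 0
        assert len(map_reads([_read("".join(sub))], ref, max_mm=2)) == 1

    def test_multimapper_takes_lowest_coordinate(self):
        unit = "ACGGTTCAGGCATTACGGAT"
        ref = NucSequence("ref", unit * 3)
        a = map_reads([_read(unit)], ref).alignments[0]
        assert a.start == 0

    def test_generator_reads_all_map(self, mitovirus_genome):
        genome, _ = mitovirus_genome
        reads = gen_srna_reads(genome, 1000, seed=3, preset="siRNA_insect")
        aln = map_reads(reads, genome)
        assert len(aln) / len(reads) >= 0.999
        for a in aln.alignments[:50]:  # placements reproduce the read
            window = genome.residues[a.start : a.start + a.length]
            assert a.mismatches == 0
            rd = next(r for r in reads if r.id == a.read_id)
            assert rd.sequence == (window if a.strand == "+" else reverse_complement(window))


class TestSizeProfile:
    def test_single_cell_profile(self):
        aln = AlignmentSet("ref", 100, [Alignment(f"r{i}", 0, 21, "+", 0) for i in range(10)])
        prof = size_profile(aln)
        assert prof.freq[21 - srna.SIZE_MIN, 0] == 1.0
        assert prof.freq.sum() == pytest.approx(1.0)

    def test_symmetric_strands(self):
        alns = [Alignment(f"p{i}", 0, 21, "+", 0) for i in range(5)]
        alns += [Alignment(f"m{i}", 0, 21, "-", 0) for i in range(5)]
        prof = size_profile(AlignmentSet("ref", 100, alns))
        assert prof.freq[21 - srna.SIZE_MIN, 0] == prof.freq[21 - srna.SIZE_MIN, 1] == 0.5
        assert prof.zscores[21 - srna.SIZE_MIN, 0] == prof.zscores[21 - srna.SIZE_MIN, 1]

    def test_empty_profile_has_zero_zscores(self):
        prof = size_profile(AlignmentSet("ref", 100, []))
        assert prof.total == 0
        assert not prof.zscores.any()

    def test_frequencies_sum_to_one_for_any_alignments(self, mitovirus_genome):
        genome, _ = mitovirus_genome
        for preset in ("siRNA_insect", "piRNA"):
            reads = gen_srna_reads(genome, 500, seed=9, preset=preset)
            prof = size_profile(map_reads(reads, genome))
            assert prof.freq.sum() == pytest.approx(1.0)


class TestFivePrimeEnrichment:
    def test_forced_u_start_is_flagged(self):
        rng = np.random.default_rng(0)
        ref = NucSequence("ref", "".join(rng.choice(list("ACGT"), size=2000)))
        t_starts = [i for i, b in enumerate(ref.residues[:-25]) if b == "T"]
        aln = AlignmentSet("ref", len(ref),
                           [Alignment(f"r{i}", t_starts[i % len(t_starts)], 21, "+", 0)
                            for i in range(1000)])
        enr = five_prime_enrichment(aln, ref)
        cell = enr.cell(21, "+")
        assert cell.enriched["T"] and cell.p_adjusted["T"] < 1e-10

    def test_small_cells_are_untested(self):
        ref = NucSequence("ref", "ACGT" * 30)
        aln = AlignmentSet("ref", len(ref), [Alignment("r", 0, 21, "+", 0)] * 5)
        enr = five_prime_enrichment(aln, ref)
        assert not enr.cell(21, "+").tested
        assert enr.enriched_bases(21, "+") == []

    def test_unbiased_generator_not_flagged(self, mitovirus_genome):
        genome, _ = mitovirus_genome
        reads = gen_srna_reads(genome, 4000, seed=17, preset="siRNA_insect")
        enr = five_prime_enrichment(map_reads(reads, genome), genome)
        mode_cells = [enr.cell(21, s) for s in "+-"]
        assert all(not any(c.enriched.values()) for c in mode_cells if c and c.tested)

    def test_empty_alignments_raise(self, mitovirus_genome):
        genome, _ = mitovirus_genome
        with pytest.raises(EmptyInputError):
            five_prime_enrichment(AlignmentSet("ref", len(genome), []), genome)


class TestCoverage:
    def test_single_read_footprint(self):
        ref = NucSequence("ref", "A" * 50)
        cov = coverage_track(AlignmentSet("ref", 50, [Alignment("r", 0, 21, "+", 0)]), ref)
        assert cov.depth_plus[:21].tolist() == [1] * 21
        assert cov.depth_plus[21:].sum() == 0 and cov.depth_minus.sum() == 0

    def test_depth_conservation_invariant(self, mitovirus_genome):
        genome, _ = mitovirus_genome
        reads = gen_srna_reads(genome, 2000, seed=2, preset="siRNA_insect")
        aln = map_reads(reads, genome)
        cov = coverage_track(aln, genome)
        assert cov.depth_plus.sum() + cov.depth_minus.sum() == sum(a.length for a in aln)

    def test_dense_symmetric_library_covers_genome(self, mitovirus_genome):
        genome, _ = mitovirus_genome
        reads = gen_srna_reads(genome, 8000, seed=4, preset="siRNA_insect")
        cov = coverage_track(map_reads(reads, genome), genome)
        assert cov.covered_fraction() >= 0.99
        assert 0.8 <= cov.strand_depth_ratio() <= 1.25

    def test_empty_alignment_set_gives_zero_track(self):
        ref = NucSequence("ref", "A" * 40)
        cov = coverage_track(AlignmentSet("ref", 40, []), ref)
        assert cov.depth_plus.sum() == cov.depth_minus.sum() == 0


class TestEcdfKs:
    def test_identical_samples_d_zero(self):
        got = ecdf_ks_compare([21] * 100, [21] * 100, seed=0)
        assert got.d == 0.0 and got.pvalue == 1.0

    def test_disjoint_samples_d_one(self):
        got = ecdf_ks_compare([21] * 100, [28] * 100, seed=0)
        assert got.d == 1.0 and got.pvalue < 0.01

    def test_asymptotic_method_available(self):
        got = ecdf_ks_compare([21] * 200 + [22] * 100, [28] * 300, method="asymp")
        assert got.d == 1.0 and got.pvalue < 1e-6

    def test_empty_sample_raises(self):
        with pytest.raises(EmptyInputError):
            ecdf_ks_compare([], [21, 22])


class TestClassification:
    @pytest.mark.parametrize(
        "preset,expected",
        [
            ("siRNA_insect", "siRNA_insect_like"),
            ("fungal_siRNA", "fungal_siRNA_like"),
            ("piRNA", "piRNA_like"),
        ],
    )
    def test_preset_recovery(self, mitovirus_genome, preset, expected):
        genome, _ = mitovirus_genome
        reads = gen_srna_reads(genome, 10000, seed=123, preset=preset)
        aln = map_reads(reads, genome)
        call = classify_signature(size_profile(aln), five_prime_enrichment(aln, genome))
        assert call == expected

    def test_uniform_single_strand_is_none(self, mitovirus_genome):
        genome, _ = mitovirus_genome
        rng = np.random.default_rng(0)
        alns = [
            Alignment(f"r{i}", int(rng.integers(0, 2000)), int(s), "+", 0)
            for i, s in enumerate(rng.integers(15, 36, size=2000))
        ]
        aln = AlignmentSet(genome.id, len(genome), alns)
        aln.alignments = [a for a in alns if a.start + a.length <= len(genome)]
        call = classify_signature(size_profile(aln), five_prime_enrichment(aln, genome))
        assert call == "none"


class TestProfileCluster:
    def test_replicates_cluster_together_presets_apart(self, mitovirus_genome):
        genome, _ = mitovirus_genome
        profiles = []
        for preset in ("siRNA_insect", "piRNA"):
            for rep in range(2):
                reads = gen_srna_reads(genome, 4000, seed=50 + rep, preset=preset)
                aln = map_reads(reads, genome)
                prof = size_profile(aln)
                prof.reference_id = f"{preset}_{rep}"
                profiles.append(prof)
        out = profile_cluster(profiles)
        a = out.assignment
        assert a["siRNA_insect_0"] == a["siRNA_insect_1"] is not None
        assert a["piRNA_0"] == a["piRNA_1"] is not None
        assert a["siRNA_insect_0"] != a["piRNA_0"]
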