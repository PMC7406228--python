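from __future__ import annotations

import numpy as np
import pytest
from Bio import SeqIO

from conftest import make_annotations
from declust.model import (
    GeneSet,
    GenomeSequence,
    MotifMatch,
    OperonTable,
    PromoterRegion,
    TSSRecord,
    ThresholdConfig,
)
from declust.promoters import (
    build_promoter_regions,
    candidate_regulators,
    emit_promoter_fasta,
    extract_upstream,
    first_in_operon_filter,
    resolve_start,
)
from oracles import revcomp


class TestOperonFilter:
    def test_gene_outside_any_operon_retained(self, annotations10):
        operons = OperonTable({"OP1": ["G5", "G6"]})
        assert first_in_operon_filter(["G1"], operons, annotations10) == ["G1"]

    def test_first_de_gene_in_operon_wins(self, annotations10):
        operons = OperonTable({"OP1": ["G1", "G2", "G3"]})
        assert first_in_operon_filter(["G2", "G3"], operons, annotations10) == ["G2"]

    def test_hand_enumerated_fixture(self, annotations10):
        # two operons with two DE genes each + one lone DE gene -> 3 retained
        operons = OperonTable({"OP1": ["G1", "G2"], "OP2": ["G4", "G5", "G6"]})
        got = first_in_operon_filter(
            ["G2", "G1", "G5", "G6", "G8"], operons, annotations10
        )
        assert got == ["G1", "G5", "G8"]

    def test_output_ordered_by_ordinal_and_deduplicated(self, annotations10):
        got = first_in_operon_filter(
            ["G9", "G3", "G9", "G1"], OperonTable({}), annotations10
        )
        assert got == ["G1", "G3", "G9"]

    def test_idempotent(self, annotations10):
        operons = OperonTable({"OP1": ["G1", "G2"], "OP2": ["G4", "G5"]})
        de = ["G2", "G4", "G5", "G7"]
        once = first_in_operon_filter(de, operons, annotations10)
        assert first_in_operon_filter(once, operons, annotations10) == once
        assert len(once) <= len(de)

    def test_unannotated_operon_member_reported(self, annotations10):
        operons = OperonTable({"OPX": ["G1", "GHOST"]})
        with pytest.raises(ValueError, match="OPX"):
            first_in_operon_filter(["G1"], operons, annotations10)

    def test_unannotated_de_locus_rejected(self, annotations10):
        with pytest.raises(ValueError, match="GHOST"):
            first_in_operon_filter(["GHOST"], OperonTable({}), annotations10)


class TestResolveStart:
    def test_primary_tss_used_as_is(self, annotations10):
        tss = {"G1": [TSSRecord("G1", 1000, "+", "primary")]}
        assert resolve_start("G1", tss, annotations10) == (1000, "+", "tss", False)

    def test_antisense_tss_switches_strand(self, annotations10):
        tss = {"G1": [TSSRecord("G1", 1000, "-", "antisense")]}
        assert resolve_start("G1", tss, annotations10) == (1000, "-", "tss", True)

    def test_minus_strand_gene_without_tss_uses_right_coordinate(self):
        anns = make_annotations(3, strand="-")
        # G2 spans 101..190 on -, so its start codon is at 190
        assert resolve_start("G2", {}, anns) == (190, "-", "start_codon", False)

    def test_plus_strand_gene_without_tss_uses_left_coordinate(self, annotations10):
        assert resolve_start("G3", {}, annotations10) == (201, "+", "start_codon", False)

    def test_primary_wins_over_other_types(self, annotations10):
        tss = {
            "G1": [
                TSSRecord("G1", 500, "+", "internal"),
                TSSRecord("G1", 900, "+", "primary"),
            ]
        }
        assert resolve_start("G1", tss, annotations10)[0] == 900

    def test_nearest_tss_breaks_ties_without_primary(self, annotations10):
        # G1 starts at 1; 40 is closer than 500
        tss = {
            "G1": [
                TSSRecord("G1", 500, "+", "internal"),
                TSSRecord("G1", 40, "+", "secondary"),
            ]
        }
        assert resolve_start("G1", tss, annotations10)[0] == 40


GENOME30 = "ACGTACGTTGCAGCTAGCTAACCGGTTAGC"  # 30 bp, hand-indexed below


class TestExtractUpstream:
    def test_plus_strand_linear_prefix(self):
        genome = GenomeSequence("A" * 300 + "C" * 100, circular=False)
        seq = extract_upstream(genome, position=251, strand="+", length=250)
        assert seq == genome.sequence[:250]

    def test_circular_wrap_hand_spelled(self):
        genome = GenomeSequence(GENOME30, circular=True)
        # upstream of position 5 on +: bases 25..30 then 1..4
        expected = GENOME30[24:30] + GENOME30[0:4]
        assert extract_upstream(genome, 5, "+", 10) == expected

    def test_minus_strand_is_reverse_complement_of_downstream(self):
        genome = GenomeSequence(GENOME30, circular=True)
        # bases 11..20 reverse-complemented
        assert extract_upstream(genome, 10, "-", 10) == revcomp(GENOME30[10:20])

    def test_strand_symmetry_involution(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=50))
        genome = GenomeSequence(seq, circular=True)
        mirrored = GenomeSequence(revcomp(seq), circular=True)
        for pos in (1, 7, 25, 50):
            # minus-strand extraction equals plus-strand extraction at the
            # mirrored coordinate of the reverse-complemented genome
            a = extract_upstream(genome, pos, "-", 12)
            b = extract_upstream(mirrored, len(seq) - pos + 1, "+", 12)
            assert a == b

    def test_window_longer_than_genome_rejected(self):
        genome = GenomeSequence(GENOME30, circular=True)
        with pytest.raises(ValueError, match="genome length"):
            extract_upstream(genome, 5, "+", 30)

    def test_linear_out_of_range_reports_truncation(self):
        genome = GenomeSequence(GENOME30, circular=False)
        with pytest.raises(ValueError, match="truncate"):
            extract_upstream(genome, 5, "+", 10)

    def test_position_outside_genome_rejected(self):
        genome = GenomeSequence(GENOME30, circular=True)
        with pytest.raises(ValueError, match="outside"):
            extract_upstream(genome, 31, "+", 5)

    def test_length_exact_across_randomized_fixtures(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        genome = GenomeSequence(seq, circular=True)
        for _ in range(300):
            pos = int(rng.integers(1, 401))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(1, 399))
            assert len(extract_upstream(genome, pos, strand, length)) == length


class TestRegions:
    def test_antisense_always_flips(self, annotations10):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genome = GenomeSequence(seq, circular=True)
        tss = {
            f"G{i + 1}": [TSSRecord(f"G{i + 1}", i * 100 + 50, "-", "antisense")]
            for i in range(10)
        }
        cfg = ThresholdConfig(upstream_len=40)
        regions = build_promoter_regions(
            [f"G{i + 1}" for i in range(10)], genome, tss, annotations10, cfg
        )
        assert all(r.flipped for r in regions)
        for r in regions:
            original = annotations10[r.locus_tag].strand
            assert r.resolved_strand != original
            assert len(r.sequence) == 40

    def test_fasta_round_trip(self, tmp_path):
        regions = [
            PromoterRegion("G1", 100, "+", "tss", False, "ACGTACGT"),
            PromoterRegion("G2", 300, "-", "start_codon", False, "TTTTAAAA"),
        ]
        path = tmp_path / "promoters.fasta"
        emit_promoter_fasta(regions, path, tmp_path / "manifest.json")
        back = list(SeqIO.parse(str(path), "fasta"))
        assert [r.id for r in back] == ["G1", "G2"]
        assert [str(r.seq) for r in back] == ["ACGTACGT", "TTTTAAAA"]
        assert (tmp_path / "manifest.json").exists()

    def test_zero_regions_rejected_without_writing(self, tmp_path):
        path = tmp_path / "promoters.fasta"
        with pytest.raises(ValueError, match="no promoter regions"):
            emit_promoter_fasta([], path)
        assert not path.exists()


class TestCandidateRegulators:
    REGULONS = [
        GeneSet(name="AlgR", members={"PA0001"}, source="CollecTF"),
        GeneSet(name="OxyR", members={"PA0002"}, source="CollecTF"),
    ]

    def test_matches_map_to_regulons(self):
        matches = [MotifMatch("M1", "algR", 0.1), MotifMatch("M2", "OXYR", 0.2)]
        mapped, unmapped = candidate_regulators(matches, self.REGULONS)
        assert [s.name for s in mapped] == ["AlgR", "OxyR"]
        assert unmapped == []

    def test_duplicate_matches_collapse(self):
        matches = [MotifMatch("M1", "AlgR", 0.1), MotifMatch("M2", "AlgR", 0.3)]
        mapped, _ = candidate_regulators(matches, self.REGULONS)
        assert len(mapped) == 1

    def test_unknown_regulator_reported_not_fatal(self):
        matches = [MotifMatch("M1", "VqsM", 0.1)]
        mapped, unmapped = candidate_regulators(matches, self.REGULONS)
        assert mapped == [] and unmapped == ["VqsM"]
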