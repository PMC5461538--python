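import numpy as np
import pytest

from ntpg.conservation import (
    MafBlock,
    MafRow,
    NEAR_COGNATE_CODONS,
    NEAR_COGNATE_RESTRICTED,
    aligned_sequence_at,
    assess_conservation,
    orthologous_peptide,
    read_maf,
    start_codon_status,
)
from ntpg.fixtures import SpeciesConfig, synth_maf
from ntpg.genome_io import GenomicInterval

from oracles import naive_aligned_query


def block(ref_text, qry_text, ref_start=10, contig="c1"):
    ref_size = len(ref_text) - ref_text.count("-")
    qry_size = len(qry_text) - qry_text.count("-")
    return MafBlock(
        [
            MafRow("ath", contig, ref_start, ref_size, "+", 1000, ref_text),
            MafRow("aly", "scaf1", 0, qry_size, "+", qry_size, qry_text),
        ]
    )


class TestAlignedSequenceAt:
    def test_identical_alignment(self):
        b = block("ATGGCC", "ATGGCC")
        tis = GenomicInterval("c1", 11, 13, "+")  # ref_start 10 -> first base 11
        assert aligned_sequence_at([b], "ath", tis, "aly") == "ATGGCC"

    def test_query_gap_removed(self):
        b = block("ATGGCC", "A-TGGCC"[:6])  # placeholder, replaced below
        b = MafBlock(
            [
                MafRow("ath", "c1", 10, 6, "+", 1000, "AT-GGCC"),
                MafRow("aly", "scaf1", 0, 6, "+", 6, "A-TGGCC"),
            ]
        )
        tis = GenomicInterval("c1", 11, 13, "+")
        assert aligned_sequence_at([b], "ath", tis, "aly") == "ATGGCC"

    def test_tis_outside_every_block_is_unaligned(self):
        b = block("ATGGCC", "ATGGCC")
        tis = GenomicInterval("c1", 500, 502, "+")
        assert aligned_sequence_at([b], "ath", tis, "aly") is None
        assert start_codon_status(None) == "unaligned"

    def test_mid_block_start(self):
        b = block("AAATGGCC", "CCATGGCC")
        tis = GenomicInterval("c1", 13, 15, "+")  # third ref base
        assert aligned_sequence_at([b], "ath", tis, "aly") == "ATGGCC"

    def test_minus_strand_reads_leftward_reverse_complement(self):
        # transcript-oriented ref is revcomp of the plus-strand block text
        b = block("GGCCAT", "GGCCAT")  # plus strand; '-' TIS at the CAT end
        tis = GenomicInterval("c1", 14, 16, "-")  # first base = 16 (plus pos 6)
        assert aligned_sequence_at([b], "ath", tis, "aly") == "ATGGCC"

    def test_column_walk_matches_naive_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n_cols = int(rng.integers(10, 120))
            ref_cols, qry_cols = [], []
            for _c in range(n_cols):
                r = "ACGT"[rng.integers(0, 4)] if rng.random() > 0.15 else "-"
                q = "ACGT"[rng.integers(0, 4)] if rng.random() > 0.15 else "-"
                if r == "-" and q == "-":
                    q = "A"
                ref_cols.append(r)
                qry_cols.append(q)
            ref_text, qry_text = "".join(ref_cols), "".join(qry_cols)
            ref_size = ref_text.count("A") + ref_text.count("C") + ref_text.count(
                "G"
            ) + ref_text.count("T")
            if ref_size < 4:
                continue
            b = block(ref_text, qry_text, ref_start=0)
            offset = int(rng.integers(0, ref_size))
            tis = GenomicInterval("c1", offset + 1, offset + 3, "+")
            got = aligned_sequence_at([b], "ath", tis, "aly")
            assert got == naive_aligned_query(ref_text, qry_text, offset)


class TestStartCodonStatus:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGGCA", "canonical"),
            ("CTGGCA", "near_cognate"),
            ("GTGGCA", "near_cognate"),
            ("ACGGCA", "near_cognate"),
            ("CCGGCA", "absent"),
            ("AT", "absent"),
        ],
    )
    def test_statuses(self, seq, expected):
        assert start_codon_status(seq) == expected

    def test_near_cognate_set_is_single_mismatch_neighbourhood(self):
        neighbours = set()
        for i in range(3):
            for base in "ACGT":
                cand = "ATG"[:i] + base + "ATG"[i + 1 :]
                if cand != "ATG":
                    neighbours.add(cand)
        assert NEAR_COGNATE_CODONS == neighbours

    def test_restricted_set_flag(self):
        assert start_codon_status("ACGGCA", NEAR_COGNATE_RESTRICTED) == "absent"
        assert start_codon_status("CTGGCA", NEAR_COGNATE_RESTRICTED) == "near_cognate"


class TestOrthologousPeptide:
    def test_full_length_peptide_recovered(self):
        seq = "ATG" + "GCT" * 24 + "TAA" + "GGG"
        ok, pep = orthologous_peptide(seq, 25)
        assert ok and pep == "M" + "A" * 24

    def test_early_stop_fails_min_length(self):
        seq = "ATG" + "GCT" * 2 + "TAA" + "GCT" * 10
        ok, pep = orthologous_peptide(seq, 8)
        assert not ok and pep == "MAA"

    def test_block_edge_truncation_fails(self):
        seq = "ATG" + "GCT" * 5  # ends mid-ORF at the block edge
        ok, pep = orthologous_peptide(seq, 8)
        assert not ok and pep == "M" + "A" * 5

    def test_near_cognate_start_decoded_to_met(self):
        seq = "CTG" + "GCT" * 8 + "TAA"
        ok, pep = orthologous_peptide(seq, 9)
        assert ok and pep[0] == "M"


class TestPlantedFates:
    def test_all_fates_recovered(self, small_fixture, tmp_path):
        tis_list = [o.tis for o in small_fixture.truth.planted_orfs]
        fates = ["keep", "near_cognate", "destroy", "unaligned"]
        cfg = SpeciesConfig(
            "lyrata",
            fate_by_tis={t.tag(): fates[i % 4] for i, t in enumerate(tis_list)},
        )
        path = tmp_path / "aln.maf"
        _text, truth = synth_maf(
            small_fixture.contigs, tis_list, [cfg], seed=3, out_path=path
        )
        blocks = read_maf(path)
        assert len(truth.planted_conservation) == len(tis_list)
        for (tag, sp), expected in truth.planted_conservation.items():
            tis = GenomicInterval.from_tag(tag)
            res = assess_conservation(blocks, "refsp", tis, sp, min_len_aa=8)
            assert res.start_status == expected, tag
            if expected == "unaligned":
                assert not res.aligned

    def test_conserved_fates_encode_ortho_peptides(self, small_fixture, tmp_path):
        tis_list = [o.tis for o in small_fixture.truth.planted_orfs]
        cfg = SpeciesConfig("brapa", fate_by_tis={})  # all keep
        path = tmp_path / "aln.maf"
        _text, truth = synth_maf(
            small_fixture.contigs, tis_list, [cfg], seed=4, out_path=path
        )
        blocks = read_maf(path)
        by_tag = {o.tis.tag(): o for o in small_fixture.truth.planted_orfs}
        for (tag, sp), expected in truth.planted_conservation.items():
            orf = by_tag[tag]
            res = assess_conservation(
                blocks, "refsp", GenomicInterval.from_tag(tag), sp,
                min_len_aa=min(len(orf.protein), 30),
            )
            assert res.start_status in ("canonical", "near_cognate")
            assert res.ortho_peptide, tag
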