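import numpy as np
import pytest

from ntpg.genome_io import GenomicInterval
from ntpg.ntpep_library import (
    PROTEASES,
    build_library,
    collapse_il,
    nt_peptides_for_protein,
    read_library_fasta,
    subtract_reference,
    validate_library,
    write_library_fasta,
    NtPeptide,
)
from ntpg.orf_discovery import OpenReadingFrame, six_frame_orfs

from oracles import brute_force_digest


def make_orf(protein, orf_id="o1", tis_start=1):
    nt = "ATG" + "GCT" * (len(protein) - 1)
    return OpenReadingFrame(
        orf_id=orf_id,
        origin="six_frame",
        contig_id="c1",
        strand="+",
        locations=[GenomicInterval("c1", tis_start, tis_start + 3 * len(protein) - 1, "+")],
        start_codon="ATG",
        protein=protein,
        nt_seq=nt,
        tis=GenomicInterval("c1", tis_start, tis_start + 2, "+"),
        frame=0,
    )


class TestDigestion:
    def test_argc_with_imet_removal(self):
        peps = nt_peptides_for_protein("MAGTELLKSWVRDDK", PROTEASES["argc_trypsin"])
        seqs = {p.sequence for p in peps}
        # K is never a boundary (acylated side chains); R at 12 is
        assert seqs == {"MAGTELLKSWVR", "AGTELLKSWVR"}
        by_seq = {p.sequence: p for p in peps}
        assert by_seq["MAGTELLKSWVR"].start_position == 1
        assert by_seq["AGTELLKSWVR"].imet_removed

    def test_gluc_missed_cleavage_and_length_floor(self):
        peps = nt_peptides_for_protein("MDSSKTAAAFERGG", PROTEASES["gluc"])
        assert {p.sequence for p in peps} == {"MDSSKTAAAFE"}
        (pep,) = peps
        assert pep.missed_cleavages == 1  # spans the internal D at position 2

    def test_aspn_cleaves_before_d(self):
        peps = nt_peptides_for_protein("MSTAAAKKLDGGGDWW", PROTEASES["aspn"])
        assert {p.sequence for p in peps} == {
            "MSTAAAKKL",
            "MSTAAAKKLDGGG",
            "STAAAKKL",
            "STAAAKKLDGGG",
        }

    def test_protein_without_cleavage_site_kept_whole(self):
        peps = nt_peptides_for_protein("MAAWWAAQQ", PROTEASES["argc_trypsin"])
        assert {p.sequence for p in peps} == {"MAAWWAAQQ", "AAWWAAQQ"}
        assert all(p.cterm_is_protein_end for p in peps)

    def test_non_imet_protein_rejected(self):
        with pytest.raises(ValueError, match="iMet"):
            nt_peptides_for_protein("AGTELLK", PROTEASES["gluc"])

    @pytest.mark.parametrize("protease", sorted(PROTEASES))
    def test_matches_quadratic_oracle_on_random_proteins(self, protease):
        rng = np.random.default_rng(99)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        spec = PROTEASES[protease]
        for _ in range(200):
            n = int(rng.integers(8, 60))
            protein = "M" + "".join(aas[i] for i in rng.integers(0, 20, n - 1))
            got = {p.sequence for p in nt_peptides_for_protein(protein, spec)}
            expected = brute_force_digest(
                protein, spec.cleave_side, set(spec.residues), spec.max_missed_library
            )
            assert got == expected, protein


class TestReferenceSubtraction:
    def _peps(self, seqs):
        return [
            NtPeptide(s, 1, False, 0, "argc_trypsin") for s in seqs
        ]

    def test_substring_and_il_equivalence(self, tmp_fasta):
        ref = tmp_fasta([("r1", "MKALSTRWWKGG")])
        kept = subtract_reference(
            self._peps(["ALSTRWWK", "AISTRWWK", "WWWPPPQR"]), [ref]
        )
        assert {p.sequence for p in kept} == {"WWWPPPQR"}

    def test_empty_reference_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="retaining all"):
            kept = subtract_reference(self._peps(["ALSTRWWK"]), [])
        assert len(kept) == 1


class TestBuildLibrary:
    def test_multi_locus_peptides_merge(self, tmp_fasta):
        ref = tmp_fasta([("r", "MWWWWWWWWWW")])
        orfs = [
            make_orf("MAGTELLKSWVR", "a", tis_start=1),
            make_orf("MAGTELLKSWVR", "b", tis_start=901),
        ]
        lib = build_library(orfs, PROTEASES["argc_trypsin"], [ref])
        target = lib.targets["MAGTELLKSWVR"]
        assert sorted(target.orf_ids) == ["a", "b"]
        assert len(target.tis_sites) == 2

    def test_decoy_is_reversed_target(self, tmp_fasta):
        ref = tmp_fasta([("r", "MWWWWWWWWWW")])
        lib = build_library([make_orf("MAGTELLKSWVR")], PROTEASES["argc_trypsin"], [ref])
        assert "MAGTELLKSWVR"[::-1] in lib.decoys

    def test_empty_orf_list_gives_empty_library(self):
        lib = build_library([], PROTEASES["gluc"], [])
        assert not lib.targets and not lib.decoys

    def test_palindromic_target_gets_shuffled_decoy(self, tmp_fasta):
        ref = tmp_fasta([("r", "MWWWWWWWWWW")])
        lib = build_library([make_orf("MAAWWAAM")], PROTEASES["argc_trypsin"], [ref])
        assert "MAAWWAAM" in lib.targets
        assert len(lib.decoys) == len(lib.targets)
        assert not set(lib.decoys) & set(lib.targets)

    def test_library_is_deterministic(self, small_fixture, tmp_fasta, tmp_path):
        ref = tmp_fasta([("r", "MWWWWWWWWWW")])
        orfs = six_frame_orfs(small_fixture.contigs)[:300]
        out1, out2 = tmp_path / "l1.fasta", tmp_path / "l2.fasta"
        for out in (out1, out2):
            write_library_fasta(
                build_library(orfs, PROTEASES["gluc"], [ref], seed=5), out
            )
        assert out1.read_bytes() == out2.read_bytes()

    def test_round_trip_preserves_sequences_and_metadata(
        self, small_fixture, tmp_fasta, tmp_path
    ):
        ref = tmp_fasta([("r", "MWWWWWWWWWW")])
        orfs = six_frame_orfs(small_fixture.contigs)[:300]
        lib = build_library(orfs, PROTEASES["aspn"], [ref], seed=1)
        path = tmp_path / "lib.fasta"
        write_library_fasta(lib, path)
        again = read_library_fasta(path, PROTEASES["aspn"])
        assert set(again.targets) == set(lib.targets)
        assert set(again.decoys) == set(lib.decoys)
        for seq, pep in lib.targets.items():
            other = again.targets[seq]
            assert (
                pep.start_position,
                pep.imet_removed,
                pep.missed_cleavages,
                sorted(iv.tag() for iv in pep.tis_sites),
            ) == (
                other.start_position,
                other.imet_removed,
                other.missed_cleavages,
                sorted(iv.tag() for iv in other.tis_sites),
            )

    def test_validator_passes_and_pos2_implies_small_residue(
        self, small_fixture, tmp_fasta
    ):
        ref = tmp_fasta([("r", "MWWWWWWWWWW")])
        orfs = six_frame_orfs(small_fixture.contigs)
        lib = build_library(orfs, PROTEASES["chymotrypsin"], [ref], seed=2)
        assert validate_library(lib) == []
        # every iMet-removed target has an iMet-retained sibling logic:
        # its own first residue must be small-gyration
        for pep in lib.targets.values():
            if pep.start_position == 2:
                assert pep.sequence[0] in set("ACGPSTV")

    def test_no_target_survives_in_reference(self, small_fixture, tmp_path):
        orfs = six_frame_orfs(small_fixture.contigs)
        # use some ORF proteins themselves as the reference proteome
        ref = tmp_path / "ref.fasta"
        with open(ref, "w") as fh:
            for o in orfs[:50]:
                fh.write(f">{o.orf_id}\n{o.protein}\n")
        lib = build_library(orfs, PROTEASES["argc_trypsin"], [ref])
        blob = "#".join(collapse_il(o.protein) for o in orfs[:50])
        assert all(collapse_il(t) not in blob for t in lib.targets)
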