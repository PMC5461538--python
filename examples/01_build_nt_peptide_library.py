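"""Build a protease-specific N-terminal peptide target-decoy library.

A synthetic genome with planted ORFs stands in for a real assembly: ORFs are
enumerated in six frames from canonical (ATG) and near-cognate (CTG/GTG)
starts, downstream-AUG truncations are added, Nt-peptides (8-30 AA) are
digested out under ArgC-like specificity with the iMet-excision rule, and
peptides matching the reference proteome are subtracted (I/L-blind) before
one reversed decoy per target completes the search database.
"""

import tempfile
from pathlib import Path

from ntpg import PROTEASES, build_library, six_frame_orfs, write_library_fasta
from ntpg.orf_discovery import downstream_start_orfs
from ntpg.fixtures import synth_genome, synth_reference_proteome, write_fasta_records

fx = synth_genome(n_contigs=2, contig_len=30_000, n_orfs=25, seed=42)
orfs = six_frame_orfs(fx.contigs)
children = [c for o in orfs for c in downstream_start_orfs(o)]
print(f"six-frame ORFs: {len(orfs)}, downstream-AUG truncations: {len(children)}")

with tempfile.TemporaryDirectory() as td:
    ref = Path(td) / "reference.fasta"
    write_fasta_records(
        synth_reference_proteome(fx.truth, fraction_planted=0.3, seed=7), ref
    )
    lib = build_library(orfs + children, PROTEASES["argc_trypsin"], [ref], seed=1)
    out = Path(td) / "library.fasta"
    write_library_fasta(lib, out)
    print(f"targets: {len(lib.targets)}, decoys: {len(lib.decoys)}")
    example = sorted(lib.targets)[0]
    pep = lib.targets[example]
    print(
        f"example target: {example} (start position {pep.start_position}, "
        f"{len(pep.tis_sites)} genomic TIS)"
    )

# Counts: every target is a genome-derived candidate protein N terminus that
# does not occur in the reference proteome; each decoy mirrors one target so
# that downstream searches can estimate their false discovery rate.
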