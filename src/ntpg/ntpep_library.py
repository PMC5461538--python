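"""Protease-specific N-terminal peptide target-decoy libraries.

From every in-silico translated ORF the anticipated protein N-terminal
peptides (8-30 AA) are extracted under the cleavage specificity of the
protease used, with the N-terminal methionine excision (NME) rule applied:
when residue 2 has a small gyration radius (A, C, G, P, S, T or V) the
peptide with its iMet removed is additionally considered. Peptides matching
the reference proteome or the contaminant database — with Ile and Leu
treated as indistinguishable, as they are isobaric — are removed, and one
reversed-sequence decoy per retained target completes the search database.

Because the downstream search runs with "no cleavage" enzyme settings (only
full-length stored peptides can be identified), decoys are generated at the
peptide level by sequence reversal.
"""

from __future__ import annotations

import hashlib
import random
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import GenomicInterval
from .orf_discovery import OpenReadingFrame

SMALL_GYRATION = frozenset("ACGPSTV")
LEN_MIN_DEFAULT = 8
LEN_MAX_DEFAULT = 30


@dataclass(frozen=True)
class ProteaseSpec:
    """Cleavage specificity of one sequencing protease.

    ``max_missed_library`` bounds missed cleavages during Nt-peptide library
    construction; ``max_missed_search`` is the (larger) bound used in the
    reference-proteome search settings. Cleavage after Lys is prohibited for
    the trypsin digest because lysine side chains are acetylated by the
    N-terminomics labelling, leaving ArgC-like specificity.
    """

    name: str
    cleave_side: str  # "after" | "before"
    residues: frozenset[str]
    max_missed_library: int
    max_missed_search: int


PROTEASES: dict[str, ProteaseSpec] = {
    "argc_trypsin": ProteaseSpec("argc_trypsin", "after", frozenset("R"), 0, 2),
    "gluc": ProteaseSpec("gluc", "after", frozenset("DE"), 1, 3),
    "chymotrypsin": ProteaseSpec("chymotrypsin", "after", frozenset("FWYLM"), 1, 3),
    "aspn": ProteaseSpec("aspn", "before", frozenset("D"), 1, 3),
}


@dataclass
class NtPeptide:
    """A candidate protein N-terminal peptide (start position 1 or 2)."""

    sequence: str
    start_position: int  # 1 = iMet retained, 2 = iMet removed
    imet_removed: bool
    missed_cleavages: int
    protease: str
    orf_ids: list[str] = field(default_factory=list)
    tis_sites: list[GenomicInterval] = field(default_factory=list)
    cterm_is_protein_end: bool = False
    decoy: bool = False


@dataclass
class PeptideLibrary:
    protease: ProteaseSpec
    targets: dict[str, NtPeptide]  # sequence -> peptide
    decoys: dict[str, NtPeptide]
    provenance: dict = field(default_factory=dict)


def collapse_il(seq: str) -> str:
    """Map Ile and Leu to one token: they are isobaric to the spectrometer."""
    return seq.replace("I", "J").replace("L", "J")


def _boundaries(protein: str, spec: ProteaseSpec, start: int) -> list[int]:
    """Cleavage boundary end-positions for a peptide starting at ``start``.

    Returned values are 1-based protein positions p such that protein[start..p]
    is a fully cleaved or missed-cleavage peptide: for cleave-after specs p is
    the position of a cleavable residue; for cleave-before specs p is the
    position immediately before a cleavable residue. A cleave-before site at
    the peptide's own first position is not a boundary.
    """
    ends: list[int] = []
    if spec.cleave_side == "after":
        for p in range(start, len(protein) + 1):
            if protein[p - 1] in spec.residues:
                ends.append(p)
    else:
        for p in range(start + 1, len(protein) + 1):
            if protein[p - 1] in spec.residues:
                ends.append(p - 1)
    return ends


def nt_peptides_for_protein(
    protein: str,
    spec: ProteaseSpec,
    len_min: int = LEN_MIN_DEFAULT,
    len_max: int = LEN_MAX_DEFAULT,
) -> list[NtPeptide]:
    """All Nt-peptides of one protein under a protease specificity.

    For k = 0..max_missed the peptide from the N terminus through the
    (k+1)-th cleavage boundary is emitted; when residue 2 is in the
    small-gyration set the same series is additionally emitted with the iMet
    removed. If the protein runs out of cleavage sites, the full protein is
    admitted (flagged ``cterm_is_protein_end``) when it spans no more than
    max_missed boundaries. Products outside [len_min, len_max] or containing
    X are discarded.
    """
    if not protein or protein[0] != "M":
        raise ValueError("Nt-peptide extraction requires an iMet-starting protein")
    starts = [1]
    if len(protein) >= 2 and protein[1] in SMALL_GYRATION:
        starts.append(2)
    out: list[NtPeptide] = []
    for start in starts:
        ends = _boundaries(protein, spec, start)
        emitted_ends: set[int] = set()
        for k in range(spec.max_missed_library + 1):
            if k >= len(ends):
                break
            end = ends[k]
            emitted_ends.add(end)
            _append_if_valid(
                out, protein, start, end, k, spec, len_min, len_max, False
            )
        # full-protein fallback: C terminus at the protein end
        end = len(protein)
        if end not in emitted_ends:
            spanned = sum(1 for e in ends if e < end)
            if spanned <= spec.max_missed_library:
                _append_if_valid(
                    out, protein, start, end, spanned, spec, len_min, len_max, True
                )
    return out


def _append_if_valid(
    out: list[NtPeptide],
    protein: str,
    start: int,
    end: int,
    missed: int,
    spec: ProteaseSpec,
    len_min: int,
    len_max: int,
    at_protein_end: bool,
) -> None:
    seq = protein[start - 1 : end]
    if not (len_min <= len(seq) <= len_max) or "X" in seq:
        return
    out.append(
        NtPeptide(
            sequence=seq,
            start_position=start,
            imet_removed=(start == 2),
            missed_cleavages=missed,
            protease=spec.name,
            cterm_is_protein_end=at_protein_end,
        )
    )


def _reference_blob(reference_fastas: Sequence[str | Path]) -> str:
    """All reference/contaminant proteins, I/L-collapsed, '#'-joined."""
    from Bio import SeqIO

    parts: list[str] = []
    for path in reference_fastas:
        for rec in SeqIO.parse(str(path), "fasta"):
            parts.append(collapse_il(str(rec.seq).upper()))
    return "#".join(parts)


def subtract_reference(
    peptides: Iterable[NtPeptide],
    reference_fastas: Sequence[str | Path],
) -> list[NtPeptide]:
    """Drop peptides whose I/L-collapsed sequence occurs in any reference protein.

    Matching is substring and position-independent: an Nt-peptide equal to an
    internal stretch of a reference protein is still unidentifiable as novel.
    """
    peptides = list(peptides)
    if not reference_fastas:
        warnings.warn("no reference databases given; retaining all peptides", stacklevel=2)
        return peptides
    blob = _reference_blob(reference_fastas)
    return [p for p in peptides if collapse_il(p.sequence) not in blob]


def _decoy_for(
    target_seq: str,
    taken: set[str],
    blob: str,
    rng: random.Random,
    max_attempts: int = 50,
) -> str | None:
    cand = target_seq[::-1]
    for _ in range(max_attempts):
        cj = collapse_il(cand)
        if cj not in taken and cj not in blob:
            return cand
        chars = list(target_seq)
        rng.shuffle(chars)
        cand = "".join(chars)
    return None


def build_library(
    orfs: Iterable[OpenReadingFrame],
    spec: ProteaseSpec,
    reference_fastas: Sequence[str | Path] = (),
    len_min: int = LEN_MIN_DEFAULT,
    len_max: int = LEN_MAX_DEFAULT,
    seed: int = 0,
) -> PeptideLibrary:
    """Build one protease's non-redundant Nt-peptide target-decoy library.

    Identical peptide sequences arising from several ORFs (or several
    genomic loci) are merged into one target carrying every orf_id and every
    distinct TIS interval. After reference subtraction, each target gets a
    reversed-sequence decoy; a decoy colliding (I/L-collapsed) with any
    target or reference sequence is re-derived by seeded shuffling, and the
    pair is dropped with a warning if no collision-free decoy is found.
    """
    orfs = list(orfs)
    targets: dict[str, NtPeptide] = {}
    for orf in orfs:
        if not orf.protein or orf.protein[0] != "M":
            continue
        for pep in nt_peptides_for_protein(orf.protein, spec, len_min, len_max):
            entry = targets.get(pep.sequence)
            if entry is None:
                entry = pep
                targets[pep.sequence] = entry
            entry.orf_ids.append(orf.orf_id)
            if orf.tis not in entry.tis_sites:
                entry.tis_sites.append(orf.tis)
    blob = _reference_blob(reference_fastas) if reference_fastas else ""
    if reference_fastas:
        targets = {
            seq: pep for seq, pep in targets.items() if collapse_il(seq) not in blob
        }
    elif targets:
        warnings.warn("no reference databases given; retaining all peptides", stacklevel=2)

    rng = random.Random(seed)
    taken = {collapse_il(s) for s in targets}
    decoys: dict[str, NtPeptide] = {}
    dropped: list[str] = []
    for seq in sorted(targets):
        dec = _decoy_for(seq, taken, blob, rng)
        if dec is None:
            dropped.append(seq)
            continue
        taken.add(collapse_il(dec))
        decoys[dec] = replace(
            targets[seq], sequence=dec, decoy=True, orf_ids=[], tis_sites=[]
        )
    for seq in dropped:
        warnings.warn(f"dropping target {seq}: no collision-free decoy", stacklevel=2)
        del targets[seq]

    digest = hashlib.sha256(
        ("|".join(sorted(targets)) + "||" + "|".join(sorted(decoys))).encode()
    ).hexdigest()[:16]
    return PeptideLibrary(
        protease=spec,
        targets=targets,
        decoys=decoys,
        provenance={
            "n_orfs": len(orfs),
            "len_range": [len_min, len_max],
            "seed": seed,
            "decoy_unit": "peptide_reversal",
            "references": [str(p) for p in reference_fastas],
            "digest": digest,
        },
    )


def _header(pep: NtPeptide, idx: int) -> str:
    prefix = "rev_" if pep.decoy else ""
    tis = ";".join(iv.tag() for iv in pep.tis_sites)
    return (
        f"{prefix}ntpep_{idx:06d}|protease={pep.protease}"
        f"|start={pep.start_position}|imet_removed={int(pep.imet_removed)}"
        f"|missed={pep.missed_cleavages}|cterm_end={int(pep.cterm_is_protein_end)}"
        f"|decoy={int(pep.decoy)}|tis={tis}"
    )


def write_library_fasta(library: PeptideLibrary, path: str | Path) -> None:
    """Serialise targets then decoys; headers carry the peptide metadata."""
    with open(path, "w") as fh:
        idx = 0
        for group in (library.targets, library.decoys):
            for seq in sorted(group):
                fh.write(f">{_header(group[seq], idx)}\n{seq}\n")
                idx += 1


def read_library_fasta(path: str | Path, spec: ProteaseSpec) -> PeptideLibrary:
    """Inverse of :func:`write_library_fasta` (round-trips the library)."""
    from Bio import SeqIO

    targets: dict[str, NtPeptide] = {}
    decoys: dict[str, NtPeptide] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split("|")[1:] if "=" in kv
        )
        tis = [
            GenomicInterval.from_tag(t) for t in fields.get("tis", "").split(";") if t
        ]
        pep = NtPeptide(
            sequence=str(rec.seq),
            start_position=int(fields["start"]),
            imet_removed=bool(int(fields["imet_removed"])),
            missed_cleavages=int(fields["missed"]),
            protease=fields["protease"],
            tis_sites=tis,
            cterm_is_protein_end=bool(int(fields["cterm_end"])),
            decoy=bool(int(fields["decoy"])),
        )
        (decoys if pep.decoy else targets)[pep.sequence] = pep
    return PeptideLibrary(protease=spec, targets=targets, decoys=decoys)


def validate_library(library: PeptideLibrary) -> list[str]:
    """Whole-library consistency check; returns a list of violation strings."""
    spec = library.protease
    lo, hi = library.provenance.get("len_range", [LEN_MIN_DEFAULT, LEN_MAX_DEFAULT])
    problems: list[str] = []
    overlap = set(library.targets) & set(library.decoys)
    if overlap:
        problems.append(f"{len(overlap)} sequences are both target and decoy")
    if len(library.decoys) != len(library.targets):
        problems.append("target and decoy counts differ")
    for pep in library.targets.values():
        seq = pep.sequence
        if not (lo <= len(seq) <= hi):
            problems.append(f"{seq}: length {len(seq)} outside [{lo},{hi}]")
        if "X" in seq:
            problems.append(f"{seq}: contains X")
        if (seq[0] == "M") != (pep.start_position == 1):
            problems.append(f"{seq}: start_position {pep.start_position} vs iMet")
        if not pep.cterm_is_protein_end:
            if spec.cleave_side == "after" and seq[-1] not in spec.residues:
                problems.append(f"{seq}: C terminus violates cleave-after rule")
    return problems
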