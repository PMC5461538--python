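"""Start-codon conservation in pairwise whole-genome MAF alignments.

For each novel TIS the aligned query-species sequence starting at the start
codon's genomic coordinate is parsed from the covering alignment block (if
any). The query start codon is classed canonical (ATG), near-cognate (a
single-substitution neighbour of ATG) or absent, and — when a start is
conserved — the query sequence is translated in frame from it to test
whether an orthologous N-terminal peptide of at least the identified
peptide's length (or its first-exon part for junction-spanning peptides)
can still be encoded. Blocks are not stitched: an ORF truncated at a block
edge conservatively counts as not encoding the peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO

from .genome_io import GenomicInterval, STOP_CODONS, revcomp, translate_cds

NEAR_COGNATE_CODONS = frozenset(
    {"CTG", "GTG", "TTG", "AAG", "ACG", "AGG", "ATA", "ATC", "ATT"}
)
NEAR_COGNATE_RESTRICTED = frozenset({"CTG", "GTG"})


@dataclass(frozen=True)
class MafRow:
    species: str
    contig: str
    start: int  # 0-based, strand-relative (MAF convention)
    size: int  # ungapped length
    strand: str
    src_size: int
    text: str  # gapped sequence

    def __post_init__(self) -> None:
        ungapped = len(self.text) - self.text.count("-")
        if ungapped != self.size:
            raise ValueError(
                f"row {self.species}.{self.contig}: size {self.size} != "
                f"ungapped length {ungapped}"
            )


@dataclass
class MafBlock:
    rows: list[MafRow]

    def __post_init__(self) -> None:
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("rows of one MAF block differ in gapped length")

    def row_for(self, species: str) -> MafRow | None:
        for row in self.rows:
            if row.species == species:
                return row
        return None


@dataclass
class ConservationResult:
    tis: GenomicInterval
    species: str
    aligned: bool
    start_status: str  # canonical | near_cognate | absent | unaligned
    ortho_peptide: bool = False
    ortho_sequence: str = ""


def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        species, contig = src.split(".", 1)
        return species, contig
    return src, src


def read_maf(path: str | Path) -> list[MafBlock]:
    """Load MAF alignment blocks (per-species rows with MAF coordinates)."""
    blocks: list[MafBlock] = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = []
        for rec in aln:
            species, contig = _split_src(rec.id)
            rows.append(
                MafRow(
                    species=species,
                    contig=contig,
                    start=int(rec.annotations["start"]),
                    size=int(rec.annotations["size"]),
                    strand="+" if rec.annotations["strand"] == 1 else "-",
                    src_size=int(rec.annotations["srcSize"]),
                    text=str(rec.seq).upper(),
                )
            )
        blocks.append(MafBlock(rows))
    return blocks


def _covering_block(
    blocks: Sequence[MafBlock], ref_species: str, contig: str, pos0: int
) -> tuple[MafBlock, MafRow] | None:
    """First block (by reference coordinate) whose reference row covers pos0.

    Only plus-strand reference rows are considered (the reference genome is
    the coordinate system of the TIS calls).
    """
    hits: list[tuple[int, MafBlock, MafRow]] = []
    for block in blocks:
        row = block.row_for(ref_species)
        if row is None or row.contig != contig or row.strand != "+":
            continue
        if row.start <= pos0 < row.start + row.size:
            hits.append((row.start, block, row))
    if not hits:
        return None
    hits.sort(key=lambda h: h[0])
    return hits[0][1], hits[0][2]


def aligned_sequence_at(
    blocks: Sequence[MafBlock],
    ref_species: str,
    tis: GenomicInterval,
    query_species: str,
) -> str | None:
    """Query-species sequence aligned from the TIS first base, gaps removed.

    The alignment column holding the TIS first base in the reference row is
    located by walking reference columns; the query row is read from that
    column to the block end (to the block start, reverse-complemented, for a
    minus-strand TIS) and returned gapless. None when no block covers the
    TIS or the block lacks reference or query rows.
    """
    first = tis.start if tis.strand == "+" else tis.end
    pos0 = first - 1
    found = _covering_block(blocks, ref_species, tis.contig_id, pos0)
    if found is None:
        return None
    block, ref_row = found
    query_row = block.row_for(query_species)
    if query_row is None:
        return None
    # column of the reference base at pos0
    offset_needed = pos0 - ref_row.start
    col = None
    seen = 0
    for i, base in enumerate(ref_row.text):
        if base != "-":
            if seen == offset_needed:
                col = i
                break
            seen += 1
    if col is None:
        return None
    if tis.strand == "+":
        segment = query_row.text[col:]
        return segment.replace("-", "")
    segment = query_row.text[: col + 1]
    return revcomp(segment.replace("-", ""))


def start_codon_status(
    query_seq: str | None, near_cognate: frozenset[str] = NEAR_COGNATE_CODONS
) -> str:
    """Classify the first codon of the aligned query sequence."""
    if query_seq is None:
        return "unaligned"
    if len(query_seq) < 3:
        return "absent"
    codon = query_seq[:3].upper()
    if codon == "ATG":
        return "canonical"
    if codon in near_cognate:
        return "near_cognate"
    return "absent"


def orthologous_peptide(query_seq: str, min_len_aa: int) -> tuple[bool, str]:
    """Translate in frame from a conserved start; test peptide coding capacity.

    The initiator codon is decoded to M. Translation proceeds until a stop
    codon or the end of the aligned sequence (a block edge); the flag is true
    iff at least ``min_len_aa`` residues are produced first.
    """
    seq = query_seq.upper()
    aas: list[str] = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            break
        aas.append(translate_cds(codon))
    if aas:
        aas[0] = "M"
    peptide = "".join(aas)
    return len(peptide) >= min_len_aa, peptide


def assess_conservation(
    blocks: Sequence[MafBlock],
    ref_species: str,
    tis: GenomicInterval,
    query_species: str,
    min_len_aa: int,
    near_cognate: frozenset[str] = NEAR_COGNATE_CODONS,
) -> ConservationResult:
    """Full conservation verdict for one TIS against one query species."""
    query_seq = aligned_sequence_at(blocks, ref_species, tis, query_species)
    status = start_codon_status(query_seq, near_cognate)
    result = ConservationResult(
        tis=tis,
        species=query_species,
        aligned=query_seq is not None,
        start_status=status,
    )
    if status in ("canonical", "near_cognate"):
        ok, pep = orthologous_peptide(query_seq, min_len_aa)  # type: ignore[arg-type]
        result.ortho_peptide = ok
        result.ortho_sequence = pep
    return result


def write_conservation_tsv(
    results: Iterable[ConservationResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("tis\tspecies\taligned\tstart_status\tortho_peptide\tortho_sequence\n")
        for r in results:
            fh.write(
                f"{r.tis.tag()}\t{r.species}\t{int(r.aligned)}\t{r.start_status}"
                f"\t{int(r.ortho_peptide)}\t{r.ortho_sequence}\n"
            )
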