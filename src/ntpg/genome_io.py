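"""Sequence/annotation IO, the genomic coordinate model, and CDS translation.

Coordinates are 1-based inclusive throughout the package (the GFF convention);
BED export converts to 0-based half-open. Genome sequences are uppercased on
ingest and any IUPAC ambiguity code other than A/C/G/T is mapped to N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gffutils
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_VALID = set("ACGTN")
_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _CODON_TABLE[_stop] = "*"

Strand = Literal["+", "-"]


class GenomeIOError(ValueError):
    """Malformed FASTA/GFF input or coordinate violation."""


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeIOError(f"contig {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive genomic span on one strand."""

    contig_id: str
    start: int
    end: int
    strand: Strand

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise GenomeIOError(
                f"invalid interval {self.contig_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def tag(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def from_tag(cls, tag: str) -> "GenomicInterval":
        contig, span, strand = tag.rsplit(":", 2)
        start, end = span.split("-")
        return cls(contig, int(start), int(end), strand)  # type: ignore[arg-type]


@dataclass
class GeneModel:
    """One transcript-level gene model with exon and CDS intervals.

    ``exons`` and ``cds`` are ordered 5'->3' in transcript orientation, i.e.
    by descending genomic coordinate for minus-strand models.
    """

    model_id: str
    gene_id: str
    biotype: str  # protein_coding | pseudogene | transposable_element | other
    strand: Strand
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    source: str = "reference"  # reference | predicted

    @property
    def contig_id(self) -> str:
        parts = self.exons or self.cds
        return parts[0].contig_id

    def footprint(self) -> GenomicInterval:
        """Genomic span from first to last exon (or CDS if no exons)."""
        parts = self.exons or self.cds
        lo = min(p.start for p in parts)
        hi = max(p.end for p in parts)
        return GenomicInterval(parts[0].contig_id, lo, hi, self.strand)


def _clean_sequence(raw: str) -> str:
    seq = raw.upper()
    if set(seq) - _VALID:
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


def load_genome(fasta_path: str | Path) -> list[Contig]:
    """Read a genome FASTA into Contigs, normalising case and ambiguity codes."""
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, _clean_sequence(str(rec.seq))))
    if not contigs:
        raise GenomeIOError(f"no FASTA records in {path}")
    return contigs


def write_genome(contigs: Iterable[Contig], fasta_path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs]
    SeqIO.write(records, str(fasta_path), "fasta")


_BIOTYPE_BY_FEATURETYPE = {
    "gene": "protein_coding",
    "protein_coding_gene": "protein_coding",
    "pseudogene": "pseudogene",
    "transposable_element_gene": "transposable_element",
    "transposable_element": "transposable_element",
}
_KNOWN_BIOTYPES = {"protein_coding", "pseudogene", "transposable_element", "other"}


def _biotype_of(feature: gffutils.Feature, gene_type: str | None) -> str:
    for key in ("biotype", "gene_biotype"):
        if key in feature.attributes:
            val = feature.attributes[key][0]
            return val if val in _KNOWN_BIOTYPES else "other"
    if gene_type is not None and gene_type in _BIOTYPE_BY_FEATURETYPE:
        return _BIOTYPE_BY_FEATURETYPE[gene_type]
    return "other"


def load_gene_models(
    gff_path: str | Path,
    dialect: Literal["gff3", "gtf"] = "gff3",
    contigs: list[Contig] | None = None,
    source: str = "reference",
) -> list[GeneModel]:
    """Parse GFF3/GTF into one GeneModel per transcript.

    Biotype comes from a ``biotype``/``gene_biotype`` attribute when present,
    otherwise from the gene feature type (e.g. ``transposable_element_gene``).
    Orphan CDS features trigger a warning and are skipped. With ``contigs``
    given, coordinates outside the contig raise.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=(dialect == "gff3"),
        disable_infer_transcripts=(dialect == "gff3"),
    )
    lengths = {c.id: len(c) for c in contigs} if contigs else None
    transcript_types = {"mRNA", "transcript", "pseudogenic_transcript"}
    models: list[GeneModel] = []
    for tx in db.all_features():
        if tx.featuretype not in transcript_types:
            continue
        parents = list(db.parents(tx, level=1))
        gene = parents[0] if parents else None
        gene_id = gene.id if gene is not None else tx.id
        gene_type = gene.featuretype if gene is not None else None
        biotype = _biotype_of(gene if gene is not None else tx, gene_type)
        strand: Strand = "-" if tx.strand == "-" else "+"
        exons, cds = [], []
        for child in db.children(tx, level=1):
            if lengths is not None:
                clen = lengths.get(child.seqid)
                if clen is not None and child.end > clen:
                    raise GenomeIOError(
                        f"feature {child.id} ends at {child.end} beyond "
                        f"contig {child.seqid} length {clen}"
                    )
            iv = GenomicInterval(child.seqid, child.start, child.end, strand)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
        reverse = strand == "-"
        exons.sort(key=lambda iv: iv.start, reverse=reverse)
        cds.sort(key=lambda iv: iv.start, reverse=reverse)
        if not exons and not cds:
            continue
        models.append(
            GeneModel(tx.id, gene_id, biotype, strand, exons, cds, source)
        )
    # orphan CDS: features of type CDS with no transcript parent
    for feat in db.features_of_type("CDS"):
        if not list(db.parents(feat, level=1)):
            warnings.warn(f"orphan CDS {feat.id} skipped", stacklevel=2)
    return models


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_interval(contigs_by_id: dict[str, Contig], iv: GenomicInterval) -> str:
    """Sequence of one interval in transcript orientation (revcomp on minus)."""
    contig = contigs_by_id[iv.contig_id]
    if iv.end > len(contig):
        raise GenomeIOError(f"interval {iv.tag()} beyond contig end {len(contig)}")
    seq = contig.sequence[iv.start - 1 : iv.end]
    return revcomp(seq) if iv.strand == "-" else seq


def spliced_cds_sequence(
    contigs_by_id: dict[str, Contig], model: GeneModel
) -> str:
    """Concatenated CDS nucleotides of a model, 5'->3' of the transcript."""
    return "".join(extract_interval(contigs_by_id, iv) for iv in model.cds)


def translate_cds(cds_nt: str, start_is_initiator: bool = False) -> str:
    """Translate a CDS with the standard nuclear code.

    The first codon is decoded to M when ``start_is_initiator`` (near-cognate
    CUG/GUG starts are decoded to iMet). Translation stops before the first
    stop codon; an N-containing codon yields X. A trailing stop codon is
    permitted; an internal stop raises.
    """
    seq = cds_nt.upper()
    if len(seq) % 3 != 0:
        raise GenomeIOError(f"CDS length {len(seq)} not divisible by 3")
    aas: list[str] = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        aa = _CODON_TABLE.get(codon, "X")
        if aa == "*":
            if i != n_codons - 1:
                raise GenomeIOError(f"internal stop codon at codon {i + 1}")
            break
        aas.append(aa)
    if aas and start_is_initiator:
        aas[0] = "M"
    return "".join(aas)


def write_bed6(
    intervals: Iterable[tuple[GenomicInterval, str, float]],
    path: str | Path,
) -> None:
    """Write (interval, name, score) triples as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                f"{iv.contig_id}\t{iv.start - 1}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
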