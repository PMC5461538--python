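"""Candidate translation-product enumeration.

Three sources of open reading frames feed the Nt-peptide library:

* six-frame ORFs of the raw genome, nucleated at canonical (ATG) and
  near-cognate (CTG, GTG by default) start codons, each requiring an in-frame
  stop codon and a minimum product of 8 amino acids;
* truncated products re-initiated at internal in-frame AUGs of those ORFs;
* spliced *ab initio* gene models (e.g. Augustus output), whose products can
  place an N-terminal peptide across a splice junction.

Near-cognate starts are decoded to initiator methionine, so every emitted
protein begins with M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import (
    Contig,
    GeneModel,
    GenomicInterval,
    GenomeIOError,
    STOP_CODONS,
    revcomp,
    spliced_cds_sequence,
    translate_cds,
    write_bed6,
)

DEFAULT_START_CODONS = frozenset({"ATG", "CTG", "GTG"})
DEFAULT_MIN_AA = 8


@dataclass
class OpenReadingFrame:
    """A genomically anchored start-to-stop translation unit.

    ``locations`` is the coding span (excluding the stop codon) as one
    interval for contiguous ORFs or an ordered 5'->3' list for spliced
    models. ``base_coords`` maps each coding nucleotide (transcript order)
    to its 1-based genomic position, so residues spanning splice junctions
    can be placed on the genome.
    """

    orf_id: str
    origin: str  # six_frame | downstream_aug | predicted_model
    contig_id: str
    strand: str
    locations: list[GenomicInterval]
    start_codon: str
    protein: str
    nt_seq: str  # coding nucleotides, transcript orientation, no stop
    tis: GenomicInterval
    frame: int | None = None
    parent_orf_id: str = ""
    base_coords: list[int] = field(default_factory=list)

    def residue_genomic_intervals(self, residue_index: int) -> list[GenomicInterval]:
        """Genomic interval(s) of one protein residue (0-based index)."""
        coords = self.base_coords[3 * residue_index : 3 * residue_index + 3]
        return _positions_to_intervals(self.contig_id, self.strand, coords)

    def span_genomic_intervals(self, res_from: int, res_to: int) -> list[GenomicInterval]:
        """Genomic interval(s) covering residues [res_from, res_to) (0-based)."""
        coords = self.base_coords[3 * res_from : 3 * res_to]
        return _positions_to_intervals(self.contig_id, self.strand, coords)


def _positions_to_intervals(
    contig_id: str, strand: str, coords: Sequence[int]
) -> list[GenomicInterval]:
    if not coords:
        return []
    ordered = sorted(coords)
    intervals: list[GenomicInterval] = []
    lo = prev = ordered[0]
    for pos in ordered[1:]:
        if pos == prev + 1:
            prev = pos
            continue
        intervals.append(GenomicInterval(contig_id, lo, prev, strand))  # type: ignore[arg-type]
        lo = prev = pos
    intervals.append(GenomicInterval(contig_id, lo, prev, strand))  # type: ignore[arg-type]
    return intervals


def _codon_walk(seq: str, start_codons: frozenset[str] | set[str], min_aa: int):
    """Yield (start, end) 0-based codon-aligned ORFs per frame of one strand.

    ``end`` is the index one past the last sense codon (stop excluded). ORFs
    running off the sequence end without a stop are not emitted.
    """
    n = len(seq)
    for frame in range(3):
        # positions of stops and starts on this frame, walked once
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                for s in starts:
                    if (pos - s) // 3 >= min_aa:
                        yield frame, s, pos
                starts = []
            elif codon in start_codons:
                starts.append(pos)
        # starts with no downstream stop are dropped


def six_frame_orfs(
    genome: Iterable[Contig],
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    min_aa: int = DEFAULT_MIN_AA,
) -> list[OpenReadingFrame]:
    """Enumerate every start-to-stop ORF on both strands and all frames.

    Every occurrence of a start codon with an in-frame downstream stop on the
    same contig defines one ORF (getorf-like every-start semantics; nested
    ORFs sharing a stop are each emitted and deduplicated later at the
    peptide level). Proteins shorter than ``min_aa`` are suppressed.
    """
    start_set = frozenset(s.upper() for s in start_codons)
    orfs: list[OpenReadingFrame] = []
    for contig in genome:
        n = len(contig)
        for strand, seq in (("+", contig.sequence), ("-", revcomp(contig.sequence))):
            for frame, s, e in _codon_walk(seq, start_set, min_aa):
                nt = seq[s:e]
                protein = translate_cds(nt, start_is_initiator=True)
                if strand == "+":
                    g_start, g_end = s + 1, e
                    tis = GenomicInterval(contig.id, s + 1, s + 3, "+")
                    coords = list(range(s + 1, e + 1))
                else:
                    # position p in revcomp maps to genomic n - p (1-based)
                    g_start, g_end = n - e + 1, n - s
                    tis = GenomicInterval(contig.id, n - s - 2, n - s, "-")
                    coords = list(range(n - s, n - e, -1))
                loc = GenomicInterval(contig.id, g_start, g_end, strand)  # type: ignore[arg-type]
                orfs.append(
                    OpenReadingFrame(
                        orf_id=f"{contig.id}:{g_start}-{g_end}:{strand}:f{frame}",
                        origin="six_frame",
                        contig_id=contig.id,
                        strand=strand,
                        locations=[loc],
                        start_codon=nt[:3],
                        protein=protein,
                        nt_seq=nt,
                        tis=tis,
                        frame=frame,
                        base_coords=coords,
                    )
                )
    return orfs


def downstream_start_orfs(
    orf: OpenReadingFrame, min_aa: int = DEFAULT_MIN_AA
) -> list[OpenReadingFrame]:
    """Truncated products from internal in-frame AUG starts of a parent ORF.

    Only ATG nucleates children (near-cognate codons initiate genuine ORFs in
    the six-frame pass but are not considered for re-initiation downstream).
    Children share the parent's stop codon.
    """
    if orf.origin != "six_frame":
        raise ValueError("downstream starts are derived from six-frame ORFs only")
    children: list[OpenReadingFrame] = []
    n_codons = len(orf.nt_seq) // 3
    for j in range(1, n_codons):
        if orf.nt_seq[3 * j : 3 * j + 3] != "ATG":
            continue
        if n_codons - j < min_aa:
            continue
        coords = orf.base_coords[3 * j :]
        tis_coords = sorted(coords[:3])
        if orf.strand == "+":
            g_start, g_end = coords[0], coords[-1]
        else:
            g_start, g_end = coords[-1], coords[0]
        loc = GenomicInterval(orf.contig_id, g_start, g_end, orf.strand)  # type: ignore[arg-type]
        children.append(
            OpenReadingFrame(
                orf_id=f"{orf.orf_id}:d{j}",
                origin="downstream_aug",
                contig_id=orf.contig_id,
                strand=orf.strand,
                locations=[loc],
                start_codon="ATG",
                protein=orf.protein[j:],
                nt_seq=orf.nt_seq[3 * j :],
                tis=GenomicInterval(
                    orf.contig_id, tis_coords[0], tis_coords[-1], orf.strand  # type: ignore[arg-type]
                ),
                frame=orf.frame,
                parent_orf_id=orf.orf_id,
                base_coords=coords,
            )
        )
    return children


def model_orfs(
    models: Iterable[GeneModel], genome: Iterable[Contig]
) -> list[OpenReadingFrame]:
    """ORFs of spliced gene models, with per-residue genomic back-mapping.

    The first CDS codon is taken as the model's TIS and decoded to M. Models
    whose CDS contains an internal stop are skipped with a warning.
    """
    by_id = {c.id: c for c in genome}
    orfs: list[OpenReadingFrame] = []
    for model in models:
        if not model.cds:
            continue
        nt = spliced_cds_sequence(by_id, model)
        trimmed = nt[:-3] if nt[-3:] in STOP_CODONS else nt
        try:
            protein = translate_cds(trimmed, start_is_initiator=True)
        except GenomeIOError as exc:
            warnings.warn(f"model {model.model_id} skipped: {exc}", stacklevel=2)
            continue
        if not protein:
            continue
        coords: list[int] = []
        for iv in model.cds:
            if model.strand == "+":
                coords.extend(range(iv.start, iv.end + 1))
            else:
                coords.extend(range(iv.end, iv.start - 1, -1))
        coords = coords[: len(trimmed)]
        tis_coords = sorted(coords[:3])
        orfs.append(
            OpenReadingFrame(
                orf_id=model.model_id,
                origin="predicted_model",
                contig_id=model.contig_id,
                strand=model.strand,
                locations=list(model.cds),
                start_codon=trimmed[:3],
                protein=protein,
                nt_seq=trimmed[: 3 * len(protein)],
                tis=GenomicInterval(
                    model.contig_id, tis_coords[0], tis_coords[-1], model.strand
                ),
                base_coords=coords[: 3 * len(protein)],
            )
        )
    return orfs


def write_orf_fasta(orfs: Iterable[OpenReadingFrame], path) -> None:
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(f">{orf.orf_id}|{orf.origin}\n{orf.protein}\n")


def write_tis_bed(orfs: Iterable[OpenReadingFrame], path) -> None:
    write_bed6(((o.tis, o.orf_id, 0.0) for o in orfs), path)
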