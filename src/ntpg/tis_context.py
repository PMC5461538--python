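"""TIS sequence-context frequency matrix and context score.

Efficient translation initiation depends on the Kozak-like context of the
start codon; in Arabidopsis, adenines at positions -5..-1 and a purine at +4
favour initiation. The matrix tabulates integer-percent nucleotide
frequencies at the nine positions -5..-1, +1..+4 around non-redundant
annotated start codons (+1 is the first base of the codon; there is no
position 0). A context's score sums the percent frequencies of its bases at
-5..-1 and +4 — six terms, so scores range 0..600 — and the start codon
itself never contributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import Contig, GenomicInterval, revcomp

POSITIONS: tuple[int, ...] = (-5, -4, -3, -2, -1, 1, 2, 3, 4)
SCORED_POSITIONS: tuple[int, ...] = (-5, -4, -3, -2, -1, 4)
NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class TisFrequencyMatrix:
    """Integer-percent nucleotide frequencies around annotated TIS.

    ``freq[(position, nucleotide)]`` are percents rounded to the nearest
    integer, so each position's four entries sum to 99-101. ``raw`` keeps the
    unrounded percents for callers that prefer exact arithmetic.
    """

    freq: dict[tuple[int, str], int]
    n_sites: int
    raw: dict[tuple[int, str], float] | None = None

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("a frequency matrix needs at least one TIS")
        for pos in POSITIONS:
            total = sum(self.freq.get((pos, nt), 0) for nt in NUCLEOTIDES)
            if not 99 <= total <= 101:
                raise ValueError(f"position {pos} percents sum to {total}")

    def consensus(self) -> str:
        """Highest-frequency base at every position (the top-scoring context)."""
        return "".join(
            max(NUCLEOTIDES, key=lambda nt: self.freq.get((pos, nt), 0))
            for pos in POSITIONS
        )

    def max_score(self) -> int:
        return sum(
            max(self.freq.get((pos, nt), 0) for nt in NUCLEOTIDES)
            for pos in SCORED_POSITIONS
        )


@dataclass
class ContextScore:
    context: str
    score: int | None
    unique_locus: bool = True


def extract_context(
    contigs_by_id: dict[str, Contig], first_base: int, contig_id: str, strand: str
) -> str | None:
    """9-mer context (-5..+4) around a start codon's first base, strand-aware.

    Returns None when the window overhangs the contig.
    """
    seq = contigs_by_id[contig_id].sequence
    n = len(seq)
    if strand == "+":
        lo, hi = first_base - 5, first_base + 3
        if lo < 1 or hi > n:
            return None
        return seq[lo - 1 : hi]
    lo, hi = first_base - 3, first_base + 5
    if lo < 1 or hi > n:
        return None
    return revcomp(seq[lo - 1 : hi])


def build_frequency_matrix(
    tis_list: Iterable[tuple[GenomicInterval, str]],
    genome: Iterable[Contig] | dict[str, Contig],
) -> TisFrequencyMatrix:
    """Genome-wide TIS context frequencies from annotated start codons.

    Alternative transcripts initiating at the same genomic site — identical
    (contig, first base, strand) — are counted once. Sites whose -5..+4
    window exceeds the contig are skipped with a warning.
    """
    by_id = genome if isinstance(genome, dict) else {c.id: c for c in genome}
    seen: set[tuple[str, int, str]] = set()
    counts = {(pos, nt): 0 for pos in POSITIONS for nt in NUCLEOTIDES}
    n_sites = 0
    tis_list = list(tis_list)
    if not tis_list:
        raise ValueError("empty TIS list")
    for tis, _model_id in tis_list:
        first = tis.start if tis.strand == "+" else tis.end
        key = (tis.contig_id, first, tis.strand)
        if key in seen:
            continue
        seen.add(key)
        context = extract_context(by_id, first, tis.contig_id, tis.strand)
        if context is None:
            warnings.warn(f"TIS {tis.tag()}: context window off contig, skipped", stacklevel=2)
            continue
        n_sites += 1
        for pos, base in zip(POSITIONS, context):
            if base in NUCLEOTIDES:
                counts[(pos, base)] += 1
    if n_sites == 0:
        raise ValueError("no TIS with a complete -5..+4 window")
    raw = {k: 100.0 * v / n_sites for k, v in counts.items()}
    freq = {k: round(v) for k, v in raw.items()}
    return TisFrequencyMatrix(freq=freq, n_sites=n_sites, raw=raw)


def score_context(
    context: str,
    matrix: TisFrequencyMatrix,
    unique_locus: bool = True,
    use_raw: bool = False,
) -> ContextScore:
    """Sum the matrix frequencies of a context's bases at -5..-1 and +4.

    ``context`` is the 9-mer with the start codon at positions +1..+3; for
    proteins starting with consecutive methionines the caller passes the
    first start codon's context, and multi-locus peptides are not scored
    (pass ``unique_locus=False``). N at a scored position makes the score
    undefined. ``use_raw`` sums unrounded percents (rounded to an int at the
    end) instead of the integer-percent matrix entries.
    """
    context = context.upper()
    if len(context) != len(POSITIONS):
        raise ValueError(f"context must be a {len(POSITIONS)}-mer, got {context!r}")
    if not unique_locus:
        return ContextScore(context, None, unique_locus=False)
    table = matrix.raw if (use_raw and matrix.raw is not None) else matrix.freq
    total = 0.0
    for pos, base in zip(POSITIONS, context):
        if pos not in SCORED_POSITIONS:
            continue
        if base not in NUCLEOTIDES:
            warnings.warn(f"ambiguous base {base!r} at position {pos}; score undefined", stacklevel=2)
            return ContextScore(context, None)
        total += table[(pos, base)]
    return ContextScore(context, round(total))


def write_matrix_tsv(matrix: TisFrequencyMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_sites={matrix.n_sites}\n")
        fh.write("position\t" + "\t".join(NUCLEOTIDES) + "\n")
        for pos in POSITIONS:
            label = f"+{pos}" if pos > 0 else str(pos)
            row = "\t".join(str(matrix.freq[(pos, nt)]) for nt in NUCLEOTIDES)
            fh.write(f"{label}\t{row}\n")


def read_matrix_tsv(path: str | Path) -> TisFrequencyMatrix:
    freq: dict[tuple[int, str], int] = {}
    n_sites = 1
    with open(path) as fh:
        line = fh.readline()
        if line.startswith("#"):
            n_sites = int(line.split("=", 1)[1])
            line = fh.readline()
        header = line.rstrip("\n").split("\t")[1:]
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            pos = int(cells[0])
            for nt, val in zip(header, cells[1:]):
                freq[(pos, nt)] = int(val)
    return TisFrequencyMatrix(freq=freq, n_sites=n_sites)
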