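"""Classification of identified N-terminal peptides and their TIS.

An Nt-peptide's modification state separates genuine in-vivo events from
labelling chemistry: free alpha-amines are blocked in vitro with trideutero
(13C2D3-)acetate (+47.04 Da), so an N terminus carrying plain acetyl
(+42.01 Da) was acetylated in vivo, one carrying +47.04 Da was free in the
cell, and Nt-glutamine may cyclise to pyroglutamate (-17.03 Da). NME
compliance applies the methionine-aminopeptidase specificity rule: iMet is
excised when residue 2 has a small gyration radius (A,C,G,P,S,T,V) and
retained otherwise. TIS are placed against annotation (protein-coding /
transposable-element / pseudogene overlap, else intergenic), matched to
ribo-seq TIS calls, and screened by the stratified MS2PIP spectral
correlation threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from intervaltree import IntervalTree

from .genome_io import GeneModel, GenomicInterval
from .ntpep_library import SMALL_GYRATION

NtClassValue = Literal["in_vivo_acetyl", "in_vitro_acetyl", "free", "pyroglu", "internal"]
TisCategory = Literal[
    "intergenic", "protein_coding_overlap", "pseudogene_overlap", "te_overlap"
]


@dataclass(frozen=True)
class ModificationSpec:
    name: str
    delta: float  # Da
    site: str  # nterm | lysine | cysteine | methionine | glutamine_nterm
    variable: bool


MODIFICATION_CATALOG: tuple[ModificationSpec, ...] = (
    ModificationSpec("trideutero_acetyl", +47.04, "nterm", True),
    ModificationSpec("trideutero_acetyl_k", +47.04, "lysine", False),
    ModificationSpec("acetyl", +42.01, "nterm", True),
    ModificationSpec("carbamidomethyl", +57.02, "cysteine", False),
    ModificationSpec("oxidation", +15.99, "methionine", False),
    ModificationSpec("pyroglu", -17.03, "glutamine_nterm", True),
)

MASS_TOLERANCE_DA = 0.02


def classify_nt_modification(
    mods: Sequence[tuple[int, str, float]],
    peptide: str = "",
    start_position: int = 1,
) -> NtClassValue:
    """Nt-modification class of one PSM from its parsed modification list.

    ``mods`` entries are (position, name, delta) with position 0 denoting the
    peptide N terminus. Exactly one N-terminal modification is allowed; an
    N-terminal delta not in the catalog raises.
    """
    if start_position > 2:
        return "internal"
    nterm = [m for m in mods if m[0] == 0]
    if len(nterm) > 1:
        raise ValueError(f"two N-terminal modifications on one PSM: {nterm}")
    if not nterm:
        return "free"
    delta = nterm[0][2]
    if abs(delta - 42.01) <= MASS_TOLERANCE_DA:
        return "in_vivo_acetyl"
    if abs(delta - 47.04) <= MASS_TOLERANCE_DA:
        return "in_vitro_acetyl"
    if abs(delta + 17.03) <= MASS_TOLERANCE_DA:
        if peptide and peptide[0] != "Q":
            raise ValueError("pyroglutamate delta on a non-Gln N terminus")
        return "pyroglu"
    raise ValueError(f"N-terminal delta {delta:+.3f} Da not in modification catalog")


def nme_compliance(start_position: int, residue2: str) -> bool:
    """Whether an observed start position obeys methionine-excision specificity.

    iMet removal (start at position 2) is expected exactly when residue 2 is
    small-gyration (A,C,G,P,S,T,V); iMet retention (start at position 1) is
    expected otherwise.
    """
    if start_position not in (1, 2):
        raise ValueError("NME compliance is defined for start positions 1 and 2")
    small = residue2.upper() in SMALL_GYRATION
    return small if start_position == 2 else not small


@dataclass
class TisCall:
    tis: GenomicInterval
    category: TisCategory | None = None
    nme_compliant: bool | None = None
    riboseq_supported: bool | None = None
    ms2pip_high: bool | None = None


_PRIORITY = ("protein_coding", "transposable_element", "pseudogene")
_CATEGORY_OF = {
    "protein_coding": "protein_coding_overlap",
    "transposable_element": "te_overlap",
    "pseudogene": "pseudogene_overlap",
}


def build_annotation_index(
    annotation: Iterable[GeneModel], use_gene_footprint: bool = False
) -> dict[str, IntervalTree]:
    """Interval index of transcript footprints keyed by contig.

    ``use_gene_footprint`` keeps the hook for gene-level spans; the default
    uses each transcript's exon footprint.
    """
    trees: dict[str, IntervalTree] = {}
    for model in annotation:
        fp = model.footprint()
        trees.setdefault(fp.contig_id, IntervalTree()).addi(
            fp.start, fp.end + 1, model.biotype
        )
    return trees


def categorize_tis(
    tis: GenomicInterval,
    annotation: Iterable[GeneModel] | dict[str, IntervalTree],
    contig_lengths: dict[str, int] | None = None,
) -> TisCategory:
    """Locate a 3-nt TIS relative to annotation (strand-agnostic overlap).

    When the TIS overlaps transcripts of several biotypes the priority is
    protein_coding > transposable_element > pseudogene; no overlap with any
    transcript footprint means intergenic.
    """
    if contig_lengths is not None:
        clen = contig_lengths.get(tis.contig_id)
        if clen is None or tis.end > clen:
            raise ValueError(f"TIS {tis.tag()} off contig")
    trees = (
        annotation
        if isinstance(annotation, dict)
        else build_annotation_index(annotation)
    )
    tree = trees.get(tis.contig_id)
    hits = {iv.data for iv in tree.overlap(tis.start, tis.end + 1)} if tree else set()
    for biotype in _PRIORITY:
        if biotype in hits:
            return _CATEGORY_OF[biotype]  # type: ignore[return-value]
    return "intergenic"


def match_riboseq_tis(
    tis_list: Sequence[GenomicInterval],
    riboseq_calls: Iterable[tuple[str, int, str]],
    tolerance_nt: int = 0,
) -> list[bool]:
    """Flag TIS supported by a ribo-seq initiation call.

    Calls are (contig, first-base position, strand) of called start codons; a
    TIS matches when a call on the same contig and strand lies within
    ``tolerance_nt`` of the TIS first base (the 5'-most base in transcript
    orientation: interval start on +, interval end on -).
    """
    calls = set()
    by_contig_strand: dict[tuple[str, str], list[int]] = {}
    for contig, pos, strand in riboseq_calls:
        calls.add((contig, int(pos), strand))
        by_contig_strand.setdefault((contig, strand), []).append(int(pos))
    flags = []
    for tis in tis_list:
        base = tis.start if tis.strand == "+" else tis.end
        if tolerance_nt == 0:
            flags.append((tis.contig_id, base, tis.strand) in calls)
        else:
            positions = by_contig_strand.get((tis.contig_id, tis.strand), [])
            flags.append(any(abs(p - base) <= tolerance_nt for p in positions))
    return flags


def ms2pip_threshold(
    annotated_corrs: dict[tuple, Sequence[float]],
    novel_corrs: Iterable[tuple[tuple, float]],
) -> list[bool | None]:
    """Stratified spectral-correlation filter for novel PSMs.

    Strata (e.g. ``(is_tryptic, charge)``) separate peptide populations whose
    prediction quality differs. Each novel PSM is flagged high when its
    Pearson correlation is >= the median of the annotated distribution of its
    stratum; an empty stratum yields None with a warning.
    """
    medians: dict[tuple, float] = {}
    for stratum, values in annotated_corrs.items():
        vals = sorted(values)
        if vals:
            n = len(vals)
            medians[stratum] = (
                vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            )
    flags: list[bool | None] = []
    for stratum, corr in novel_corrs:
        med = medians.get(stratum)
        if med is None or math.isnan(med):
            warnings.warn(f"no annotated correlations for stratum {stratum}", stacklevel=2)
            flags.append(None)
        else:
            flags.append(corr >= med)
    return flags


def peptide_ms2pip_high(psm_flags: Iterable[bool | None]) -> bool:
    """A peptide is high-correlation when at least one of its PSMs is."""
    return any(flag is True for flag in psm_flags)
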