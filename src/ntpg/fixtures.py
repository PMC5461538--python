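"""Seeded synthetic inputs for every pipeline stage.

Three generators emulate the data the pipeline ingests, each alongside a
ground-truth record so downstream precision/recall is computable exactly:

* :func:`synth_genome` — contigs with planted start-to-stop ORFs (canonical
  and near-cognate starts, optionally A-rich Kozak-like -5..-1 contexts),
  wrapped in protein-coding / transposable-element / pseudogene annotation
  or left intergenic, plus optional spliced two-exon models;
* :func:`synth_psm_tables` — three-engine PSM tables drawn from a peptide
  library under a two-component score mixture (correct matches high-scoring,
  incorrect matches split evenly between targets and decoys at null scores),
  with correlated per-engine jitter and dropout;
* :func:`synth_maf` — pairwise alignment blocks per TIS with a planted
  start-codon fate (keep / near_cognate / destroy / unaligned).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import Contig, GenomicInterval, STOP_CODONS, revcomp, translate_cds
from .ntpep_library import PeptideLibrary
from .orf_discovery import OpenReadingFrame

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
DEFAULT_START_MIX = {"ATG": 0.7, "CTG": 0.15, "GTG": 0.15}
DEFAULT_CATEGORY_WEIGHTS = {
    "intergenic": 0.4,
    "protein_coding_overlap": 0.3,
    "te_overlap": 0.2,
    "pseudogene_overlap": 0.1,
}


@dataclass
class SyntheticTruth:
    planted_orfs: list[OpenReadingFrame] = field(default_factory=list)
    planted_categories: dict[str, str] = field(default_factory=dict)
    planted_psm_labels: dict[tuple, str] = field(default_factory=dict)
    planted_conservation: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_orfs": [
                    {"orf_id": o.orf_id, "protein": o.protein, "tis": o.tis.tag()}
                    for o in self.planted_orfs
                ],
                "planted_categories": self.planted_categories,
                "planted_psm_labels": {
                    "|".join(map(str, k)): v
                    for k, v in self.planted_psm_labels.items()
                },
                "planted_conservation": {
                    f"{tis}|{sp}": v
                    for (tis, sp), v in self.planted_conservation.items()
                },
            },
            indent=1,
        )


@dataclass
class GenomeFixture:
    contigs: list[Contig]
    gff3_text: str
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        from .genome_io import write_genome

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "genome.fasta"
        gff = out / "annotation.gff3"
        write_genome(self.contigs, fasta)
        gff.write_text(self.gff3_text)
        (out / "truth.json").write_text(self.truth.to_json())
        return fasta, gff


def _random_orf_nt(rng: np.random.Generator, n_aa: int, start_mix: dict[str, float]) -> str:
    codons = list(start_mix)
    probs = np.array([start_mix[c] for c in codons], dtype=float)
    start = codons[rng.choice(len(codons), p=probs / probs.sum())]
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_aa - 1)]
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return start + "".join(body) + stop


def _planted_orf(
    contig_id: str, strand: str, g0: int, orf_nt_full: str, idx: int
) -> OpenReadingFrame:
    """Build the truth OpenReadingFrame for an insertion at 0-based plus g0."""
    coding = orf_nt_full[:-3]
    total = len(orf_nt_full)
    protein = translate_cds(coding, start_is_initiator=True)
    if strand == "+":
        loc = GenomicInterval(contig_id, g0 + 1, g0 + len(coding), "+")
        tis = GenomicInterval(contig_id, g0 + 1, g0 + 3, "+")
        coords = list(range(g0 + 1, g0 + len(coding) + 1))
    else:
        loc = GenomicInterval(contig_id, g0 + 4, g0 + total, "-")
        tis = GenomicInterval(contig_id, g0 + total - 2, g0 + total, "-")
        coords = list(range(g0 + total, g0 + 3, -1))
    return OpenReadingFrame(
        orf_id=f"planted_{idx:03d}",
        origin="six_frame",
        contig_id=contig_id,
        strand=strand,
        locations=[loc],
        start_codon=orf_nt_full[:3],
        protein=protein,
        nt_seq=coding,
        tis=tis,
        base_coords=coords,
    )


def _gff_gene(
    contig: str, start: int, end: int, strand: str, idx: int, category: str
) -> list[str]:
    gene_type = {
        "protein_coding_overlap": "gene",
        "te_overlap": "transposable_element_gene",
        "pseudogene_overlap": "pseudogene",
    }[category]
    tx_type = "pseudogenic_transcript" if category == "pseudogene_overlap" else "mRNA"
    gid, tid = f"sgene{idx:03d}", f"sgene{idx:03d}.1"
    lines = [
        f"{contig}\tsynth\t{gene_type}\t{start}\t{end}\t.\t{strand}\t.\tID={gid}",
        f"{contig}\tsynth\t{tx_type}\t{start}\t{end}\t.\t{strand}\t.\tID={tid};Parent={gid}",
        f"{contig}\tsynth\texon\t{start}\t{end}\t.\t{strand}\t.\tID={tid}.e1;Parent={tid}",
    ]
    if category == "protein_coding_overlap":
        lines.append(
            f"{contig}\tsynth\tCDS\t{start}\t{end}\t.\t{strand}\t.\tID={tid}.c1;Parent={tid}"
        )
    return lines


def synth_genome(
    n_contigs: int = 2,
    contig_len: int = 50_000,
    n_orfs: int = 20,
    start_codon_mix: dict[str, float] | None = None,
    context_bias: float = 0.8,
    category_weights: dict[str, float] | None = None,
    orf_len_aa: tuple[int, int] = (10, 35),
    seed: int = 0,
) -> GenomeFixture:
    """Random genome with planted ORFs, annotation, and a truth record.

    Background nucleotides are i.i.d. uniform; ORFs (start codon sampled from
    ``start_codon_mix``, body free of in-frame stops, delimiting stop codon)
    are inserted without overlap on either strand. A ``context_bias``
    fraction of ORFs receives an A-rich -5..-1 context. Each ORF draws a
    genomic category from ``category_weights``; annotated categories emit
    GFF3 gene/transcript/exon (and CDS for protein-coding) features over the
    ORF span, intergenic ORFs emit nothing.
    """
    if n_contigs <= 0 or contig_len <= 0 or n_orfs <= 0:
        raise ValueError("n_contigs, contig_len and n_orfs must be positive")
    start_mix = start_codon_mix or DEFAULT_START_MIX
    weights = category_weights or DEFAULT_CATEGORY_WEIGHTS
    rng = np.random.default_rng(seed)
    seqs = [
        list("ACGT"[i] for i in rng.integers(0, 4, contig_len))
        for _ in range(n_contigs)
    ]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_contigs)]
    margin = 30
    truth = SyntheticTruth()
    gff_lines = ["##gff-version 3"]
    cats = list(weights)
    cat_probs = np.array([weights[c] for c in cats], dtype=float)
    cat_probs /= cat_probs.sum()
    for idx in range(n_orfs):
        n_aa = int(rng.integers(orf_len_aa[0], orf_len_aa[1] + 1))
        orf_nt = _random_orf_nt(rng, n_aa, start_mix)
        total = len(orf_nt)
        if total + 2 * margin >= contig_len:
            raise ValueError(f"ORF of {total} nt does not fit contig of {contig_len}")
        placed = False
        for _attempt in range(200):
            ci = int(rng.integers(0, n_contigs))
            g0 = int(rng.integers(margin, contig_len - total - margin))
            span = (g0 - margin, g0 + total + margin)
            if any(a < span[1] and span[0] < b for a, b in occupied[ci]):
                continue
            placed = True
            break
        if not placed:
            raise ValueError("could not place ORF without overlap; genome too dense")
        occupied[ci].append(span)
        strand = "+" if rng.random() < 0.5 else "-"
        insert = orf_nt if strand == "+" else revcomp(orf_nt)
        seqs[ci][g0 : g0 + total] = list(insert)
        if rng.random() < context_bias:
            if strand == "+":
                seqs[ci][g0 - 5 : g0] = list("AAAAA")
            else:
                seqs[ci][g0 + total : g0 + total + 5] = list("TTTTT")
        contig_id = f"chr{ci + 1}"
        orf = _planted_orf(contig_id, strand, g0, orf_nt, idx)
        truth.planted_orfs.append(orf)
        category = cats[int(rng.choice(len(cats), p=cat_probs))]
        truth.planted_categories[orf.tis.tag()] = category
        if category != "intergenic":
            gff_lines.extend(
                _gff_gene(contig_id, g0 + 1, g0 + total, strand, idx, category)
            )
    contigs = [Contig(f"chr{i + 1}", "".join(s)) for i, s in enumerate(seqs)]
    return GenomeFixture(contigs, "\n".join(gff_lines) + "\n", truth)


def synth_reference_proteome(
    truth: SyntheticTruth,
    fraction_planted: float = 0.3,
    n_random: int = 20,
    random_len_aa: tuple[int, int] = (50, 200),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Reference/contaminant proteins: some planted ORF products plus noise.

    Including a fraction of the planted proteins makes reference subtraction
    consequential: their Nt-peptides must vanish from the library.
    """
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    records: list[tuple[str, str]] = []
    for i, orf in enumerate(truth.planted_orfs):
        if rng.random() < fraction_planted:
            records.append((f"ref_planted_{i:03d}", orf.protein))
    for j in range(n_random):
        n = int(rng.integers(random_len_aa[0], random_len_aa[1] + 1))
        body = "".join(aas[k] for k in rng.integers(0, len(aas), n - 1))
        records.append((f"ref_random_{j:03d}", "M" + body))
    return records


def write_fasta_records(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# -- PSM tables ---------------------------------------------------------------

DEFAULT_SCORE_MODELS = {
    "cometlike": {"mu_correct": 3.2, "mu_incorrect": 1.2, "sigma": 0.55},
    "cruxlike": {"mu_correct": 3.0, "mu_incorrect": 1.1, "sigma": 0.55},
    "msgflike": {"mu_correct": 9.0, "mu_incorrect": 4.5, "sigma": 1.1},
}
_MOD_CHOICES = ("0:acetyl:+42.01", "0:trideutero_acetyl:+47.04", "")


def synth_psm_tables(
    library: PeptideLibrary,
    n_spectra: int = 5000,
    frac_incorrect: float = 0.3,
    engine_score_models: dict | None = None,
    dropout: float = 0.15,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Three-engine PSM tables with known correct/incorrect labels.

    Correct spectra match target peptides with scores from the high
    component; incorrect spectra match targets or decoys (50/50) with scores
    from the null component. Engines share a per-spectrum latent quality
    (scores correlate) with independent jitter, and each engine drops a
    spectrum with probability ``dropout``, creating engine-agreement
    partitions. XCorr-like engines report the latent scale directly; the
    e-value engine reports 10**(-latent). Returns ``(tables, truth)`` where
    ``tables`` maps engine name to a pandas DataFrame in the PSM TSV layout
    (written under ``out_dir`` when given).
    """
    import pandas as pd

    if not 0.0 <= frac_incorrect <= 1.0:
        raise ValueError("frac_incorrect must lie in [0, 1]")
    models = engine_score_models or DEFAULT_SCORE_MODELS
    rng = np.random.default_rng(seed)
    targets = sorted(library.targets)
    decoys = sorted(library.decoys)
    if not targets or not decoys:
        raise ValueError("library must contain targets and decoys")
    truth = SyntheticTruth()
    rows_by_engine: dict[str, list[dict]] = {e: [] for e in models}
    for i in range(n_spectra):
        sid = f"sp{i:06d}"
        incorrect = rng.random() < frac_incorrect
        if incorrect and rng.random() < 0.5:
            peptide, is_decoy = decoys[int(rng.integers(0, len(decoys)))], True
        else:
            peptide, is_decoy = targets[int(rng.integers(0, len(targets)))], False
        mods = _MOD_CHOICES[int(rng.integers(0, len(_MOD_CHOICES)))]
        latent = float(rng.normal(0.0, 1.0))
        from .psm_fdr import parse_mods

        truth.planted_psm_labels[(sid, peptide, parse_mods(mods))] = (
            "incorrect" if incorrect else "correct"
        )
        for engine, m in models.items():
            if rng.random() < dropout:
                continue
            mu = m["mu_incorrect"] if incorrect else m["mu_correct"]
            value = mu + m["sigma"] * (0.8 * latent + 0.6 * float(rng.normal(0.0, 1.0)))
            score = 10.0 ** (-value) if engine == "msgflike" else value
            rows_by_engine[engine].append(
                {
                    "spectrum_id": sid,
                    "peptide": peptide,
                    "mods": mods,
                    "score": score,
                    "decoy": int(is_decoy),
                }
            )
    tables = {e: pd.DataFrame(rows) for e, rows in rows_by_engine.items()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for engine, df in tables.items():
            df.to_csv(out / f"psms_{engine}.tsv", sep="\t", index=False)
    return tables, truth


# -- MAF alignments -----------------------------------------------------------

@dataclass
class SpeciesConfig:
    name: str
    sub_rate: float = 0.05
    gap_rate: float = 0.02
    fate_by_tis: dict[str, str] = field(default_factory=dict)  # tis tag -> fate
    protect_nt: int = 60  # prefix spared from frame-breaking edits


def _mutate_codon_safe(codon: str, pos_in_codon: int, rng: np.random.Generator) -> str:
    """Substitute one base of a codon without creating a stop codon."""
    for base in rng.permutation(list("ACGT")):
        if base == codon[pos_in_codon]:
            continue
        cand = codon[:pos_in_codon] + base + codon[pos_in_codon + 1 :]
        if cand not in STOP_CODONS:
            return cand
    return codon


def _near_cognate_replacement(start: str) -> str:
    return "GTG" if start == "CTG" else "CTG"


def synth_maf(
    genome: Sequence[Contig],
    tis_list: Sequence[GenomicInterval],
    species_configs: Sequence[SpeciesConfig],
    window_nt: int = 120,
    ref_species: str = "refsp",
    seed: int = 0,
    out_path: str | Path | None = None,
) -> tuple[str, SyntheticTruth]:
    """Pairwise MAF blocks around each TIS with planted start-codon fates.

    One block per (TIS, species) unless the fate is ``unaligned``. The query
    sequence is the reference window with substitutions (stop-codon-safe) at
    ``sub_rate``, codon-sized query insertions at ``gap_rate`` downstream of
    the start codon, and the fate applied to the start codon itself: keep
    (expected status canonical for ATG starts, near-cognate otherwise),
    near_cognate (ATG -> CTG style single substitution), destroy (-> CCG).
    Returns the MAF text (also written to ``out_path``) and the truth map.
    """
    by_id = {c.id: c for c in genome}
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    # plus-strand coordinates (0-based) of every listed start codon: spared
    # from background substitutions so overlapping windows of nearby TIS
    # cannot corrupt each other's planted fate
    protected: dict[str, set[int]] = {}
    for t in tis_list:
        protected.setdefault(t.contig_id, set()).update(
            range(t.start - 1, t.end)
        )
    lines = ["##maf version=1 scoring=synthetic"]
    for t_idx, tis in enumerate(tis_list):
        contig = by_id[tis.contig_id]
        n = len(contig)
        first = tis.start if tis.strand == "+" else tis.end
        for cfg in species_configs:
            fate = cfg.fate_by_tis.get(tis.tag(), "keep")
            if fate == "unaligned":
                truth.planted_conservation[(tis.tag(), cfg.name)] = "unaligned"
                continue
            if tis.strand == "+":
                lo0 = first - 1
                hi0 = min(n, lo0 + window_nt)
                plus_segment = contig.sequence[lo0:hi0]
                t_ref = plus_segment
            else:
                hi0 = first  # exclusive end on plus strand, 0-based
                lo0 = max(0, hi0 - window_nt)
                plus_segment = contig.sequence[lo0:hi0]
                t_ref = revcomp(plus_segment)
            start_codon = t_ref[:3]
            if fate == "keep":
                new_start = start_codon
                expected = "canonical" if start_codon == "ATG" else "near_cognate"
            elif fate == "near_cognate":
                new_start = (
                    _near_cognate_replacement(start_codon)
                    if start_codon != "ATG"
                    else "CTG"
                )
                expected = "near_cognate"
            elif fate == "destroy":
                new_start = "CCG"
                expected = "absent"
            else:
                raise ValueError(f"unknown fate {fate!r}")
            truth.planted_conservation[(tis.tag(), cfg.name)] = expected
            # build transcript-oriented gapped rows
            ref_cols: list[str] = []
            qry_cols: list[str] = []
            ref_cols.extend(t_ref[:3])
            qry_cols.extend(new_start)
            guarded = protected.get(tis.contig_id, set())
            i = 3
            while i < len(t_ref):
                codon = t_ref[i : i + 3]
                if tis.strand == "+":
                    plus_span = range(lo0 + i, lo0 + i + 3)
                else:
                    plus_span = range(hi0 - i - 3, hi0 - i)
                untouchable = any(p in guarded for p in plus_span)
                if len(codon) == 3 and not untouchable and rng.random() < cfg.sub_rate:
                    j = int(rng.integers(0, 3))
                    codon_q = _mutate_codon_safe(codon, j, rng)
                else:
                    codon_q = codon
                ref_cols.extend(codon)
                qry_cols.extend(codon_q)
                if len(codon) == 3 and i >= 3 and rng.random() < cfg.gap_rate:
                    ins = SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))]
                    ref_cols.extend("---")
                    qry_cols.extend(ins)
                i += 3
            t_ref_gapped = "".join(ref_cols)
            t_qry_gapped = "".join(qry_cols)
            if tis.strand == "-":
                t_ref_gapped = revcomp(t_ref_gapped)
                t_qry_gapped = revcomp(t_qry_gapped)
            ref_size = len(t_ref_gapped) - t_ref_gapped.count("-")
            qry_size = len(t_qry_gapped) - t_qry_gapped.count("-")
            lines.append("")
            lines.append("a score=0.0")
            lines.append(
                f"s {ref_species}.{tis.contig_id} {lo0} {ref_size} + {n} {t_ref_gapped}"
            )
            lines.append(
                f"s {cfg.name}.q{t_idx}_{cfg.name} 0 {qry_size} + {qry_size} {t_qry_gapped}"
            )
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text, truth
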