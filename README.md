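# ntpg — N-terminal proteogenomics toolkit

`ntpg` implements a proteogenomic pipeline specialised for N-terminomics
(positional proteomics) data, aimed at discovering translation initiation
sites (TIS) that are missing from genome annotation. Instead of searching
MS/MS spectra against full-length six-frame translations — the classic
"needle in a haystack" problem — it builds databases containing only the
peptides an N-terminal enrichment experiment can actually observe: protein
N termini.

It is written for computational proteomics / plant genomics researchers who
want to run or study each stage of such a pipeline in isolation, on real
files (FASTA, GFF3/GTF, TSV PSM tables, BED, MAF) or on fully synthetic,
seeded inputs generated by the built-in `ntpg.fixtures` module.

## What it does

1. **ORF discovery** (`orf_discovery`): six-frame enumeration of start-to-stop
   ORFs from canonical (ATG) and near-cognate (CTG, GTG) start codons — all
   decoded to initiator methionine — with a ≥ 8 aa product floor, plus
   downstream-AUG truncations and spliced *ab initio* gene models (e.g.
   Augustus GTF) with per-residue genomic back-mapping.
2. **Nt-peptide libraries** (`ntpep_library`): protease-specific digestion
   of every ORF's N terminus (ArgC-like trypsin: cleave after R only, since
   lysines are acetylated by the labelling chemistry; GluC after D/E;
   chymotrypsin after F/W/Y/L/M; AspN before D), peptides of 8–30 aa,
   N-terminal methionine excision (iMet removed when residue 2 ∈
   {A,C,G,P,S,T,V}), subtraction of reference proteome + contaminants with
   I/L treated as indistinguishable, and reversed-sequence decoys.
3. **Multi-engine FDR** (`psm_fdr`): per-engine FDR scores (target-decoy
   q-values anchored at decoy ranks, interpolated in rank), combined FDR
   scores per engine-agreement partition, and the multistage filter
   (individual ≤ 0.01 **or** combined ≤ 0.01, safeguarded by ≥ 1 engine
   ≤ 0.05; novel identifications additionally need ≥ 2 engines).
4. **N-terminus annotation** (`nt_annotation`): modification-state classes
   (in vivo acetyl +42.01 Da vs. in vitro trideutero-acetyl +47.04 Da vs.
   free vs. pyroglutamate −17.03 Da), NME-compliance of the observed start
   position, TIS category against annotation (protein-coding > transposable
   element > pseudogene > intergenic), ribo-seq TIS matching, and the
   stratified spectral-correlation (MS²PIP-style) median threshold.
5. **TIS context scoring** (`tis_context`): integer-percent nucleotide
   frequency matrix at positions −5..+4 around non-redundant annotated start
   codons; a context's score is the sum of the six percents at −5..−1 and
   +4 (range 0–600).
6. **Conservation** (`conservation`): from pairwise MAF genome alignments,
   whether a TIS start codon is conserved (canonical / near-cognate /
   absent / unaligned) in another species and whether the aligned sequence
   still encodes an orthologous N-terminal peptide of the identified length.
7. **Synthetic data** (`fixtures`): seeded generators for genomes with
   planted ORFs and annotation, three-engine PSM tables with known
   correct/incorrect labels, and MAF alignments with planted start-codon
   fates — every stage is testable without downloads.

## Worked example

```bash
python examples/01_build_nt_peptide_library.py
```

```
six-frame ORFs: 4012, downstream-AUG truncations: 1285
targets: 2924, decoys: 2924
example target: AAAVDSLCR (start position 2, 1 genomic TIS)
```

On a seeded 2×30 kb synthetic genome with 25 planted ORFs, 4012 six-frame
ORFs and 1285 internal-AUG truncations yield 2924 non-redundant candidate
N-terminal peptides after reference subtraction, each paired with a decoy.
The example target starts at protein position 2 — its initiator methionine
was removed because residue 2 (A) has a small gyration radius — and maps to
a single genomic TIS.

The context-scoring example prints the frequency-sum arithmetic:

```bash
python examples/04_tis_context_score.py
```

```
score(AAAAAATGG) = 266
```

i.e. 33 + 45 + 49 + 42 + 43 (A at −5..−1) + 54 (G at +4) = 266, the score of
the most frequent — and therefore highest-scoring — Arabidopsis TIS context.
The other `examples/` scripts exercise FDR aggregation, N-terminus
annotation, and conservation calling the same way, each printing what it
computes and what the numbers mean.

There is also a thin CLI (`ntpg build-library | score | annotate | context |
conserve | simulate`) over the same functions.

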