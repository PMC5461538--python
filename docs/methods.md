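# Methods

This note records the models implemented by `ntpg`, the parameter choices
that matter, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## Coordinate model and sequence handling

All genomic coordinates are 1-based inclusive with an explicit strand (the
GFF convention); BED export converts to 0-based half-open. Genome sequences
are uppercased on ingest and IUPAC ambiguity codes other than A/C/G/T map to
N. A codon containing N translates to X; X-containing peptides are excluded
at the library stage, so ORF enumeration itself stays annotation- and
ambiguity-agnostic. Stop codons are the nuclear TAA/TAG/TGA set; organellar
codes are out of scope.

## ORF enumeration

Six-frame ORFs run from every occurrence of a start codon (default set
{ATG, CTG, GTG}; near-cognate starts are decoded to initiator Met) to the
first in-frame stop on the same contig. Every start is emitted, including
nested starts sharing a stop — redundancy is resolved later at the peptide
level, where identical sequences merge. ORFs whose frame runs off the contig
end without a stop are dropped: an ORF must be delimited by its stop codon.
The product floor is 8 amino acids excluding the stop (equivalently a
24-nucleotide coding span). Downstream truncations re-initiate only at
internal in-frame ATG codons of six-frame parents; near-cognate codons
nucleate primary ORFs but not truncations. Spliced model ORFs keep a
per-nucleotide map from coding position to genomic coordinate so that a
peptide spanning a splice junction can be placed on the genome as two (or
more) intervals.

## Nt-peptide libraries

Protease specificities (cleavage side, residue set, missed-cleavage caps)
are fixed per enzyme: trypsin behaves ArgC-like (after R only) because
lysine side chains are blocked by the in vitro acetylation; GluC after D/E;
chymotrypsin after F/W/Y/L/M; AspN before D. Library construction allows 0
missed cleavages for ArgC and 1 for the other three (the larger caps of 2/3
used in reference-proteome search settings are stored on the same spec).
A missed-cleavage count of k means the peptide spans k internal cleavage
boundaries; for cleave-before enzymes a boundary at the peptide's own first
residue does not count.

From each ORF protein, peptides run from position 1 through the (k+1)-th
boundary for k = 0..max_missed. When residue 2 has a small gyration radius
(A, C, G, P, S, T, V) the same series is *additionally* emitted from
position 2 with the iMet removed — both forms are kept, since either may be
observed. A protein whose C terminus arrives before the next boundary is
admitted whole (flagged `cterm_is_protein_end`); without this rule, short
near-cognate ORF products would be unrepresentable. All peptides are
length-filtered to 8–30 aa and must be X-free.

Reference subtraction removes any peptide whose I/L-collapsed sequence
occurs as a substring of an I/L-collapsed reference or contaminant protein
(Ile and Leu are isobaric and indistinguishable to the spectrometer; stored
sequences keep the genomic translation). Decoys are per-peptide sequence
reversals — the downstream search is run with "no cleavage" settings, so
the search statistics live at the peptide level and peptide-level decoys
preserve them; a decoy colliding with a target or reference sequence is
re-derived by seeded shuffling (bounded attempts, pair dropped on failure).
Library construction is deterministic given inputs and seed.

## FDR score and combined FDR score

Per engine, PSMs (one best hit per spectrum, chosen direction-aware:
XCorr-like scores higher-better, e-value lower-better) are ranked best
first, decoys after targets on raw-score ties (conservative). The per-rank
false discovery proportion is #decoys / max(1, #targets), capped at 1, and
is converted to q-values by a running minimum from the worst rank upward —
this makes the decoy-rank anchor values identical to a brute-force
threshold-sweep q-value oracle. Target PSMs between anchors are linearly
interpolated in rank; PSMs ranked before the first anchor score 0 and PSMs
after the last anchor inherit its value. Rank (not raw score) is the
interpolation domain because it is scale-free across engines; exact
raw-score ties are ordered targets-first and otherwise keep their
positional ranks, which only matters on discrete score scales.

PSM keys are (spectrum, peptide, modifications), so in vivo and in vitro
acetylated forms of one peptide are distinct identifications. Keys reported
by ≥ 2 engines are pooled per engine-agreement partition; the arithmetic
mean of the engine FDR scores re-ranks the partition and the anchored
estimator is re-applied to the partition's own target/decoy labels. This
re-estimation is the point of the combined score: engine-agreement subsets
are strongly enriched for correct matches and may contain few or no decoys,
in which case a partition-level estimate (0 when decoy-free) is the honest
one. Partitions smaller than 10 keys are flagged in the output rather than
merged upward. The multistage filter keeps a PSM when its best individual
FDR score is ≤ 0.01 or its combined FDR score is ≤ 0.01, provided at least
one engine scored it ≤ 0.05; spectra with no retained PSM form the input of
the novel search, whose PSMs must additionally be found by ≥ 2 engines.

## N-terminus classes, NME, TIS placement

The modification catalog is fixed: trideutero-acetyl +47.04 Da (N terminus
variable, lysine fixed), acetyl +42.01 Da (N terminus variable),
carbamidomethyl +57.02 Da (Cys fixed), oxidation +15.99 Da (Met fixed),
pyroglutamate −17.03 Da (N-terminal Gln variable); deltas are matched at
±0.02 Da. An N-terminal +42.01 means in vivo acetylation, +47.04 means the
terminus was free in the cell and blocked in vitro, no N-terminal
modification means free, and out-of-catalog N-terminal deltas raise.

NME compliance uses the methionine-aminopeptidase specificity rule only: a
position-2 start is compliant iff residue 2 ∈ {A,C,G,P,S,T,V}, a position-1
start iff it is not. Acetylation-propensity prediction (as in dedicated NME
predictors) is deliberately not reimplemented; the observed modification
carries that information. TIS categorisation intersects the 3-nt start
codon with transcript exon footprints, strand-agnostic (an antisense TIS
inside a gene still counts as intragenic), with the priority protein-coding
> transposable element > pseudogene when biotypes overlap; a gene-footprint
variant is exposed as a flag. Ribo-seq support means an initiation call on
the same contig and strand within a configurable tolerance (default 0 nt)
of the TIS first base. The spectral-correlation filter stratifies PSMs by
(tryptic?, charge) and flags a novel PSM high when its correlation is ≥ the
median of the annotated-peptide distribution of its stratum; a peptide is
high-correlation when at least one of its PSMs is.

## TIS context score

The frequency matrix covers nine positions −5..−1, +1..+4 (there is no
position 0; +1 is the first base of the start codon). Start codons shared
by alternative transcripts — identical (contig, first base, strand) — count
once; windows overhanging the contig are skipped. Frequencies are percents
rounded to the nearest integer *before* summation, which reproduces the
published integer arithmetic exactly (e.g. 33+45+49+42+43+54 = 266 for
AAAAAATGG); an unrounded variant is available via `use_raw`. A context's
score sums the entries of its bases at −5..−1 and +4, so the start codon
identity never contributes and scores lie in 0–600. Callers pass the first
start codon's context for proteins beginning with consecutive methionines,
and multi-locus peptides are reported unscored — only the peptide and its
ORF know these facts, so the responsibility sits with the caller.

## Conservation in MAF alignments

For a TIS, the first alignment block (by reference start coordinate) whose
plus-strand reference row covers the start codon's first base is selected;
the query row is read from that column to the block end (for minus-strand
TIS: from the block start to the column, reverse-complemented) with query
gaps removed. Blocks are never stitched, so an ORF truncated at a block
edge conservatively counts as not encoding the peptide. The near-cognate
set defaults to all nine single-substitution neighbours of ATG, with a
restriction flag for {CTG, GTG}. Orthologous-peptide capacity translates
the query in frame from the conserved start (initiator → Met) until a stop
or the sequence end and requires at least the identified peptide's length
(or its first-exon portion for junction-spanning peptides, supplied by the
caller).

## Synthetic data

`synth_genome` plants non-overlapping start-to-stop ORFs (default 10–35 aa,
start codons 70% ATG / 15% CTG / 15% GTG) into i.i.d. uniform background on
both strands, optionally forcing A-rich −5..−1 contexts (default bias 0.8,
emulating the adenine preference upstream of efficient plant TIS), and
wraps a configurable fraction in protein-coding, transposable-element or
pseudogene annotation, leaving the rest intergenic. `synth_psm_tables`
draws correct matches from library targets with a high-scoring Normal
component and incorrect matches (default 30%) from targets and decoys in
equal shares with a null component; engines share a per-spectrum latent
quality (correlation ≈ 0.64) with independent jitter and 15% dropout,
giving realistic engine-agreement partitions; the e-value engine reports
10^(−latent). `synth_maf` writes one pairwise block per (TIS, species) with
a planted start-codon fate, stop-codon-safe substitutions, codon-sized
query insertions, and all listed start codons shielded from background
substitutions so overlapping windows of nearby TIS cannot corrupt each
other's fate.

What the generators do **not** emulate: real fragmentation spectra,
retention times or intensity-dependent score distributions; sequence
composition biases of real genomes (GC content, repeats, isochores);
transcription-driven splice structures (spliced models are planted, not
inferred); indel-rich or rearranged alignments. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under the
stated generative assumptions, not end-to-end performance on real MS data.

## Problem sizes and determinism

The test suite exercises the digestion oracle on a 2×50 kb genome with 50
planted ORFs (≈ 6,700 six-frame ORFs, ≈ 5,000 ArgC targets), six-frame
enumeration against exhaustive brute force on 500 random 2 kb contigs, and
FDR calibration on 20,000 synthetic PSMs at 30% incorrect matches — sizes
chosen so each property is measured with comfortable statistical resolution
while the whole suite runs in seconds. Every stochastic component takes an
explicit integer seed (numpy `default_rng` or `random.Random`), and all
generators are byte-deterministic under a fixed seed.

## Known limitations

* Internal (position > 2) peptides and proteolytic neo-N-termini are out of
  scope by design; the library represents translation initiation only.
* The biotype mapping from GFF3/GTF attributes is a convention
  (`biotype`/`gene_biotype` attribute, else feature type); annotation
  sources with other encodings need a preprocessing pass.
* Combined-FDR partitions with very few PSMs have noisy estimates; they are
  flagged, not suppressed.
* MAF handling assumes plus-strand reference rows (the usual export
  convention for reference-anchored pairwise alignments).
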