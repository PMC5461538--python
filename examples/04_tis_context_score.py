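"""Score TIS sequence contexts with the summed-frequency method.

The matrix holds integer-percent nucleotide frequencies at positions -5..+4
around non-redundant annotated start codons; a context's score sums the six
percents at -5..-1 and +4 (the start codon itself never contributes), so the
consensus context attains the matrix's maximum score.
"""

from ntpg import build_frequency_matrix, score_context
from ntpg.fixtures import synth_genome
from ntpg.tis_context import NUCLEOTIDES, POSITIONS, TisFrequencyMatrix

# with the published component percents the context AAAAAATGG scores 266
freq = {}
published_a = {-5: 33, -4: 45, -3: 49, -2: 42, -1: 43}
for pos in POSITIONS:
    anchor_nt = "G" if pos == 4 else "A"
    anchor = published_a.get(pos, 54 if pos == 4 else 25)
    rest = 100 - anchor
    freq[(pos, anchor_nt)] = anchor
    others = [nt for nt in NUCLEOTIDES if nt != anchor_nt]
    for i, nt in enumerate(others):
        freq[(pos, nt)] = rest // 3 + (1 if i < rest % 3 else 0)
matrix = TisFrequencyMatrix(freq=freq, n_sites=100)
print("score(AAAAAATGG) =", score_context("AAAAAATGG", matrix).score)

# matrix built from a genome with A-rich planted contexts
fx = synth_genome(n_contigs=2, contig_len=25_000, n_orfs=20, context_bias=0.9, seed=12)
built = build_frequency_matrix(
    [(o.tis, o.orf_id) for o in fx.truth.planted_orfs], fx.contigs
)
print(f"matrix from {built.n_sites} planted TIS; consensus {built.consensus()}")
print("consensus score =", score_context(built.consensus(), built).score,
      "(= matrix maximum", built.max_score(), ")")
# A-rich planted contexts push the consensus toward A at -5..-1, mirroring
# the adenine preference upstream of efficient plant start codons.
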