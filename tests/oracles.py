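"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: ORF enumeration is a
naive per-position codon walk, digestion is a quadratic scan over all
(start, end) pairs, and q-values come from an explicit threshold sweep.
"""

from __future__ import annotations

STOPS = {"TAA", "TAG", "TGA"}
CODONS = {}


def _codon_table():
    if CODONS:
        return CODONS
    from Bio.Seq import Seq

    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                codon = a + b + c
                CODONS[codon] = "*" if codon in STOPS else str(Seq(codon).translate())
    return CODONS


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def brute_force_orfs(contig_seq: str, starts: set[str], min_aa: int):
    """Every start-to-stop ORF as (strand, g_start, g_end, protein), 1-based.

    Walks from every position of both strands independently of frame
    bookkeeping; coordinates are the coding span excluding the stop codon.
    """
    table = _codon_table()
    results = set()
    n = len(contig_seq)
    for strand in "+-":
        seq = contig_seq if strand == "+" else _revcomp(contig_seq)
        for s in range(n - 2):
            if seq[s : s + 3] not in starts:
                continue
            aas = []
            stopped = False
            e = s
            for p in range(s, n - 2, 3):
                codon = seq[p : p + 3]
                if codon in STOPS:
                    stopped = True
                    e = p
                    break
                aas.append(table.get(codon, "X"))
            if not stopped or len(aas) < min_aa:
                continue
            protein = "M" + "".join(aas[1:])
            if strand == "+":
                g_start, g_end = s + 1, e
            else:
                g_start, g_end = n - e + 1, n - s
            results.add((strand, g_start, g_end, protein))
    return results


def brute_force_digest(protein: str, cleave_side: str, residues: set[str],
                       max_missed: int, len_min: int = 8, len_max: int = 30):
    """All Nt-peptide sequences of one protein by quadratic enumeration."""
    assert protein[0] == "M"
    small = set("ACGPSTV")
    starts = [1]
    if len(protein) >= 2 and protein[1] in small:
        starts.append(2)
    n = len(protein)
    out = set()
    for start in starts:
        if cleave_side == "after":
            bset = {p for p in range(start, n + 1) if protein[p - 1] in residues}
        else:
            bset = {q - 1 for q in range(start + 1, n + 1) if protein[q - 1] in residues}
        for end in range(start, n + 1):
            if end not in bset and end != n:
                continue
            missed = sum(1 for b in bset if b < end)
            if missed > max_missed:
                continue
            pep = protein[start - 1 : end]
            if len_min <= len(pep) <= len_max and "X" not in pep:
                out.add(pep)
    return out


def collapse_il(seq: str) -> str:
    return seq.replace("I", "J").replace("L", "J")


def brute_force_library(proteins, cleave_side, residues, max_missed,
                        reference_proteins, len_min: int = 8, len_max: int = 30):
    """Non-redundant target peptide set after reference subtraction."""
    peptides = set()
    for protein in proteins:
        peptides |= brute_force_digest(
            protein, cleave_side, residues, max_missed, len_min, len_max
        )
    refs = [collapse_il(r) for r in reference_proteins]
    return {
        p for p in peptides if not any(collapse_il(p) in r for r in refs)
    }


def sweep_qvalues(decoy_flags):
    """q-values by explicit threshold sweep over a best-first ranked list."""
    n = len(decoy_flags)
    fdp = []
    for r in range(1, n + 1):
        d = sum(decoy_flags[:r])
        t = r - d
        fdp.append(min(1.0, d / max(1, t)))
    return [min(fdp[i:]) for i in range(n)]


def naive_aligned_query(ref_gapped: str, query_gapped: str, offset: int):
    """Query subsequence aligned from the reference's ``offset``-th base.

    Per-column walk: advance a reference base counter column by column and
    collect query bases from the first column holding reference base
    ``offset`` (0-based) onward.
    """
    seen = -1
    out = []
    collecting = False
    for rc, qc in zip(ref_gapped, query_gapped):
        if rc != "-":
            seen += 1
            if seen == offset:
                collecting = True
        if collecting and qc != "-":
            out.append(qc)
    return "".join(out) if collecting else None
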