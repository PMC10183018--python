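"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own interval algebra and codon
machinery: ZCRs are found by a literal per-base scan over numpy masks, and
codon effects come from a hand-frozen standard genetic code table.
"""

from __future__ import annotations

import numpy as np

# standard genetic code, written out by hand (stop = '*')
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def codon_effect(codon: str, position: int, alt_base: str) -> str:
    """'synonymous' or 'nonsynonymous' for one substituted codon base."""
    new_codon = codon[:position] + alt_base + codon[position + 1:]
    return (
        "synonymous"
        if CODON_TABLE[codon] == CODON_TABLE[new_codon]
        else "nonsynonymous"
    )


def perbase_zcrs(
    chrom_length: int,
    covered: list[tuple[int, int, float]],
    gaps: list[tuple[int, int]],
    min_length: int,
) -> list[tuple[int, int]]:
    """Literal per-base scan: mask gaps, collect maximal zero runs, filter.

    Gap bases terminate runs (non-bridging semantics).
    """
    depth = np.zeros(chrom_length)
    for start, end, value in covered:
        depth[start:end] += value
    gap_mask = np.zeros(chrom_length, dtype=bool)
    for start, end in gaps:
        gap_mask[start:end] = True
    runs = []
    run_start = None
    for pos in range(chrom_length):
        zero_here = depth[pos] == 0 and not gap_mask[pos]
        if zero_here and run_start is None:
            run_start = pos
        elif not zero_here and run_start is not None:
            runs.append((run_start, pos))
            run_start = None
    if run_start is not None:
        runs.append((run_start, chrom_length))
    return [(s, e) for s, e in runs if e - s >= min_length]


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    from math import comb

    total = comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        if n - j > N - K:
            continue
        acc += comb(K, j) * comb(N - K, n - j)
    return acc / total
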