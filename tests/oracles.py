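"""Independent brute-force oracles used to check the package's operations.

These are deliberately naive re-implementations (quadratic dynamic
programming, factorial enumeration, flatten-and-correlate) kept separate
from the package so that agreement is a genuine dual-route check.
"""

from math import comb

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Affine-gap local alignment score by the Gotoh recursion.

    A gap of length L costs gap_open + L * gap_extend (the BLAST
    convention), so opening a gap charges gap_open + gap_extend at once.
    """
    la, lb = len(a), len(b)
    NEG = -10**9
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    E = np.full((la + 1, lb + 1), NEG, dtype=np.int64)  # gap in a (up)
    F = np.full((la + 1, lb + 1), NEG, dtype=np.int64)  # gap in b (left)
    best = 0
    open_cost = gap_open + gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i, j] = max(H[i - 1, j] - open_cost, E[i - 1, j] - gap_extend)
            F[i, j] = max(H[i, j - 1] - open_cost, F[i, j - 1] - gap_extend)
            sub = int(_BLOSUM62[a[i - 1], b[j - 1]])
            H[i, j] = max(0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            if H[i, j] > best:
                best = int(H[i, j])
    return best


_CODON_TABLE = {
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


def translate_frame1(nt: str) -> str:
    """Frame +1 translation by direct codon-table lookup."""
    nt = nt.upper().replace("U", "T")
    return "".join(_CODON_TABLE.get(nt[i : i + 3], "X")
                   for i in range(0, len(nt) - len(nt) % 3, 3))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact summation of the hypergeometric pmf."""
    denom = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / denom


def hypergeom_pmf_sum(K: int, n: int, N: int) -> float:
    denom = comb(N, n)
    lo, hi = max(0, n - (N - K)), min(K, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(lo, hi + 1)) / denom


def flatten_and_correlate(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of the strict upper triangles of two matrices."""
    iu = np.triu_indices(x.shape[0], k=1)
    return float(np.corrcoef(x[iu], y[iu])[0, 1])


def brute_force_lca_ranking(tree, query, candidates):
    """Rank candidates by LCA depth via explicit lineage-prefix comparison."""
    from mss.taxonomy import lineage

    qpath = lineage(tree, query).path
    scored = []
    for c in candidates:
        cpath = lineage(tree, c).path
        depth = sum(1 for a, b in zip(qpath, cpath) if a == b) - 1
        scored.append((c, depth))
    return sorted(scored, key=lambda cd: (-cd[1], cd[0]))
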