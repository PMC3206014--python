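"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by direct enumeration or naive dynamic
programming, sharing no code path with the package implementation it
checks.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _tr(codon: str) -> str:
    return str(Seq(codon).translate())


# --- NG86 pathway-enumeration oracle ---------------------------------------


def syn_sites_oracle(codon: str) -> float:
    """Synonymous site count of one codon by direct mutation enumeration."""
    aa = _tr(codon)
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            if _tr(codon[:pos] + alt + codon[pos + 1:]) == aa:
                syn += 1
    return syn / 3.0


def _step_class(c1: str, c2: str) -> tuple[int, int]:
    """(syn, nonsyn) for a single-nucleotide step; stop involvement is nonsyn."""
    a1, a2 = _tr(c1), _tr(c2)
    if a1 == a2 and a1 != "*":
        return 1, 0
    return 0, 1


def path_diffs_oracle(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) substitution counts over all mutation pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    s_tot = n_tot = 0
    paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        s = n = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            ds, dn = _step_class(cur, nxt)
            s += ds
            n += dn
            cur = nxt
        s_tot += s
        n_tot += n
        paths += 1
    return s_tot / paths, n_tot / paths


def kaks_oracle(a: str, b: str) -> tuple[float, float]:
    """(Ka, Ks) for a codon-aligned gap/stop-free pair, all by enumeration."""
    assert len(a) == len(b) and len(a) % 3 == 0
    S = Sd = Nd = 0.0
    n_codons = len(a) // 3
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        S += (syn_sites_oracle(ca) + syn_sites_oracle(cb)) / 2.0
        ds, dn = path_diffs_oracle(ca, cb)
        Sd += ds
        Nd += dn
    N = 3.0 * n_codons - S

    def jc(p):
        return math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(Nd / N) if N else 0.0, jc(Sd / S) if S else 0.0


# --- affine-gap Smith-Waterman oracle --------------------------------------


def sw_affine_score(
    a: str, b: str, match=5.0, mismatch=-4.0, gap_open=12.0, gap_extend=3.0
) -> float:
    """Optimal local alignment score, naive O(nm) three-matrix DP.

    Gap convention: a gap of length k costs gap_open + (k-1)*gap_extend.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                                       Iy[i - 1][j - 1]))
            best = max(best, M[i][j])
    return best


def sw_protein_coverage(
    query: str, target: str, gap_open=11.0, gap_extend=1.0
) -> float:
    """Fraction of ``query`` residues inside the best local protein alignment.

    Naive affine SW over BLOSUM62 with traceback of the best-scoring cell;
    the coverage is (query span of the alignment) / len(query).
    """
    NEG = float("-inf")
    n, m = len(target), len(query)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    start = [[(0, 0)] * (m + 1) for _ in range(n + 1)]
    sx = [[(0, 0)] * (m + 1) for _ in range(n + 1)]
    sy = [[(0, 0)] * (m + 1) for _ in range(n + 1)]
    best, best_cell = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            try:
                s = _BLOSUM62[target[i - 1], query[j - 1]]
            except (KeyError, IndexError):
                s = -4.0
            if M[i - 1][j] - gap_open >= Ix[i - 1][j] - gap_extend:
                Ix[i][j], sx[i][j] = M[i - 1][j] - gap_open, start[i - 1][j]
            else:
                Ix[i][j], sx[i][j] = Ix[i - 1][j] - gap_extend, sx[i - 1][j]
            if M[i][j - 1] - gap_open >= Iy[i][j - 1] - gap_extend:
                Iy[i][j], sy[i][j] = M[i][j - 1] - gap_open, start[i][j - 1]
            else:
                Iy[i][j], sy[i][j] = Iy[i][j - 1] - gap_extend, sy[i][j - 1]
            prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            if prev == M[i - 1][j - 1]:
                org = start[i - 1][j - 1]
            elif prev == Ix[i - 1][j - 1]:
                org = sx[i - 1][j - 1]
            else:
                org = sy[i - 1][j - 1]
            val = s + prev
            if val <= 0.0:
                M[i][j], start[i][j] = 0.0, (i, j)
            else:
                M[i][j], start[i][j] = val, org if prev > 0 else (i - 1, j - 1)
            if M[i][j] > best:
                best, best_cell = M[i][j], (i, j)
    if best_cell is None or m == 0:
        return 0.0
    i, j = best_cell
    j0 = start[i][j][1]
    return (j - j0) / m


# --- PWM rescoring oracle ---------------------------------------------------

_RC = str.maketrans("ACGT", "TGCA")


def pwm_hits_oracle(seq: str, log_odds, min_score: float, max_score: float,
                    threshold: float) -> set[tuple[int, str]]:
    """All (position, strand) with relative score >= threshold, re-scored naively."""
    L = log_odds.shape[1]
    idx = {b: k for k, b in enumerate("ACGT")}
    out = set()
    span = max_score - min_score
    for strand in ("+", "-"):
        s = seq if strand == "+" else seq.translate(_RC)[::-1]
        for i in range(len(s) - L + 1):
            raw = sum(log_odds[idx[s[i + j]], j] for j in range(L))
            if (raw - min_score) / span >= threshold:
                pos = i if strand == "+" else len(seq) - L - i
                out.add((pos, strand))
    return out


# --- brute-force small parsimony --------------------------------------------


def parsimony_score_oracle(tree, msa: dict[str, str]) -> int:
    """Minimum changes over all ancestral labelings, enumerated exhaustively.

    ``tree`` is a dendropy Tree with <=6 leaves; the state space per column
    is the set of characters present in that column (sufficient for the
    minimum under uniform cost).
    """
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    edges = []
    for nd in tree.preorder_node_iter():
        for child in nd.child_nodes():
            edges.append((nd, child))
    length = len(next(iter(msa.values())))
    total = 0
    for col in range(length):
        leaf_state = {}
        for leaf in tree.leaf_node_iter():
            leaf_state[id(leaf)] = msa[leaf.taxon.label][col]
        states = sorted(set(leaf_state.values()))
        best = None
        for combo in itertools.product(states, repeat=len(internals)):
            assign = {id(nd): s for nd, s in zip(internals, combo)}
            assign.update(leaf_state)
            cost = sum(
                1 for p, c in edges if assign[id(p)] != assign[id(c)]
            )
            if best is None or cost < best:
                best = cost
        total += best
    return total
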