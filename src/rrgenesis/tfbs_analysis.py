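"""PWM scanning, ancestral reconstruction and regulatory-potential statistics.

The downstream question for a recycled region is whether it gained
transcription-factor binding sites (TFBSs) in the teleost lineage after the
duplication.  The toolkit here mirrors the classic workflow:

* JASPAR-format position frequency matrices are turned into log-odds PWMs
  and scanned at a *relative* score threshold (default 80% of the matrix's
  min–max score range, both strands);
* the ancestral sequence at an internal node of the species tree is
  reconstructed by Fitch parsimony on the alignment columns (IUPAC codes for
  ambiguous columns);
* binding sites are called lineage-specific when present in every teleost
  sequence and absent from all other vertebrates *and* from the
  reconstructed ancestor (any disambiguation of an ambiguous ancestor that
  reaches the threshold counts as present);
* S200 (binding sites per 200 bp) summarises a sequence set, and the
  histogram-overlap of two S200 distributions gives a "regulatory
  potential" percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import motifs as bio_motifs

from .errors import ConfigurationError, InputError, PreconditionError

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: IUPAC nucleotide code -> set of bases
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items()}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """A position weight matrix with its log-odds form and score range."""

    matrix_id: str
    name: str
    counts: np.ndarray  # shape (4, L), rows A, C, G, T
    log_odds: np.ndarray = field(init=False)
    min_score: float = field(init=False)
    max_score: float = field(init=False)
    background: np.ndarray = field(default=None)
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise InputError(f"{self.matrix_id}: counts must be a 4xL matrix")
        if (self.counts < 0).any():
            raise InputError(f"{self.matrix_id}: negative counts")
        col_sums = self.counts.sum(axis=0)
        if (col_sums <= 0).any():
            raise InputError(f"{self.matrix_id}: zero-sum column in PFM")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ConfigurationError("background probabilities must sum to 1")
        # pseudocount distributed by background (per column), then log2 odds
        probs = (self.counts + self.pseudocount * self.background[:, None]) / (
            col_sums + self.pseudocount
        )
        self.log_odds = np.log2(probs / self.background[:, None])
        self.min_score = float(self.log_odds.min(axis=0).sum())
        self.max_score = float(self.log_odds.max(axis=0).sum())

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def informative(self) -> bool:
        return self.max_score > self.min_score

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))

    @property
    def anticonsensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds.argmin(axis=0))


def load_pwms(path, background=None, pseudocount: float = 0.8) -> list[PWM]:
    """Read JASPAR PFM text into PWMs; uninformative (flat) matrices are skipped."""
    pwms = []
    with open(path) as fh:
        for motif in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([motif.counts[b] for b in _BASES], dtype=float)
            pwm = PWM(
                matrix_id=motif.matrix_id or motif.name,
                name=motif.name or motif.matrix_id,
                counts=counts,
                background=background,
                pseudocount=pseudocount,
            )
            if not pwm.informative:
                warnings.warn(
                    f"PWM {pwm.matrix_id} is uninformative (flat score range); skipped"
                )
                continue
            pwms.append(pwm)
    return pwms


def write_pwms(pwms: list[PWM], path) -> None:
    """Write PWMs back to JASPAR PFM text (counts only)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.matrix_id} {pwm.name}\n")
            for i, base in enumerate(_BASES):
                vals = " ".join(f"{v:.0f}" for v in pwm.counts[i])
                fh.write(f"{base} [ {vals} ]\n")


@dataclass
class TFBSHit:
    """One PWM match on one sequence."""

    matrix_id: str
    sequence_id: str
    position: int  # 0-based start on the forward strand of the scanned sequence
    strand: str
    score: float
    rel_score: float
    aligned_start: int | None = None  # alignment-column interval, when scanned via an MSA
    aligned_end: int | None = None

    def overlaps(self, other: "TFBSHit") -> bool:
        """Same matrix and >=1 shared aligned column (or raw position overlap)."""
        if self.matrix_id != other.matrix_id:
            return False
        if self.aligned_start is not None and other.aligned_start is not None:
            return self.aligned_start < other.aligned_end and other.aligned_start < self.aligned_end
        return self.position == other.position and self.strand == other.strand


def _window_score(window: str, pwm: PWM) -> float:
    """Log-odds score of one window; ambiguous bases score as the best disambiguation."""
    total = 0.0
    for j, base in enumerate(window):
        allowed = IUPAC.get(base.upper())
        if allowed is None:
            allowed = IUPAC["N"]
        total += max(pwm.log_odds[_BASE_INDEX[b], j] for b in allowed)
    return total


def scan_pwm(
    sequence: str,
    pwm: PWM,
    rel_threshold: float = 0.8,
    sequence_id: str = "",
) -> list[TFBSHit]:
    """Scan both strands of ``sequence``; report hits at relative score >= threshold.

    The relative score is ``(raw − min_score) / (max_score − min_score)``,
    the standard JASPAR-style normalisation; it is invariant to affine
    rescaling of the log-odds matrix.
    """
    if not 0.0 < rel_threshold <= 1.0:
        raise PreconditionError(f"rel_threshold must be in (0, 1], got {rel_threshold}")
    L = pwm.length
    seq = sequence.upper()
    n = len(seq)
    if n < L:
        return []
    span = pwm.max_score - pwm.min_score
    hits = []
    rc = _revcomp(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for i in range(n - L + 1):
            raw = _window_score(s[i : i + L], pwm)
            rel = (raw - pwm.min_score) / span
            if rel >= rel_threshold:
                pos = i if strand == "+" else n - L - i
                hits.append(
                    TFBSHit(pwm.matrix_id, sequence_id, pos, strand, raw, rel)
                )
    hits.sort(key=lambda h: (h.position, h.strand, h.matrix_id))
    return hits


def scan_sequences(
    sequences: dict[str, str], pwms: list[PWM], rel_threshold: float = 0.8
) -> dict[str, list[TFBSHit]]:
    """All-PWM scan of a set of (ungapped) sequences."""
    return {
        sid: [
            h
            for pwm in pwms
            for h in scan_pwm(seq, pwm, rel_threshold, sequence_id=sid)
        ]
        for sid, seq in sequences.items()
    }


def scan_aligned(
    msa: dict[str, str], pwms: list[PWM], rel_threshold: float = 0.8
) -> dict[str, list[TFBSHit]]:
    """Scan each MSA row (degapped) and map hit coordinates to alignment columns."""
    out: dict[str, list[TFBSHit]] = {}
    for sid, row in msa.items():
        degapped = row.replace("-", "")
        col_of = [i for i, c in enumerate(row) if c != "-"]
        hits = []
        for pwm in pwms:
            for h in scan_pwm(degapped, pwm, rel_threshold, sequence_id=sid):
                h.aligned_start = col_of[h.position]
                h.aligned_end = col_of[h.position + pwm.length - 1] + 1
                hits.append(h)
        out[sid] = hits
    return out


# --- Fitch parsimony ancestral reconstruction ------------------------------


@dataclass
class AncestralSequence:
    """A reconstructed sequence at an internal node (IUPAC codes where ambiguous)."""

    node: str
    sequence: str
    method: str = "fitch_parsimony"
    parsimony_score: int = 0


def _column_state(char: str) -> frozenset[str]:
    c = char.upper()
    if c == "-":
        return frozenset({"-"})
    allowed = IUPAC.get(c)
    if allowed is None:
        raise InputError(f"invalid alignment character {char!r}")
    return frozenset(allowed)


_STATES = ("A", "C", "G", "T", "-")
_INF = float("inf")


def _fitch_root_sets(
    tree: dendropy.Tree, msa: dict[str, str], length: int
) -> tuple[list[frozenset[str]], int]:
    """Per-column optimal root state sets and the total parsimony score.

    Uniform-cost small parsimony (Sankoff recursion), which coincides with
    Fitch's union/intersection sets on binary trees and handles
    multifurcations correctly: the root set is the set of states attaining
    the minimum number of changes.
    """
    score = 0
    root_sets: list[frozenset[str]] = []
    for col in range(length):
        costs: dict[int, list[float]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                allowed = _column_state(msa[node.taxon.label][col])
                costs[id(node)] = [
                    0.0 if s in allowed else _INF for s in _STATES
                ]
            else:
                vec = [0.0] * len(_STATES)
                for child in node.child_nodes():
                    cvec = costs[id(child)]
                    cmin = min(cvec)
                    for i in range(len(_STATES)):
                        # stay (cvec[i]) or switch from the cheapest state (+1)
                        vec[i] += min(cvec[i], cmin + 1.0)
                costs[id(node)] = vec
        root = costs[id(tree.seed_node)]
        best = min(root)
        score += int(best)
        root_sets.append(
            frozenset(s for s, c in zip(_STATES, root) if c == best)
        )
    return root_sets, score


def fitch_parsimony_score(msa: dict[str, str], tree: str | dendropy.Tree) -> int:
    """Minimum number of state changes over the tree (uniform cost, all columns)."""
    t, length = _prepare_tree(msa, tree)
    _, score = _fitch_root_sets(t, msa, length)
    return score


def _prepare_tree(
    msa: dict[str, str], tree: str | dendropy.Tree
) -> tuple[dendropy.Tree, int]:
    if isinstance(tree, dendropy.Tree):
        t = tree.clone(depth=1)
    else:
        t = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    tips = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    missing = sorted(tips - set(msa)) + sorted(set(msa) - tips)
    if tips != set(msa):
        raise InputError(f"tree tips and alignment names differ: {missing}")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise InputError("alignment rows have unequal lengths")
    return t, lengths.pop()


def reconstruct_ancestor(
    msa: dict[str, str], tree: str | dendropy.Tree, node: str
) -> AncestralSequence:
    """Fitch-parsimony ancestral sequence at the named internal node.

    The tree is re-rooted at the requested node, so the reported per-column
    state set is the set of states optimal at that node; sets with more than
    one base are written as IUPAC ambiguity codes.  A column whose optimal
    state set is only a gap is written as '-'.
    """
    t, length = _prepare_tree(msa, tree)
    target = None
    for nd in t.preorder_node_iter():
        label = nd.taxon.label if nd.taxon else nd.label
        if label == node:
            target = nd
            break
    if target is None:
        raise InputError(f"node {node!r} not found in tree")
    if target is not t.seed_node:
        t.reroot_at_node(target, update_bipartitions=False)
    root_sets, score = _fitch_root_sets(t, msa, length)
    chars = []
    for states in root_sets:
        bases = frozenset(states - {"-"})
        if not bases:
            chars.append("-")
        else:
            chars.append(_SET_TO_IUPAC[bases])
    return AncestralSequence(node=node, sequence="".join(chars), parsimony_score=score)


# --- lineage-specific binding sites ----------------------------------------


def lineage_specific_sites(
    query_hits: dict[str, list[TFBSHit]],
    other_hits: dict[str, list[TFBSHit]],
    ancestor_hits: list[TFBSHit],
    require: str = "all",
) -> list[TFBSHit]:
    """Binding sites specific to the query (teleost) lineage.

    A site (matrix id + aligned interval) is reported when it is present in
    every query species (``require='all'``, the default; ``'any'`` relaxes
    this), and absent — no same-matrix hit overlapping by >=1 aligned
    column — from every other species and from the ancestor.
    """
    if not query_hits:
        raise PreconditionError("query (teleost) hit sets must be non-empty")
    if require not in ("all", "any"):
        raise PreconditionError("require must be 'all' or 'any'")
    species = sorted(query_hits)
    candidates = list(query_hits[species[0]])
    out = []
    for hit in candidates:
        in_query = [
            any(hit.overlaps(h) for h in query_hits[sp]) for sp in species
        ]
        present = all(in_query) if require == "all" else any(in_query)
        if not present:
            continue
        if any(
            any(hit.overlaps(h) for h in hits) for hits in other_hits.values()
        ):
            continue
        if any(hit.overlaps(h) for h in ancestor_hits):
            continue
        out.append(hit)
    return out


# --- S200 / regulatory potential -------------------------------------------


@dataclass
class S200Distribution:
    """Per-sequence binding-site density (sites per 200 bp) for one sequence set."""

    label: str
    values: dict[str, float]
    bin_width: float = 1.0

    def histogram(self, bin_edges: np.ndarray) -> np.ndarray:
        counts, _ = np.histogram(list(self.values.values()), bins=bin_edges)
        return counts


def s200(
    sequences: dict[str, str],
    pwms: list[PWM],
    rel_threshold: float = 0.8,
    label: str = "",
    bin_width: float = 1.0,
) -> S200Distribution:
    """Binding sites per 200 bp for every sequence (all PWMs pooled)."""
    if not sequences:
        raise PreconditionError("sequence set must be non-empty")
    values = {}
    for sid, seq in sequences.items():
        if len(seq) == 0:
            warnings.warn(f"sequence {sid!r} has zero length; skipped")
            continue
        n_hits = sum(len(scan_pwm(seq, p, rel_threshold, sid)) for p in pwms)
        values[sid] = n_hits * 200.0 / len(seq)
    return S200Distribution(label=label, values=values, bin_width=bin_width)


def regulatory_potential(
    query: S200Distribution, enhancer_ref: S200Distribution
) -> float:
    """Percent histogram overlap of two S200 distributions.

    The overlap coefficient sums, over common bins, the minimum of the two
    bin proportions; 100% for identical distributions, 0% for disjoint
    support.  Distributions are binned on common edges covering both
    supports (bin width taken from the query distribution).
    """
    if not query.values or not enhancer_ref.values:
        raise PreconditionError("both distributions must be non-empty")
    bw = query.bin_width
    if enhancer_ref.bin_width != bw:
        warnings.warn("bin widths differ; rebinning both on the query's width")
    hi = max(max(query.values.values()), max(enhancer_ref.values.values()))
    edges = np.arange(0.0, hi + 2 * bw, bw)
    q = query.histogram(edges).astype(float)
    r = enhancer_ref.histogram(edges).astype(float)
    q /= q.sum()
    r /= r.sum()
    return float(np.minimum(q, r).sum() * 100.0)
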