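"""Cross-species evolutionary diagnostics for recycled-region candidates.

A recycled region (RR) is an exon relic that lost coding function after a
whole-genome duplication.  Relative to the still-coding reference exon it is
expected to show (i) in-frame stop codons or frameshifts, (ii) nucleotide
identity exceeding amino-acid similarity (selection acting on the DNA, not
the protein), and (iii) an elevated Ka/Ks.  This module provides the
primitives for all three diagnostics:

* ``scan_frame_stops`` — stop-codon scan in a fixed reading frame;
* ``global_align`` — affine-gap global alignment with the pipeline's
  standard nucleotide scoring (match 5.0, mismatch −4.0, gap 12/3);
* ``identity_profile`` — percent nucleotide identity and percent amino-acid
  similarity against the reference exon;
* ``strip_indels_and_stops`` + ``compute_kaks`` — NG86 Ka/Ks with
  Jukes–Cantor correction after codon-consistent removal of indels and
  stop codons;
* ``contrast_kaks`` — ordered comparison of two Ka/Ks results.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .errors import InsufficientDataError, PreconditionError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon -> single-letter amino acid, with '*' for stops
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
CODON_TO_AA.update({c: "*" for c in _standard.stop_codons})

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

DEFAULT_MATCH = 5.0
DEFAULT_MISMATCH = -4.0
DEFAULT_GAP_OPEN = 12.0
DEFAULT_GAP_EXTEND = 3.0

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string in frame 0, '*' for stops, 'X' for ambiguity."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aas.append(CODON_TO_AA.get(seq[i : i + 3].upper(), "X"))
    return "".join(aas)


def scan_frame_stops(sequence: str, frame: int = 0, strand: str = "+") -> list[int]:
    """Positions (0-based nt start, on the scanned strand) of stop codons in ``frame``.

    An empty list means the reading frame is intact over the scanned span.
    """
    if frame not in (0, 1, 2):
        raise PreconditionError(f"frame must be 0, 1 or 2, got {frame!r}")
    if strand not in ("+", "-"):
        raise PreconditionError(f"strand must be '+' or '-', got {strand!r}")
    seq = sequence.upper() if strand == "+" else reverse_complement(sequence).upper()
    stops = []
    for i in range(frame, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            stops.append(i)
    return stops


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment: two equal-length gapped strings plus scoring."""

    aligned_a: str
    aligned_b: str
    score: float
    match: float = DEFAULT_MATCH
    mismatch: float = DEFAULT_MISMATCH
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise PreconditionError("aligned sequences must have equal length")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")


def global_align(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two nucleotide sequences.

    Defaults are the pipeline's standard scheme: match 5.0, mismatch −4.0,
    gap open/extension penalties 12/3 (a gap of length k costs
    ``gap_open + (k−1)·gap_extend``).  Ties are broken deterministically by
    taking the first optimal alignment in Biopython's enumeration order.
    """
    if not a or not b:
        raise PreconditionError("global_align requires two non-empty sequences")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a.upper(), b.upper())[0]
    return PairwiseAlignment(
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=aln.score,
        match=match,
        mismatch=mismatch,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


@dataclass
class IdentityProfile:
    """Percent identity/similarity of one species sequence vs the reference exon."""

    species: str
    nt_identity_pct: float
    aa_similarity_pct: float
    alignable_length: int

    def __post_init__(self) -> None:
        for v in (self.nt_identity_pct, self.aa_similarity_pct):
            if not 0.0 <= v <= 100.0:
                raise PreconditionError(f"percentage out of [0, 100]: {v}")


def _codon_columns(
    ref_aligned: str, other_aligned: str, frame_offset: int
) -> list[tuple[str, str]]:
    """Pair each reference codon with the other sequence's bases in its columns.

    Walks alignment columns, grouping every three reference (non-gap) bases
    into a codon after skipping ``frame_offset`` leading reference bases.
    Columns that are insertions relative to the reference contribute nothing.
    Returns (ref_codon, other_bases) pairs; ``other_bases`` may contain gaps.
    """
    pairs: list[tuple[str, str]] = []
    ref_seen = 0
    cur_ref: list[str] = []
    cur_other: list[str] = []
    for ra, oa in zip(ref_aligned, other_aligned):
        if ra == "-":
            continue
        ref_seen += 1
        if ref_seen <= frame_offset:
            continue
        cur_ref.append(ra)
        cur_other.append(oa)
        if len(cur_ref) == 3:
            pairs.append(("".join(cur_ref), "".join(cur_other)))
            cur_ref, cur_other = [], []
    return pairs


def _aa_similar(a: str, b: str) -> bool:
    """Positive BLOSUM62 score defines 'similar' (identity is always similar)."""
    try:
        return _BLOSUM62[a, b] > 0
    except (KeyError, IndexError):
        return False


def identity_profile(
    aln: PairwiseAlignment,
    reference: str = "a",
    species: str = "",
    frame_offset: int = 0,
    denominator: str = "reference",
) -> IdentityProfile:
    """NT identity and AA similarity of an alignment, relative to the reference.

    ``denominator='reference'`` divides by the (ungapped) reference exon
    length, the pipeline default; ``'shortest'`` divides by the shorter of
    the two ungapped sequences.  AA similarity is computed per reference
    codon in the reference reading frame: a codon counts as similar when the
    aligned bases are gap-free on both sides and the two translated residues
    have a positive BLOSUM62 score.
    """
    if reference not in ("a", "b"):
        raise PreconditionError("reference must be 'a' or 'b'")
    if denominator not in ("reference", "shortest"):
        raise PreconditionError("denominator must be 'reference' or 'shortest'")
    ref_aln = aln.aligned_a if reference == "a" else aln.aligned_b
    oth_aln = aln.aligned_b if reference == "a" else aln.aligned_a
    ref_len = len(ref_aln.replace("-", ""))
    oth_len = len(oth_aln.replace("-", ""))
    denom_nt = ref_len if denominator == "reference" else min(ref_len, oth_len)
    if denom_nt == 0:
        raise PreconditionError("reference sequence is empty")

    nt_matches = sum(
        1 for ra, oa in zip(ref_aln, oth_aln) if ra == oa and ra != "-"
    )

    codons = _codon_columns(ref_aln, oth_aln, frame_offset)
    denom_aa = len(codons) if denominator == "reference" else max(
        1, min(len(codons), (oth_len - frame_offset) // 3)
    )
    similar = 0
    for ref_codon, other_bases in codons:
        if "-" in other_bases or len(other_bases) != 3:
            continue
        ra = CODON_TO_AA.get(ref_codon.upper(), "X")
        oa = CODON_TO_AA.get(other_bases.upper(), "X")
        if ra in "X*" or oa in "X*":
            continue
        if _aa_similar(ra, oa):
            similar += 1
    aa_pct = 100.0 * similar / denom_aa if denom_aa else 0.0
    return IdentityProfile(
        species=species,
        nt_identity_pct=min(100.0, 100.0 * nt_matches / denom_nt),
        aa_similarity_pct=min(100.0, aa_pct),
        alignable_length=denom_nt,
    )


def strip_indels_and_stops(
    aln: PairwiseAlignment, frame_offset: int = 0, reference: str = "a"
) -> tuple[str, str, int, int]:
    """Reduce an alignment to a gap-free, stop-free codon-aligned pair.

    Whole reference codons are the unit of removal: any codon whose three
    reference columns touch a gap on either side is dropped (counted as an
    indel removal), and any codon that is a stop in either sequence is
    dropped (counted as a stop removal).  Returns
    ``(ref_codons, other_codons, n_indel_codons, n_stop_codons)``.
    """
    ref_aln = aln.aligned_a if reference == "a" else aln.aligned_b
    oth_aln = aln.aligned_b if reference == "a" else aln.aligned_a
    kept_a: list[str] = []
    kept_b: list[str] = []
    n_indels = 0
    n_stops = 0
    for ref_codon, other_bases in _codon_columns(ref_aln, oth_aln, frame_offset):
        if len(ref_codon) != 3:
            continue
        if "-" in other_bases or len(other_bases) != 3:
            n_indels += 1
            continue
        if ref_codon.upper() in STOP_CODONS or other_bases.upper() in STOP_CODONS:
            n_stops += 1
            continue
        kept_a.append(ref_codon.upper())
        kept_b.append(other_bases.upper())
    if len(kept_a) < 3:
        raise InsufficientDataError(
            f"only {len(kept_a)} codons remain after stripping indels/stops"
        )
    return "".join(kept_a), "".join(kept_b), n_indels, n_stops


# --- NG86 Ka/Ks ------------------------------------------------------------

#: ratio sentinels for degenerate cases
UNDEFINED_NO_SITES = "undefined_no_sites"
INFINITE_KS_ZERO = "infinite_ks_zero"
SATURATED = "saturated"

_BASES = "ACGT"


def _codon_site_counts(codon: str) -> float:
    """Number of synonymous sites in a codon (out of 3); mutation-to-stop is nonsynonymous."""
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if CODON_TO_AA[mutant] == aa:
                syn += 1.0
    return syn / 3.0


def _pathway_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous substitution counts between two codons.

    Equal-weight average over all orderings of the differing positions
    (the NG86 pathway average); steps to or from a stop codon count as
    nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_total = 0.0
    non_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        s = n = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt] and CODON_TO_AA[cur] != "*":
                s += 1
            else:
                n += 1
            cur = nxt
        syn_total += s
        non_total += n
        n_paths += 1
    return syn_total / n_paths, non_total / n_paths


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites; inf at saturation."""
    if p < 0:
        raise PreconditionError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    """NG86 Ka/Ks with preprocessing bookkeeping.

    ``ratio`` is a float when both rates are defined and Ks > 0, otherwise
    one of the string sentinels ``undefined_no_sites`` (no substitutions at
    all), ``infinite_ks_zero`` (Ka > 0 with Ks = 0) or ``saturated``
    (Jukes–Cantor correction undefined).
    """

    ka: float
    ks: float
    ratio: float | str
    codons_used: int
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    removed_indels: int = 0
    removed_stops: int = 0
    saturated: bool = False

    @property
    def defined(self) -> bool:
        return isinstance(self.ratio, float)


def compute_kaks(seq_a: str, seq_b: str) -> KaKsResult:
    """Nei–Gojobori (1986) Ka and Ks for a codon-aligned, gap- and stop-free pair.

    Site counts are averaged over the two sequences; substitution counts use
    equal-weight pathway averaging for multi-hit codons; proportions are
    corrected with the Jukes–Cantor formula.
    """
    a = seq_a.upper()
    b = seq_b.upper()
    if len(a) != len(b):
        raise PreconditionError("sequences must be equal length")
    if len(a) % 3 != 0 or len(a) == 0:
        raise PreconditionError("sequence length must be a positive multiple of 3")
    n_codons = len(a) // 3
    syn_sites_a = syn_sites_b = 0.0
    sd = nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        for codon in (ca, cb):
            if "-" in codon:
                raise PreconditionError("gaps are not allowed; strip indels first")
            if codon not in CODON_TO_AA:
                raise PreconditionError(f"invalid codon {codon!r}")
            if codon in STOP_CODONS:
                raise PreconditionError("stop codons are not allowed; strip stops first")
        syn_sites_a += _codon_site_counts(ca)
        syn_sites_b += _codon_site_counts(cb)
        s, n = _pathway_diff_counts(ca, cb)
        sd += s
        nd += n
    syn_sites = (syn_sites_a + syn_sites_b) / 2.0
    nonsyn_sites = 3.0 * n_codons - syn_sites

    ps = sd / syn_sites if syn_sites > 0 else 0.0
    pn = nd / nonsyn_sites if nonsyn_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = math.isinf(ka) or math.isinf(ks)

    ratio: float | str
    if sd == 0.0 and nd == 0.0:
        ratio = UNDEFINED_NO_SITES
    elif nd == 0.0:
        # no nonsynonymous change at all: the ratio is 0 even when the
        # synonymous distance is saturated (tiny toy alignments)
        ratio = 0.0
    elif saturated:
        ratio = SATURATED
    elif ks == 0.0:
        ratio = INFINITE_KS_ZERO
    else:
        ratio = ka / ks
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        codons_used=n_codons,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        saturated=saturated,
    )


def kaks_from_alignment(aln: PairwiseAlignment, frame_offset: int = 0) -> KaKsResult:
    """Strip indels and stop codons from a global alignment, then run NG86."""
    a, b, n_indels, n_stops = strip_indels_and_stops(aln, frame_offset=frame_offset)
    result = compute_kaks(a, b)
    result.removed_indels = n_indels
    result.removed_stops = n_stops
    return result


@dataclass
class KaKsContrast:
    """Ordered comparison of an RR locus against its coding homolog."""

    difference: float | None
    coding_signature: str  # 'coding' | 'rr' | 'tie' | 'indeterminate'
    rr_ratio: float | str
    coding_ratio: float | str


def contrast_kaks(rr: KaKsResult, coding: KaKsResult) -> KaKsContrast:
    """Report which locus carries the low-Ka/Ks (protein-coding) signature."""
    if not (rr.defined and coding.defined):
        return KaKsContrast(None, "indeterminate", rr.ratio, coding.ratio)
    diff = rr.ratio - coding.ratio
    if diff > 0:
        signature = "coding"  # the coding homolog has the lower ratio, as expected
    elif diff < 0:
        signature = "rr"
    else:
        signature = "tie"
    return KaKsContrast(diff, signature, rr.ratio, coding.ratio)


@dataclass
class SpeciesSequenceSet:
    """Orthologous sequences for one exon/RR locus across species."""

    sequences: dict[str, str]
    reference: str
    query: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        for name in (self.reference, self.query):
            if name not in self.sequences:
                raise PreconditionError(f"species {name!r} missing from sequence set")

    def profiles(self, denominator: str = "reference") -> list[IdentityProfile]:
        """Per-species identity/similarity vs the reference sequence."""
        ref = self.sequences[self.reference]
        out = []
        for species in sorted(self.sequences):
            if species == self.reference:
                continue
            aln = global_align(ref, self.sequences[species])
            out.append(
                identity_profile(
                    aln,
                    reference="a",
                    species=species,
                    frame_offset=self.frame_offset,
                    denominator=denominator,
                )
            )
        return out

    def kaks(self, species: str) -> KaKsResult:
        aln = global_align(self.sequences[self.reference], self.sequences[species])
        return kaks_from_alignment(aln, frame_offset=self.frame_offset)
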