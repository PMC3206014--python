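"""Exon-to-genome homology mapping: hit production, normalisation and fusion.

The discovery pipeline starts from local alignments of reference (human-like)
exon sequences against a duplicated target genome.  Hits can come from an
external aligner's 12-column tabular output or from the built-in desk-scale
local aligner; either way they are normalised to 0-based half-open
coordinates and then fused: hits of the same exon on the same contig that
lie within the fusion distance (default 1 kb) of each other are merged into
a single putative regulatory unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ConfigurationError, InputError
from .evo_analysis import reverse_complement

logger = logging.getLogger(__name__)

MIN_EXON_LENGTH = 20  # exons of <20 bp are too short to align reliably
DEFAULT_FUSION_GAP = 1000

_EXON_ALPHABET = frozenset("ACGTN")


@dataclass
class ExonRecord:
    """One reference exon: the query unit of the homology search."""

    exon_id: str
    gene_id: str
    sequence: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _EXON_ALPHABET
        if bad:
            raise InputError(f"exon {self.exon_id}: invalid characters {sorted(bad)}")
        if self.frame_offset not in (0, 1, 2):
            raise InputError(f"exon {self.exon_id}: frame_offset must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentHit:
    """One local alignment of an exon on the target genome (0-based half-open)."""

    exon_id: str
    target_contig: str
    target_start: int
    target_end: int
    strand: str
    score: float
    query_start: int = 0
    query_end: int = 0

    def __post_init__(self) -> None:
        if self.target_start >= self.target_end:
            raise InputError(
                f"hit {self.exon_id}@{self.target_contig}: start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"hit {self.exon_id}: strand must be '+' or '-'")

    @property
    def hit_id(self) -> str:
        return f"{self.exon_id}:{self.target_contig}:{self.target_start}-{self.target_end}"


@dataclass
class FusedHit:
    """Hits of one exon within the fusion distance, merged into one unit."""

    exon_id: str
    target_contig: str
    target_start: int
    target_end: int
    strand: str
    max_score: float
    member_hits: list[AlignmentHit] = field(default_factory=list)

    @property
    def hit_id(self) -> str:
        return f"{self.exon_id}:{self.target_contig}:{self.target_start}-{self.target_end}"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an id -> uppercase sequence dict."""
    try:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    except (ValueError, UnicodeDecodeError) as exc:
        raise InputError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def load_exons(
    annotation_path, genome_path, min_length: int = MIN_EXON_LENGTH
) -> list[ExonRecord]:
    """Extract exon sequences from a genome + GFF3 annotation.

    Exons shorter than ``min_length`` (default 20 bp, the minimum length the
    homology search accepts) are excluded and counted in the log.  Minus-strand
    exons are reverse-complemented so the stored sequence is the coding strand.
    """
    import gffutils

    genome = read_fasta(genome_path)
    try:
        db = gffutils.create_db(
            str(annotation_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        logger.warning("annotation %s contains no features", annotation_path)
        return []
    exons: list[ExonRecord] = []
    n_short = 0
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        exon_id = feat.id
        gene_id = feat.attributes.get("gene_id", feat.attributes.get("Parent", [exon_id]))[0]
        if feat.seqid not in genome:
            raise InputError(f"exon {exon_id}: contig {feat.seqid!r} not in genome")
        contig = genome[feat.seqid]
        start, end = feat.start - 1, feat.end  # GFF3 1-based inclusive -> half-open
        if start < 0 or end > len(contig):
            raise InputError(f"exon {exon_id}: interval out of contig bounds")
        if end - start < min_length:
            n_short += 1
            continue
        seq = contig[start:end]
        if feat.strand == "-":
            seq = reverse_complement(seq)
        frame = 0
        if "frame_offset" in feat.attributes:
            frame = int(feat.attributes["frame_offset"][0])
        exons.append(ExonRecord(exon_id, gene_id, seq, frame))
    if n_short:
        logger.info("excluded %d exon(s) shorter than %d bp", n_short, min_length)
    if not exons:
        logger.warning("no usable exons loaded from %s", annotation_path)
    return exons


def load_hits(path, min_score: float) -> list[AlignmentHit]:
    """Read 12-column BLAST-tabular hits, dropping those scoring below ``min_score``.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  Subject coordinates given high-to-low are read as
    minus-strand hits; all coordinates are normalised to 0-based half-open
    with start < end.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise InputError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                score = float(fields[11])
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: {exc}") from exc
            if score < min_score:
                continue
            if sstart <= send:
                strand, s, e = "+", sstart - 1, send
            else:
                strand, s, e = "-", send - 1, sstart
            hits.append(
                AlignmentHit(
                    exon_id=qseqid,
                    target_contig=sseqid,
                    target_start=s,
                    target_end=e,
                    strand=strand,
                    score=score,
                    query_start=min(qstart, qend) - 1,
                    query_end=max(qstart, qend),
                )
            )
    return hits


def _nt_matrix(match: float, mismatch: float):
    """ACGTN substitution matrix; N never matches anything (masked positions)."""
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == "N" or b == "N":
                mat[a, b] = mismatch
            else:
                mat[a, b] = match if a == b else mismatch
    return mat


def local_align(
    exon: ExonRecord,
    genome: dict[str, str],
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 12.0,
    gap_extend: float = 3.0,
    min_rel_score: float = 0.5,
    max_hits_per_contig: int = 5,
) -> list[AlignmentHit]:
    """Desk-scale local aligner: exact affine-gap Smith–Waterman on both strands.

    The score threshold is expressed as a fraction of the exon's maximum
    attainable score (``min_rel_score * match * exon_length``).  Multiple
    hits per contig are found by masking each reported interval with 'N'
    (which scores as a mismatch against everything) and re-aligning.
    """
    if min_rel_score <= 0 or min_rel_score > 1:
        raise ConfigurationError(f"min_rel_score must be in (0, 1], got {min_rel_score}")
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _nt_matrix(match, mismatch)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    threshold = min_rel_score * match * exon.length

    hits: list[AlignmentHit] = []
    queries = {"+": exon.sequence.upper(), "-": reverse_complement(exon.sequence.upper())}
    for contig_id in sorted(genome):
        for strand in ("+", "-"):
            query = queries[strand]
            subject = genome[contig_id].upper()
            for _ in range(max_hits_per_contig):
                if aligner.score(subject, query) < threshold:
                    break
                aln = aligner.align(subject, query)[0]
                t_blocks, q_blocks = aln.aligned
                t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
                q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
                if strand == "-":
                    q_start, q_end = exon.length - q_end, exon.length - q_start
                hits.append(
                    AlignmentHit(
                        exon_id=exon.exon_id,
                        target_contig=contig_id,
                        target_start=t_start,
                        target_end=t_end,
                        strand=strand,
                        score=float(aln.score),
                        query_start=q_start,
                        query_end=q_end,
                    )
                )
                subject = subject[:t_start] + "N" * (t_end - t_start) + subject[t_end:]
    hits.sort(key=lambda h: (h.target_contig, h.target_start, h.strand))
    return hits


def fuse_hits(
    hits: list[AlignmentHit], max_gap: int = DEFAULT_FUSION_GAP
) -> list[FusedHit]:
    """Single-linkage fusion of same-exon, same-contig hits within ``max_gap`` bp.

    The inter-interval gap is boundary-inclusive (gap == max_gap still
    fuses).  The fused interval is the hull of the members; hits on opposite
    strands fuse, with strand recorded as 'mixed'.  Fusion is idempotent and
    independent of input order.
    """
    if max_gap < 0:
        raise ConfigurationError(f"max_gap must be >= 0, got {max_gap}")
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for hit in hits:
        groups.setdefault((hit.exon_id, hit.target_contig), []).append(hit)
    fused: list[FusedHit] = []
    for (exon_id, contig), members in groups.items():
        members = sorted(members, key=lambda h: (h.target_start, h.target_end))
        cluster: list[AlignmentHit] = []
        end = None
        for hit in members:
            if cluster and hit.target_start - end > max_gap:
                fused.append(_make_fused(exon_id, contig, cluster))
                cluster = []
                end = None
            cluster.append(hit)
            end = hit.target_end if end is None else max(end, hit.target_end)
        if cluster:
            fused.append(_make_fused(exon_id, contig, cluster))
    fused.sort(key=lambda f: (f.exon_id, f.target_contig, f.target_start))
    return fused


def _make_fused(exon_id: str, contig: str, members: list[AlignmentHit]) -> FusedHit:
    strands = {m.strand for m in members}
    return FusedHit(
        exon_id=exon_id,
        target_contig=contig,
        target_start=min(m.target_start for m in members),
        target_end=max(m.target_end for m in members),
        strand=strands.pop() if len(strands) == 1 else "mixed",
        max_score=max(m.score for m in members),
        member_hits=list(members),
    )


def refuse(fused: list[FusedHit], max_gap: int = DEFAULT_FUSION_GAP) -> list[FusedHit]:
    """Fuse a fused-hit list again (used to check idempotence)."""
    return fuse_hits([m for f in fused for m in f.member_hits], max_gap=max_gap)


def hits_to_bed(hits, path) -> None:
    """Write hits (plain or fused) as 6-column BED with the score field."""
    with open(path, "w") as fh:
        for h in hits:
            score = getattr(h, "score", None)
            if score is None:
                score = h.max_score
            strand = h.strand if h.strand in ("+", "-") else "."
            fh.write(
                f"{h.target_contig}\t{h.target_start}\t{h.target_end}"
                f"\t{h.exon_id}\t{score:g}\t{strand}\n"
            )


def hits_to_tsv(hits, path) -> None:
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "exon_id": h.exon_id,
                "contig": h.target_contig,
                "start": h.target_start,
                "end": h.target_end,
                "strand": h.strand,
                "score": getattr(h, "score", None) or getattr(h, "max_score", None),
                "n_members": len(getattr(h, "member_hits", [])) or 1,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
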