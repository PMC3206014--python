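"""The recycled-region discovery funnel.

Fused exon-to-genome hits are reduced to RR candidates by six filters,
applied in a fixed order:

1. ``ortholog_presence`` — the source gene must have at least one annotated
   ortholog in the target genome (removes un-annotated genes);
2. ``ortholog_proximity`` — hits within 2 Mb of any ortholog locus of the
   source gene are removed (those are the still-coding copy, not a relic);
3. ``exonic_overlap`` — hits overlapping any annotated exon or EST by even
   one bp are removed (the relic must be non-coding in the target);
4. ``synteny`` — developmental genes within a 300 kb window of the source
   exon are mapped to their target orthologs; a hit is retained only if it
   lies within 100 kb of such an ortholog with at most five intervening
   genes, and a gene with more than one surviving hit inside a window-sized
   span loses all its hits;
5. ``developmental_flank`` — at least one of the hit's nearest flanking
   target genes must carry a developmental GO annotation (the putative
   regulatory target);
6. ``frame_disruption`` — the hit region must *not* align to the source
   exon over its full span in a single stop-free reading frame; intact
   regions are conserved coding sequence, not relics.

``run_funnel`` chains the stages over a scenario-bundle directory and
returns the surviving candidates plus a per-stage count report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

from .errors import ConfigurationError, InputError, PreconditionError
from .evo_analysis import reverse_complement, scan_frame_stops, translate
from .homology_mapping import (
    ExonRecord,
    FusedHit,
    fuse_hits,
    load_exons,
    load_hits,
    local_align,
    read_fasta,
)

logger = logging.getLogger(__name__)

DEFAULT_GO_ROOTS = ("GO:0045165", "GO:0032502", "GO:0030528", "GO:0003700")


@dataclass
class GeneModel:
    """A target- or reference-genome gene with its exons and GO annotation."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    go_terms: set[str] = field(default_factory=set)
    is_est: bool = False

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise InputError(f"gene {self.gene_id}: exon outside gene interval")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Minimum gap between two half-open intervals; 0 when they overlap."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(b[0] - a[1], a[0] - b[1])


def load_gene_models(
    gff_path, gene2go: dict[str, set[str]] | None = None
) -> tuple[dict[str, GeneModel], list[GeneModel]]:
    """Load genes (+exons) and EST records from GFF3; attach GO terms if given."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    gene2go = gene2go or {}
    genes: dict[str, GeneModel] = {}
    ests: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.id
        genes[gid] = GeneModel(
            gene_id=gid, contig=feat.seqid, start=feat.start - 1, end=feat.end,
            strand=feat.strand, go_terms=set(gene2go.get(gid, ())),
        )
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        parent = feat.attributes.get("Parent", feat.attributes.get("gene_id", [None]))[0]
        if parent in genes:
            genes[parent].exons.append((feat.start - 1, feat.end))
    for feat in db.features_of_type("expressed_sequence_match", order_by=("seqid", "start")):
        ests.append(
            GeneModel(feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand,
                      is_est=True)
        )
    return genes, ests


def load_orthology(path) -> dict[str, set[str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError(f"orthology table {path} needs two columns")
    out: dict[str, set[str]] = {}
    for ref, tgt in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(ref), set()).add(str(tgt))
    return out


def load_gene2go(path) -> dict[str, set[str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(gene), set()).add(str(term))
    return out


def developmental_closure(
    obo_path, roots: tuple[str, ...] = DEFAULT_GO_ROOTS
) -> set[str]:
    """The root terms plus all their ontology descendants (is_a/part_of edges).

    These are the GO classes whose annotation marks a gene as
    "developmental" for the synteny and flanking-gene filters.
    """
    graph = obonet.read_obo(str(obo_path))
    closure: set[str] = set()
    for root in roots:
        if root not in graph:
            raise ConfigurationError(f"GO root {root} missing from ontology")
        closure.add(root)
        # obonet edges point child -> parent, so ontology descendants of a
        # root are the graph-theoretic ancestors of its node
        closure.update(nx.ancestors(graph, root))
    return closure


# --- individual filters -----------------------------------------------------


def _gene_of(hit: FusedHit, exon2gene: dict[str, str]) -> str:
    try:
        return exon2gene[hit.exon_id]
    except KeyError:
        raise InputError(f"hit {hit.hit_id}: exon {hit.exon_id} has no source gene")


def filter_ortholog_presence(
    hits: list[FusedHit],
    exon2gene: dict[str, str],
    orthology: dict[str, set[str]],
) -> tuple[list[FusedHit], list[FusedHit]]:
    """Keep hits whose source gene has >=1 annotated target ortholog."""
    if not orthology:
        logger.warning("orthology map is empty; all hits will be dropped")
    kept, dropped = [], []
    for hit in hits:
        gene = _gene_of(hit, exon2gene)
        (kept if orthology.get(gene) else dropped).append(hit)
    return kept, dropped


def filter_ortholog_proximity(
    hits: list[FusedHit],
    exon2gene: dict[str, str],
    orthology: dict[str, set[str]],
    target_genes: dict[str, GeneModel],
    radius: int = 2_000_000,
) -> tuple[list[FusedHit], list[FusedHit]]:
    """Remove hits within ``radius`` bp of any same-contig ortholog of their gene.

    A hit on a contig carrying no ortholog of its source gene is treated as
    infinitely distant and kept.
    """
    kept, dropped = [], []
    for hit in hits:
        gene = _gene_of(hit, exon2gene)
        close = False
        for orth_id in orthology.get(gene, ()):  # genes may have 2 post-WGD copies
            orth = target_genes.get(orth_id)
            if orth is None:
                raise InputError(f"ortholog {orth_id!r} not in target annotation")
            if orth.contig != hit.target_contig:
                continue
            if _gap(hit.interval, orth.interval) <= radius:
                close = True
                break
        (dropped if close else kept).append(hit)
    return kept, dropped


def filter_exonic_overlap(
    hits: list[FusedHit],
    target_genes: dict[str, GeneModel],
    ests: list[GeneModel],
) -> tuple[list[FusedHit], list[FusedHit]]:
    """Remove hits overlapping any annotated exon or EST by >=1 bp."""
    features: dict[str, list[tuple[int, int]]] = {}
    for gene in target_genes.values():
        for iv in gene.exons or [gene.interval]:
            features.setdefault(gene.contig, []).append(iv)
    for est in ests:
        features.setdefault(est.contig, []).append(est.interval)
    kept, dropped = [], []
    for hit in hits:
        ivs = features.get(hit.target_contig, ())
        # half-open intervals: a shared boundary is adjacency, not overlap
        overlapping = any(
            hit.target_start < iv[1] and iv[0] < hit.target_end for iv in ivs
        )
        (dropped if overlapping else kept).append(hit)
    return kept, dropped


def assess_synteny(
    hits: list[FusedHit],
    exon2gene: dict[str, str],
    ref_genes: dict[str, GeneModel],
    ref_exons: dict[str, tuple[str, int, int, str]],
    orthology: dict[str, set[str]],
    target_genes: dict[str, GeneModel],
    closure: set[str],
    window: int = 300_000,
    max_dist: int = 100_000,
    max_intervening: int = 5,
) -> tuple[list[FusedHit], list[FusedHit]]:
    """The synteny filter: proximity to a developmental-gene ortholog.

    For each hit, developmental genes within ``window`` bp of the source
    exon on the reference are mapped to their target orthologs; the hit is
    retained if some such ortholog lies on the hit's contig within
    ``max_dist`` bp with at most ``max_intervening`` annotated genes
    strictly in between.  Afterwards, any source gene with more than one
    retained hit inside a window-sized span loses all of its hits.
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for g in target_genes.values():
        by_contig.setdefault(g.contig, []).append(g)

    retained, dropped = [], []
    for hit in hits:
        gene = _gene_of(hit, exon2gene)
        exon_entry = ref_exons.get(hit.exon_id)
        if exon_entry is None:
            raise InputError(f"exon {hit.exon_id} has no reference coordinates")
        ref_contig, ex_start, ex_end, _ = exon_entry
        dev_genes = [
            g for g in ref_genes.values()
            if g.contig == ref_contig
            and g.gene_id != gene
            and g.go_terms & closure
            and _gap((ex_start, ex_end), g.interval) <= window
        ]
        ok = False
        for dev in dev_genes:
            for orth_id in orthology.get(dev.gene_id, ()):
                orth = target_genes.get(orth_id)
                if orth is None or orth.contig != hit.target_contig:
                    continue
                if _gap(hit.interval, orth.interval) >= max_dist:
                    continue
                if hit.target_end <= orth.start:
                    inner = (hit.target_end, orth.start)
                else:
                    inner = (orth.end, hit.target_start)
                intervening = sum(
                    1 for g in by_contig.get(hit.target_contig, ())
                    if g.gene_id != orth_id
                    and g.start >= inner[0] and g.end <= inner[1]
                )
                if intervening <= max_intervening:
                    ok = True
                    break
            if ok:
                break
        (retained if ok else dropped).append(hit)

    # multi-hit rule: a gene presenting >1 hit within a window-sized span is
    # suspect (un-annotated duplicate) and loses all of its hits, including
    # any that passed the distance test above
    by_gene: dict[str, list[FusedHit]] = {}
    for hit in hits:
        by_gene.setdefault(_gene_of(hit, exon2gene), []).append(hit)
    clustered_genes = set()
    for gene, gene_hits in by_gene.items():
        for i, a in enumerate(gene_hits):
            for b in gene_hits[i + 1:]:
                if (a.target_contig == b.target_contig
                        and _gap(a.interval, b.interval) <= window):
                    clustered_genes.add(gene)
    kept = []
    for hit in retained:
        if _gene_of(hit, exon2gene) in clustered_genes:
            dropped.append(hit)
        else:
            kept.append(hit)
    kept.sort(key=lambda h: h.hit_id)
    return kept, dropped


def flanking_genes(
    hit: FusedHit, target_genes: dict[str, GeneModel], window: int
) -> list[GeneModel]:
    """Nearest annotated gene on each side of the hit, within ``window`` bp."""
    left = right = None
    for g in target_genes.values():
        if g.contig != hit.target_contig:
            continue
        if g.end <= hit.target_start:
            if hit.target_start - g.end <= window and (left is None or g.end > left.end):
                left = g
        elif g.start >= hit.target_end:
            if g.start - hit.target_end <= window and (right is None or g.start < right.start):
                right = g
    return [g for g in (left, right) if g is not None]


def filter_developmental_flank(
    hits: list[FusedHit],
    target_genes: dict[str, GeneModel],
    closure: set[str],
    window: int = 300_000,
) -> tuple[list[FusedHit], list[FusedHit]]:
    """Keep hits with >=1 developmental gene among their nearest flanking genes."""
    kept, dropped = [], []
    for hit in hits:
        flanks = flanking_genes(hit, target_genes, window)
        if not flanks:
            logger.debug("hit %s has no annotated flanking genes", hit.hit_id)
        if any(g.go_terms & closure for g in flanks):
            kept.append(hit)
        else:
            dropped.append(hit)
    return kept, dropped


# --- frame assessment -------------------------------------------------------


@dataclass
class FrameEvidence:
    """Result of the six-frame disruption scan of a hit region vs its exon."""

    intact: bool
    stops_by_frame: dict[str, list[int]]
    best_coverage: float
    covering_frame: str | None
    frameshift: bool  # no stop-free frame covers the region


_protein_aligner = None


def _get_protein_aligner():
    global _protein_aligner
    if _protein_aligner is None:
        from Bio.Align import PairwiseAligner, substitution_matrices

        a = PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _protein_aligner = a
    return _protein_aligner


def assess_frame_disruption(
    region: str, exon: ExonRecord, coverage_threshold: float = 0.95
) -> FrameEvidence:
    """Six-frame translate-and-align of a hit region against its source exon.

    The region is *intact* (still protein-coding, hence discarded by the
    funnel) when some single reading frame translates without any stop
    codon and its peptide locally aligns to the exon peptide over at least
    ``coverage_threshold`` of the region's codons.  Otherwise the evidence
    — per-frame stop positions and/or the absence of a covering frame — is
    returned.
    """
    if not region or not exon.sequence:
        raise PreconditionError("region and exon sequences must be non-empty")
    exon_pep = translate(exon.sequence[exon.frame_offset:]).replace("*", "X")
    aligner = _get_protein_aligner()
    stops_by_frame: dict[str, list[int]] = {}
    best_cov = 0.0
    covering = None
    for strand in ("+", "-"):
        seq = region if strand == "+" else reverse_complement(region)
        for frame in (0, 1, 2):
            label = f"{strand}{frame}"
            stops = scan_frame_stops(seq, frame=frame, strand="+")
            stops_by_frame[label] = stops
            sub = seq[frame:]
            pep = translate(sub[: len(sub) - len(sub) % 3])
            if not pep:
                continue
            pep_clean = pep.replace("*", "X")
            if len(exon_pep) == 0:
                continue
            score = aligner.score(exon_pep, pep_clean)
            if score <= 0:
                continue
            aln = aligner.align(exon_pep, pep_clean)[0]
            q_blocks = aln.aligned[1]
            covered = sum(int(e) - int(s) for s, e in q_blocks)
            cov = covered / len(pep)
            if not stops and cov > best_cov:
                best_cov = cov
            if not stops and cov >= coverage_threshold:
                covering = label
    intact = covering is not None
    # disrupted despite some stop-free frame existing => frameshift-type evidence
    frameshift = (not intact) and any(
        len(v) == 0 for v in stops_by_frame.values()
    )
    return FrameEvidence(
        intact=intact,
        stops_by_frame=stops_by_frame,
        best_coverage=best_cov,
        covering_frame=covering,
        frameshift=frameshift,
    )


# --- the funnel -------------------------------------------------------------


@dataclass
class FunnelConfig:
    """All thresholds of the funnel; ``scale_divisor`` shrinks the distance
    thresholds consistently for desk-scale toy genomes."""

    min_rel_score: float = 0.5
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 12.0
    gap_extend: float = 3.0
    fusion_gap: int = 1_000
    proximity_radius: int = 2_000_000
    synteny_window: int = 300_000
    synteny_max_dist: int = 100_000
    max_intervening: int = 5
    go_roots: tuple[str, ...] = DEFAULT_GO_ROOTS
    frame_coverage: float = 0.95
    min_exon_length: int = 20
    scale_divisor: float = 1.0
    hits_path: str | None = None   # external BLAST-tabular hits instead of local_align
    min_hit_score: float = 2_900.0  # score cutoff for the external-hit path

    def __post_init__(self) -> None:
        for name in ("fusion_gap", "proximity_radius", "synteny_window",
                     "synteny_max_dist"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.scale_divisor <= 0:
            raise ConfigurationError("scale_divisor must be positive")

    def scaled(self, value: int) -> int:
        return max(1, int(round(value / self.scale_divisor)))


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    dropped: list[str]


@dataclass
class FunnelReport:
    stages: list[StageRecord] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, dropped: list[str]) -> None:
        if n_out > n_in:
            raise RuntimeError(f"stage {stage}: output exceeds input")
        self.stages.append(StageRecord(stage, n_in, n_out, sorted(dropped)))

    def to_dict(self) -> dict:
        return {"stages": [dataclasses.asdict(s) for s in self.stages]}

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tn_in\tn_out\tn_dropped\n")
            for s in self.stages:
                fh.write(f"{s.stage}\t{s.n_in}\t{s.n_out}\t{len(s.dropped)}\n")


@dataclass
class RRCandidate:
    """A fused hit that survived every filter, with its supporting evidence."""

    hit: FusedHit
    exon: ExonRecord
    gene_id: str
    region_sequence: str
    flanking_gene_ids: list[str]
    frame_evidence: FrameEvidence | None
    stage_log: list[str] = field(default_factory=list)

    @property
    def candidate_id(self) -> str:
        return self.hit.hit_id


#: funnel stage order (after hit production and fusion)
FILTER_STAGES = (
    "ortholog_presence",
    "ortholog_proximity",
    "exonic_overlap",
    "synteny",
    "developmental_flank",
    "frame_disruption",
)


@dataclass
class BundlePaths:
    """File layout of a scenario-bundle directory."""

    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    @property
    def reference_genome(self): return self.root / "reference_genome.fa"
    @property
    def reference_annotation(self): return self.root / "reference_annotation.gff3"
    @property
    def target_genome(self): return self.root / "target_genome.fa"
    @property
    def target_annotation(self): return self.root / "target_annotation.gff3"
    @property
    def orthology(self): return self.root / "orthology.tsv"
    @property
    def gene2go(self): return self.root / "gene2go.tsv"
    @property
    def ontology(self): return self.root / "ontology.obo"
    @property
    def pwms(self): return self.root / "pwms.pfm"
    @property
    def species_tree(self): return self.root / "species_tree.nwk"
    @property
    def truth(self): return self.root / "truth.json"
    @property
    def msa_dir(self): return self.root / "msa"


def run_funnel(
    bundle_dir,
    config: FunnelConfig | None = None,
    disable: set[str] = frozenset(),
) -> tuple[list[RRCandidate], FunnelReport]:
    """Run the full discovery funnel over a scenario-bundle directory.

    ``disable`` names filter stages to skip (for ablation studies); stage
    order always follows :data:`FILTER_STAGES`.
    """
    config = config or FunnelConfig()
    unknown = set(disable) - set(FILTER_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages in disable set: {sorted(unknown)}")
    paths = BundlePaths(bundle_dir)

    try:
        exons = load_exons(paths.reference_annotation, paths.reference_genome,
                           min_length=config.min_exon_length)
        target_genome = read_fasta(paths.target_genome)
        gene2go = load_gene2go(paths.gene2go)
        ref_genes, _ = load_gene_models(paths.reference_annotation, gene2go)
        target_genes, ests = load_gene_models(paths.target_annotation, gene2go)
        orthology = load_orthology(paths.orthology)
        closure = developmental_closure(paths.ontology, config.go_roots)
    except InputError:
        raise
    except Exception as exc:
        raise InputError(f"funnel aborted while loading inputs: {exc}") from exc

    exon_by_id = {e.exon_id: e for e in exons}
    exon2gene = {e.exon_id: e.gene_id for e in exons}
    ref_exons = {}
    for gid, gene in ref_genes.items():
        for k, (s, e) in enumerate(gene.exons, start=1):
            ref_exons[f"{gid}.e{k}"] = (gene.contig, s, e, gene.strand)

    report = FunnelReport()

    # hit production
    if config.hits_path:
        raw_hits = load_hits(config.hits_path, min_score=config.min_hit_score)
    else:
        raw_hits = []
        for exon in exons:
            raw_hits.extend(
                local_align(
                    exon, target_genome,
                    match=config.match, mismatch=config.mismatch,
                    gap_open=config.gap_open, gap_extend=config.gap_extend,
                    min_rel_score=config.min_rel_score,
                )
            )

    fused = fuse_hits(raw_hits, max_gap=config.scaled(config.fusion_gap))
    report.add("fusion", len(raw_hits), len(fused), [])

    stage_funcs = {
        "ortholog_presence": lambda h: filter_ortholog_presence(h, exon2gene, orthology),
        "ortholog_proximity": lambda h: filter_ortholog_proximity(
            h, exon2gene, orthology, target_genes,
            radius=config.scaled(config.proximity_radius)),
        "exonic_overlap": lambda h: filter_exonic_overlap(h, target_genes, ests),
        "synteny": lambda h: assess_synteny(
            h, exon2gene, ref_genes, ref_exons, orthology, target_genes, closure,
            window=config.scaled(config.synteny_window),
            max_dist=config.scaled(config.synteny_max_dist),
            max_intervening=config.max_intervening),
        "developmental_flank": lambda h: filter_developmental_flank(
            h, target_genes, closure, window=config.scaled(config.synteny_window)),
    }

    current = fused
    passed_stages = ["fusion"]
    for stage in FILTER_STAGES[:-1]:
        if stage in disable:
            continue
        try:
            kept, dropped_hits = stage_funcs[stage](current)
        except InputError as exc:
            raise InputError(f"funnel aborted at stage {stage!r}: {exc}") from exc
        report.add(stage, len(current), len(kept),
                   [h.hit_id for h in dropped_hits])
        for h in dropped_hits:
            logger.debug("stage %s dropped %s", stage, h.hit_id)
        current = kept
        passed_stages.append(stage)

    # frame disruption: keep only regions whose coding frame is broken
    candidates: list[RRCandidate] = []
    dropped_ids: list[str] = []
    run_frame = "frame_disruption" not in disable
    n_in = len(current)
    for hit in current:
        exon = exon_by_id[hit.exon_id]
        region = target_genome[hit.target_contig][hit.target_start:hit.target_end]
        evidence = None
        if run_frame:
            evidence = assess_frame_disruption(
                region, exon, coverage_threshold=config.frame_coverage
            )
            if evidence.intact:
                dropped_ids.append(hit.hit_id)
                logger.debug("stage frame_disruption dropped %s (intact ORF)",
                             hit.hit_id)
                continue
        flanks = flanking_genes(hit, target_genes,
                                config.scaled(config.synteny_window))
        candidates.append(
            RRCandidate(
                hit=hit,
                exon=exon,
                gene_id=exon2gene[hit.exon_id],
                region_sequence=region,
                flanking_gene_ids=[g.gene_id for g in flanks],
                frame_evidence=evidence,
                stage_log=passed_stages + (
                    ["frame_disruption"] if run_frame else []
                ),
            )
        )
    if run_frame:
        report.add("frame_disruption", n_in, len(candidates), dropped_ids)
    return candidates, report


def candidates_to_tsv(candidates: list[RRCandidate], path) -> None:
    import pandas as pd

    rows = []
    for c in candidates:
        ev = c.frame_evidence
        rows.append(
            {
                "candidate_id": c.candidate_id,
                "exon_id": c.exon.exon_id,
                "gene_id": c.gene_id,
                "contig": c.hit.target_contig,
                "start": c.hit.target_start,
                "end": c.hit.target_end,
                "strand": c.hit.strand,
                "max_score": c.hit.max_score,
                "flanking_genes": ",".join(c.flanking_gene_ids),
                "frame0_stops": len(ev.stops_by_frame.get("+0", [])) if ev else "NA",
                "intact": ev.intact if ev else "NA",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def candidates_to_bed(candidates: list[RRCandidate], path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            strand = c.hit.strand if c.hit.strand in ("+", "-") else "."
            fh.write(
                f"{c.hit.target_contig}\t{c.hit.target_start}\t{c.hit.target_end}"
                f"\t{c.candidate_id}\t{c.hit.max_score:g}\t{strand}\n"
            )
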