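"""Synthetic evolutionary-trap scenarios with planted recycled regions.

The generator emulates the data situation the discovery pipeline was built
for: a reference species ("human-like") whose coding exon maps, after a
whole-genome duplication in the target lineage ("fish-like"), onto two
syntenic loci — one that retained the coding gene and one where the gene
was lost but an alignable, stop-disrupted exon relic (the planted recycled
region, RR) survives next to a developmental gene.  Every filter of the
discovery funnel can additionally be given one *decoy*: a relic engineered
to violate exactly that filter while satisfying all the others.

A bundle also carries a cross-species sequence cohort per planted locus
(outgroups with intact ORFs, teleosts sharing the degenerate relic state
and one planted transcription-factor binding motif), a species tree, a
small GO ontology, an orthology map and a JASPAR PWM set — everything the
downstream modules consume, written in standard text formats.

All randomness flows from a single ``numpy`` Generator seeded from
``ScenarioConfig.seed``; identical configs produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, PreconditionError, RRGenesisError
from .evo_analysis import CODON_TO_AA, STOP_CODONS
from . import tfbs_analysis as tfa

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*")

#: filter stages a decoy can be engineered to violate (funnel stage names)
DECOY_CLASSES = (
    "ortholog_presence",
    "ortholog_proximity",
    "exonic_overlap",
    "synteny",
    "developmental_flank",
    "frame_disruption",
)

#: GO terms used by the toy ontology
DEV_TERM = "GO:0007420"        # brain development, is_a descendant of GO:0032502
NONDEV_TERMS = ("GO:0008152", "GO:0016310")

SPECIES_TREE = (
    "(shark:1,((human:1,mouse:1)mammalia:1,chicken:1)tetrapoda:1,"
    "(zebrafish:1,(stickleback:1,medaka:1)percomorpha:1)teleostei:1)osteichthyes;"
)
#: the node whose reconstruction the TFBS stage uses (bony-vertebrate root)
ANCESTOR_NODE = "osteichthyes"
TELEOSTS = ("zebrafish", "stickleback", "medaka")
OUTGROUPS = ("human", "mouse", "chicken", "shark")

GENE_LENGTH = 300  # flanking-gene length in bp

_OBO_TEXT = """format-version: 1.2
ontology: go-mini

[Term]
id: GO:0008150
name: biological_process

[Term]
id: GO:0003674
name: molecular_function

[Term]
id: GO:0032502
name: developmental process
is_a: GO:0008150

[Term]
id: GO:0045165
name: cell fate commitment
is_a: GO:0032502

[Term]
id: GO:0007420
name: brain development
is_a: GO:0032502

[Term]
id: GO:0030528
name: transcription regulator activity
is_a: GO:0003674

[Term]
id: GO:0003700
name: transcription factor activity
is_a: GO:0030528

[Term]
id: GO:0008152
name: metabolic process
is_a: GO:0008150

[Term]
id: GO:0016310
name: phosphorylation
is_a: GO:0008152
"""

# consensus strings deliberately far from their own reverse complements, so a
# planted site is called once, on one strand
_PWM_SPECS = [
    ("MA9001.1", "RRG1", "AAACCGTTGC"),
    ("MA9002.1", "RRG2", "GGATTACAG"),
    ("MA9003.1", "RRG3", "CCAGATAAGGC"),
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario; the seed fixes every byte of output."""

    seed: int = 0
    n_reference_genes: int = 3
    exon_length_codons: int = 60
    intergenic_length: int = 2000
    nt_substitution_rate: float = 0.10
    indel_rate: float = 0.01
    n_planted_stops: int = 2
    decoy_classes: frozenset[str] = frozenset()
    flanking_gene_count: int = 2
    genome_scale_divisor: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "decoy_classes", frozenset(self.decoy_classes))
        for name in ("nt_substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_reference_genes", "exon_length_codons", "intergenic_length",
                     "flanking_gene_count"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_planted_stops < 1:
            raise ConfigurationError("n_planted_stops must be >= 1")
        if self.exon_length_codons * 3 <= 19:
            raise ConfigurationError(
                "exon_length_codons * 3 must exceed 19 bp (minimum alignable exon)"
            )
        if self.exon_length_codons < self.n_planted_stops + 8:
            raise ConfigurationError("exon too short for the requested stop count")
        if self.genome_scale_divisor <= 0:
            raise ConfigurationError("genome_scale_divisor must be positive")
        unknown = self.decoy_classes - set(DECOY_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown decoy classes: {sorted(unknown)}")

    def scaled(self, threshold: float) -> int:
        return max(1, int(round(threshold / self.genome_scale_divisor)))


@dataclass
class TruthRecord:
    """Ground truth for one planted relic (a real RR or a decoy)."""

    kind: str                      # 'planted_rr' | 'decoy'
    violated_filter: str | None    # funnel stage name for decoys
    contig: str
    start: int                     # 0-based half-open, target genome
    end: int
    source_exon_id: str
    n_planted_stops: int = 0
    stop_positions: list[int] = field(default_factory=list)  # nt offsets in relic
    n_indels: int = 0


@dataclass
class GeneRecord:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    go_terms: tuple[str, ...] = ()
    is_est: bool = False


@dataclass
class ScenarioBundle:
    """A complete in-memory scenario; ``write`` serialises it to standard formats."""

    config: ScenarioConfig
    reference_genome: dict[str, str]
    reference_genes: list[GeneRecord]
    reference_exons: dict[str, tuple[str, int, int, str]]  # exon_id -> contig interval
    target_genome: dict[str, str]
    target_genes: list[GeneRecord]
    target_ests: list[GeneRecord]
    orthology: dict[str, list[str]]
    gene2go: dict[str, list[str]]
    species_tree: str
    pwms: list[tfa.PWM]
    msas: dict[str, dict[str, str]]          # focal gene id -> species -> sequence
    truth: list[TruthRecord]
    tfbs_truth: dict[str, dict]              # focal gene id -> planted-motif record

    def write(self, outdir) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(self.reference_genome, out / "reference_genome.fa")
        _write_fasta(self.target_genome, out / "target_genome.fa")
        _write_gff(self.reference_genes, [], out / "reference_annotation.gff3")
        _write_gff(self.target_genes, self.target_ests, out / "target_annotation.gff3")
        with open(out / "orthology.tsv", "w") as fh:
            fh.write("reference_gene\ttarget_gene\n")
            for ref in sorted(self.orthology):
                for tgt in sorted(self.orthology[ref]):
                    fh.write(f"{ref}\t{tgt}\n")
        with open(out / "gene2go.tsv", "w") as fh:
            fh.write("gene\tgo_term\n")
            for gene in sorted(self.gene2go):
                for term in sorted(self.gene2go[gene]):
                    fh.write(f"{gene}\t{term}\n")
        (out / "ontology.obo").write_text(_OBO_TEXT)
        (out / "species_tree.nwk").write_text(self.species_tree + "\n")
        tfa.write_pwms(self.pwms, out / "pwms.pfm")
        msa_dir = out / "msa"
        msa_dir.mkdir(exist_ok=True)
        for gene in sorted(self.msas):
            _write_fasta(self.msas[gene], msa_dir / f"{gene}.fa")
        with open(out / "truth.json", "w") as fh:
            json.dump([dataclasses.asdict(t) for t in self.truth], fh, indent=1,
                      sort_keys=True)
            fh.write("\n")
        with open(out / "tfbs_truth.json", "w") as fh:
            json.dump(self.tfbs_truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        cfg = dataclasses.asdict(self.config)
        cfg["decoy_classes"] = sorted(cfg["decoy_classes"])
        with open(out / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return out


def _write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_gff(genes: list[GeneRecord], ests: list[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id};gene_id={g.gene_id}"
            fh.write(
                f"{g.contig}\trrgenesis\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.contig}\trrgenesis\texon\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.e1;Parent={g.gene_id};"
                f"gene_id={g.gene_id}\n"
            )
        for e in sorted(ests, key=lambda g: (g.contig, g.start, g.gene_id)):
            fh.write(
                f"{e.contig}\trrgenesis\texpressed_sequence_match\t{e.start + 1}\t"
                f"{e.end}\t.\t{e.strand}\t.\tID={e.gene_id}\n"
            )


# --- sequence-level operations ---------------------------------------------


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random open reading frame: sense codons only, no internal stops."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _frame0_stops(seq: str) -> list[int]:
    return [i for i in range(0, len(seq) - 2, 3) if seq[i : i + 3] in STOP_CODONS]


@dataclass
class DegradationResult:
    """A degenerated coding sequence plus the full edit log."""

    sequence: str
    edits: list[dict]
    stop_positions: list[int]  # nt start of each planted in-frame stop codon
    n_substitutions: int
    n_indels: int


def degrade_coding_sequence(
    cds: str,
    nt_rate: float,
    indel_rate: float,
    n_stops: int,
    seed: int,
) -> DegradationResult:
    """Simulate post-duplication degeneration of a coding sequence.

    Applies point substitutions (binomially at ``nt_rate`` per site, never
    creating an in-frame stop by themselves), then plants exactly
    ``n_stops`` stop codons in the coding frame at codon positions drawn
    uniformly away from the first and last three codons, then applies short
    indels (events at ``indel_rate`` per site, lengths 1–3 bp) that never
    touch a planted stop codon.  Because the stops are planted before the
    indels, they always disrupt the exon-homologous reading frame: with
    ``indel_rate=0`` the frame-0 translation contains exactly ``n_stops``
    stop symbols, and with indels every planted stop codon survives intact
    at its (shifted) recorded position.  Every edit is recorded.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise PreconditionError("cds length must be divisible by 3")
    if _frame0_stops(cds):
        raise PreconditionError("cds contains an internal in-frame stop codon")
    if n_stops < 0:
        raise ConfigurationError("n_stops must be >= 0")
    rng = np.random.default_rng(seed)
    seq = list(cds)
    edits: list[dict] = []

    # substitutions, avoiding incidental frame-0 stop creation
    n_sub = int(rng.binomial(len(seq), nt_rate)) if nt_rate > 0 else 0
    if n_sub:
        positions = sorted(rng.choice(len(seq), size=n_sub, replace=False))
        for pos in positions:
            old = seq[pos]
            codon_start = (pos // 3) * 3
            alts = [b for b in "ACGT" if b != old]
            alts = [alts[k] for k in rng.permutation(len(alts))]
            for alt in alts:
                trial = seq[codon_start:codon_start + 3]
                trial[pos - codon_start] = alt
                if "".join(trial) not in STOP_CODONS:
                    seq[pos] = alt
                    edits.append({"op": "sub", "pos": int(pos), "from": old, "to": alt})
                    break

    # plant stops in the coding frame (before indels, so they always break
    # the exon-homologous reading)
    stop_positions: list[int] = []
    n_codons = len(seq) // 3
    if n_stops:
        if n_codons < n_stops + 6:
            raise PreconditionError("sequence too short to plant the requested stops")
        codon_choices = rng.choice(
            np.arange(3, n_codons - 3), size=n_stops, replace=False
        )
        stop_options = sorted(STOP_CODONS)
        for codon_idx in sorted(int(c) for c in codon_choices):
            stop = stop_options[int(rng.integers(0, 3))]
            pos = codon_idx * 3
            old = "".join(seq[pos : pos + 3])
            seq[pos : pos + 3] = list(stop)
            stop_positions.append(pos)
            edits.append({"op": "stop", "pos": pos, "from": old, "to": stop})

    # indels (1-3 bp), applied left to right, never touching a planted stop
    n_indel_events = int(rng.binomial(len(seq), indel_rate)) if indel_rate > 0 else 0
    for _ in range(n_indel_events):
        if len(seq) < 30:
            break
        size = int(rng.integers(1, 4))
        deletion = rng.random() < 0.5
        pos = None
        for _attempt in range(50):
            cand = int(rng.integers(3, len(seq) - 3 - size))
            if deletion:
                clash = any(cand < s + 3 and s < cand + size for s in stop_positions)
            else:
                clash = any(s < cand < s + 3 for s in stop_positions)
            if not clash:
                pos = cand
                break
        if pos is None:
            continue
        if deletion:
            removed = "".join(seq[pos : pos + size])
            del seq[pos : pos + size]
            edits.append({"op": "del", "pos": pos, "seq": removed})
            stop_positions = [s - size if s > pos else s for s in stop_positions]
        else:
            ins = random_sequence(rng, size)
            seq[pos:pos] = list(ins)
            edits.append({"op": "ins", "pos": pos, "seq": ins})
            stop_positions = [s + size if s >= pos else s for s in stop_positions]

    return DegradationResult(
        sequence="".join(seq),
        edits=edits,
        stop_positions=stop_positions,
        n_substitutions=n_sub,
        n_indels=n_indel_events,
    )


def evolve_sequence(
    cds: str,
    mode: str,
    n_substitutions: int,
    seed: int,
    anchors: set[int] | None = None,
) -> str:
    """Apply ``n_substitutions`` point substitutions under a selection regime.

    ``protein_constrained`` accepts only synonymous changes (the coding
    regime); ``neutral`` accepts anything; ``nucleotide_constrained`` (the
    RR-like regime) accepts anything outside the ``anchors`` positions,
    which stand in for functional binding sites.
    """
    if mode not in ("protein_constrained", "nucleotide_constrained", "neutral"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise PreconditionError("cds length must be divisible by 3")
    anchors = anchors or set()
    rng = np.random.default_rng(seed)
    seq = list(cds)
    applied = 0
    attempts = 0
    max_attempts = max(2000, 400 * n_substitutions)
    while applied < n_substitutions:
        attempts += 1
        if attempts > max_attempts:
            raise RRGenesisError(
                f"could not place {n_substitutions} substitutions in mode {mode!r} "
                f"after {max_attempts} attempts"
            )
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != old]))
        if mode == "nucleotide_constrained" and pos in anchors:
            continue
        if mode == "protein_constrained":
            start = (pos // 3) * 3
            codon = seq[start : start + 3]
            trial = codon.copy()
            trial[pos - start] = alt
            if CODON_TO_AA["".join(trial)] != CODON_TO_AA["".join(codon)]:
                continue
        seq[pos] = alt
        applied += 1
    return "".join(seq)


# --- scenario assembly ------------------------------------------------------


class _ContigBuilder:
    def __init__(self, name: str, rng: np.random.Generator):
        self.name = name
        self.rng = rng
        self.parts: list[str] = []
        self.cursor = 0

    def spacer(self, n: int) -> None:
        self.parts.append(random_sequence(self.rng, int(n)))
        self.cursor += int(n)

    def place(self, seq: str) -> tuple[int, int]:
        start = self.cursor
        self.parts.append(seq)
        self.cursor += len(seq)
        return start, self.cursor

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


class _Scenario:
    """Mutable state while one bundle is assembled."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.ref_genome: dict[str, str] = {}
        self.ref_genes: list[GeneRecord] = []
        self.ref_exons: dict[str, tuple[str, int, int, str]] = {}
        self.tgt_genome: dict[str, str] = {}
        self.tgt_genes: list[GeneRecord] = []
        self.tgt_ests: list[GeneRecord] = []
        self.orthology: dict[str, list[str]] = {}
        self.gene2go: dict[str, list[str]] = {}
        self.truth: list[TruthRecord] = []
        self.msas: dict[str, dict[str, str]] = {}
        self.tfbs_truth: dict[str, dict] = {}
        self.pwms = _make_pwms()
        # scaled funnel thresholds the layout must respect
        self.fuse_gap = config.scaled(1_000)
        self.prox = config.scaled(2_000_000)
        self.window = config.scaled(300_000)
        self.max_dist = config.scaled(100_000)
        self.inter = max(30, config.scaled(config.intergenic_length))
        self.near = max(30, self.max_dist // 8)
        self.pad = 60

    def seed_for(self, tag: str) -> int:
        # independent deterministic sub-streams, bounded below 2**31
        return int(self.rng.integers(0, 2**31 - 1))

    # -- gene helpers --------------------------------------------------------

    def add_gene(
        self,
        builder: _ContigBuilder,
        gene_id: str,
        seq: str,
        go_terms: tuple[str, ...],
        target: bool,
    ) -> GeneRecord:
        start, end = builder.place(seq)
        rec = GeneRecord(gene_id, builder.name, start, end, "+", go_terms)
        (self.tgt_genes if target else self.ref_genes).append(rec)
        if go_terms:
            self.gene2go[gene_id] = sorted(go_terms)
        return rec

    def link(self, ref_gene: str, tgt_gene: str) -> None:
        self.orthology.setdefault(ref_gene, []).append(tgt_gene)

    def diverged(self, seq: str, factor: float = 0.3) -> str:
        n = max(1, int(len(seq) * self.config.nt_substitution_rate * factor))
        return evolve_sequence(seq, "neutral", n, self.seed_for("div"))

    # -- one reference locus -------------------------------------------------

    def build_reference_locus(
        self, tag: str, flank_go: dict[str, tuple[str, ...]] | None = None
    ) -> tuple[str, str, dict[str, str]]:
        """Reference contig with flanking genes around one focal coding exon.

        Returns (focal gene id, focal CDS, flank gene id -> sequence).
        ``flank_go`` can override per-flank GO terms (keyed L1, L2, R1, ...).
        """
        cfg = self.config
        focal = f"g{tag}"
        builder = _ContigBuilder(f"ref_{tag}", self.rng)
        flank_seqs: dict[str, str] = {}
        names_left = [f"{focal}_L{k}" for k in range(cfg.flanking_gene_count, 0, -1)]
        names_right = [f"{focal}_R{k}" for k in range(1, cfg.flanking_gene_count + 1)]
        go_default = {}
        for name in names_left + names_right:
            short = name.rsplit("_", 1)[1]
            go_default[name] = (DEV_TERM,) if short == "L1" else (NONDEV_TERMS[1],)
            if flank_go and short in flank_go:
                go_default[name] = flank_go[short]
        builder.spacer(self.pad)
        cds = random_cds(self.rng, cfg.exon_length_codons)
        for name in names_left:
            seq = random_sequence(self.rng, GENE_LENGTH)
            flank_seqs[name] = seq
            self.add_gene(builder, name, seq, go_default[name], target=False)
            builder.spacer(self.inter)
        rec = self.add_gene(builder, focal, cds, (NONDEV_TERMS[0],), target=False)
        self.ref_exons[f"{focal}.e1"] = (builder.name, rec.start, rec.end, "+")
        for name in names_right:
            builder.spacer(self.inter)
            seq = random_sequence(self.rng, GENE_LENGTH)
            flank_seqs[name] = seq
            self.add_gene(builder, name, seq, go_default[name], target=False)
        builder.spacer(self.pad)
        self.ref_genome[builder.name] = builder.sequence
        return focal, cds, flank_seqs

    # -- planted locus -------------------------------------------------------

    def build_planted_locus(self, i: int) -> None:
        cfg = self.config
        focal, cds, flanks = self.build_reference_locus(str(i))

        # retained duplicate: full ortholog complement, focal gene kept coding
        b = _ContigBuilder(f"tgt_{i}_retained", self.rng)
        b.spacer(self.pad)
        order = sorted(flanks)  # L1, L2, ..., R1, ... alphabetical is fine
        left = [n for n in order if "_L" in n][::-1]
        right = [n for n in order if "_R" in n]
        for name in left:
            g = self.add_gene(b, f"{name}_ta", self.diverged(flanks[name]),
                              tuple(self.gene2go.get(name, ())), target=True)
            self.link(name, g.gene_id)
            b.spacer(self.inter)
        coding_orth = evolve_sequence(
            cds, "protein_constrained",
            max(2, int(len(cds) * cfg.nt_substitution_rate * 0.5)),
            self.seed_for("coding"),
        )
        g = self.add_gene(b, f"{focal}_ta", coding_orth, (NONDEV_TERMS[0],), target=True)
        self.link(focal, g.gene_id)
        for name in right:
            b.spacer(self.inter)
            g = self.add_gene(b, f"{name}_ta", self.diverged(flanks[name]),
                              tuple(self.gene2go.get(name, ())), target=True)
            self.link(name, g.gene_id)
        b.spacer(self.pad)
        # an EST elsewhere on the retained contig (exercises EST parsing)
        est_start = self.pad + 10
        self.tgt_ests.append(
            GeneRecord(f"est_{i}", b.name, est_start, est_start + 80, "+", (), True)
        )
        self.tgt_genome[b.name] = b.sequence

        # gene-lost duplicate: flank orthologs only, plus the unannotated relic
        b = _ContigBuilder(f"tgt_{i}_lost", self.rng)
        b.spacer(self.pad)
        for name in left:
            g = self.add_gene(b, f"{name}_tb", self.diverged(flanks[name]),
                              tuple(self.gene2go.get(name, ())), target=True)
            self.link(name, g.gene_id)
            b.spacer(self.near)
        relic = degrade_coding_sequence(
            cds, cfg.nt_substitution_rate, cfg.indel_rate, cfg.n_planted_stops,
            self.seed_for("relic"),
        )
        start, end = b.place(relic.sequence)
        self.truth.append(
            TruthRecord(
                kind="planted_rr",
                violated_filter=None,
                contig=b.name,
                start=start,
                end=end,
                source_exon_id=f"{focal}.e1",
                n_planted_stops=cfg.n_planted_stops,
                stop_positions=relic.stop_positions,
                n_indels=len([e for e in relic.edits if e["op"] in ("ins", "del")]),
            )
        )
        for name in right:
            b.spacer(self.near)
            g = self.add_gene(b, f"{name}_tb", self.diverged(flanks[name]),
                              tuple(self.gene2go.get(name, ())), target=True)
            self.link(name, g.gene_id)
        b.spacer(self.pad)
        self.tgt_genome[b.name] = b.sequence

        self.build_species_cohort(focal, cds)

    # -- cross-species cohort ------------------------------------------------

    def build_species_cohort(self, focal: str, cds: str) -> None:
        """Substitution-only cohort: intact outgroups, shared degenerate teleosts.

        Teleosts share planted stop codons and one planted binding motif
        (the consensus of the first PWM); a bounded deterministic redraw
        guarantees that the planted motif is the *only* teleost-specific
        binding site and that truth labels are exact.
        """
        cfg = self.config
        L = len(cds)
        rate = max(cfg.nt_substitution_rate, 0.02)
        pwm = self.pwms[0]
        n_codons = L // 3

        for attempt in range(25):
            salt = self.seed_for(f"cohort{attempt}")
            rng = np.random.default_rng(salt)
            msa: dict[str, str] = {"human": cds}
            for sp, factor in (("mouse", 0.3), ("chicken", 0.5), ("shark", 0.8)):
                msa[sp] = evolve_sequence(
                    cds, "protein_constrained", max(2, int(L * rate * factor)),
                    int(rng.integers(0, 2**31 - 1)),
                )
            # shared post-duplication state of the teleost relic
            ancestor = list(cds)
            stop_codons = rng.choice(
                np.arange(3, n_codons - 3), size=cfg.n_planted_stops, replace=False
            )
            stop_nt = sorted(int(c) * 3 for c in stop_codons)
            stop_opts = sorted(STOP_CODONS)
            for pos in stop_nt:
                ancestor[pos : pos + 3] = list(stop_opts[int(rng.integers(0, 3))])
            # plant the motif clear of the stops and the sequence edges
            motif = pwm.consensus
            placed = None
            occupied = set()
            for p in stop_nt:
                occupied.update(range(p, p + 3))
            for _ in range(200):
                pos = int(rng.integers(6, L - len(motif) - 6))
                if not occupied & set(range(pos, pos + len(motif))):
                    placed = pos
                    break
            if placed is None:
                continue
            ancestor[placed : placed + len(motif)] = list(motif)
            anchors = set(range(placed, placed + len(motif)))
            for p in stop_nt:
                anchors.update(range(p, p + 3))
            for sp in TELEOSTS:
                msa[sp] = evolve_sequence(
                    "".join(ancestor), "nucleotide_constrained",
                    max(2, int(L * rate * 0.4)),
                    int(rng.integers(0, 2**31 - 1)), anchors=anchors,
                )
            if self._cohort_clean(msa, pwm, placed):
                self.msas[focal] = msa
                self.tfbs_truth[focal] = {
                    "matrix_id": pwm.matrix_id,
                    "start": placed,
                    "end": placed + len(motif),
                    "stop_positions": stop_nt,
                    "teleosts": list(TELEOSTS),
                }
                return
        raise RRGenesisError(
            f"could not build a clean species cohort for {focal} after 25 attempts"
        )

    def _cohort_clean(self, msa: dict[str, str], pwm: tfa.PWM, placed: int) -> bool:
        """True iff the planted motif is the only teleost-specific binding site."""
        hits = tfa.scan_aligned(msa, self.pwms, rel_threshold=0.8)
        ancestor = tfa.reconstruct_ancestor(msa, SPECIES_TREE, ANCESTOR_NODE)
        lengths = {p.matrix_id: p.length for p in self.pwms}
        anc_hits = []
        for p in self.pwms:
            anc_hits.extend(tfa.scan_pwm(ancestor.sequence, p, 0.8, "ancestor"))
        for h in anc_hits:  # the cohort MSA is gap-free: columns == positions
            h.aligned_start = h.position
            h.aligned_end = h.position + lengths[h.matrix_id]
        specific = tfa.lineage_specific_sites(
            {sp: hits[sp] for sp in TELEOSTS},
            {sp: hits[sp] for sp in OUTGROUPS},
            anc_hits,
        )
        if len(specific) != 1:
            return False
        s = specific[0]
        return s.matrix_id == pwm.matrix_id and s.position == placed

    # -- decoy loci ----------------------------------------------------------

    def build_decoy_locus(self, cls: str) -> None:
        cfg = self.config
        tag = f"d_{cls}"
        flank_go = {"L2": (NONDEV_TERMS[0],)}
        focal, cds, flanks = self.build_reference_locus(tag, flank_go=flank_go)
        dev_gene = f"{focal}_L1"
        nondev_gene = f"{focal}_L2"
        exon_id = f"{focal}.e1"
        stops = cfg.n_planted_stops

        def relic_seq(n_stops: int = stops, mode: str | None = None) -> DegradationResult:
            if mode == "intact":
                seq = evolve_sequence(
                    cds, "protein_constrained",
                    max(2, int(len(cds) * cfg.nt_substitution_rate * 0.6)),
                    self.seed_for("decoy"),
                )
                return DegradationResult(seq, [], [], 0, 0)
            return degrade_coding_sequence(
                cds, cfg.nt_substitution_rate, cfg.indel_rate, n_stops,
                self.seed_for("decoy"),
            )

        def place_orth(builder, ref_gene, suffix, go=None) -> GeneRecord:
            seq = self.diverged(flanks[ref_gene] if ref_gene in flanks else cds)
            terms = tuple(self.gene2go.get(ref_gene, ())) if go is None else go
            g = self.add_gene(builder, f"{ref_gene}_{suffix}", seq, terms, target=True)
            self.link(ref_gene, g.gene_id)
            return g

        def separate_ortholog_contig() -> None:
            b2 = _ContigBuilder(f"tgt_{tag}_orth", self.rng)
            b2.spacer(self.pad)
            orth = evolve_sequence(
                cds, "protein_constrained",
                max(2, int(len(cds) * cfg.nt_substitution_rate * 0.5)),
                self.seed_for("orth"),
            )
            g = self.add_gene(b2, f"{focal}_ta", orth, (NONDEV_TERMS[0],), target=True)
            self.link(focal, g.gene_id)
            b2.spacer(self.pad)
            self.tgt_genome[b2.name] = b2.sequence

        b = _ContigBuilder(f"tgt_{tag}", self.rng)
        b.spacer(self.pad)

        if cls == "ortholog_presence":
            # focal gene deliberately absent from the orthology map
            place_orth(b, dev_gene, "tb")
            b.spacer(self.near)
            res = relic_seq()
            start, end = b.place(res.sequence)
            b.spacer(self.near)
            place_orth(b, nondev_gene, "tb")
        elif cls == "ortholog_proximity":
            # the focal ortholog sits on the same contig, within the radius
            orth_seq = evolve_sequence(
                cds, "protein_constrained",
                max(2, int(len(cds) * cfg.nt_substitution_rate * 0.5)),
                self.seed_for("orth"),
            )
            g = self.add_gene(b, f"{focal}_ta", orth_seq, (NONDEV_TERMS[0],), target=True)
            self.link(focal, g.gene_id)
            b.spacer(max(3 * self.fuse_gap + 10, self.near))
            place_orth(b, dev_gene, "tb")
            b.spacer(self.near)
            res = relic_seq()
            start, end = b.place(res.sequence)
        elif cls == "exonic_overlap":
            separate_ortholog_contig()
            place_orth(b, dev_gene, "tb")
            b.spacer(self.near)
            res = relic_seq()
            start, end = b.place(res.sequence)
            # an EST overlapping the relic's tail by 30 bp
            self.tgt_ests.append(
                GeneRecord(f"est_{tag}", b.name, end - 30, end + 40, "+", (), True)
            )
            b.spacer(self.near)
            place_orth(b, nondev_gene, "tb")
        elif cls == "synteny":
            separate_ortholog_contig()
            place_orth(b, dev_gene, "tb")
            # farther than max_dist but still inside the flank window
            b.spacer(self.max_dist + max(30, (self.window - self.max_dist) // 3))
            res = relic_seq()
            start, end = b.place(res.sequence)
            b.spacer(self.near)
            place_orth(b, nondev_gene, "tb")
        elif cls == "developmental_flank":
            separate_ortholog_contig()
            place_orth(b, dev_gene, "tb")
            b.spacer(self.near)
            # a non-developmental gene shields the relic from the dev flank
            place_orth(b, nondev_gene, "tb")
            b.spacer(self.near)
            res = relic_seq()
            start, end = b.place(res.sequence)
            b.spacer(self.near)
            g = self.add_gene(
                b, f"{focal}_X_tb", random_sequence(self.rng, GENE_LENGTH),
                (NONDEV_TERMS[1],), target=True,
            )
        elif cls == "frame_disruption":
            separate_ortholog_contig()
            place_orth(b, dev_gene, "tb")
            b.spacer(self.near)
            res = relic_seq(mode="intact")
            start, end = b.place(res.sequence)
            b.spacer(self.near)
            place_orth(b, nondev_gene, "tb")
        else:  # pragma: no cover - guarded by ScenarioConfig validation
            raise ConfigurationError(f"unknown decoy class {cls!r}")

        b.spacer(self.pad)
        self.tgt_genome[b.name] = b.sequence
        self.truth.append(
            TruthRecord(
                kind="decoy",
                violated_filter=cls,
                contig=b.name,
                start=start,
                end=end,
                source_exon_id=exon_id,
                n_planted_stops=len(res.stop_positions),
                stop_positions=res.stop_positions,
                n_indels=len([e for e in res.edits if e["op"] in ("ins", "del")]),
            )
        )


def _make_pwms() -> list[tfa.PWM]:
    pwms = []
    for matrix_id, name, consensus in _PWM_SPECS:
        counts = np.ones((4, len(consensus)))
        for j, base in enumerate(consensus):
            counts["ACGT".index(base), j] = 97.0
        pwms.append(tfa.PWM(matrix_id=matrix_id, name=name, counts=counts))
    return pwms


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Build a complete synthetic bundle; deterministic in ``config.seed``."""
    s = _Scenario(config)
    for i in range(1, config.n_reference_genes + 1):
        s.build_planted_locus(i)
    for cls in sorted(config.decoy_classes):
        s.build_decoy_locus(cls)
    return ScenarioBundle(
        config=config,
        reference_genome=s.ref_genome,
        reference_genes=s.ref_genes,
        reference_exons=s.ref_exons,
        target_genome=s.tgt_genome,
        target_genes=s.tgt_genes,
        target_ests=s.tgt_ests,
        orthology={k: sorted(v) for k, v in s.orthology.items()},
        gene2go=s.gene2go,
        species_tree=SPECIES_TREE,
        pwms=s.pwms,
        msas=s.msas,
        truth=s.truth,
        tfbs_truth=s.tfbs_truth,
    )
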