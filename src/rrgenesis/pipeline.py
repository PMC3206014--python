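"""End-to-end orchestration: simulate -> map/discover -> evo -> tfbs -> report.

``run_pipeline`` wires the modules together over a single configuration,
writes every stage's outputs under one directory and records a run manifest
(config snapshot, input checksums, per-stage wall times).  All scientific
outputs (candidates, funnel report, evo/tfbs tables, the summary report)
are deterministic given the seed; timings live only in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import ConfigurationError, RRGenesisError
from .evo_analysis import (
    SpeciesSequenceSet,
    contrast_kaks,
    global_align,
    identity_profile,
    kaks_from_alignment,
)
from .homology_mapping import read_fasta
from .rr_filtering import (
    BundlePaths,
    FunnelConfig,
    FunnelReport,
    RRCandidate,
    candidates_to_bed,
    candidates_to_tsv,
    run_funnel,
)
from .synthetic_data import (
    ANCESTOR_NODE,
    OUTGROUPS,
    TELEOSTS,
    ScenarioConfig,
    generate_scenario,
)
from . import tfbs_analysis as tfa

logger = logging.getLogger(__name__)

_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}
_FUNNEL_FIELDS = {f.name for f in dataclasses.fields(FunnelConfig)}


@dataclass
class PipelineConfig:
    """Everything one ``rrgenesis all`` run needs; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "rr_out"
    bundle_dir: str | None = None  # reuse an existing bundle instead of simulating
    scenario: dict = field(default_factory=dict)
    funnel: dict = field(default_factory=dict)
    disable_stages: tuple[str, ...] = ()
    reference_species: str = "human"
    query_species: str = "medaka"
    teleosts: tuple[str, ...] = TELEOSTS
    ancestor_node: str = ANCESTOR_NODE
    rel_threshold: float = 0.8

    def __post_init__(self) -> None:
        bad = set(self.scenario) - _SCENARIO_FIELDS
        if bad:
            raise ConfigurationError(f"unknown scenario keys: {sorted(bad)}")
        bad = set(self.funnel) - _FUNNEL_FIELDS
        if bad:
            raise ConfigurationError(f"unknown funnel keys: {sorted(bad)}")
        if not 0.0 < self.rel_threshold <= 1.0:
            raise ConfigurationError("rel_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        for tuple_key in ("disable_stages", "teleosts"):
            if tuple_key in data:
                data[tuple_key] = tuple(data[tuple_key])
        return cls(**data)

    def scenario_config(self) -> ScenarioConfig:
        kwargs = dict(self.scenario)
        kwargs.setdefault("seed", self.seed)
        return ScenarioConfig(**kwargs)

    def funnel_config(self) -> FunnelConfig:
        return FunnelConfig(**self.funnel)


@dataclass
class RunManifest:
    config: dict
    version: str
    input_checksums: dict[str, str]
    timings: dict[str, float]
    n_candidates: int
    funnel_report: str

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, Path]:
    """Execute every enabled stage; returns the manifest and the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def timed(stage):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, *exc):
                timings[stage] = round(time.perf_counter() - self_.t0, 4)
                return False

        return _T()

    # 1. simulate (or reuse a bundle)
    if config.bundle_dir is None:
        with timed("simulate"):
            bundle = generate_scenario(config.scenario_config())
            bundle_dir = bundle.write(out / "bundle")
    else:
        bundle_dir = Path(config.bundle_dir)
        if not bundle_dir.is_dir():
            raise RRGenesisError(f"bundle directory {bundle_dir} does not exist")
    paths = BundlePaths(bundle_dir)

    checksums = {
        p.name: _checksum(p) for p in sorted(bundle_dir.glob("*")) if p.is_file()
    }

    # 2. discover (map + fuse + funnel)
    with timed("discover"):
        candidates, report = run_funnel(
            bundle_dir, config.funnel_config(), disable=set(config.disable_stages)
        )
        candidates_to_tsv(candidates, out / "candidates.tsv")
        candidates_to_bed(candidates, out / "candidates.bed")
        report.write_json(out / "funnel_report.json")
        report.write_tsv(out / "funnel_report.tsv")

    # 3+4. per-candidate cross-species diagnostics, where a cohort exists
    with timed("evo_tfbs"):
        evo_rows, tfbs_rows = _characterize(candidates, paths, config)
    _write_tsv(evo_rows, out / "evo_profiles.tsv")
    _write_tsv(tfbs_rows, out / "tfbs_summary.tsv")

    # 5. report
    with timed("report"):
        summary = render_report(report, candidates, evo_rows, tfbs_rows)
        (out / "report.txt").write_text(summary["text"])
        with open(out / "report.json", "w") as fh:
            json.dump(summary["json"], fh, indent=1, sort_keys=True)
            fh.write("\n")

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        input_checksums=checksums,
        timings=timings,
        n_candidates=len(candidates),
        funnel_report=str(out / "funnel_report.json"),
    )
    manifest.write(out / "manifest.json")
    return manifest, out


def _characterize(
    candidates: list[RRCandidate], paths: BundlePaths, config: PipelineConfig
) -> tuple[list[dict], list[dict]]:
    """Evo + TFBS diagnostics for every candidate with a species cohort."""
    evo_rows: list[dict] = []
    tfbs_rows: list[dict] = []
    if not paths.msa_dir.is_dir():
        return evo_rows, tfbs_rows
    pwms = tfa.load_pwms(paths.pwms) if paths.pwms.exists() else []
    tree = paths.species_tree.read_text().strip() if paths.species_tree.exists() else None
    for cand in sorted(candidates, key=lambda c: c.candidate_id):
        msa_path = paths.msa_dir / f"{cand.gene_id}.fa"
        if not msa_path.exists():
            continue
        msa = read_fasta(msa_path)
        ref = config.reference_species
        query = config.query_species
        if ref not in msa or query not in msa:
            logger.warning("cohort %s lacks %s/%s; skipped", msa_path, ref, query)
            continue

        # candidate relic vs reference exon, plus the within-cohort profiles
        sset = SpeciesSequenceSet(sequences=msa, reference=ref, query=query)
        aln_rr = global_align(cand.exon.sequence, cand.region_sequence)
        rr_profile = identity_profile(aln_rr, reference="a", species="rr_region")
        rr_kaks = kaks_from_alignment(aln_rr)
        query_kaks = sset.kaks(query)
        coding_species = next(
            (s for s in OUTGROUPS if s != ref and s in msa), None
        )
        contrast = None
        if coding_species:
            contrast = contrast_kaks(query_kaks, sset.kaks(coding_species))
        for prof in sset.profiles():
            evo_rows.append(
                {
                    "candidate_id": cand.candidate_id,
                    "species": prof.species,
                    "nt_identity_pct": round(prof.nt_identity_pct, 2),
                    "aa_similarity_pct": round(prof.aa_similarity_pct, 2),
                    "alignable_length": prof.alignable_length,
                }
            )
        evo_rows.append(
            {
                "candidate_id": cand.candidate_id,
                "species": "rr_region_vs_exon",
                "nt_identity_pct": round(rr_profile.nt_identity_pct, 2),
                "aa_similarity_pct": round(rr_profile.aa_similarity_pct, 2),
                "alignable_length": rr_profile.alignable_length,
                "ka": None if rr_kaks.saturated else round(rr_kaks.ka, 4),
                "ks": None if rr_kaks.saturated else round(rr_kaks.ks, 4),
                "kaks": rr_kaks.ratio if isinstance(rr_kaks.ratio, str)
                else round(rr_kaks.ratio, 4),
                "removed_stops": rr_kaks.removed_stops,
                "removed_indels": rr_kaks.removed_indels,
                "coding_signature": contrast.coding_signature if contrast else "NA",
            }
        )

        if pwms and tree:
            hits = tfa.scan_aligned(msa, pwms, config.rel_threshold)
            ancestor = tfa.reconstruct_ancestor(msa, tree, config.ancestor_node)
            anc_hits = []
            lengths = {p.matrix_id: p.length for p in pwms}
            anc_ungapped = ancestor.sequence.replace("-", "")
            for p in pwms:
                anc_hits.extend(
                    tfa.scan_pwm(anc_ungapped, p, config.rel_threshold, "ancestor")
                )
            col_of = [i for i, c in enumerate(ancestor.sequence) if c != "-"]
            for h in anc_hits:
                h.aligned_start = col_of[h.position]
                h.aligned_end = col_of[h.position + lengths[h.matrix_id] - 1] + 1
            teleosts = [t for t in config.teleosts if t in msa]
            others = {s: hs for s, hs in hits.items() if s not in teleosts}
            specific = tfa.lineage_specific_sites(
                {t: hits[t] for t in teleosts}, others, anc_hits
            )
            s200_rr = tfa.s200(
                {cand.candidate_id: cand.region_sequence}, pwms,
                config.rel_threshold,
            )
            tfbs_rows.append(
                {
                    "candidate_id": cand.candidate_id,
                    "n_teleost_specific_sites": len(specific),
                    "specific_matrices": ",".join(
                        sorted({h.matrix_id for h in specific})
                    ),
                    "s200": round(
                        s200_rr.values.get(cand.candidate_id, 0.0), 3
                    ),
                    "ancestor_node": config.ancestor_node,
                }
            )
    return evo_rows, tfbs_rows


def _write_tsv(rows: list[dict], path) -> None:
    import pandas as pd

    if rows:
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        path.write_text("")


def render_report(
    report: FunnelReport,
    candidates: list[RRCandidate],
    evo_rows: list[dict] | None = None,
    tfbs_rows: list[dict] | None = None,
) -> dict:
    """Human-readable funnel/candidate summary plus its machine-readable twin."""
    lines = ["RECYCLED-REGION DISCOVERY REPORT", "", "Filter funnel:"]
    lines.append(f"  {'stage':<22}{'in':>6}{'out':>6}{'dropped':>9}")
    for s in report.stages:
        lines.append(f"  {s.stage:<22}{s.n_in:>6}{s.n_out:>6}{len(s.dropped):>9}")
    if report.stages:
        last_nonempty = next(
            (s.stage for s in reversed(report.stages) if s.n_out > 0), "none"
        )
    else:
        last_nonempty = "none"
    lines.append("")
    lines.append(f"Candidates: {len(candidates)}")
    if not candidates:
        lines.append(f"  (no candidates; last non-empty stage: {last_nonempty})")
    for c in sorted(candidates, key=lambda c: c.candidate_id):
        ev = c.frame_evidence
        stops = len(ev.stops_by_frame.get("+0", [])) if ev else "n/a"
        lines.append(
            f"  {c.candidate_id}  gene={c.gene_id}  "
            f"flanks={','.join(c.flanking_gene_ids) or '-'}  frame0_stops={stops}"
        )
    by_cand: dict[str, dict] = {}
    for row in evo_rows or []:
        if row.get("species") == "rr_region_vs_exon":
            by_cand[row["candidate_id"]] = row
    for row in tfbs_rows or []:
        by_cand.setdefault(row["candidate_id"], {}).update(row)
    if by_cand:
        lines.append("")
        lines.append("Evolutionary diagnostics:")
        for cid in sorted(by_cand):
            row = by_cand[cid]
            lines.append(
                f"  {cid}  NTid={row.get('nt_identity_pct', 'n/a')}%  "
                f"AAsim={row.get('aa_similarity_pct', 'n/a')}%  "
                f"Ka/Ks={row.get('kaks', 'n/a')}  "
                f"teleost_TFBS={row.get('n_teleost_specific_sites', 'n/a')}"
            )
    text = "\n".join(lines) + "\n"
    payload = {
        "funnel": report.to_dict(),
        "n_candidates": len(candidates),
        "last_non_empty_stage": last_nonempty,
        "candidates": [
            {
                "candidate_id": c.candidate_id,
                "gene_id": c.gene_id,
                "contig": c.hit.target_contig,
                "start": c.hit.target_start,
                "end": c.hit.target_end,
                "flanking_genes": c.flanking_gene_ids,
                "frame0_stops": (
                    len(c.frame_evidence.stops_by_frame.get("+0", []))
                    if c.frame_evidence else None
                ),
            }
            for c in sorted(candidates, key=lambda c: c.candidate_id)
        ],
        "diagnostics": by_cand,
    }
    return {"text": text, "json": payload}
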