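"""Tests for the discovery funnel: individual filters and the full chain."""

import json

import numpy as np
import pytest

from rrgenesis.errors import ConfigurationError, InputError
from rrgenesis.homology_mapping import AlignmentHit, ExonRecord, FusedHit
from rrgenesis.rr_filtering import (
    FILTER_STAGES,
    FunnelConfig,
    GeneModel,
    assess_frame_disruption,
    assess_synteny,
    developmental_closure,
    filter_developmental_flank,
    filter_exonic_overlap,
    filter_ortholog_presence,
    filter_ortholog_proximity,
    run_funnel,
)
from rrgenesis.synthetic_data import (
    degrade_coding_sequence,
    evolve_sequence,
    random_cds,
)

from conftest import SCALE, reciprocal_overlap
from _oracles import sw_protein_coverage

from Bio.Seq import Seq


def fused(start, end, exon="g1.e1", contig="t1", score=100.0):
    hit = AlignmentHit(exon, contig, start, end, "+", score)
    return FusedHit(exon, contig, start, end, "+", score, [hit])


def gene(gene_id, contig, start, end, go=(), exons=None):
    return GeneModel(gene_id, contig, start, end, "+",
                     exons=exons if exons is not None else [(start, end)],
                     go_terms=set(go))


EXON2GENE = {"g1.e1": "g1", "g2.e1": "g2"}


class TestDevelopmentalClosure:
    def test_descendants_included(self, bundle_dir):
        closure = developmental_closure(bundle_dir / "ontology.obo")
        assert "GO:0032502" in closure          # root itself
        assert "GO:0007420" in closure          # is_a descendant
        assert "GO:0003700" in closure          # root from the MF branch

    def test_unrelated_branch_excluded(self, bundle_dir):
        closure = developmental_closure(bundle_dir / "ontology.obo")
        assert "GO:0008152" not in closure
        assert "GO:0016310" not in closure

    def test_childless_roots_fixpoint(self, bundle_dir):
        closure = developmental_closure(
            bundle_dir / "ontology.obo", roots=("GO:0007420",)
        )
        assert closure == {"GO:0007420"}

    def test_missing_root_error(self, bundle_dir):
        with pytest.raises(ConfigurationError, match="GO:9999999"):
            developmental_closure(bundle_dir / "ontology.obo", roots=("GO:9999999",))


class TestOrthologPresence:
    def test_gene_with_orthologs_kept(self):
        kept, dropped = filter_ortholog_presence(
            [fused(0, 100)], EXON2GENE, {"g1": {"t_a", "t_b"}}
        )
        assert len(kept) == 1 and not dropped

    def test_gene_without_ortholog_dropped(self):
        kept, dropped = filter_ortholog_presence(
            [fused(0, 100)], EXON2GENE, {"g2": {"t_a"}}
        )
        assert not kept and len(dropped) == 1

    def test_empty_orthology_drops_all(self):
        kept, dropped = filter_ortholog_presence([fused(0, 100)], EXON2GENE, {})
        assert not kept and len(dropped) == 1

    def test_unresolvable_gene_error(self):
        with pytest.raises(InputError):
            filter_ortholog_presence([fused(0, 100, exon="gX.e1")], {}, {})


class TestOrthologProximity:
    def _genes(self):
        return {"t1_orth": gene("t1_orth", "t1", 0, 1000)}

    def test_within_radius_removed(self):
        hit = fused(1_901_000, 1_901_100)  # 1.9 Mb from the ortholog
        kept, dropped = filter_ortholog_proximity(
            [hit], EXON2GENE, {"g1": {"t1_orth"}}, self._genes()
        )
        assert not kept and dropped

    def test_beyond_radius_kept(self):
        hit = fused(2_101_000, 2_101_100)  # 2.1 Mb away
        kept, dropped = filter_ortholog_proximity(
            [hit], EXON2GENE, {"g1": {"t1_orth"}}, self._genes()
        )
        assert kept and not dropped

    def test_different_contig_is_infinitely_distant(self):
        hit = fused(10, 100, contig="t2")
        kept, _ = filter_ortholog_proximity(
            [hit], EXON2GENE, {"g1": {"t1_orth"}}, self._genes()
        )
        assert kept


class TestExonicOverlap:
    def test_one_bp_overlap_removed(self):
        genes = {"tg": gene("tg", "t1", 100, 200)}
        kept, dropped = filter_exonic_overlap([fused(199, 300)], genes, [])
        assert not kept and dropped

    def test_half_open_touch_kept(self):
        genes = {"tg": gene("tg", "t1", 100, 200)}
        kept, _ = filter_exonic_overlap([fused(200, 300)], genes, [])
        assert kept

    def test_est_overlap_removed(self):
        est = GeneModel("est1", "t1", 150, 250, "+", is_est=True)
        kept, dropped = filter_exonic_overlap([fused(200, 300)], {}, [est])
        assert not kept and dropped

    def test_intronic_hit_kept(self):
        genes = {
            "tg": gene("tg", "t1", 0, 1000, exons=[(0, 100), (900, 1000)])
        }
        kept, _ = filter_exonic_overlap([fused(400, 500)], genes, [])
        assert kept


class TestSynteny:
    """Hand-built loci exercising the 100 kb / 5-gene / 300 kb rules."""

    REF_GENES = {
        "g1": gene("g1", "r1", 500_000, 500_300),
        "dev": gene("dev", "r1", 400_000, 400_300, go={"GO:0007420"}),
    }
    REF_EXONS = {"g1.e1": ("r1", 500_000, 500_300, "+")}
    ORTH = {"g1": {"g1_t"}, "dev": {"dev_t"}}
    CLOSURE = {"GO:0032502", "GO:0007420"}

    def _run(self, hits, target_genes):
        return assess_synteny(
            hits, EXON2GENE, self.REF_GENES, self.REF_EXONS, self.ORTH,
            target_genes, self.CLOSURE,
        )

    def test_close_hit_few_intervening_retained(self):
        tg = {
            "dev_t": gene("dev_t", "t1", 0, 1000),
            "a": gene("a", "t1", 10_000, 11_000),
            "b": gene("b", "t1", 20_000, 21_000),
            "c": gene("c", "t1", 30_000, 31_000),
        }
        kept, _ = self._run([fused(51_000, 51_200)], tg)  # 50 kb, 3 intervening
        assert kept

    def test_distance_150kb_dropped(self):
        tg = {"dev_t": gene("dev_t", "t1", 0, 1000)}
        kept, dropped = self._run([fused(151_000, 151_200)], tg)
        assert not kept and dropped

    def test_six_intervening_genes_dropped(self):
        tg = {"dev_t": gene("dev_t", "t1", 0, 1000)}
        for k in range(6):
            s = 2000 + k * 1000
            tg[f"i{k}"] = gene(f"i{k}", "t1", s, s + 500)
        kept, _ = self._run([fused(60_000, 60_200)], tg)
        assert not kept

    def test_two_hits_of_one_gene_within_window_all_dropped(self):
        tg = {"dev_t": gene("dev_t", "t1", 0, 1000)}
        hits = [fused(10_000, 10_200), fused(210_000, 210_200)]  # 200 kb apart
        kept, dropped = self._run(hits, tg)
        assert not kept and len(dropped) == 2

    def test_dev_gene_outside_ref_window_does_not_rescue(self):
        far = dict(self.REF_GENES)
        far["dev"] = gene("dev", "r1", 900_000, 900_300, go={"GO:0007420"})
        tg = {"dev_t": gene("dev_t", "t1", 0, 1000)}
        kept, _ = assess_synteny(
            [fused(10_000, 10_200)], EXON2GENE, far, self.REF_EXONS, self.ORTH,
            tg, self.CLOSURE,
        )
        assert not kept


class TestDevelopmentalFlank:
    CLOSURE = {"GO:0032502", "GO:0007420", "GO:0003700"}

    def test_dev_flanking_gene_keeps_hit(self):
        tg = {"d": gene("d", "t1", 0, 500, go={"GO:0003700"})}
        kept, _ = filter_developmental_flank([fused(1000, 1200)], tg, self.CLOSURE)
        assert kept

    def test_metabolic_flanks_drop_hit(self):
        tg = {
            "m1": gene("m1", "t1", 0, 500, go={"GO:0008152"}),
            "m2": gene("m2", "t1", 2000, 2500, go={"GO:0016310"}),
        }
        kept, dropped = filter_developmental_flank(
            [fused(1000, 1200)], tg, self.CLOSURE
        )
        assert not kept and dropped

    def test_no_flanking_genes_drops_hit(self):
        kept, dropped = filter_developmental_flank([fused(0, 100)], {}, self.CLOSURE)
        assert not kept and dropped

    def test_shielding_nondev_gene_blocks_distant_dev_gene(self):
        """Only the *nearest* gene per side counts as a flank."""
        tg = {
            "dev": gene("dev", "t1", 0, 300, go={"GO:0007420"}),
            "shield": gene("shield", "t1", 400, 700, go={"GO:0008152"}),
            "right": gene("right", "t1", 2000, 2300, go={"GO:0016310"}),
        }
        kept, _ = filter_developmental_flank([fused(1000, 1200)], tg, self.CLOSURE)
        assert not kept


class TestFrameDisruption:
    def _exon(self, seed=0, n=60):
        return ExonRecord("e1", "g1", random_cds(np.random.default_rng(seed), n))

    def test_verbatim_exon_intact(self):
        exon = self._exon()
        ev = assess_frame_disruption(exon.sequence, exon)
        assert ev.intact
        assert ev.covering_frame == "+0"
        assert ev.stops_by_frame["+0"] == []

    def test_single_planted_stop_disrupts(self):
        exon = self._exon(1)
        region = exon.sequence[:90] + "TAA" + exon.sequence[93:]
        ev = assess_frame_disruption(region, exon)
        assert not ev.intact
        assert ev.stops_by_frame["+0"] == [90]

    def test_one_bp_deletion_disrupts(self):
        exon = self._exon(2)
        region = exon.sequence[:91] + exon.sequence[92:]
        ev = assess_frame_disruption(region, exon)
        assert not ev.intact

    def test_agrees_with_translate_and_align_oracle(self):
        """Disruption calls match a naive 6-frame translate-and-align check."""
        rng = np.random.default_rng(12)
        for i in range(30):
            exon = self._exon(100 + i)
            kind = i % 3
            if kind == 0:  # synonymous divergence: frame intact
                region = evolve_sequence(
                    exon.sequence, "protein_constrained", 12, seed=300 + i
                )
            elif kind == 1:  # stop-planting degeneration
                region = degrade_coding_sequence(
                    exon.sequence, 0.05, 0.0, 2, seed=300 + i
                ).sequence
            else:  # frameshift
                cut = int(rng.integers(30, 150))
                region = exon.sequence[:cut] + exon.sequence[cut + 1:]
            ev = assess_frame_disruption(region, exon)
            oracle_intact = self._oracle_intact(region, exon)
            assert ev.intact == oracle_intact

    @staticmethod
    def _oracle_intact(region, exon, cov=0.95):
        from rrgenesis.evo_analysis import reverse_complement

        pep_exon = str(Seq(exon.sequence).translate()).replace("*", "X")
        for seq in (region, reverse_complement(region)):
            for f in (0, 1, 2):
                sub = seq[f:]
                sub = sub[: len(sub) - len(sub) % 3]
                pep = str(Seq(sub).translate())
                if "*" in pep:
                    continue
                if sw_protein_coverage(pep, pep_exon) >= cov:
                    return True
        return False


class TestRunFunnel:
    def test_planted_rrs_recovered_and_decoys_staged(self, bundle, funnel_result):
        candidates, report = funnel_result
        planted = [t for t in bundle.truth if t.kind == "planted_rr"]
        assert len(candidates) == len(planted)
        for t in planted:
            match = [
                c for c in candidates
                if c.hit.target_contig == t.contig
                and reciprocal_overlap(
                    (c.hit.target_start, c.hit.target_end), (t.start, t.end)
                ) >= 0.8
            ]
            assert match, f"planted RR at {t.contig}:{t.start}-{t.end} not recovered"
        stage_dropped = {s.stage: s.dropped for s in report.stages}
        for t in bundle.truth:
            if t.kind != "decoy":
                continue
            hits_at_stage = [
                d for d in stage_dropped[t.violated_filter]
                if d.split(":")[1] == t.contig
            ]
            assert hits_at_stage, (
                f"decoy for {t.violated_filter} not dropped at its stage"
            )

    def test_disabling_a_filter_admits_exactly_its_decoy(
        self, bundle, bundle_dir, funnel_config
    ):
        decoys = {t.violated_filter: t for t in bundle.truth if t.kind == "decoy"}
        for stage, truth in sorted(decoys.items()):
            candidates, _ = run_funnel(bundle_dir, funnel_config, disable={stage})
            admitted = [
                c for c in candidates
                if c.hit.target_contig == truth.contig
                and reciprocal_overlap(
                    (c.hit.target_start, c.hit.target_end),
                    (truth.start, truth.end),
                ) >= 0.8
            ]
            assert admitted, f"decoy not admitted when {stage} is disabled"
            other_decoys = [
                c for c in candidates
                if c.hit.target_contig.startswith("tgt_d_")
                and c.hit.target_contig != truth.contig
            ]
            assert not other_decoys

    def test_report_counts_chain(self, funnel_result):
        _, report = funnel_result
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert prev.n_out == nxt.n_in
        for s in report.stages:
            assert s.n_out <= s.n_in
            if s.stage in FILTER_STAGES:
                assert s.n_out == s.n_in - len(s.dropped)

    def test_empty_hits_give_zero_report(self, tmp_path, bundle_dir, funnel_config):
        import shutil

        target = tmp_path / "b"
        shutil.copytree(bundle_dir, target)
        # external empty hit file: no hits enter the funnel
        (target / "hits.tsv").write_text("")
        cfg = FunnelConfig(
            scale_divisor=SCALE, hits_path=str(target / "hits.tsv")
        )
        candidates, report = run_funnel(target, cfg)
        assert candidates == []
        assert all(s.n_out == 0 for s in report.stages)

    def test_report_json_roundtrip(self, funnel_result, tmp_path):
        _, report = funnel_result
        path = tmp_path / "report.json"
        report.write_json(path)
        data = json.loads(path.read_text())
        assert [s["stage"] for s in data["stages"]] == [
            s.stage for s in report.stages
        ]
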