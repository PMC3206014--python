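"""Tests for PWM scanning, ancestral reconstruction and S200 statistics."""

import copy

import dendropy
import numpy as np
import pytest

from rrgenesis.errors import InputError, PreconditionError
from rrgenesis.synthetic_data import random_sequence
from rrgenesis.tfbs_analysis import (
    PWM,
    S200Distribution,
    TFBSHit,
    lineage_specific_sites,
    load_pwms,
    reconstruct_ancestor,
    regulatory_potential,
    s200,
    scan_pwm,
    fitch_parsimony_score,
    write_pwms,
)

from _oracles import parsimony_score_oracle, pwm_hits_oracle


def make_pwm(consensus="ACGTACGT", matrix_id="M1"):
    counts = np.ones((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 97.0
    return PWM(matrix_id=matrix_id, name=matrix_id, counts=counts)


class TestPWMLoading:
    def test_single_column_max_at_dominant_base(self):
        pwm = PWM("M", "M", np.array([[10.0], [0.0], [0.0], [0.0]]))
        assert pwm.consensus == "A"
        assert pwm.max_score == pwm.log_odds[0, 0]

    def test_uniform_matrix_skipped_with_warning(self, tmp_path):
        p = tmp_path / "flat.pfm"
        p.write_text(
            ">M0 flat\nA [ 5 5 ]\nC [ 5 5 ]\nG [ 5 5 ]\nT [ 5 5 ]\n"
        )
        with pytest.warns(UserWarning, match="uninformative"):
            assert load_pwms(p) == []

    def test_zero_column_rejected(self):
        with pytest.raises(InputError, match="zero-sum"):
            PWM("M", "M", np.zeros((4, 3)))

    def test_jaspar_roundtrip(self, tmp_path):
        pwms = [make_pwm("ACGTTGCA", "MA0001.1"), make_pwm("TTTTACGT", "MA0002.1")]
        path = tmp_path / "out.pfm"
        write_pwms(pwms, path)
        loaded = load_pwms(path)
        assert [p.matrix_id for p in loaded] == ["MA0001.1", "MA0002.1"]
        for a, b in zip(pwms, loaded):
            np.testing.assert_allclose(a.counts, b.counts)


class TestScanPWM:
    def test_consensus_scores_relative_one(self):
        pwm = make_pwm("ACGTTGCA")
        hits = scan_pwm("GG" + pwm.consensus + "GG", pwm, rel_threshold=0.99)
        plus = [h for h in hits if h.strand == "+"]
        assert plus[0].position == 2
        assert plus[0].rel_score == pytest.approx(1.0)

    def test_anticonsensus_scores_relative_zero(self):
        pwm = make_pwm("ACGTTGCA")
        anti = pwm.anticonsensus
        hits = scan_pwm(anti, pwm, rel_threshold=0.01)
        raw = [h for h in hits if h.strand == "+" and h.position == 0]
        assert raw == []  # relative score 0 is below any positive threshold

    def test_sequence_shorter_than_motif_empty(self):
        assert scan_pwm("ACG", make_pwm("ACGTACGT"), 0.5) == []

    def test_matches_per_position_rescoring_oracle(self):
        rng = np.random.default_rng(21)
        for i in range(10):
            pwm = make_pwm("".join(rng.choice(list("ACGT"), size=8)), f"M{i}")
            seq = random_sequence(rng, 300)
            hits = scan_pwm(seq, pwm, rel_threshold=0.75)
            got = {(h.position, h.strand) for h in hits}
            expected = pwm_hits_oracle(
                seq, pwm.log_odds, pwm.min_score, pwm.max_score, 0.75
            )
            assert got == expected

    def test_relative_score_invariant_to_affine_rescaling(self):
        pwm = make_pwm("ACGTTGCA")
        seq = random_sequence(np.random.default_rng(5), 200)
        before = [(h.position, h.strand, round(h.rel_score, 9))
                  for h in scan_pwm(seq, pwm, 0.6)]
        scaled = copy.deepcopy(pwm)
        scaled.log_odds = 3.0 * scaled.log_odds + 0.25
        scaled.min_score = float(scaled.log_odds.min(axis=0).sum())
        scaled.max_score = float(scaled.log_odds.max(axis=0).sum())
        after = [(h.position, h.strand, round(h.rel_score, 9))
                 for h in scan_pwm(seq, scaled, 0.6)]
        assert before == after


class TestReconstructAncestor:
    TREE = "((a:1,b:1)n1:1,(c:1,d:1)n2:1)root;"

    def test_identical_leaves_identical_ancestor(self):
        msa = {k: "ACGTACGT" for k in "abcd"}
        anc = reconstruct_ancestor(msa, self.TREE, "root")
        assert anc.sequence == "ACGTACGT"
        assert anc.parsimony_score == 0

    def test_two_against_two_gives_ambiguity_code(self):
        msa = {"a": "A", "b": "A", "c": "C", "d": "C"}
        anc = reconstruct_ancestor(msa, self.TREE, "root")
        assert anc.sequence == "M"  # A or C, one change either way

    def test_internal_node_reconstruction(self):
        msa = {"a": "G", "b": "G", "c": "T", "d": "T"}
        anc = reconstruct_ancestor(msa, self.TREE, "n1")
        assert anc.sequence == "G"

    def test_missing_tip_errors_with_names(self):
        msa = {"a": "A", "b": "A", "c": "C"}
        with pytest.raises(InputError, match="d"):
            reconstruct_ancestor(msa, self.TREE, "root")

    def test_unknown_node_errors(self):
        msa = {k: "A" for k in "abcd"}
        with pytest.raises(InputError, match="nope"):
            reconstruct_ancestor(msa, self.TREE, "nope")

    def test_score_matches_bruteforce_on_random_trees(self):
        """Parsimony counts equal exhaustive minimization on trees of 3-6 leaves."""
        rng = np.random.default_rng(33)
        checked = 0
        for n_leaves in (3, 4, 5, 6):
            for rep in range(5):
                taxa = [f"t{k}" for k in range(n_leaves)]
                ns = dendropy.TaxonNamespace(taxa)
                tree = dendropy.simulate.treesim.birth_death_tree(
                    birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves,
                    taxon_namespace=ns,
                    rng=__import__("random").Random(int(rng.integers(1 << 30))),
                )
                msa = {
                    t: "".join(rng.choice(list("ACGT"), size=12)) for t in taxa
                }
                assert fitch_parsimony_score(msa, tree) == \
                    parsimony_score_oracle(tree, msa)
                checked += 1
        assert checked == 20


def _hit(matrix, pos, length=8, species="s", strand="+"):
    return TFBSHit(matrix, species, pos, strand, 1.0, 0.9,
                   aligned_start=pos, aligned_end=pos + length)


class TestLineageSpecificSites:
    def test_site_in_single_teleost_set_reported(self):
        out = lineage_specific_sites({"medaka": [_hit("M1", 10)]}, {}, [])
        assert len(out) == 1

    def test_site_present_in_ancestor_excluded(self):
        out = lineage_specific_sites(
            {"medaka": [_hit("M1", 10)]}, {}, [_hit("M1", 12)]
        )
        assert out == []

    def test_site_present_in_outgroup_excluded(self):
        out = lineage_specific_sites(
            {"medaka": [_hit("M1", 10)]}, {"shark": [_hit("M1", 10)]}, []
        )
        assert out == []

    def test_require_all_teleosts(self):
        query = {"medaka": [_hit("M1", 10)], "stickleback": []}
        assert lineage_specific_sites(query, {}, []) == []
        assert len(
            lineage_specific_sites(query, {}, [], require="any")
        ) == 1

    def test_same_matrix_needs_positional_overlap(self):
        out = lineage_specific_sites(
            {"medaka": [_hit("M1", 10)]}, {"shark": [_hit("M1", 40)]}, []
        )
        assert len(out) == 1

    def test_monotone_shrinkage_with_more_outgroups(self):
        query = {"medaka": [_hit("M1", 10), _hit("M2", 30)]}
        others = {}
        sizes = []
        for sp, hits in (
            ("shark", [_hit("M1", 11)]),
            ("mouse", [_hit("M2", 29)]),
        ):
            sizes.append(len(lineage_specific_sites(query, dict(others), [])))
            others[sp] = hits
        sizes.append(len(lineage_specific_sites(query, others, [])))
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_teleost_set_errors(self):
        with pytest.raises(PreconditionError):
            lineage_specific_sites({}, {}, [])


class TestS200AndRegulatoryPotential:
    def test_s200_arithmetic(self):
        pwm = make_pwm("ACGTTGCA")
        seq = "GG" * 96 + pwm.consensus * 4 + "GG" * 96  # 4 planted sites, 416 bp
        dist = s200({"s1": seq}, [pwm], rel_threshold=0.99)
        n_hits = len(scan_pwm(seq, pwm, 0.99))
        assert dist.values["s1"] == pytest.approx(n_hits * 200.0 / len(seq))
        assert n_hits >= 4

    def test_zero_hits_zero_density(self):
        pwm = make_pwm("ACGTTGCA")
        dist = s200({"s1": "G" * 200}, [pwm], rel_threshold=0.99)
        assert dist.values["s1"] == 0.0

    def test_zero_length_sequence_skipped(self):
        pwm = make_pwm("ACGTTGCA")
        with pytest.warns(UserWarning, match="zero length"):
            dist = s200({"empty": "", "ok": "G" * 50}, [pwm], 0.9)
        assert "empty" not in dist.values

    def test_identical_distributions_overlap_100(self):
        d = S200Distribution("a", {f"s{i}": float(i % 4) for i in range(20)})
        assert regulatory_potential(d, d) == pytest.approx(100.0)

    def test_disjoint_distributions_overlap_0(self):
        a = S200Distribution("a", {"s1": 0.5, "s2": 0.5})
        b = S200Distribution("b", {"s1": 10.5, "s2": 10.5})
        assert regulatory_potential(a, b) == pytest.approx(0.0)

    def test_three_bin_half_overlap(self):
        # proportions (0.5, 0.5, 0) vs (0, 0.5, 0.5): sum of minima = 0.5
        a = S200Distribution("a", {"s1": 0.5, "s2": 1.5})
        b = S200Distribution("b", {"s1": 1.5, "s2": 2.5})
        assert regulatory_potential(a, b) == pytest.approx(50.0)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        a = S200Distribution("a", {f"x{i}": float(v) for i, v in
                                   enumerate(rng.uniform(0, 5, 30))})
        b = S200Distribution("b", {f"y{i}": float(v) for i, v in
                                   enumerate(rng.uniform(2, 8, 30))})
        ab = regulatory_potential(a, b)
        ba = regulatory_potential(b, a)
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 100.0
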