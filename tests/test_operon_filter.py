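import random

import pytest

from genelinker.errors import ConfigError
from genelinker.operon_filter import (DiscardedHit, Operon,
                                      StructuralRequirements,
                                      candidate_partners, evaluate_genome,
                                      evaluate_hit, gene_gap,
                                      has_ambiguous_run)
from genelinker.presets import load_preset

from _factories import make_hit, make_orf


@pytest.fixture()
def ta(ta_requirements):
    return ta_requirements


class TestGeneGap:
    def test_abutting(self):
        a = make_orf(start=1, end=100, protein="M" + "K" * 31,
                     nt_seq="A" * 100)
        b = make_orf(start=101, aa=10)
        assert gene_gap(a, b) == 0

    def test_distance_50(self):
        a = make_orf(start=1, end=100, protein="M" + "K" * 31,
                     nt_seq="A" * 100)
        b = make_orf(start=151, aa=10)
        assert gene_gap(a, b) == 50

    def test_overlap_negative(self):
        a = make_orf(start=1, end=100, protein="M" + "K" * 31,
                     nt_seq="A" * 100)
        b = make_orf(start=80, aa=10)
        assert gene_gap(a, b) == -21

    def test_different_contigs_is_contract_violation(self):
        a = make_orf(contig="c1", start=1, aa=5)
        b = make_orf(contig="c2", start=100, aa=5)
        with pytest.raises(ValueError):
            gene_gap(a, b)


class TestAmbiguousRun:
    def test_eight_ns_removed(self):
        orf = make_orf(nt_seq="ATG" + "N" * 8 + "AAATAA", aa=5)
        assert has_ambiguous_run(orf)

    def test_seven_ns_kept(self):
        orf = make_orf(nt_seq="ATG" + "N" * 7 + "AAATAA", aa=5)
        assert not has_ambiguous_run(orf)

    def test_interrupted_run_kept(self):
        orf = make_orf(nt_seq="ATG" + "NNNN" + "A" + "NNNN" + "TAA", aa=5)
        assert not has_ambiguous_run(orf)

    def test_x_and_case_insensitive(self):
        orf = make_orf(nt_seq="ATG" + "nxNXnxNX" + "TAA", aa=4)
        assert has_ambiguous_run(orf)


class TestRequirementsValidation:
    def test_min_above_max_rejected(self):
        with pytest.raises(ConfigError):
            StructuralRequirements(orientation="either", hit_min_aa=300,
                                   hit_max_aa=200, partner_min_aa_up=1,
                                   partner_max_aa_up=10,
                                   partner_min_aa_down=1,
                                   partner_max_aa_down=10,
                                   max_distance_bp=50, max_overlap_bp=20)

    def test_bad_orientation_rejected(self, ta):
        with pytest.raises(ConfigError):
            ta.with_overrides(orientation="sideways")

    def test_override_revalidates(self, ta):
        with pytest.raises(ConfigError):
            ta.with_overrides(hit_min_aa=300)


def ta_scene(partner_start=None, partner_aa=90, partner_strand="+",
             hit_strand="+", partner_nt=None):
    """A '+'-strand 100-aa hit at 1..303 plus an optional partner."""
    hit_orf = make_orf(start=1, aa=100, strand=hit_strand)
    orfs = [hit_orf]
    if partner_start is not None:
        orfs.append(make_orf(start=partner_start, aa=partner_aa,
                             strand=partner_strand, nt_seq=partner_nt))
    return make_hit(orf=hit_orf), orfs


class TestCandidatePartners:
    def test_downstream_partner_found(self, ta):
        hit, orfs = ta_scene(partner_start=334)  # gap 30
        cands, _ = candidate_partners(hit, orfs, ta)
        assert [p.gap_bp for p in cands["downstream"]] == [30]
        assert cands["upstream"] == []

    def test_opposite_strand_excluded(self, ta):
        hit, orfs = ta_scene(partner_start=334, partner_strand="-")
        cands, _ = candidate_partners(hit, orfs, ta)
        assert cands["downstream"] == [] and cands["upstream"] == []

    def test_allow_antisense_relaxes_strand_rule(self, ta):
        hit, orfs = ta_scene(partner_start=334, partner_strand="-")
        cands, _ = candidate_partners(hit, orfs, ta, allow_antisense=True)
        assert len(cands["downstream"]) == 1

    def test_candidates_ordered_by_gap(self, ta):
        hit_orf = make_orf(start=1, aa=100)
        near = make_orf(start=309, aa=90)   # gap 5
        far = make_orf(start=344, aa=90)    # gap 40
        cands, _ = candidate_partners(make_hit(orf=hit_orf),
                                      [hit_orf, far, near], ta)
        assert [p.gap_bp for p in cands["downstream"]] == [5, 40]

    def test_minus_strand_hit_sides_flip(self, ta):
        # partner at larger forward coordinates is *upstream* of a '-' hit
        hit_orf = make_orf(start=1000, aa=100, strand="-")
        partner = make_orf(start=1000 + 303 + 30, aa=90, strand="-")
        cands, _ = candidate_partners(make_hit(orf=hit_orf),
                                      [hit_orf, partner], ta)
        assert len(cands["upstream"]) == 1
        assert cands["upstream"][0].gap_bp == 30


class TestEvaluateHit:
    def test_accepted_single_partner(self, ta):
        hit, orfs = ta_scene(partner_start=334)
        verdict = evaluate_hit(hit, orfs, ta)
        assert isinstance(verdict, Operon)
        assert len(verdict.partners) == 1
        assert verdict.partners[0].gap_bp == 30

    def test_hit_too_long_discarded_first(self, ta):
        hit_orf = make_orf(start=1, aa=250)
        partner = make_orf(start=hit_orf.end + 31, aa=90)
        verdict = evaluate_hit(make_hit(orf=hit_orf), [hit_orf, partner], ta)
        assert isinstance(verdict, DiscardedHit)
        assert verdict.reason == "hit_length"

    def test_no_neighbour_discarded_no_partner(self, ta):
        hit, orfs = ta_scene()
        verdict = evaluate_hit(hit, orfs, ta)
        assert verdict.reason == "no_partner"

    def test_either_with_both_sides_attaches_two(self, ta):
        hit_orf = make_orf(start=500, aa=100)
        up = make_orf(start=500 - 30 - 273 - 1 + 1 - 2, aa=90)
        # exact: upstream gap = hit.start - up.end - 1
        up = make_orf(start=hit_orf.start - 31 - (3 * 91 - 1) - 1 + 1, aa=90)
        down = make_orf(start=hit_orf.end + 31, aa=90)
        verdict = evaluate_hit(make_hit(orf=hit_orf),
                               [hit_orf, up, down], ta)
        assert isinstance(verdict, Operon)
        assert {p.side for p in verdict.partners} == {"upstream",
                                                      "downstream"}

    def test_orientation_both_requires_both(self, ta):
        req = ta.with_overrides(orientation="both")
        hit, orfs = ta_scene(partner_start=334)
        verdict = evaluate_hit(hit, orfs, req)
        assert isinstance(verdict, DiscardedHit)
        assert verdict.reason == "no_partner"

    def test_orientation_upstream_ignores_downstream(self, ta):
        req = ta.with_overrides(orientation="upstream")
        hit, orfs = ta_scene(partner_start=334)  # downstream only
        assert isinstance(evaluate_hit(hit, orfs, req), DiscardedHit)

    def test_distance_near_miss_reason(self, ta):
        hit, orfs = ta_scene(partner_start=355)  # gap 51
        assert evaluate_hit(hit, orfs, ta).reason == "distance"

    def test_overlap_near_miss_reason(self, ta):
        hit, orfs = ta_scene(partner_start=283)  # gap -21
        assert evaluate_hit(hit, orfs, ta).reason == "overlap"

    def test_partner_length_near_miss_reason(self, ta):
        hit, orfs = ta_scene(partner_start=334, partner_aa=49)
        assert evaluate_hit(hit, orfs, ta).reason == "partner_length"

    def test_ambiguous_near_miss_reason(self, ta):
        nt = "ATG" + "N" * 8 + "A" * (3 * 91 - 14) + "TAA"
        hit, orfs = ta_scene(partner_start=334, partner_nt=nt)
        assert evaluate_hit(hit, orfs, ta).reason == "ambiguous"

    def test_double_failure_neighbour_is_not_informative(self, ta):
        # a short ORF overlapping far into the hit fails two constraints;
        # it must not convert an orphan into a specific failure reason
        hit_orf = make_orf(start=1, aa=100)
        junk = make_orf(start=100, aa=12)  # deep overlap AND wrong length
        verdict = evaluate_hit(make_hit(orf=hit_orf), [hit_orf, junk], ta)
        assert verdict.reason == "no_partner"

    def test_far_orf_beyond_window_gives_no_partner(self, ta):
        hit, orfs = ta_scene(partner_start=5000)
        assert evaluate_hit(hit, orfs, ta).reason == "no_partner"


def random_scene(rng):
    """A random hit with a handful of random neighbours on one contig."""
    hit_orf = make_orf(start=2000, aa=rng.randint(20, 220),
                       strand=rng.choice("+-"))
    orfs = [hit_orf]
    for i in range(rng.randint(0, 4)):
        aa = rng.randint(10, 200)
        if rng.random() < 0.6:  # bias neighbours into the hit's vicinity
            gap = rng.randint(-60, 120)
            if rng.random() < 0.5:
                start = hit_orf.end + 1 + gap
            else:
                start = hit_orf.start - gap - 3 * (aa + 1)
        else:
            start = rng.randint(1, 4000)
        start = max(1, start)
        orfs.append(make_orf(start=start, aa=aa, strand=rng.choice("+-"),
                             genome="g", contig="c"))
    orfs = [o for i, o in enumerate(orfs)
            if i == 0 or (o.start, o.end) != (hit_orf.start, hit_orf.end)]
    return make_hit(orf=hit_orf), orfs


def oracle_accepts(hit, orfs, req):
    """Independent exhaustive re-check of acceptance and the partner set."""
    h = hit.orf
    if not req.hit_min_aa <= h.length_aa <= req.hit_max_aa:
        return None
    per_side = {}
    for other in orfs:
        if other.orf_id == h.orf_id or other.contig_id != h.contig_id:
            continue
        if (other.start, other.end) == (h.start, h.end):
            continue
        if other.strand != h.strand:
            continue
        if h.strand == "+":
            gd, gu = other.start - h.end - 1, h.start - other.end - 1
        else:
            gd, gu = h.start - other.end - 1, other.start - h.end - 1
        side, gap = ("downstream", gd) if gd >= gu else ("upstream", gu)
        lo, hi = req.partner_bounds(side)
        if not (-req.max_overlap_bp <= gap <= req.max_distance_bp):
            continue
        if not lo <= other.length_aa <= hi:
            continue
        if has_ambiguous_run(other):
            continue
        key = (abs(gap), other.start)
        if side not in per_side or key < per_side[side][0]:
            per_side[side] = (key, other.orf_id, gap)
    sides = set(req.searched_sides()) & set(per_side)
    if req.orientation in ("upstream", "downstream"):
        ok = req.orientation in sides
    elif req.orientation == "both":
        ok = len(sides) == 2
    else:
        ok = bool(sides)
    if not ok:
        return None
    return {(per_side[s][1], per_side[s][2]) for s in sorted(sides)}


class TestOracleAndProperties:
    def test_matches_bruteforce_oracle(self, ta):
        rng = random.Random(17)
        n_accepted = 0
        for _ in range(300):
            hit, orfs = random_scene(rng)
            verdict = evaluate_hit(hit, orfs, ta)
            expected = oracle_accepts(hit, orfs, ta)
            if isinstance(verdict, Operon):
                got = {(p.orf.orf_id, p.gap_bp) for p in verdict.partners}
                assert got == expected
                n_accepted += 1
            else:
                assert expected is None
        assert n_accepted > 10  # the scenes exercise both branches

    def test_partition_invariant(self, ta):
        rng = random.Random(23)
        hits, orfs = [], []
        for i in range(30):
            hit, scene_orfs = random_scene(rng)
            hits.append(hit)
            orfs.extend(scene_orfs)
        operons, discarded = evaluate_genome(hits, orfs, ta)
        assert len(operons) + len(discarded) == len(hits)

    def test_every_accepted_partner_satisfies_all_constraints(self, ta):
        rng = random.Random(31)
        for _ in range(200):
            hit, orfs = random_scene(rng)
            verdict = evaluate_hit(hit, orfs, ta)
            if not isinstance(verdict, Operon):
                continue
            for p in verdict.partners:
                lo, hi = ta.partner_bounds(p.side)
                assert -ta.max_overlap_bp <= p.gap_bp <= ta.max_distance_bp
                assert lo <= p.orf.length_aa <= hi
                assert not has_ambiguous_run(p.orf)

    def test_tightening_never_grows_accepted_set(self, ta):
        rng = random.Random(41)
        scenes = [random_scene(rng) for _ in range(150)]

        def accepted_count(req):
            return sum(isinstance(evaluate_hit(h, o, req), Operon)
                       for h, o in scenes)

        base = accepted_count(ta)
        for tighter in (
                ta.with_overrides(max_distance_bp=10),
                ta.with_overrides(max_overlap_bp=0),
                ta.with_overrides(hit_min_aa=60, hit_max_aa=150),
                ta.with_overrides(partner_min_aa_up=80, partner_min_aa_down=80),
                ta.with_overrides(partner_max_aa_up=100,
                                  partner_max_aa_down=100),
        ):
            assert accepted_count(tighter) <= base
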