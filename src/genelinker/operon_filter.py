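"""Structural filtering: locate partner genes near each hit and accept or
discard the hit under orientation, length, distance and overlap rules.

Upstream/downstream are relative to the hit's direction of transcription:
for a minus-strand hit, upstream means larger forward-strand coordinates.
Partners must lie on the same strand as the hit (operonic co-transcription)
unless antisense partners are explicitly allowed.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Literal

from .errors import ConfigError
from .genome_io import ORF
from .profile_search import Hit

Orientation = Literal["upstream", "downstream", "either", "both"]

ORIENTATIONS = ("upstream", "downstream", "either", "both")

#: discard reasons ordered most-informative first
REASON_PRECEDENCE = ("ambiguous", "overlap", "distance", "partner_length")


@dataclass(frozen=True)
class StructuralRequirements:
    """The rule set a hit/partner pair must satisfy to form an operon."""

    orientation: str
    hit_min_aa: int
    hit_max_aa: int
    partner_min_aa_up: int
    partner_max_aa_up: int
    partner_min_aa_down: int
    partner_max_aa_down: int
    max_distance_bp: int
    max_overlap_bp: int

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ConfigError(
                f"orientation must be one of {ORIENTATIONS}, "
                f"got {self.orientation!r}")
        for lo, hi, what in (
                (self.hit_min_aa, self.hit_max_aa, "hit length"),
                (self.partner_min_aa_up, self.partner_max_aa_up,
                 "upstream partner length"),
                (self.partner_min_aa_down, self.partner_max_aa_down,
                 "downstream partner length")):
            if lo > hi:
                raise ConfigError(f"{what}: min {lo} > max {hi}")
        if self.max_distance_bp < 0 or self.max_overlap_bp < 0:
            raise ConfigError("max_distance_bp and max_overlap_bp must be >= 0")

    def with_overrides(self, **overrides) -> "StructuralRequirements":
        """Field-wise replacement; invariants are re-validated."""
        bad = set(overrides) - set(self.__dataclass_fields__)
        if bad:
            raise ConfigError(f"unknown requirement field(s): {sorted(bad)}")
        return replace(self, **overrides)

    def partner_bounds(self, side: str) -> tuple[int, int]:
        if side == "upstream":
            return self.partner_min_aa_up, self.partner_max_aa_up
        return self.partner_min_aa_down, self.partner_max_aa_down

    def searched_sides(self) -> tuple[str, ...]:
        if self.orientation == "upstream":
            return ("upstream",)
        if self.orientation == "downstream":
            return ("downstream",)
        return ("upstream", "downstream")


@dataclass(frozen=True)
class Partner:
    """A qualifying neighbour: the ORF, its side and the gap to the hit.

    ``gap_bp`` >= 0 counts intervening nucleotides; negative values are
    shared (overlapping) nucleotides.
    """

    orf: ORF
    side: str
    gap_bp: int


@dataclass(frozen=True)
class Operon:
    operon_id: str
    genome_id: str
    hit: Hit
    partners: tuple[Partner, ...]


@dataclass(frozen=True)
class DiscardedHit:
    hit: Hit
    reason: str  # hit_length | no_partner | partner_length | distance | overlap | ambiguous


def gene_gap(a: ORF, b: ORF) -> int:
    """Intervening nucleotides between two same-contig ORFs, a 5' of b.

    Returns ``b.start - a.end - 1``: 0 means abutting, negative magnitude is
    the number of shared nucleotides.
    """
    if a.contig_id != b.contig_id:
        raise ValueError("gene_gap requires ORFs on the same contig")
    if a.start > b.start:
        raise ValueError("gene_gap requires a 5' of b in forward coordinates")
    return b.start - a.end - 1


_AMBIG_TEMPLATE = "[NX]{%d,}"


def has_ambiguous_run(orf: ORF, run_len: int = 8) -> bool:
    """True iff nt_seq contains >= run_len consecutive N/X characters."""
    return re.search(_AMBIG_TEMPLATE % run_len, orf.nt_seq.upper()) is not None


def _oriented_gaps(hit_orf: ORF, other: ORF) -> tuple[int, int]:
    """(downstream_gap, upstream_gap) of *other* relative to the hit."""
    if hit_orf.strand == "+":
        gap_down = other.start - hit_orf.end - 1
        gap_up = hit_orf.start - other.end - 1
    else:
        gap_down = hit_orf.start - other.end - 1
        gap_up = other.start - hit_orf.end - 1
    return gap_down, gap_up


def _distance_window(req: StructuralRequirements) -> int:
    # Near-miss horizon: beyond this an over-distant ORF is not reported as
    # a "distance" failure but simply ignored (-> no_partner).
    return max(2 * req.max_distance_bp, req.max_distance_bp + 100)


def candidate_partners(hit: Hit, orfs: list[ORF], req: StructuralRequirements,
                       allow_antisense: bool = False,
                       ) -> tuple[dict[str, list[Partner]], dict[str, list[str]]]:
    """Qualifying partner candidates per side, plus near-miss failure reasons.

    Candidates must sit on the hit's contig (and strand, unless antisense is
    allowed), on a searched side, with gap within
    ``[-max_overlap_bp, max_distance_bp]``, a protein length within that
    side's bounds and no ambiguous-base run. They are sorted by \\|gap\\|
    ascending, ties by smaller start coordinate.

    A non-qualifying neighbour is recorded as a near miss only when it fails
    exactly one constraint class, so that incidental short ORFs overlapping
    the hit do not masquerade as informative failures.
    """
    sides = req.searched_sides()
    candidates: dict[str, list[Partner]] = {s: [] for s in sides}
    near_misses: dict[str, list[str]] = {s: [] for s in sides}
    window = _distance_window(req)
    h = hit.orf
    for other in orfs:
        if other.contig_id != h.contig_id or other.orf_id == h.orf_id:
            continue
        if (other.start, other.end) == (h.start, h.end):
            continue
        if other.strand != h.strand and not allow_antisense:
            continue
        gap_down, gap_up = _oriented_gaps(h, other)
        if gap_down >= gap_up:
            side, gap = "downstream", gap_down
        else:
            side, gap = "upstream", gap_up
        if side not in candidates:
            continue
        failures = []
        if gap < -req.max_overlap_bp:
            failures.append("overlap")
        if gap > req.max_distance_bp:
            if gap > window:
                continue
            failures.append("distance")
        lo, hi = req.partner_bounds(side)
        if not lo <= other.length_aa <= hi:
            failures.append("partner_length")
        if has_ambiguous_run(other):
            failures.append("ambiguous")
        if not failures:
            candidates[side].append(Partner(orf=other, side=side, gap_bp=gap))
        elif len(failures) == 1:
            near_misses[side].append(failures[0])
    for side in candidates:
        candidates[side].sort(key=lambda p: (abs(p.gap_bp), p.orf.start))
    return candidates, near_misses


def evaluate_hit(hit: Hit, orfs: list[ORF], req: StructuralRequirements,
                 allow_antisense: bool = False) -> Operon | DiscardedHit:
    """Promote a hit to an operon or discard it with the most specific reason.

    The hit protein length is checked first. Then the nearest qualifying
    candidate on each searched side is taken: orientation ``upstream`` /
    ``downstream`` requires that side, ``both`` requires both sides, and
    ``either`` accepts one or two partners. When no side qualifies the most
    informative near-miss reason is reported
    (ambiguous > overlap > distance > partner_length > no_partner).
    """
    if not (req.hit_min_aa <= hit.orf.length_aa <= req.hit_max_aa):
        return DiscardedHit(hit=hit, reason="hit_length")
    candidates, near_misses = candidate_partners(hit, orfs, req,
                                                 allow_antisense)
    chosen: dict[str, Partner] = {
        side: cands[0] for side, cands in candidates.items() if cands
    }
    orientation = req.orientation
    if orientation in ("upstream", "downstream"):
        accepted = orientation in chosen
    elif orientation == "both":
        accepted = len(chosen) == 2
    else:  # either
        accepted = len(chosen) >= 1
    if accepted:
        partners = tuple(chosen[s] for s in ("upstream", "downstream")
                         if s in chosen)
        return Operon(operon_id=hit.orf.orf_id, genome_id=hit.orf.genome_id,
                      hit=hit, partners=partners)
    observed = [r for side, reasons in near_misses.items()
                if side not in chosen for r in reasons]
    for reason in REASON_PRECEDENCE:
        if reason in observed:
            return DiscardedHit(hit=hit, reason=reason)
    return DiscardedHit(hit=hit, reason="no_partner")


def evaluate_genome(hits: list[Hit], orfs: list[ORF],
                    req: StructuralRequirements,
                    allow_antisense: bool = False,
                    ) -> tuple[list[Operon], list[DiscardedHit]]:
    """Evaluate every hit of one genome; accepted + discarded partition hits."""
    operons: list[Operon] = []
    discarded: list[DiscardedHit] = []
    for hit in hits:
        verdict = evaluate_hit(hit, orfs, req, allow_antisense)
        if isinstance(verdict, Operon):
            operons.append(verdict)
        else:
            discarded.append(verdict)
    return operons, discarded
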