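"""End-to-end orchestration: genomes -> ORFs -> hits -> operons -> reports."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome_io import (GenomeRecord, ORF, extract_orfs, merge_orf_sets,
                        read_gff_cds)
from .operon_filter import (DiscardedHit, Operon, StructuralRequirements,
                            evaluate_genome)
from .profile_search import (Hit, ProfileLibrary, dedupe_hits,
                             filter_by_expected_length, filter_by_score,
                             run_profile_search)
from .reporting import CountMatrix, tabulate_counts, write_operon_table
from .ssn_clustering import (ClusterAssignment, LabeledOperon,
                             cluster_sequences, label_operons, map_discarded,
                             partition_partner_networks)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    requirements: StructuralRequirements
    orfs_by_genome: dict[str, list[ORF]]
    hits: list[Hit]  # hits entering the structural filter
    operons: list[LabeledOperon]
    discarded: list[DiscardedHit]
    hit_assignment: ClusterAssignment
    partner_assignments: dict[str, ClusterAssignment]
    discarded_assignment: ClusterAssignment
    matrices: dict[str, CountMatrix]
    table: pd.DataFrame = field(repr=False, default=None)


def run_pipeline(genomes: list[GenomeRecord], library: ProfileLibrary,
                 requirements: StructuralRequirements,
                 min_bitscore: float = 20.0,
                 min_orf_aa: int = 10,
                 gff_paths: dict[str, str | Path] | None = None,
                 allow_antisense: bool = False,
                 dedupe: bool = True,
                 max_evalue: float = 0.01,
                 min_identity: float = 30.0) -> PipelineResult:
    """Run the full search on in-memory genomes.

    ``gff_paths`` optionally maps genome_id -> GFF3 path; annotated CDSs are
    merged into the six-frame ORF set for those genomes.
    """
    gff_paths = gff_paths or {}
    orfs_by_genome: dict[str, list[ORF]] = {}
    for genome in genomes:
        orfs = extract_orfs(genome, min_len_aa=min_orf_aa)
        if genome.genome_id in gff_paths:
            annotated = read_gff_cds(gff_paths[genome.genome_id], genome)
            orfs = merge_orf_sets(orfs, annotated)
        orfs_by_genome[genome.genome_id] = orfs
    all_orfs = [o for gid in sorted(orfs_by_genome)
                for o in orfs_by_genome[gid]]
    log.info("extracted %d candidate ORFs from %d genomes",
             len(all_orfs), len(genomes))

    hits = run_profile_search(all_orfs, library)
    hits = filter_by_score(hits, min_bitscore)
    hits = filter_by_expected_length(hits, library)
    if dedupe:
        hits = dedupe_hits(hits)
    hits.sort(key=lambda h: (h.orf.genome_id, h.orf.contig_id, h.orf.start,
                             h.orf.orf_id))
    log.info("%d hits enter the structural filter", len(hits))

    operons: list[Operon] = []
    discarded: list[DiscardedHit] = []
    by_genome: dict[str, list[Hit]] = {}
    for h in hits:
        by_genome.setdefault(h.orf.genome_id, []).append(h)
    for genome_id, genome_hits in sorted(by_genome.items()):
        acc, disc = evaluate_genome(genome_hits, orfs_by_genome[genome_id],
                                    requirements, allow_antisense)
        operons.extend(acc)
        discarded.extend(disc)
    assert len(operons) + len(discarded) == len(hits)

    hit_seqs = {op.hit.orf.orf_id: op.hit.orf.protein for op in operons}
    hit_assignment = cluster_sequences(hit_seqs, "hit", max_evalue,
                                       min_identity)
    partner_assignments = {
        role: cluster_sequences(seqs, role, max_evalue, min_identity)
        for role, seqs in partition_partner_networks(
            operons, requirements.orientation).items()
    }
    labeled = label_operons(operons, hit_assignment, partner_assignments,
                            requirements.orientation)

    discarded_seqs = {d.hit.orf.orf_id: d.hit.orf.protein for d in discarded}
    discarded_assignment = map_discarded(discarded_seqs, hit_seqs,
                                         hit_assignment, max_evalue,
                                         min_identity)

    genome_ids = [g.genome_id for g in genomes]
    matrices = tabulate_counts(labeled, discarded, discarded_assignment,
                               genome_ids)
    table = write_operon_table(labeled, discarded, discarded_assignment)
    return PipelineResult(
        requirements=requirements,
        orfs_by_genome=orfs_by_genome,
        hits=hits,
        operons=labeled,
        discarded=discarded,
        hit_assignment=hit_assignment,
        partner_assignments=partner_assignments,
        discarded_assignment=discarded_assignment,
        matrices=matrices,
        table=table,
    )
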