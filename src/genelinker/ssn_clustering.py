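"""Sequence similarity networks and connected-component clustering.

Hits, partners and discarded hits are each grouped by all-vs-all protein
alignment (delegated to BLAST+ ``blastp``); an edge survives when any
direction of the pair meets both the e-value and percent-identity cutoffs,
and connected components define clusters. The comparison database is always
exactly the sequence set being clustered so e-values are reproducible for a
given input set.
"""
from __future__ import annotations

import logging
import string
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import GeneLinkerError
from .operon_filter import Operon
from ._tools import require_tool, run_checked, tool_version

log = logging.getLogger(__name__)

DEFAULT_MAX_EVALUE = 0.01
DEFAULT_MIN_IDENTITY = 30.0

_BLAST_HINT = ("install NCBI BLAST+ (e.g. `conda install -c bioconda blast`) "
               "so that blastp and makeblastdb are on PATH")


@dataclass(frozen=True)
class SimilarityEdge:
    """Best local alignment between two distinct sequences (one direction).

    Stored with canonically ordered endpoints; both query/subject directions
    of a pair may each contribute an edge record.
    """

    seq_a: str
    seq_b: str
    evalue: float
    identity_pct: float

    def __post_init__(self):
        if self.seq_a == self.seq_b:
            raise GeneLinkerError("self-edges are not allowed")
        if self.seq_a > self.seq_b:
            a, b = self.seq_b, self.seq_a
            object.__setattr__(self, "seq_a", a)
            object.__setattr__(self, "seq_b", b)


@dataclass
class ClusterAssignment:
    """Mapping of sequence id -> cluster label for one role."""

    role: str  # hit | partner_up | partner_down | partner_pooled | discarded
    labels: dict[str, str] = field(default_factory=dict)

    def partition(self) -> frozenset[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for seq_id, label in self.labels.items():
            groups.setdefault(label, set()).add(seq_id)
        return frozenset(frozenset(v) for v in groups.values())


def _write_fasta(seqs: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sorted(seqs.items()):
            fh.write(f">{name}\n{seq}\n")


def _blastp_pairs(query: Mapping[str, str], subject: Mapping[str, str],
                  ) -> list[tuple[str, str, float, float]]:
    """Run blastp of query vs subject DB; (qid, sid, identity, evalue) rows."""
    blastp = require_tool("blastp", _BLAST_HINT)
    makeblastdb = require_tool("makeblastdb", _BLAST_HINT)
    log.info("pairwise aligner: %s", tool_version("blastp"))
    rows: list[tuple[str, str, float, float]] = []
    with tempfile.TemporaryDirectory(prefix="genelinker_ssn_") as tmp:
        qf = Path(tmp) / "query.faa"
        sf = Path(tmp) / "subject.faa"
        out = Path(tmp) / "pairs.tsv"
        _write_fasta(query, qf)
        _write_fasta(subject, sf)
        run_checked([makeblastdb, "-in", str(sf), "-dbtype", "prot",
                     "-out", str(Path(tmp) / "db")], "makeblastdb")
        run_checked([blastp, "-query", str(qf), "-db", str(Path(tmp) / "db"),
                     "-outfmt", "6 qseqid sseqid pident evalue",
                     "-evalue", "10", "-num_threads", "1",
                     "-out", str(out)], "blastp")
        with open(out) as fh:
            for line in fh:
                qid, sid, pident, evalue = line.split("\t")
                rows.append((qid, sid, float(pident), float(evalue)))
    return rows


def pairwise_similarity(seqs: Mapping[str, str]) -> list[SimilarityEdge]:
    """All-vs-all local protein alignment of a sequence set.

    For each ordered pair with at least one alignment, the best alignment
    (smallest e-value, then highest identity) is recorded; self-comparisons
    are excluded. The BLAST database is the query set itself.
    """
    if not seqs:
        raise ValueError("pairwise_similarity requires at least one sequence")
    if len(seqs) == 1:
        return []
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for qid, sid, pident, evalue in _blastp_pairs(seqs, seqs):
        if qid == sid:
            continue
        key = (qid, sid)
        cur = best.get(key)
        if cur is None or (evalue, -pident) < (cur[0], -cur[1]):
            best[key] = (evalue, pident)
    edges = [SimilarityEdge(seq_a=q, seq_b=s, evalue=e, identity_pct=p)
             for (q, s), (e, p) in sorted(best.items())]
    return edges


def build_ssn(seq_ids: Iterable[str], edges: Iterable[SimilarityEdge],
              max_evalue: float = DEFAULT_MAX_EVALUE,
              min_identity: float = DEFAULT_MIN_IDENTITY) -> nx.Graph:
    """Build the similarity graph: all sequences are nodes (singletons kept);
    a pair is connected when any direction passes both thresholds."""
    graph = nx.Graph()
    graph.add_nodes_from(seq_ids)
    for edge in edges:
        if edge.evalue <= max_evalue and edge.identity_pct >= min_identity:
            graph.add_edge(edge.seq_a, edge.seq_b,
                           evalue=edge.evalue, identity=edge.identity_pct)
    return graph


def _cluster_label(role: str, index: int) -> str:
    letters = string.ascii_lowercase if role == "hit" else string.ascii_uppercase
    suffix = "" if index < 26 else str(index // 26)
    return letters[index % 26] + suffix


def connected_components(graph: nx.Graph, role: str) -> ClusterAssignment:
    """Label connected components alphabetically.

    Components are ordered by descending size, ties by lexicographically
    smallest member id, making labels deterministic under permutation of
    the input order.
    """
    comps = sorted(nx.connected_components(graph),
                   key=lambda c: (-len(c), min(c)))
    labels: dict[str, str] = {}
    for i, comp in enumerate(comps):
        label = _cluster_label(role, i)
        for seq_id in comp:
            labels[seq_id] = label
    return ClusterAssignment(role=role, labels=labels)


def cluster_sequences(seqs: Mapping[str, str], role: str,
                      max_evalue: float = DEFAULT_MAX_EVALUE,
                      min_identity: float = DEFAULT_MIN_IDENTITY,
                      ) -> ClusterAssignment:
    """Convenience: pairwise alignment -> thresholded SSN -> components."""
    if not seqs:
        return ClusterAssignment(role=role, labels={})
    edges = pairwise_similarity(seqs) if len(seqs) > 1 else []
    graph = build_ssn(seqs.keys(), edges, max_evalue, min_identity)
    return connected_components(graph, role)


def partition_partner_networks(operons: list[Operon], orientation: str,
                               ) -> dict[str, dict[str, str]]:
    """Split partner sequences into the networks the orientation demands.

    ``both`` clusters upstream and downstream partners separately; any other
    orientation pools all partners into a single network.
    """
    if orientation == "both":
        networks: dict[str, dict[str, str]] = {"partner_up": {},
                                               "partner_down": {}}
        for op in operons:
            for p in op.partners:
                role = "partner_up" if p.side == "upstream" else "partner_down"
                networks[role][p.orf.orf_id] = p.orf.protein
        return networks
    pooled: dict[str, str] = {}
    for op in operons:
        for p in op.partners:
            pooled[p.orf.orf_id] = p.orf.protein
    return {"partner_pooled": pooled}


@dataclass(frozen=True)
class LabeledOperon:
    operon: Operon
    hit_label: str
    partner_labels: tuple[tuple[str, str], ...]  # (side, label)
    label: str  # operon type, e.g. "A-a"


def _partner_role(side: str, orientation: str) -> str:
    if orientation == "both":
        return "partner_up" if side == "upstream" else "partner_down"
    return "partner_pooled"


def label_operons(operons: list[Operon], hit_assignment: ClusterAssignment,
                  partner_assignments: Mapping[str, ClusterAssignment],
                  orientation: str) -> list[LabeledOperon]:
    """Attach cluster labels; the operon type is partner label(s) then hit
    label joined with '-', upstream before downstream."""
    labeled: list[LabeledOperon] = []
    for op in operons:
        hit_label = hit_assignment.labels.get(op.hit.orf.orf_id)
        if hit_label is None:
            raise GeneLinkerError(
                f"hit sequence {op.hit.orf.orf_id} has no cluster label")
        plabels: list[tuple[str, str]] = []
        for p in op.partners:
            role = _partner_role(p.side, orientation)
            label = partner_assignments[role].labels.get(p.orf.orf_id)
            if label is None:
                raise GeneLinkerError(
                    f"partner sequence {p.orf.orf_id} has no cluster label")
            plabels.append((p.side, label))
        plabels.sort(key=lambda sl: 0 if sl[0] == "upstream" else 1)
        operon_label = "-".join([lb for _, lb in plabels] + [hit_label])
        labeled.append(LabeledOperon(operon=op, hit_label=hit_label,
                                     partner_labels=tuple(plabels),
                                     label=operon_label))
    return labeled


def map_discarded(discarded_seqs: Mapping[str, str],
                  accepted_seqs: Mapping[str, str],
                  hit_assignment: ClusterAssignment,
                  max_evalue: float = DEFAULT_MAX_EVALUE,
                  min_identity: float = DEFAULT_MIN_IDENTITY,
                  ) -> ClusterAssignment:
    """Cluster discarded hit sequences and map them back to accepted clusters.

    Discarded sequences form their own SSN under the same thresholds. Each
    component is then compared against the accepted hit sequences; if any
    member aligns to an accepted hit within the thresholds, the component is
    labelled ``<accepted-cluster>_discarded`` (best e-value wins when several
    accepted clusters match, and a numeric suffix keeps repeat mappings to
    one cluster distinct); otherwise it gets a fresh ``X<i>_discarded`` label.
    """
    if not discarded_seqs:
        return ClusterAssignment(role="discarded", labels={})
    edges = pairwise_similarity(discarded_seqs) if len(discarded_seqs) > 1 else []
    graph = build_ssn(discarded_seqs.keys(), edges, max_evalue, min_identity)
    comps = sorted(nx.connected_components(graph),
                   key=lambda c: (-len(c), min(c)))

    best_match: dict[str, tuple[float, str]] = {}
    if accepted_seqs:
        for qid, sid, pident, evalue in _blastp_pairs(discarded_seqs,
                                                      accepted_seqs):
            if evalue > max_evalue or pident < min_identity:
                continue
            cur = best_match.get(qid)
            if cur is None or (evalue, sid) < cur:
                best_match[qid] = (evalue, sid)

    labels: dict[str, str] = {}
    fresh = 0
    used: dict[str, int] = {}
    for comp in comps:
        matches = sorted(best_match[m] for m in comp if m in best_match)
        if matches:
            accepted_id = matches[0][1]
            base = hit_assignment.labels[accepted_id]
        else:
            fresh += 1
            base = f"X{fresh}"
        used[base] = used.get(base, 0) + 1
        label = f"{base}_discarded"
        if used[base] > 1:
            label = f"{base}_discarded{used[base]}"
        for seq_id in comp:
            labels[seq_id] = label
    return ClusterAssignment(role="discarded", labels=labels)
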