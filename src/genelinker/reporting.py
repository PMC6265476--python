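"""Per-genome copy-number matrices, iTOL datasets and the per-operon table."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .operon_filter import DiscardedHit
from .ssn_clustering import ClusterAssignment, LabeledOperon

log = logging.getLogger(__name__)

_SEP_NAMES = {",": "COMMA", "\t": "TAB", " ": "SPACE"}


@dataclass(frozen=True)
class CountMatrix:
    """Genomes x cluster-labels table of non-negative integer copy numbers."""

    genomes: tuple[str, ...]
    labels: tuple[str, ...]
    counts: np.ndarray  # shape (len(genomes), len(labels)), dtype int

    @classmethod
    def from_pairs(cls, genomes: Iterable[str],
                   pairs: Iterable[tuple[str, str]]) -> "CountMatrix":
        """Build a matrix from (genome_id, label) occurrences.

        ``genomes`` is the full genome universe: genomes contributing no
        occurrences become all-zero rows. Rows and columns are sorted so the
        result is independent of input order.
        """
        genomes = tuple(sorted(set(genomes)))
        pairs = list(pairs)
        labels = tuple(sorted({label for _, label in pairs}))
        counts = np.zeros((len(genomes), len(labels)), dtype=int)
        gi = {g: i for i, g in enumerate(genomes)}
        li = {l: i for i, l in enumerate(labels)}
        for genome, label in pairs:
            if genome not in gi:
                raise InputError(f"genome {genome!r} not in genome universe")
            counts[gi[genome], li[label]] += 1
        return cls(genomes=genomes, labels=labels, counts=counts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.genomes),
                            columns=list(self.labels))

    def row_sums(self) -> dict[str, int]:
        return {g: int(s) for g, s in zip(self.genomes, self.counts.sum(axis=1))}

    def total(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other) -> bool:  # ndarray needs explicit comparison
        return (isinstance(other, CountMatrix)
                and self.genomes == other.genomes
                and self.labels == other.labels
                and np.array_equal(self.counts, other.counts))


def tabulate_counts(labeled_operons: list[LabeledOperon],
                    discarded: list[DiscardedHit],
                    discarded_assignment: ClusterAssignment,
                    genomes: Iterable[str]) -> dict[str, CountMatrix]:
    """Four matrices: hit clusters, partner clusters, operon types and
    discarded clusters, each counted per genome."""
    genomes = list(genomes)
    hit_pairs = [(lo.operon.genome_id, lo.hit_label) for lo in labeled_operons]
    partner_pairs = [(lo.operon.genome_id, label)
                     for lo in labeled_operons
                     for _, label in lo.partner_labels]
    operon_pairs = [(lo.operon.genome_id, lo.label) for lo in labeled_operons]
    discarded_pairs = [
        (d.hit.orf.genome_id, discarded_assignment.labels[d.hit.orf.orf_id])
        for d in discarded
    ]
    return {
        "hits": CountMatrix.from_pairs(genomes, hit_pairs),
        "partners": CountMatrix.from_pairs(genomes, partner_pairs),
        "operons": CountMatrix.from_pairs(genomes, operon_pairs),
        "discarded": CountMatrix.from_pairs(genomes, discarded_pairs),
    }


def export_itol(matrix: CountMatrix, title: str, sep: str = ",",
                binary: bool = False) -> str:
    """Render a matrix as an iTOL heatmap dataset.

    Genome ids must match the tree leaf names verbatim; a separator
    character occurring in a genome id or label is an error. ``binary``
    collapses counts to presence/absence.
    """
    if sep not in _SEP_NAMES:
        raise InputError(f"unsupported iTOL separator {sep!r}")
    for genome in matrix.genomes:
        if sep in genome:
            raise InputError(
                f"separator {sep!r} occurs in genome id {genome!r}")
    for label in matrix.labels:
        if sep in label:
            raise InputError(f"separator {sep!r} occurs in label {label!r}")
    if not matrix.labels:
        log.warning("iTOL export %r: matrix has no columns", title)
    lines = [
        "DATASET_HEATMAP",
        f"SEPARATOR {_SEP_NAMES[sep]}",
        sep.join(["DATASET_LABEL", title]),
        sep.join(["COLOR", "#2a6fdb"]),
        sep.join(["FIELD_LABELS", *matrix.labels]),
        "DATA",
    ]
    counts = (matrix.counts > 0).astype(int) if binary else matrix.counts
    for genome, row in zip(matrix.genomes, counts):
        lines.append(sep.join([genome, *(str(int(v)) for v in row)]))
    return "\n".join(lines) + "\n"


def parse_itol(text: str) -> CountMatrix:
    """Parse an iTOL heatmap dataset back into a CountMatrix (round-trip)."""
    sep = ","
    labels: tuple[str, ...] = ()
    rows: list[tuple[str, list[int]]] = []
    in_data = False
    for line in text.splitlines():
        if not line:
            continue
        if line.startswith("SEPARATOR"):
            name = line.split()[1]
            sep = {v: k for k, v in _SEP_NAMES.items()}[name]
        elif line.startswith("FIELD_LABELS"):
            labels = tuple(line.split(sep)[1:])
        elif line == "DATA":
            in_data = True
        elif in_data:
            parts = line.split(sep)
            rows.append((parts[0], [int(v) for v in parts[1:]]))
    genomes = tuple(g for g, _ in rows)
    counts = (np.array([r for _, r in rows], dtype=int)
              if rows else np.zeros((0, len(labels)), dtype=int))
    if counts.size == 0:
        counts = counts.reshape((len(genomes), len(labels)))
    return CountMatrix(genomes=genomes, labels=labels, counts=counts)


_TABLE_COLUMNS = [
    "genome", "contig", "strand", "status", "reason", "profile",
    "bitscore", "hit_start", "hit_end", "hit_cluster",
    "up_partner_start", "up_partner_end", "up_gap", "up_cluster",
    "down_partner_start", "down_partner_end", "down_gap", "down_cluster",
    "operon_label",
]


def write_operon_table(labeled_operons: list[LabeledOperon],
                       discarded: list[DiscardedHit],
                       discarded_assignment: ClusterAssignment | None = None,
                       path: str | Path | None = None) -> pd.DataFrame:
    """One row per accepted operon and per discarded hit, deterministically
    sorted by genome, contig then hit start."""
    rows = []
    for lo in labeled_operons:
        hit = lo.operon.hit
        row = {c: "" for c in _TABLE_COLUMNS}
        row.update(genome=hit.orf.genome_id, contig=hit.orf.contig_id,
                   strand=hit.orf.strand, status="accepted", reason="",
                   profile=hit.profile_name, bitscore=hit.bitscore,
                   hit_start=hit.orf.start, hit_end=hit.orf.end,
                   hit_cluster=lo.hit_label, operon_label=lo.label)
        side_labels = dict(lo.partner_labels)
        for p in lo.operon.partners:
            prefix = "up" if p.side == "upstream" else "down"
            row[f"{prefix}_partner_start"] = p.orf.start
            row[f"{prefix}_partner_end"] = p.orf.end
            row[f"{prefix}_gap"] = p.gap_bp
            row[f"{prefix}_cluster"] = side_labels[p.side]
        rows.append(row)
    for d in discarded:
        hit = d.hit
        row = {c: "" for c in _TABLE_COLUMNS}
        cluster = ""
        if discarded_assignment is not None:
            cluster = discarded_assignment.labels.get(hit.orf.orf_id, "")
        row.update(genome=hit.orf.genome_id, contig=hit.orf.contig_id,
                   strand=hit.orf.strand, status="discarded", reason=d.reason,
                   profile=hit.profile_name, bitscore=hit.bitscore,
                   hit_start=hit.orf.start, hit_end=hit.orf.end,
                   hit_cluster=cluster)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df = df.sort_values(["genome", "contig", "hit_start"],
                        kind="mergesort").reset_index(drop=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
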