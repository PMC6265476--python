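"""Profile-HMM search over candidate ORF proteins plus the score/length gates.

Scoring is delegated to the external ``hmmsearch`` executable (HMMER 3);
the full-sequence bit score is the only HMM-level acceptance criterion, with
a default cutoff of 20 bits. An optional per-profile expected-length table
removes hits whose protein length deviates too far from the profile's
expected length.
"""
from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError
from .genome_io import ORF, orfs_to_fasta
from ._tools import require_tool, run_checked, tool_version

log = logging.getLogger(__name__)

_HMMER_HINT = ("install HMMER 3 (e.g. `conda install -c bioconda hmmer`) "
               "so that hmmsearch is on PATH")


@dataclass
class ProfileLibrary:
    """A concatenated HMMER3 text-format profile file plus optional lengths.

    ``expected_lengths`` maps profile name -> (expected_aa, max_deviation_aa).
    Profiles absent from the map are not length-filtered.
    """

    path: Path
    names: tuple[str, ...]
    expected_lengths: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass(frozen=True)
class Hit:
    """One ORF matched by one profile, with the full-sequence bit score."""

    orf: ORF
    profile_name: str
    bitscore: float
    evalue: float


def load_profile_library(path: str | Path,
                         expected_lengths: dict[str, tuple[int, int]] | None = None,
                         ) -> ProfileLibrary:
    """Load a HMMER3 text-format profile file, collecting profile names."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"profile library does not exist: {path}")
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("NAME"):
                names.append(line.split(maxsplit=1)[1].strip())
    if not names:
        raise InputError(f"no HMMER3 profiles found in {path}")
    if len(set(names)) != len(names):
        raise InputError(f"duplicate profile names in {path}")
    lengths = dict(expected_lengths or {})
    for name, (exp, dev) in lengths.items():
        if exp <= 0 or dev < 0:
            raise InputError(f"invalid expected length for profile {name!r}")
    return ProfileLibrary(path=path, names=tuple(names), expected_lengths=lengths)


def run_profile_search(orfs: list[ORF], library: ProfileLibrary) -> list[Hit]:
    """Search every ORF protein against every profile with hmmsearch.

    Returns one :class:`Hit` per (ORF, profile) pair reported by the engine
    with a full-sequence bit score >= 0. No user-level filtering is applied
    here; see :func:`filter_by_score` / :func:`filter_by_expected_length`.
    """
    if not orfs:
        return []
    hmmsearch = require_tool("hmmsearch", _HMMER_HINT)
    log.info("profile search engine: %s", tool_version("hmmsearch"))
    by_id = {orf.orf_id: orf for orf in orfs}
    hits: list[Hit] = []
    with tempfile.TemporaryDirectory(prefix="genelinker_hmm_") as tmp:
        faa = Path(tmp) / "orfs.faa"
        tbl = Path(tmp) / "hits.tbl"
        orfs_to_fasta(orfs, faa)
        run_checked(
            [hmmsearch, "--noali", "--cpu", "1", "-T", "0", "--domT", "0",
             "--tblout", str(tbl), str(library.path), str(faa)],
            "hmmsearch",
        )
        with open(tbl) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                cols = line.split()
                target, query = cols[0], cols[2]
                evalue, score = float(cols[4]), float(cols[5])
                hits.append(Hit(orf=by_id[target], profile_name=query,
                                bitscore=score, evalue=evalue))
    hits.sort(key=lambda h: (h.orf.orf_id, h.profile_name))
    return hits


def filter_by_score(hits: list[Hit], min_bitscore: float = 20.0) -> list[Hit]:
    """Keep hits with a full-sequence bit score of at least ``min_bitscore``."""
    return [h for h in hits if h.bitscore >= min_bitscore]


def filter_by_expected_length(hits: list[Hit], library: ProfileLibrary) -> list[Hit]:
    """Apply the per-profile expected-length filter.

    A hit whose profile is listed in the library's expected-length table is
    kept iff ``|protein length - expected| <= max_deviation``; hits of
    unlisted profiles pass unchanged.
    """
    if not library.expected_lengths:
        return list(hits)
    kept = []
    for h in hits:
        entry = library.expected_lengths.get(h.profile_name)
        if entry is None:
            kept.append(h)
            continue
        expected, deviation = entry
        if abs(h.orf.length_aa - expected) <= deviation:
            kept.append(h)
    return kept


def _interval_overlap(a: ORF, b: ORF) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


def dedupe_hits(hits: list[Hit]) -> list[Hit]:
    """Collapse redundant hits so each locus is counted once.

    First, at most one hit per ORF is kept (highest bit score, ties broken
    by lexicographically smallest profile name). Second, among ORFs on the
    same contig whose intervals overlap by more than 50% of the shorter ORF
    (frame-shifted readings of one locus), only the highest-scoring hit
    survives.
    """
    best: dict[str, Hit] = {}
    for h in hits:
        cur = best.get(h.orf.orf_id)
        if cur is None or (-h.bitscore, h.profile_name) < (-cur.bitscore,
                                                           cur.profile_name):
            best[h.orf.orf_id] = h
    ranked = sorted(best.values(),
                    key=lambda h: (-h.bitscore, h.profile_name, h.orf.orf_id))
    kept: list[Hit] = []
    for h in ranked:
        clash = False
        for k in kept:
            if (k.orf.genome_id, k.orf.contig_id) != (h.orf.genome_id,
                                                      h.orf.contig_id):
                continue
            ov = _interval_overlap(h.orf, k.orf)
            shorter = min(h.orf.end - h.orf.start + 1,
                          k.orf.end - k.orf.start + 1)
            if ov > 0.5 * shorter:
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.orf.genome_id, h.orf.contig_id, h.orf.start,
                             h.orf.orf_id))
    return kept


def referential_check(hits: list[Hit], orfs: list[ORF]) -> bool:
    """True iff every hit's ORF is present in the given ORF set."""
    ids = {o.orf_id for o in orfs}
    return all(h.orf.orf_id in ids for h in hits)
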