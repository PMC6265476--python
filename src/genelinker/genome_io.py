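"""Genome input and candidate ORF extraction.

Genomes are read from nucleotide FASTA files. The candidate protein-coding
set is produced by six-frame translation: every stop-to-stop segment in each
frame contributes at most one ORF, anchored at the 5'-most ATG if present,
otherwise the 5'-most TTG, otherwise GTG. Annotated CDS features from a GFF3
file can be merged in to recover genes with non-canonical starts.

Coordinates are 1-based inclusive on the forward strand throughout. The stop
codon is included in the nucleotide coordinates and ``nt_seq`` but excluded
from the protein.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import InputError

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: start codons in priority order
START_CODONS = ("ATG", "TTG", "GTG")

_NON_NUCLEOTIDE = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class GenomeRecord:
    """A genome: an identifier plus an ordered tuple of (contig_id, sequence)."""

    genome_id: str
    contigs: tuple[tuple[str, str], ...]

    def contig_map(self) -> dict[str, str]:
        return dict(self.contigs)


@dataclass(frozen=True)
class ORF:
    """A candidate coding sequence with forward-strand coordinates.

    ``nt_seq`` is the forward-strand slice ``contig[start-1:end]``; for
    minus-strand ORFs the protein is the translation of its reverse
    complement. The terminal stop codon (when present) is included in the
    coordinates but not in ``protein``.
    """

    orf_id: str
    genome_id: str
    contig_id: str
    strand: str  # "+" or "-"
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive, start <= end
    nt_seq: str
    protein: str
    source: str  # "sixframe" or "annotation"

    @property
    def three_prime(self) -> int:
        """Forward-strand coordinate of the 3' end (stop-side) of the ORF."""
        return self.end if self.strand == "+" else self.start

    @property
    def length_aa(self) -> int:
        return len(self.protein)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate_coding(coding: str) -> str:
    """Translate an in-frame coding-orientation sequence, dropping the stop."""
    prot = str(Seq(coding).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def _orf_id(genome_id: str, contig_id: str, start: int, end: int,
            strand: str, source: str) -> str:
    return f"{genome_id}|{contig_id}|{start}|{end}|{strand}|{source}"


def read_fasta(path: str | Path) -> GenomeRecord:
    """Read a nucleotide FASTA file into a :class:`GenomeRecord`.

    The genome id is the file name without its extension. Sequences are
    upcased, U is mapped to T and any remaining non-ACGTN character is
    replaced by N with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file does not exist: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    contigs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise InputError(f"zero-length record {rec.id!r} in {path}")
        cleaned = _NON_NUCLEOTIDE.sub("N", seq)
        n_replaced = sum(a != b for a, b in zip(seq, cleaned))
        if n_replaced:
            log.warning("%s: replaced %d non-ACGTN characters with N in %r",
                        path.name, n_replaced, rec.id)
        if rec.id in seen:
            raise InputError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append((rec.id, cleaned))
    return GenomeRecord(genome_id=path.stem, contigs=tuple(contigs))


def _segments(codons: list[str]):
    """Yield (first_codon, one_past_last_codon, has_stop) stop-to-stop segments."""
    seg_start = 0
    for j, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if j > seg_start:
                yield seg_start, j, True
            seg_start = j + 1
    if seg_start < len(codons):
        yield seg_start, len(codons), False


def extract_orfs(genome: GenomeRecord, min_len_aa: int = 10) -> list[ORF]:
    """Six-frame ORF extraction with start-codon priority ATG > TTG > GTG.

    Each stop-delimited segment in each of the six frames emits at most one
    ORF. Segments running off the contig end without a stop codon are emitted
    truncated to the last complete codon. ORFs whose protein is shorter than
    ``min_len_aa`` are dropped.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    orfs: list[ORF] = []
    for contig_id, fwd in genome.contigs:
        length = len(fwd)
        for strand in "+-":
            s = fwd if strand == "+" else _revcomp(fwd)
            for frame in range(3):
                n_codons = (length - frame) // 3
                codons = [s[frame + 3 * j:frame + 3 * j + 3]
                          for j in range(n_codons)]
                for a, b, has_stop in _segments(codons):
                    pos = None
                    for start_codon in START_CODONS:
                        for j in range(a, b):
                            if codons[j] == start_codon:
                                pos = j
                                break
                        if pos is not None:
                            break
                    if pos is None:
                        continue
                    if b - pos < min_len_aa:
                        continue
                    o0 = frame + 3 * pos
                    o1 = frame + 3 * (b + (1 if has_stop else 0))
                    coding = s[o0:o1]
                    protein = "M" + _translate_coding(coding)[1:]
                    if strand == "+":
                        start, end = o0 + 1, o1
                    else:
                        start, end = length - o1 + 1, length - o0
                    orfs.append(ORF(
                        orf_id=_orf_id(genome.genome_id, contig_id, start,
                                       end, strand, "sixframe"),
                        genome_id=genome.genome_id,
                        contig_id=contig_id,
                        strand=strand,
                        start=start,
                        end=end,
                        nt_seq=fwd[start - 1:end],
                        protein=protein,
                        source="sixframe",
                    ))
    orfs.sort(key=lambda o: (o.contig_id, o.start, o.end, o.strand))
    return orfs


def read_gff_cds(path: str | Path, genome: GenomeRecord) -> list[ORF]:
    """Read CDS features from a GFF3 file as annotation-sourced ORFs.

    Features on unknown contigs, with lengths that are not codon multiples,
    or whose translation has an internal stop are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GFF file does not exist: {path}")
    contigs = genome.contig_map()
    orfs: list[ORF] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                log.warning("%s:%d: unparseable GFF line, skipped", path.name, lineno)
                skipped += 1
                continue
            seqid, _src, ftype, start_s, end_s, _score, strand = cols[:7]
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                log.warning("%s:%d: non-integer coordinates, skipped", path.name, lineno)
                skipped += 1
                continue
            if seqid not in contigs:
                log.warning("%s:%d: unknown contig %r, skipped", path.name, lineno, seqid)
                skipped += 1
                continue
            contig = contigs[seqid]
            if strand not in "+-" or not (1 <= start <= end <= len(contig)):
                log.warning("%s:%d: bad strand/coordinates, skipped", path.name, lineno)
                skipped += 1
                continue
            if (end - start + 1) % 3 != 0:
                log.warning("%s:%d: CDS length not a codon multiple, skipped",
                            path.name, lineno)
                skipped += 1
                continue
            nt = contig[start - 1:end]
            coding = nt if strand == "+" else _revcomp(nt)
            protein = _translate_coding(coding)
            if "*" in protein:
                log.warning("%s:%d: internal stop in CDS translation, skipped",
                            path.name, lineno)
                skipped += 1
                continue
            if coding[:3] in START_CODONS:
                protein = "M" + protein[1:]
            orfs.append(ORF(
                orf_id=_orf_id(genome.genome_id, seqid, start, end, strand,
                               "annotation"),
                genome_id=genome.genome_id,
                contig_id=seqid,
                strand=strand,
                start=start,
                end=end,
                nt_seq=nt,
                protein=protein,
                source="annotation",
            ))
    if skipped:
        log.warning("%s: skipped %d GFF feature(s)", path.name, skipped)
    return orfs


def merge_orf_sets(sixframe: list[ORF], annotated: list[ORF]) -> list[ORF]:
    """Union of six-frame and annotated ORFs, deduplicated by 3' end.

    Two ORFs are the same gene when they share contig, strand and 3'-end
    coordinate (alternative starts of one stop-delimited CDS); annotated
    ORFs win so non-canonical starts are preserved.
    """
    merged: dict[tuple[str, str, int], ORF] = {}
    for orf in sixframe:
        merged[(orf.contig_id, orf.strand, orf.three_prime)] = orf
    for orf in annotated:
        merged[(orf.contig_id, orf.strand, orf.three_prime)] = orf
    out = list(merged.values())
    out.sort(key=lambda o: (o.contig_id, o.start, o.end, o.strand))
    return out


def orfs_to_fasta(orfs: list[ORF], path: str | Path) -> None:
    """Write ORF proteins as amino-acid FASTA keyed by the ORF id."""
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(f">{orf.orf_id}\n{orf.protein}\n")
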