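"""Deterministic synthetic genomes with planted gene arrays.

Each plant is a hit gene (drawn from a toy protein family) plus, usually, a
partner gene at a controlled gap/overlap/side/strand, inserted on its own
contig between stop-rich spacers so the stop-to-stop ORF structure around
the plant is exact. Every violation class the structural filter recognises
can be planted, and a truth table records the expected pipeline verdict for
each plant. Profile HMMs are built from the family alignments with the
external ``hmmbuild``.

Generation is validated: after assembling a contig the generator re-extracts
its ORFs and checks that the planted genes come out at exactly the planted
coordinates and that the structural filter returns the expected verdict,
retrying with fresh random draws otherwise. Output is byte-identical for a
fixed seed.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import GenerationError
from .genome_io import GenomeRecord, ORF, STOP_CODONS, extract_orfs
from .operon_filter import (Operon, StructuralRequirements, evaluate_hit)
from .profile_search import Hit, ProfileLibrary, load_profile_library
from ._tools import require_tool, run_checked

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS = tuple(sorted(_CODON_TABLE.forward_table))
_AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_CODON_TABLE.forward_table.items()):
    _AA_TO_CODONS.setdefault(_aa, ())
    _AA_TO_CODONS[_aa] += (_codon,)

_AMINO_ACIDS = tuple(sorted(_AA_TO_CODONS))
_STOPS = ("TAA", "TAG", "TGA")

# conservative-substitution groups: mutations stay within a group
_GROUPS = ("AG", "ST", "DE", "KR", "NQ", "ILMV", "FWY")
_CONSERVATIVE: dict[str, str] = {}
for _g in _GROUPS:
    for _a in _g:
        _CONSERVATIVE[_a] = _g

VIOLATIONS = ("none", "distance", "overlap", "partner_short", "partner_long",
              "hit_short", "hit_long", "orphan", "ambiguous", "antisense")


@dataclass(frozen=True)
class PlantSpec:
    """One planted gene array: geometry, lengths and the violation class."""

    family: str
    hit_len_aa: int
    partner_len_aa: int
    gap_bp: int
    side: str  # upstream | downstream | both_sides
    strand: str
    violation: str = "none"
    partner_family: str = "antA"


@dataclass(frozen=True)
class TruthRecord:
    """Planted coordinates plus the verdict the pipeline must reproduce."""

    genome_id: str
    contig_id: str
    family: str
    strand: str
    hit_start: int
    hit_end: int
    partner_start: int | None
    partner_end: int | None
    outcome: str  # "accepted" or "discarded:<reason>"


@dataclass(frozen=True)
class Family:
    """A toy protein family: equal-length variant proteins plus one nt
    realisation per variant (the alignment is the protein set itself)."""

    name: str
    base_protein: str
    proteins: tuple[str, ...]
    variant_genes: tuple[str, ...]


@dataclass
class Dataset:
    genomes: list[GenomeRecord]
    truth: list[TruthRecord]
    plants: list[PlantSpec]


_OUTCOME_BY_VIOLATION = {
    "none": "accepted",
    "distance": "discarded:distance",
    "overlap": "discarded:overlap",
    "partner_short": "discarded:partner_length",
    "partner_long": "discarded:partner_length",
    "hit_short": "discarded:hit_length",
    "hit_long": "discarded:hit_length",
    "orphan": "discarded:no_partner",
    "antisense": "discarded:no_partner",
    "ambiguous": "discarded:ambiguous",
}


def expected_outcome(spec: PlantSpec) -> str:
    """Pipeline verdict implied by a plant's violation class alone."""
    return _OUTCOME_BY_VIOLATION[spec.violation]


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def back_translate(protein: str, rng: random.Random, stop: str = "TAA") -> str:
    """Random codon realisation of a protein, terminal stop appended."""
    codons = [rng.choice(_AA_TO_CODONS[aa]) for aa in protein]
    return "".join(codons) + stop


def synth_gene(length_aa: int, seed: int | random.Random,
               stop: str = "TAA") -> str:
    """A random gene: ATG start, ``length_aa - 1`` sense codons, one stop."""
    if length_aa < 2:
        raise ValueError("length_aa must be >= 2")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    protein = "M" + "".join(rng.choice(_AMINO_ACIDS) for _ in range(length_aa - 1))
    return back_translate(protein, rng, stop=stop)


def make_family(base_gene: str, n_variants: int, sub_rate: float,
                seed: int, name: str = "fam") -> Family:
    """Mutated copies of a gene, conservative substitutions only.

    The variant proteins all have the base protein's length, so the protein
    set doubles as an alignment suitable for profile building.
    """
    if not 0 <= sub_rate <= 0.3:
        raise ValueError("sub_rate must be within [0, 0.3]")
    rng = random.Random(seed)
    base_protein = "M" + str(Seq(base_gene[3:-3]).translate())
    if "*" in base_protein:
        raise GenerationError("base gene has an internal stop")
    proteins = []
    genes = []
    for _ in range(n_variants):
        chars = list(base_protein)
        for i in range(1, len(chars)):
            if rng.random() < sub_rate:
                group = _CONSERVATIVE.get(chars[i], chars[i])
                options = [a for a in group if a != chars[i]]
                if options:
                    chars[i] = rng.choice(options)
        prot = "".join(chars)
        proteins.append(prot)
        genes.append(back_translate(prot, rng))
    return Family(name=name, base_protein=base_protein,
                  proteins=tuple(proteins), variant_genes=tuple(genes))


def default_families(seed: int = 0) -> dict[str, Family]:
    """Hit families (three length regimes) plus two partner families."""
    rng = random.Random(seed)
    spec = [("fam100", 100), ("famS", 36), ("famL", 190),
            ("antA", 90), ("antB", 120)]
    fams = {}
    for name, length in spec:
        base = synth_gene(length, rng)
        fams[name] = make_family(base, n_variants=20, sub_rate=0.05,
                                 seed=rng.getrandbits(32), name=name)
    return fams


def write_family_alignment(family: Family, path: Path) -> None:
    with open(path, "w") as fh:
        for i, prot in enumerate(family.proteins):
            fh.write(f">{family.name}_{i}\n{prot}\n")


def build_profile_library(families: dict[str, Family], out_dir: str | Path,
                          hit_family_names: list[str] | None = None,
                          ) -> ProfileLibrary:
    """hmmbuild a profile per hit family and concatenate into one library."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hmmbuild = require_tool("hmmbuild", "install HMMER 3 for hmmbuild")
    names = hit_family_names or sorted(families)
    parts = []
    for name in names:
        family = families[name]
        afa = out_dir / f"{name}.afa"
        hmm = out_dir / f"{name}.hmm"
        write_family_alignment(family, afa)
        run_checked([hmmbuild, "--amino", "-n", name, str(hmm), str(afa)],
                    "hmmbuild")
        parts.append(hmm.read_text())
    library_path = out_dir / "library.hmm"
    library_path.write_text("".join(parts))
    return load_profile_library(library_path)


# ---------------------------------------------------------------------------
# contig assembly


def stop_rich_spacer(n: int, rng: random.Random) -> str:
    """Spacer DNA with frequent stops in all frames of this strand."""
    out: list[str] = []
    total = 0
    while total < n:
        unit = rng.choice(_STOPS) + rng.choice(_STOPS) + rng.choice("ACGT")
        out.append(unit)
        total += len(unit)
    return "".join(out)[:n]


def _gap_join(gap: int, rng: random.Random) -> str:
    """Intervening bases; when there is room the last three are an in-frame
    stop anchoring the following gene's segment."""
    if gap >= 3:
        return stop_rich_spacer(gap - 3, rng) + "TAA"
    return "".join(rng.choice("ACGT") for _ in range(gap))


def _codons_ok(nt: str) -> bool:
    """All codons sense except a single terminal stop."""
    if len(nt) % 3 != 0:
        return False
    codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
    return (codons[-1] in STOP_CODONS
            and not any(c in STOP_CODONS for c in codons[:-1]))


def _splice_overlap(left: str, right: str, k: int, rng: random.Random,
                    ) -> tuple[str, str]:
    """Rewrite the genes so *right* starts ``k`` bp before *left* ends.

    The shared region is the right gene's first ``k`` bases; the right
    gene's head codons are re-drawn until that region also reads as sense
    codons ending in a stop in the left gene's frame. This is impossible
    when ``k`` is a multiple of 3 (the genes would share a frame, so the
    left stop would terminate the right gene) and for k in {2, 5}.
    Returns the realised (left, right); ``left[-k:] == right[:k]`` so the
    caller assembles ``left + right[k:]``.
    """
    if k % 3 == 0:
        raise GenerationError(
            f"overlap of {k} bp (a codon multiple) puts both genes in one "
            "frame; unrealisable on a single strand")
    if k in (2, 5):
        raise GenerationError(
            f"overlap of {k} bp cannot host the left stop and right start")
    if not right.startswith("ATG"):
        raise GenerationError("right gene must start with ATG")
    if k == 1:
        if left[-3:] not in ("TAA", "TGA"):
            left = left[:-3] + "TAA"
        return left, right
    n_head = k // 3 + 1  # right codons overlapping the shared region
    prefix_len = len(left) - k
    junction = 3 * (prefix_len // 3)  # last codon boundary before the overlap
    for _ in range(2000):
        head = ["ATG"] + [rng.choice(SENSE_CODONS) for _ in range(n_head - 1)]
        candidate_right = "".join(head) + right[3 * n_head:]
        # the left codon spanning the junction is re-drawn too: its fixed
        # bases can otherwise force a premature stop for any head choice
        spacer = "".join(rng.choice("ACGT")
                         for _ in range(prefix_len - junction))
        new_left = left[:junction] + spacer + candidate_right[:k]
        if _codons_ok(new_left):
            return new_left, candidate_right
    raise GenerationError(f"could not engineer a {k} bp overlap")


def _adjust_protein(protein: str, target_len: int, rng: random.Random) -> str:
    if target_len <= len(protein):
        return protein[:target_len]
    extra = "".join(rng.choice(_AMINO_ACIDS)
                    for _ in range(target_len - len(protein)))
    return protein + extra


def _inject_ambiguous(gene_nt: str) -> str:
    # 8 Ns inside the coding region, clear of the start and stop codons
    if len(gene_nt) < 24:
        raise GenerationError("gene too short for an ambiguous run")
    return gene_nt[:12] + "N" * 8 + gene_nt[20:]


def _try_build(spec: PlantSpec, hit_prot: str, partner_prots: list[str],
               spacer_len: int, rng: random.Random,
               ) -> tuple[str, tuple[int, int, str],
                          list[tuple[int, int, str]]]:
    """One assembly attempt. Returns (contig, hit_span, partner_spans) with
    1-based inclusive forward-strand spans."""
    hit_nt = back_translate(hit_prot, rng)
    partner_nts: list[str] = []
    if spec.violation == "antisense":
        partner_nts = [_antisafe_gene(spec.partner_len_aa, rng)]
    elif spec.violation != "orphan":
        partner_nts = [back_translate(p, rng) for p in partner_prots]
        if spec.violation == "ambiguous":
            partner_nts[0] = _inject_ambiguous(partner_nts[0])

    gap = spec.gap_bp
    # lay out the transcription-orientation block; offsets are 0-based
    if spec.violation == "orphan":
        body, hit_off, partner_offs = hit_nt, 0, []
    elif spec.side == "both_sides":
        up, down = partner_nts[0], partner_nts[1]
        j1, j2 = _gap_join(gap, rng), _gap_join(gap, rng)
        body = up + j1 + hit_nt + j2 + down
        hit_off = len(up) + gap
        partner_offs = [(0, len(up)), (hit_off + len(hit_nt) + gap, len(down))]
    else:
        pnt = partner_nts[0]
        if spec.violation == "antisense":
            placed = _revcomp(pnt)
        else:
            placed = pnt
        if spec.side == "downstream":
            if gap >= 0:
                body = hit_nt + _gap_join(gap, rng) + placed
                hit_off, p_off = 0, len(hit_nt) + gap
            else:
                left, right = _splice_overlap(hit_nt, placed, -gap, rng)
                hit_nt = left
                body = left + right[-gap:]
                hit_off, p_off = 0, len(left) + gap
        else:  # upstream
            if gap >= 0:
                body = placed + _gap_join(gap, rng) + hit_nt
                hit_off, p_off = len(placed) + gap, 0
            else:
                left, right = _splice_overlap(placed, hit_nt, -gap, rng)
                body = left + right[-gap:]
                hit_off, p_off = len(left) + gap, 0
        partner_offs = [(p_off, len(placed))]

    flank_l = stop_rich_spacer(spacer_len, rng) + "TAA"
    flank_r = stop_rich_spacer(spacer_len, rng)
    block = flank_l + body + flank_r
    base = len(flank_l)

    def to_forward(off: int, length: int, gene_strand: str,
                   ) -> tuple[int, int, str]:
        a0 = base + off
        if spec.strand == "+":
            return a0 + 1, a0 + length, gene_strand
        total = len(block)
        flipped = "-" if gene_strand == "+" else "+"
        return total - (a0 + length) + 1, total - a0, flipped

    contig = block if spec.strand == "+" else _revcomp(block)
    hit_span = to_forward(hit_off, len(hit_nt), "+")
    partner_strand = "-" if spec.violation == "antisense" else "+"
    partner_spans = [to_forward(off, length, partner_strand)
                     for off, length in partner_offs]
    return contig, hit_span, partner_spans


def _antisafe_gene(length_aa: int, rng: random.Random) -> str:
    """A gene whose reverse-strand frames are stop-rich, so placing it
    antisense does not create long ORFs on the opposite strand."""
    codons = ["ATG"]
    mode = 0
    while len(codons) < length_aa:
        if mode == 0:
            codons.append("TTA")
        elif mode == 1:
            codons.append(rng.choice(("GTT", "CTT", "ATT")))
            if len(codons) < length_aa:
                codons.append(rng.choice(("AAT", "ACT", "AGT")))
        else:
            codons.append(rng.choice(("GCT", "ACT", "CCT", "TCT")))
            if len(codons) < length_aa:
                codons.append(rng.choice(("TAT", "TAC")))
        if len(codons) < length_aa:
            codons.append(rng.choice(SENSE_CODONS))
        mode = (mode + 1) % 3
    return "".join(codons[:length_aa]) + "TAA"


def _contig_ok(contig: str, spec: PlantSpec,
               hit_span: tuple[int, int, str],
               partner_spans: list[tuple[int, int, str]],
               req: StructuralRequirements) -> bool:
    """Re-extract ORFs and verify the plant realises its intended verdict."""
    genome = GenomeRecord("tmp", (("c", contig),))
    orfs = extract_orfs(genome, min_len_aa=10)
    by_span = {(o.start, o.end, o.strand): o for o in orfs}
    if hit_span not in by_span:
        return False
    hit_strand = hit_span[2]
    planted_partner_spans = []
    for span in partner_spans:
        if span[2] == hit_strand:  # antisense partners are checked loosely
            if span not in by_span:
                return False
            planted_partner_spans.append(span[:2])
    fake = Hit(orf=by_span[hit_span], profile_name=spec.family,
               bitscore=99.0, evalue=1e-10)
    verdict = evaluate_hit(fake, orfs, req)
    if isinstance(verdict, Operon):
        actual = "accepted"
        chosen = sorted((p.orf.start, p.orf.end) for p in verdict.partners)
        if chosen != sorted(planted_partner_spans):
            return False
    else:
        actual = f"discarded:{verdict.reason}"
    return actual == expected_outcome(spec)


def generate_dataset(n_genomes: int, plants: list[PlantSpec],
                     families: dict[str, Family] | None = None,
                     spacer_len_bp: int = 60, seed: int = 0,
                     req: StructuralRequirements | None = None,
                     max_attempts: int = 300) -> Dataset:
    """Realise plants as genomes plus a truth table.

    Plant *i* goes to genome ``i % n_genomes``, each on its own contig.
    ``req`` (default: the TA preset requirements) defines what the planted
    verdicts are validated against. Deterministic for a fixed seed.
    """
    from .presets import load_preset  # local import to avoid a cycle

    if req is None:
        req = load_preset("TA").requirements
    if families is None:
        families = default_families(seed)
    rng = random.Random(seed)
    per_genome: list[list[PlantSpec]] = [[] for _ in range(n_genomes)]
    for i, spec in enumerate(plants):
        per_genome[i % n_genomes].append(spec)

    variant_cursor: dict[str, int] = {}

    def next_protein(family_name: str, target_len: int) -> str:
        family = families[family_name]
        idx = variant_cursor.get(family_name, 0)
        variant_cursor[family_name] = idx + 1
        prot = family.proteins[idx % len(family.proteins)]
        return _adjust_protein(prot, target_len, rng)

    genomes: list[GenomeRecord] = []
    truth: list[TruthRecord] = []
    for g, genome_plants in enumerate(per_genome):
        genome_id = f"g{g:03d}"
        contigs: list[tuple[str, str]] = []
        for j, spec in enumerate(genome_plants):
            contig_id = f"c{j:02d}"
            hit_prot = next_protein(spec.family, spec.hit_len_aa)
            partner_prots: list[str] = []
            if spec.violation not in ("orphan", "antisense"):
                n_partners = 2 if spec.side == "both_sides" else 1
                partner_prots = [
                    next_protein(spec.partner_family, spec.partner_len_aa)
                    for _ in range(n_partners)
                ]
            last_error = None
            for _attempt in range(max_attempts):
                try:
                    contig, hit_span, partner_spans = _try_build(
                        spec, hit_prot, partner_prots, spacer_len_bp, rng)
                except GenerationError as exc:
                    # e.g. a splice blocked by this codon realisation's tail;
                    # the next attempt re-draws the codons
                    last_error = exc
                    continue
                if _contig_ok(contig, spec, hit_span, partner_spans, req):
                    break
            else:
                detail = f" (last error: {last_error})" if last_error else ""
                raise GenerationError(
                    f"could not realise plant {spec} after {max_attempts} "
                    f"attempts{detail}")
            contigs.append((contig_id, contig))
            same_strand = [s for s in partner_spans if s[2] == hit_span[2]]
            first_partner = min(same_strand) if same_strand else None
            truth.append(TruthRecord(
                genome_id=genome_id, contig_id=contig_id, family=spec.family,
                strand=hit_span[2], hit_start=hit_span[0], hit_end=hit_span[1],
                partner_start=first_partner[0] if first_partner else None,
                partner_end=first_partner[1] if first_partner else None,
                outcome=expected_outcome(spec),
            ))
        genomes.append(GenomeRecord(genome_id=genome_id,
                                    contigs=tuple(contigs)))
    return Dataset(genomes=genomes, truth=truth, plants=list(plants))


def standard_plant_specs(n_genomes: int,
                         req: StructuralRequirements | None = None,
                         ) -> list[PlantSpec]:
    """One plant of every verdict class (plus threshold-boundary plants) per
    genome, alternating sides, strands and partner families.

    Note the overlap violation is planted at ``max_overlap + 2`` (not +1):
    an overlap that is a codon multiple cannot host both genes' start/stop
    on one strand, and ``max_overlap + 1 = 21`` is one. The exact +/-1
    boundary is exercised at unit level instead.
    """
    from .presets import load_preset

    if req is None:
        req = load_preset("TA").requirements
    d, v = req.max_distance_bp, req.max_overlap_bp
    pmin, pmax = req.partner_min_aa_up, req.partner_max_aa_up
    classes = [
        # (violation, hit family, hit aa, partner aa, gap)
        ("none", "fam100", 100, 90, 30),
        ("none", "fam100", 100, 90, d),            # distance boundary
        ("none", "fam100", 100, 90, -v),           # overlap boundary
        ("none", "fam100", 100, pmin, 20),         # partner min boundary
        ("none", "fam100", 100, pmax, 20),         # partner max boundary
        ("none", "famS", req.hit_min_aa, 90, 30),  # hit min boundary
        ("none", "famL", req.hit_max_aa, 90, 30),  # hit max boundary
        ("none", "fam100", 100, 90, 30),           # realised two-sided below
        ("distance", "fam100", 100, 90, d + 1),
        ("overlap", "fam100", 100, 90, -(v + 2)),
        ("partner_short", "fam100", 100, pmin - 1, 30),
        ("partner_long", "fam100", 100, pmax + 1, 30),
        ("hit_short", "famS", req.hit_min_aa - 1, 90, 30),
        ("hit_long", "famL", req.hit_max_aa + 1, 90, 30),
        ("orphan", "fam100", 100, 0, 0),
        ("ambiguous", "fam100", 100, 90, 30),
        ("antisense", "fam100", 100, 90, 30),
    ]
    plants: list[PlantSpec] = []
    for c, (violation, family, hit_aa, partner_aa, gap) in enumerate(classes):
        for g in range(n_genomes):
            two_sided = c == 7
            side = ("both_sides" if two_sided
                    else ("upstream" if (c + g) % 2 else "downstream"))
            plants.append(PlantSpec(
                family=family, hit_len_aa=hit_aa, partner_len_aa=partner_aa,
                gap_bp=gap, side=side, strand="+-"[(c + g) % 2],
                violation=violation,
                partner_family="antA" if (c + g) % 2 == 0 else "antB",
            ))
    return plants


# ---------------------------------------------------------------------------
# on-disk output


def write_dataset(dataset: Dataset, out_dir: str | Path,
                  families: dict[str, Family] | None = None) -> None:
    """Write genome FASTAs, the truth TSV and family alignments."""
    out_dir = Path(out_dir)
    genome_dir = out_dir / "genomes"
    genome_dir.mkdir(parents=True, exist_ok=True)
    for genome in dataset.genomes:
        with open(genome_dir / f"{genome.genome_id}.fasta", "w") as fh:
            for contig_id, seq in genome.contigs:
                fh.write(f">{contig_id}\n{seq}\n")
    header = ("genome_id\tcontig_id\tfamily\tstrand\thit_start\thit_end\t"
              "partner_start\tpartner_end\toutcome\n")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write(header)
        for t in dataset.truth:
            fh.write("\t".join(str(x) if x is not None else "" for x in (
                t.genome_id, t.contig_id, t.family, t.strand, t.hit_start,
                t.hit_end, t.partner_start, t.partner_end, t.outcome)) + "\n")
    if families:
        fam_dir = out_dir / "families"
        fam_dir.mkdir(exist_ok=True)
        for family in families.values():
            write_family_alignment(family, fam_dir / f"{family.name}.afa")


def write_truth_gff(dataset: Dataset, out_dir: str | Path) -> None:
    """GFF3 files listing the planted hit CDS features (for merge tests)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_genome: dict[str, list[TruthRecord]] = {}
    for t in dataset.truth:
        by_genome.setdefault(t.genome_id, []).append(t)
    for genome in dataset.genomes:
        with open(out_dir / f"{genome.genome_id}.gff", "w") as fh:
            fh.write("##gff-version 3\n")
            for t in by_genome.get(genome.genome_id, []):
                fh.write("\t".join(map(str, (
                    t.contig_id, "genelinker_fixture", "CDS", t.hit_start,
                    t.hit_end, ".", t.strand, "0",
                    f"ID={t.genome_id}_{t.contig_id}_hit"))) + "\n")
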