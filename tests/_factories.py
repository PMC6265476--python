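"""Small object factories shared by the unit tests."""
from __future__ import annotations

from genelinker.genome_io import ORF
from genelinker.operon_filter import Operon, Partner
from genelinker.profile_search import Hit
from genelinker.ssn_clustering import LabeledOperon


def make_orf(contig="c", strand="+", start=1, aa=10, genome="g",
             protein=None, nt_seq=None, source="sixframe", end=None):
    """A coordinate-consistent ORF with a synthetic sequence.

    ``aa`` is the protein length; coordinates span 3*(aa+1) bases
    (stop codon included) unless ``end`` is given explicitly.
    """
    if protein is None:
        protein = "M" + "K" * (aa - 1)
    aa = len(protein)
    if end is None:
        end = start + 3 * (aa + 1) - 1
    if nt_seq is None:
        nt_seq = "ATG" + "AAA" * (aa - 1) + "TAA"
    orf_id = f"{genome}|{contig}|{start}|{end}|{strand}|{source}"
    return ORF(orf_id=orf_id, genome_id=genome, contig_id=contig,
               strand=strand, start=start, end=end, nt_seq=nt_seq,
               protein=protein, source=source)


def make_hit(orf=None, profile="prof", bitscore=50.0, evalue=1e-10, **kw):
    if orf is None:
        orf = make_orf(**kw)
    return Hit(orf=orf, profile_name=profile, bitscore=bitscore,
               evalue=evalue)


def make_labeled_operon(genome="g", hit_label="a", partner_labels=("A",),
                        sides=("downstream",), contig="c", start=1):
    hit = make_hit(orf=make_orf(genome=genome, contig=contig, start=start,
                                aa=100))
    partners = []
    pls = []
    pstart = start + 400
    for side, label in zip(sides, partner_labels):
        partners.append(Partner(orf=make_orf(genome=genome, contig=contig,
                                             start=pstart, aa=90),
                                side=side, gap_bp=10))
        pls.append((side, label))
        pstart += 400
    operon = Operon(operon_id=hit.orf.orf_id, genome_id=genome, hit=hit,
                    partners=tuple(partners))
    ordered = sorted(pls, key=lambda sl: 0 if sl[0] == "upstream" else 1)
    label = "-".join([lb for _, lb in ordered] + [hit_label])
    return LabeledOperon(operon=operon, hit_label=hit_label,
                         partner_labels=tuple(ordered), label=label)
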