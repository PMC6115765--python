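"""Synteny-anchored candidate delimitation.

A TER locus is projected from an annotated reference species into a target
species through its orthologous flanking protein-coding genes: if both
anchors land on one target contig with conserved neighborhood, the
inter-anchor interval (plus slack) is the candidate region — a few thousand
nucleotides instead of a whole genome. Split anchors signal a genome
rearrangement and yield no candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .intervals import Interval, revcomp
from .io import GeneAnnotation, Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntenyInterval:
    species: str
    contig: str
    interval: Interval  # 1-based inclusive, includes slack
    anchor_left: str  # gene_id in target
    anchor_right: str
    orientation: str  # same | inverted
    slack: int

    def __post_init__(self):
        if self.orientation not in ("same", "inverted"):
            raise ValueError("orientation must be same or inverted")


def flanking_anchors(
    genome: Genome, locus_interval: Interval, contig: str
) -> tuple[GeneAnnotation, GeneAnnotation]:
    """Nearest ortholog-labelled genes strictly left and right of a locus.

    Genes without an ortholog group are skipped (logged); a side without
    any eligible gene raises (the locus cannot be anchored).
    """
    genes = [g for g in genome.genes_on(contig)]
    left = None
    right = None
    skipped = 0
    for g in genes:
        if g.ortholog_group is None:
            skipped += 1
            continue
        if g.end < locus_interval[0]:
            if left is None or g.end > left.end:
                left = g
        elif g.start > locus_interval[1]:
            if right is None or g.start < right.start:
                right = g
    if skipped:
        logger.debug("flanking_anchors: skipped %d unassigned genes", skipped)
    if left is None or right is None:
        raise ValueError(
            f"locus {locus_interval} on {contig} unanchored "
            f"({'left' if left is None else 'right'} side has no ortholog-labelled gene)"
        )
    return left, right


def project_interval(
    anchors: tuple[GeneAnnotation, GeneAnnotation],
    genome_b: Genome,
    slack: int = 500,
    max_intervening: int = 3,
) -> SyntenyInterval | None:
    """Project the region between two reference anchors into genome_b.

    Returns None when the anchor orthologs are split across contigs or
    separated by more than ``max_intervening`` genes (synteny broken).
    Ambiguous ortholog groups resolve to the gene pair minimizing the
    inter-anchor distance (warned). Orientation is inverted when anchor
    order or strands flip relative to the reference; if the two signals
    disagree, the projection is treated as inverted and a warning logged.
    """
    left_a, right_a = anchors
    cand_left = [g for g in genome_b.genes if g.ortholog_group == left_a.ortholog_group]
    cand_right = [
        g for g in genome_b.genes if g.ortholog_group == right_a.ortholog_group
    ]
    if not cand_left or not cand_right:
        return None
    pairs = [
        (gl, gr)
        for gl in cand_left
        for gr in cand_right
        if gl.contig_id == gr.contig_id and gl.gene_id != gr.gene_id
    ]
    if not pairs:
        return None  # anchors split across contigs: synteny broken
    if len(cand_left) > 1 or len(cand_right) > 1:
        logger.warning(
            "ambiguous ortholog mapping for %s/%s in %s; using closest pair",
            left_a.ortholog_group,
            right_a.ortholog_group,
            genome_b.species_id,
        )
    def gap(p):
        gl, gr = p
        lo = min(gl.end, gr.end)
        hi = max(gl.start, gr.start)
        return hi - lo
    gl, gr = min(pairs, key=gap)
    contig = gl.contig_id
    between = [
        g
        for g in genome_b.genes_on(contig)
        if g.start > min(gl.end, gr.end)
        and g.end < max(gl.start, gr.start)
        and g.gene_id not in (gl.gene_id, gr.gene_id)
    ]
    if len(between) > max_intervening:
        return None
    order_flipped = gl.start > gr.start
    # strand agreement: both anchor orthologs flipping strand relative to
    # the reference indicates an inverted segment; mixed strands carry no
    # orientation signal and defer to anchor order
    both_flipped = (gl.strand != left_a.strand) and (gr.strand != right_a.strand)
    both_same = (gl.strand == left_a.strand) and (gr.strand == right_a.strand)
    if both_flipped or both_same:
        if both_flipped != order_flipped:
            logger.warning(
                "orientation signals disagree for projection into %s; "
                "treating as inverted",
                genome_b.species_id,
            )
            inverted = True
        else:
            inverted = order_flipped
    else:
        inverted = order_flipped
    lo_gene, hi_gene = (gr, gl) if order_flipped else (gl, gr)
    contig_len = len(genome_b.contigs[contig])
    start = max(1, lo_gene.end + 1 - slack)
    end = min(contig_len, hi_gene.start - 1 + slack)
    if start > end:
        return None  # anchors abut; no intergenic space to search
    return SyntenyInterval(
        species=genome_b.species_id,
        contig=contig,
        interval=(start, end),
        anchor_left=lo_gene.gene_id,
        anchor_right=hi_gene.gene_id,
        orientation="inverted" if inverted else "same",
        slack=slack,
    )


def extract_region(
    genome_b: Genome, si: SyntenyInterval
) -> tuple[str, int, bool]:
    """Forward-strand sequence of a candidate region, its genomic offset
    (1-based position of the first returned base), and whether downstream
    analysis should expect the locus in inverted orientation."""
    seq = genome_b.contigs[si.contig][si.interval[0] - 1 : si.interval[1]]
    return seq, si.interval[0], si.orientation == "inverted"
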