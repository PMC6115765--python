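"""Clade-wide TER survey orchestration and recovery scoring.

Starting from at least one annotated seed species, the survey walks the
guide tree outward: for each unannotated genome it projects a candidate
interval from the nearest annotated relative via orthologous flanking
genes, localizes the telomere template, refines the locus boundaries
against the relative's TER by iterated free-end-gap alignment, annotates
the conserved substructures, and — when template or Sm evidence exists —
promotes the new locus into the query set, exactly the expanding-reference
strategy that makes the search reach across the clade. The final outputs
are a Table-style annotation set, a homology graph over the loci, and a
survey summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from . import aligner as al
from . import features as ft
from . import refine as rf
from . import synteny as sy
from . import telomere as tl
from .intervals import Interval, reciprocal_overlap, revcomp
from .io import (
    Genome,
    SurveySummary,
    TerAnnotation,
    summarize_table,
    write_annotations,
)

logger = logging.getLogger(__name__)


@dataclass
class SurveyConfig:
    slack: int = 500
    max_intervening: int = 3
    word_size: int = 11
    min_refine_score: float = 100.0
    feature_config: ft.FeatureConfig = field(default_factory=ft.FeatureConfig)
    infer_repeats: bool = True
    seed: int = 0


@dataclass
class SurveyResult:
    annotations: list
    graph: object
    summary: SurveySummary
    report: dict


def ter_sequence(genome: Genome, ann: TerAnnotation) -> str:
    """TER sequence in transcript orientation."""
    seq = genome.contigs[ann.accession][ann.ter[0] - 1 : ann.ter[1]]
    return seq if ann.strand == "pos" else revcomp(seq)


def _tree_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            d = pdm.distance(t1, t2)
            a = t1.label.replace(" ", "_")
            b = t2.label.replace(" ", "_")
            out[(a, b)] = d
            out[(b, a)] = d
    return out


def run_survey(
    genomes: list[Genome],
    tree_newick: str,
    known: list[TerAnnotation],
    repeat_catalog: dict[str, str] | None = None,
    config: SurveyConfig | None = None,
) -> SurveyResult:
    """Survey a clade for TER loci starting from known annotations.

    ``known`` must annotate at least one species present in ``genomes``
    (unless genomes is empty, which yields empty outputs). Deterministic
    for a fixed config.
    """
    cfg = config or SurveyConfig()
    repeat_catalog = repeat_catalog or {}
    by_species = {g.species_id: g for g in genomes}
    report: dict = {
        "seed": cfg.seed,
        "parameters": {
            "slack": cfg.slack,
            "max_intervening": cfg.max_intervening,
            "word_size": cfg.word_size,
        },
        "species": {},
    }
    if not genomes:
        logger.warning("no genomes given; survey is empty")
        return SurveyResult([], al.build_homology_graph([], {}), summarize_table([]), report)

    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    dist = _tree_distances(tree)
    annotations: dict[str, TerAnnotation] = {
        a.species: a for a in known if a.species in by_species
    }
    if not annotations:
        raise ValueError("no known TER annotates any input genome")
    status = {sp: "literature" for sp in annotations}
    for sp in annotations:
        report["species"][sp] = {"status": "seed"}

    # telomere repeats per species: catalog, else inferred, else neighbor's
    repeats: dict[str, tl.TelomereRepeat | None] = {}

    def repeat_for(sp: str) -> tl.TelomereRepeat | None:
        if sp in repeats:
            return repeats[sp]
        rep = None
        if sp in repeat_catalog:
            rep = tl.TelomereRepeat(
                tl.canonical_unit(repeat_catalog[sp]), source="catalog"
            )
        elif cfg.infer_repeats:
            rep = tl.infer_repeat_unit(by_species[sp])
        if rep is None:
            for other in sorted(
                (o for o in repeats if repeats[o] is not None),
                key=lambda o: dist.get((sp, o), float("inf")),
            ):
                rep = repeats[other]
                break
        repeats[sp] = rep
        return rep

    pending = [sp for sp in by_species if sp not in annotations]
    while pending:
        # closest (target, annotated reference) pair next — breadth-first
        # from the seeded species over the guide tree
        best = None
        for sp in pending:
            for ref_sp in annotations:
                d = dist.get((sp, ref_sp), float("inf"))
                if best is None or d < best[0]:
                    best = (d, sp, ref_sp)
        _, sp, ref_sp = best
        pending.remove(sp)
        entry: dict = {"reference": ref_sp}
        report["species"][sp] = entry
        target = by_species[sp]
        ref_genome = by_species[ref_sp]
        ref_ann = annotations[ref_sp]
        try:
            anchors = sy.flanking_anchors(
                ref_genome, ref_ann.ter, ref_ann.accession
            )
        except ValueError as exc:
            entry["outcome"] = f"reference unanchored: {exc}"
            continue
        proj = sy.project_interval(
            anchors, target, slack=cfg.slack, max_intervening=cfg.max_intervening
        )
        if proj is None:
            entry["outcome"] = "synteny broken (no candidate interval)"
            continue
        entry["candidate"] = {
            "contig": proj.contig,
            "interval": [int(x) for x in proj.interval],
        }
        seq, offset, _ = sy.extract_region(target, proj)
        rep = repeat_for(sp) or repeat_for(ref_sp)

        # orient the candidate against the reference TER and refine bounds
        ref_seq = ter_sequence(ref_genome, ref_ann)
        fwd_hit = al.seed_extend_search(
            ref_seq, seq, word_size=cfg.word_size,
            query_id=ref_sp, target_id=proj.contig,
        )
        best_hit = fwd_hit[0] if fwd_hit else None
        orient_inverted = best_hit.strand == "-" if best_hit else False
        ts_cand = seq if not orient_inverted else revcomp(seq)
        interval_ts, trace = rf.refine_boundaries(
            ts_cand, ref_seq, min_score=cfg.min_refine_score
        )
        entry["refinement"] = {
            "converged": trace.converged,
            "n_iter": trace.n_iter,
        }
        if trace.converged:
            pad = 60  # retain room for feature edges around the core
            lo = max(1, interval_ts[0] - pad)
            hi = min(len(ts_cand), interval_ts[1] + pad)
        else:
            lo, hi = 1, len(ts_cand)
        # map the refined transcript-space window back to forward coords
        L = len(seq)
        if orient_inverted:
            f_lo, f_hi = L - hi + 1, L - lo + 1
        else:
            f_lo, f_hi = lo, hi
        window_seq = seq[f_lo - 1 : f_hi]
        ann = ft.annotate_ter(
            window_seq,
            rep,
            species=sp,
            contig=proj.contig,
            offset=offset + f_lo - 1,
            contig_length=len(target.contigs[proj.contig]),
            config=cfg.feature_config,
            profile=ft.feature_profile(ref_ann),
        )
        if ann is None:
            entry["outcome"] = "no credible TER (no template or Sm evidence)"
            continue
        annotations[sp] = ann
        status[sp] = "identified"
        entry["outcome"] = "annotated"
        entry["ter"] = {
            "strand": ann.strand,
            "interval": [int(x) for x in ann.ter],
        }

    # homology graph over all annotated loci
    ter_seqs = {
        sp: ter_sequence(by_species[sp], ann) for sp, ann in annotations.items()
    }
    pair_hits = []
    species_sorted = sorted(ter_seqs)
    for i, u in enumerate(species_sorted):
        for v in species_sorted[i + 1 :]:
            hits = al.seed_extend_search(
                ter_seqs[u], ter_seqs[v], word_size=cfg.word_size,
                query_id=u, target_id=v,
            )
            pair_hits.extend(al.filter_hits(hits))
    graph = al.build_homology_graph(pair_hits, status)
    ann_list = [annotations[sp] for sp in sorted(annotations)]
    summary = summarize_table(ann_list)
    report["summary"] = {
        "n_species_with_ter": summary.n_species_with_ter,
        "n_novel": summary.n_novel,
    }
    return SurveyResult(ann_list, graph, summary, report)


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass(frozen=True)
class RecoveryMetrics:
    locus_recall: float
    false_loci: int
    per_feature_recall: dict
    per_feature_mean_error: dict
    n_truth: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "locus_recall": self.locus_recall,
                "false_loci": self.false_loci,
                "per_feature_recall": self.per_feature_recall,
                "per_feature_mean_error": self.per_feature_mean_error,
                "n_truth": self.n_truth,
            }
        )


def score_recovery(
    predicted: list[TerAnnotation],
    truth: list[TerAnnotation],
    tolerance_nt: int = 10,
) -> RecoveryMetrics:
    """Locus recall (reciprocal overlap >= 0.5 on the same contig), count
    of predicted loci matching no truth locus, and per-feature recall /
    mean absolute boundary error (both boundaries within ``tolerance_nt``
    counts as recovered; errors average over recovered features)."""
    truth_by_sp = {t.species: t for t in truth}
    kinds = ("ku", "template", "est1", "twj", "sm1")
    feat_total = {k: 0 for k in kinds}
    feat_hit = {k: 0 for k in kinds}
    feat_err: dict[str, list[float]] = {k: [] for k in kinds}
    locus_hits = 0
    false_loci = 0
    matched_truth = set()
    for p in predicted:
        t = truth_by_sp.get(p.species)
        if (
            t is not None
            and t.accession == p.accession
            and reciprocal_overlap(p.ter, t.ter) >= 0.5
        ):
            locus_hits += 1
            matched_truth.add(p.species)
            for k in kinds:
                ti = getattr(t, k)
                pi = getattr(p, k)
                if ti is None:
                    continue
                if pi is None:
                    continue
                err = max(abs(ti[0] - pi[0]), abs(ti[1] - pi[1]))
                if err <= tolerance_nt:
                    feat_hit[k] += 1
                    feat_err[k].append((abs(ti[0] - pi[0]) + abs(ti[1] - pi[1])) / 2)
        else:
            false_loci += 1
    for t in truth:
        for k in kinds:
            if getattr(t, k) is not None:
                feat_total[k] += 1
    return RecoveryMetrics(
        locus_recall=locus_hits / len(truth) if truth else 0.0,
        false_loci=false_loci,
        per_feature_recall={
            k: (feat_hit[k] / feat_total[k]) if feat_total[k] else None
            for k in kinds
        },
        per_feature_mean_error={
            k: (sum(v) / len(v)) if (v := feat_err[k]) else None for k in kinds
        },
        n_truth=len(truth),
    )


# ---------------------------------------------------------------------------
# output writing


def write_survey_outputs(result: SurveyResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotations(result.annotations, outdir / "annotations.tsv", "TSV")
    write_annotations(result.annotations, outdir / "annotations.gff3", "GFF3")
    write_annotations(result.annotations, outdir / "annotations.bed", "BED")
    with open(outdir / "graph_edges.tsv", "w") as fh:
        fh.write("node_u\tnode_v\tweight\taln_length\n")
        for u, v, data in sorted(result.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']:.6g}\t{data['aln_length']}\n")
    with open(outdir / "graph_nodes.tsv", "w") as fh:
        fh.write("node\tstatus\n")
        for n, data in sorted(result.graph.nodes(data=True)):
            fh.write(f"{n}\t{data.get('status', 'candidate')}\n")
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True, default=int)
    manifest = [
        "annotations.tsv",
        "annotations.gff3",
        "annotations.bed",
        "graph_edges.tsv",
        "graph_nodes.tsv",
        "report.json",
    ]
    (outdir / "MANIFEST").write_text("\n".join(manifest) + "\n")
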