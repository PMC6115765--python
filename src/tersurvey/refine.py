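"""Iterative TER boundary refinement and boundary-contamination flagging.

A candidate region (extracted with generous slack) is aligned globally to
the most closely related known TER with free end gaps, trimmed to the
aligned core plus a small slack, and realigned until the interval
stabilizes — the sequence-level analogue of the iterative refinement used
to pin down locus boundaries against a homolog. Separately, a query TER
whose edges repeatedly hit protein-coding regions of other genomes is
flagged for boundary contamination (the query probably swallowed a
neighboring coding fragment).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .aligner import LocalHit, ScoringScheme, _clean, _pairwise_aligner
from .intervals import Interval, overlaps

logger = logging.getLogger(__name__)


@dataclass
class RefinementTrace:
    iterations: list = field(default_factory=list)  # (interval, score)
    converged: bool = False
    n_iter: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "iterations": [
                    {"interval": list(iv), "score": s} for iv, s in self.iterations
                ],
                "converged": self.converged,
                "n_iter": self.n_iter,
            }
        )


def refine_boundaries(
    candidate_seq: str,
    reference_ter_seq: str,
    scheme: ScoringScheme | None = None,
    trim_slack: int = 25,
    tolerance: int = 10,
    max_iter: int = 5,
    min_score: float = 100.0,
) -> tuple[Interval, RefinementTrace]:
    """Estimate the TER interval inside ``candidate_seq`` (1-based local
    coordinates) by iterated free-end-gap global alignment against the
    reference TER.

    Both sequences must be in the same (transcript) orientation. When the
    alignment score never reaches ``min_score`` the input interval is
    returned unchanged with ``converged=False``.
    """
    if scheme is None:
        scheme = ScoringScheme()
    trace = RefinementTrace()
    cand = _clean(candidate_seq)
    ref = _clean(reference_ter_seq)
    current: Interval = (1, len(cand))
    if not cand or not ref:
        return current, trace
    aligner = _pairwise_aligner(scheme, "global", free_end=True)
    for it in range(max_iter):
        sub = cand[current[0] - 1 : current[1]]
        score = aligner.score(sub, ref)
        if score < min_score:
            logger.warning(
                "refinement alignment score %.0f below floor %.0f; keeping "
                "input interval",
                score,
                min_score,
            )
            trace.n_iter = it + 1
            trace.iterations.append((current, score))
            return (1, len(cand)), trace
        aln = next(iter(aligner.align(sub, ref)))
        blocks_sub = aln.aligned[0]
        core_s = blocks_sub[0][0] + 1  # 1-based within sub
        core_e = blocks_sub[-1][1]
        core = (current[0] + core_s - 1, current[0] + core_e - 1)
        # keep working slack so the next alignment may re-expand the core
        new = (
            max(1, core[0] - trim_slack),
            min(len(cand), core[1] + trim_slack),
        )
        trace.iterations.append((new, score))
        trace.n_iter = it + 1
        delta = abs(new[0] - current[0]) + abs(new[1] - current[1])
        current = new
        if delta < tolerance:
            trace.converged = True
            current = core  # final estimate: the aligned core itself
            break
    return current, trace


def flag_boundary_contamination(
    query_length: int,
    hit_lists: dict[str, list[LocalHit]],
    coding_annotations: dict[str, dict[str, list[Interval]]],
    edge_window: int = 100,
) -> dict[str, bool]:
    """Flag a query edge when hits from at least two genomes are confined
    to that edge's window and overlap annotated coding genes in their
    target — the signature of a query that includes a neighboring coding
    fragment.

    ``hit_lists`` maps genome name -> filtered hits of the query against
    that genome; ``coding_annotations`` maps genome name -> contig ->
    gene intervals.
    """
    votes = {"left": set(), "right": set()}
    left_win = (1, edge_window)
    right_win = (max(1, query_length - edge_window + 1), query_length)
    for genome_name, hits in hit_lists.items():
        genes_by_contig = coding_annotations.get(genome_name, {})
        for h in hits:
            coding = any(
                overlaps(h.t_interval, iv)
                for iv in genes_by_contig.get(h.target_id, [])
            )
            if not coding:
                continue
            if h.q_start >= left_win[0] and h.q_end <= left_win[1]:
                votes["left"].add(genome_name)
            if h.q_start >= right_win[0] and h.q_end <= right_win[1]:
                votes["right"].add(genome_name)
    return {side: len(v) >= 2 for side, v in votes.items()}
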