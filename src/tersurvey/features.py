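"""Conserved TER substructure annotation inside a candidate region.

In transcript order a Saccharomycetaceae-type TER carries: a Ku-binding
hairpin whose loop contains the conserved GCUA, the telomere template, an
Est1-binding hairpin resembling the P3 domain of RNase P/MRP, a three-way
junction region containing the conserved AATA, and near the 3' end the Sm
binding motif AATTTTTGG; the mature 3' end is taken as 10 nt downstream of
the Sm site. Hairpins are detected by maximal complementary-arm search
(Watson-Crick plus G-U wobble on the transcript) rather than thermodynamic
folding; the 5' end is approximate by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .intervals import (
    Interval,
    local_interval_to_genomic,
    revcomp,
)
from .io import TerAnnotation
from .telomere import TelomereRepeat, find_template

logger = logging.getLogger(__name__)

SM_MOTIF = "AATTTTTGG"
KU_LOOP_MOTIF = "GCTA"  # GCUA on the RNA
TWJ_MOTIF = "AATA"

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}
_PAIRS = _WC | _WOBBLE


def _pair_weight(a: str, b: str) -> float:
    """Watson-Crick pairs count fully; G-U wobble counts half — enough to
    extend through a genuine wobble rung without letting chance pairing
    (probability 6/16 per rung when wobble counts fully) build stems."""
    if (a, b) in _WC:
        return 1.0
    if (a, b) in _WOBBLE:
        return 0.5
    return 0.0


@dataclass(frozen=True)
class FeatureHit:
    kind: str  # KU | TEMPLATE | EST1 | TWJ | SM1
    interval: Interval  # 1-based, local to the scanned sequence
    score: float
    evidence: str

    def __post_init__(self):
        if self.interval[1] - self.interval[0] + 1 < 4:
            raise ValueError("feature interval must span at least 4 nt")


@dataclass(frozen=True)
class HairpinCall:
    stem_length: int  # paired positions in the stem
    outer: Interval  # 1-based local span of the whole hairpin
    loop: Interval
    pairing_fraction: float
    score: float = 0.0  # stem pairs minus bulge/mismatch penalties


@dataclass
class FeatureConfig:
    sm_max_mismatch: int = 1
    sm_search_downstream: int = 2000
    ku_window: int = 600
    ku_min_stem: int = 8
    ku_max_bulges: int = 2
    est1_min_stem: int = 10
    est1_pairing_threshold: float = 0.6
    twj_min_stem: int = 6
    twj_flank: int = 120
    three_prime_offset: int = 10
    five_prime_margin: int = 200


# ---------------------------------------------------------------------------
# SM motif and the 3'-end rule


def scan_sm(seq: str, max_mismatch: int = 1) -> list[FeatureHit]:
    """All matches of the Sm motif with at most ``max_mismatch`` mismatches
    (N never matches), sorted by mismatch count then position."""
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    seq = seq.upper()
    k = len(SM_MOTIF)
    hits = []
    for i in range(len(seq) - k + 1):
        mm = 0
        for a, b in zip(seq[i : i + k], SM_MOTIF):
            if a != b or a == "N":
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append(
                FeatureHit(
                    kind="SM1",
                    interval=(i + 1, i + k),
                    score=1.0 - mm / k,
                    evidence=f"{SM_MOTIF} {'exact' if mm == 0 else f'{mm} mismatch'}",
                )
            )
    hits.sort(key=lambda h: (-h.score, h.interval[0]))
    return hits


def assign_three_prime(
    sm_interval: Interval,
    strand: str,
    contig_length: int | None = None,
    offset: int = 10,
) -> int:
    """TER 3' end = ``offset`` nt downstream of the Sm motif in transcript
    direction (forward-strand coordinates; mirrored on the minus strand).
    Positions outside the contig clamp to its end with a warning."""
    if strand == "pos":
        pos = sm_interval[1] + offset
    elif strand == "neg":
        pos = sm_interval[0] - offset
    else:
        raise ValueError("strand must be pos or neg")
    if pos < 1:
        logger.warning("3' end %d before contig start; clamped", pos)
        pos = 1
    if contig_length is not None and pos > contig_length:
        logger.warning("3' end %d beyond contig end; clamped", pos)
        pos = contig_length
    return pos


# ---------------------------------------------------------------------------
# hairpin search


def _extend_stem(seq, i, j, lo, hi, max_bulges, max_bulge_len=3):
    """Extend a stem outward from loop-closing pair (i, j); returns
    (pairs, weight, outer_i, outer_j, columns, penalty) at the best-scoring
    extension point. An internal 1x1 mismatch costs 1, a bulge (skip of up
    to max_bulge_len nt on one side) costs 2; penalties and the
    anchored-run rule keep stems from wandering into chance complementarity
    beyond the genuine arm."""
    pairs = 0
    weight = 0.0
    columns = 0
    defects = 0
    penalty = 0
    best_score = 0.0
    best = (0, 0.0, i + 1, j - 1, 0, 0)
    run_since_defect = 4  # improvements before any defect count immediately
    while i >= lo and j < hi:
        if (seq[i], seq[j]) in _PAIRS:
            pairs += 1
            weight += _pair_weight(seq[i], seq[j])
            columns += 1
            if (seq[i], seq[j]) in _WC:
                run_since_defect += 1
            score = weight - penalty
            # record only once the extension is re-anchored by a run of
            # Watson-Crick pairs; chance pairing rarely sustains such a run
            # after a defect, so stems cannot wander into random flanks
            if score > best_score and run_since_defect >= 4:
                best_score = score
                best = (pairs, weight, i, j, columns, penalty)
            i -= 1
            j += 1
            continue
        if defects >= max_bulges:
            break
        defects += 1
        run_since_defect = 0
        # an internal 1x1 mismatch (e.g. a point substitution breaking one
        # rung) is cheaper than a bulge and keeps the arms in register
        if (
            i - 1 >= lo
            and j + 1 < hi
            and (seq[i - 1], seq[j + 1]) in _PAIRS
        ):
            penalty += 1
            i -= 1
            j += 1
            columns += 1
            continue
        advanced = False
        for skip in range(1, max_bulge_len + 1):
            if i - skip >= lo and (seq[i - skip], seq[j]) in _PAIRS:
                i -= skip
                columns += skip
                advanced = True
                break
            if j + skip < hi and (seq[i], seq[j + skip]) in _PAIRS:
                j += skip
                columns += skip
                advanced = True
                break
        penalty += 2
        if not advanced:
            break
    return best


def best_hairpin(
    seq: str,
    lo: int,
    hi: int,
    min_stem: int,
    max_bulges: int = 0,
    loop_range: tuple[int, int] = (3, 12),
    loop_must_contain: str | None = None,
    rank_key=None,
) -> HairpinCall | None:
    """Best stem-loop within seq[lo:hi] (0-based half-open bounds) by
    maximal complementary-arm extension; None when no stem reaches
    ``min_stem`` pairs. Optionally the loop must contain a given motif;
    ``rank_key(call)`` overrides the default (stem, pairing, compactness)
    ranking."""
    seq = seq.upper()
    hi = min(hi, len(seq))
    lo = max(lo, 0)
    best = None
    if loop_must_contain:
        anchors = []
        start = lo
        while True:
            p = seq.find(loop_must_contain, start, hi)
            if p < 0:
                break
            anchors.append(p)
            start = p + 1
        loop_starts = anchors
    else:
        loop_starts = None
    min_loop, max_loop = loop_range
    candidates = []
    if loop_starts is None:
        for ls in range(lo + 1, hi - min_loop):
            for ll in range(min_loop, max_loop + 1):
                candidates.append((ls, ls + ll))
    else:
        mlen = len(loop_must_contain)
        for a in loop_starts:
            for ll in range(max(min_loop, mlen), max_loop + 1):
                for ls in range(a + mlen - ll, a + 1):
                    if ls > lo and ls + ll < hi:
                        candidates.append((ls, ls + ll))
    for ls, le in candidates:
        pairs, weight, oi, oj, columns, penalty = _extend_stem(
            seq, ls - 1, le, lo, hi, max_bulges
        )
        if pairs < min_stem:
            continue
        frac = pairs / columns if columns else 0.0
        call = HairpinCall(
            stem_length=pairs,
            outer=(oi + 1, oj + 1),
            loop=(ls + 1, le),
            pairing_fraction=frac,
            score=weight - penalty,
        )
        key = (
            rank_key(call)
            if rank_key
            else (call.score, frac, -(oj - oi))
        )
        if best is None or key > best[0]:
            best = (key, call)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# individual features


def find_ku_hairpin(
    seq: str,
    template_local_start: int | None,
    window: int = 600,
    min_stem: int = 8,
    max_bulges: int = 2,
) -> FeatureHit | None:
    """Ku-binding hairpin: best stem-loop with the GCUA anchor in its loop,
    within ``window`` nt upstream (transcript 5' side) of the template.

    No GCUA in the window means no Ku call — the logic used to classify a
    species as Ku-less rather than forcing a structure onto noise."""
    seq = seq.upper()
    if template_local_start is None:
        logger.warning("template position unknown; scanning whole candidate for Ku")
        lo, hi = 0, len(seq)
    else:
        hi = template_local_start - 1  # 0-based exclusive end of the window
        lo = max(0, hi - window)
    if KU_LOOP_MOTIF not in seq[lo:hi]:
        return None
    hp = best_hairpin(
        seq,
        lo,
        hi,
        min_stem=min_stem,
        max_bulges=max_bulges,
        loop_range=(4, 12),
        loop_must_contain=KU_LOOP_MOTIF,
    )
    # gate on the defect-penalized score: chance stems reach min_stem raw
    # pairs via bulges far more often than a net-clean stem
    if hp is None or hp.score < min_stem:
        return None
    return FeatureHit(
        kind="KU",
        interval=hp.outer,
        score=float(hp.stem_length),
        evidence="GCUA in hairpin loop",
    )


def find_est1(
    seq: str,
    search_region: Interval,
    min_stem: int = 10,
    pairing_threshold: float = 0.6,
    expected_mid: int | None = None,
) -> FeatureHit | None:
    """Est1-binding site: best P3-like hairpin (long stem, one internal
    loop tolerated) in the region between template and Sm site; None when
    the best pairing fraction falls below threshold. ``expected_mid``
    (from a homologous reference) biases the choice toward the expected
    position."""
    lo, hi = search_region[0] - 1, search_region[1]
    if hi - lo < 40:
        logger.warning("Est1 search region shorter than 40 nt; skipping")
        return None
    rank = None
    if expected_mid is not None:
        rank = lambda c: (
            c.score - abs((c.outer[0] + c.outer[1]) / 2 - expected_mid) / 25.0,
            c.pairing_fraction,
        )
    hp = best_hairpin(
        seq, lo, hi, min_stem=min_stem, max_bulges=2, loop_range=(3, 10),
        rank_key=rank,
    )
    if (
        hp is None
        or hp.pairing_fraction < pairing_threshold
        or hp.score < min_stem
    ):
        return None
    return FeatureHit(
        kind="EST1",
        interval=hp.outer,
        score=hp.pairing_fraction,
        evidence=f"P3-like hairpin, {hp.stem_length} bp stem",
    )


def find_twj(
    seq: str,
    search_region: Interval,
    min_stem: int = 6,
    flank: int = 120,
    expected_mid: int | None = None,
    expected_span: int | None = None,
) -> FeatureHit | None:
    """Three-way junction surrogate: a conserved AATA flanked within
    ``flank`` nt by two hairpins. A lone AATA without flanking structure is
    reported as evidence "sequence-only" with score 0 (the pattern seen in
    species whose junction has no recognizable structure); no AATA means no
    call."""
    seq = seq.upper()
    lo, hi = search_region[0] - 1, search_region[1]
    occurrences = []
    start = lo
    while True:
        p = seq.find(TWJ_MOTIF, start, hi)
        if p < 0:
            break
        occurrences.append(p)
        start = p + 1
    if not occurrences:
        return None
    best = None
    for a in occurrences:
        # flanking stems of a real junction sit close to the conserved
        # AATA; consider both the nearest strong stem and the strongest
        # stem on each side and score the combinations
        lefts = {
            c.outer: c
            for c in (
                best_hairpin(
                    seq, max(lo, a - flank), a, min_stem=min_stem, max_bulges=1,
                    rank_key=key_fn,
                )
                for key_fn in (
                    lambda c: (c.score - (a - (c.outer[1] - 1)) / 6.0,),
                    None,
                )
            )
            if c is not None and c.score >= min_stem
        }
        rights = {
            c.outer: c
            for c in (
                best_hairpin(
                    seq, a + 4, min(hi, a + 4 + flank), min_stem=min_stem,
                    max_bulges=1, rank_key=key_fn,
                )
                for key_fn in (
                    lambda c: (c.score - ((c.outer[0] - 1) - a - 4) / 6.0,),
                    None,
                )
            )
            if c is not None and c.score >= min_stem
        }
        for left in lefts.values():
            for right in rights.values():
                strength = min(left.score, right.score)
                span = (left.outer[0], right.outer[1])
                gaps = (a - (left.outer[1] - 1)) + ((right.outer[0] - 1) - a - 4)
                key = strength - gaps / 12.0
                if expected_mid is not None:
                    key -= abs(a + 2 - expected_mid) / 25.0
                if expected_span is not None:
                    key -= abs((span[1] - span[0] + 1) - expected_span) / 20.0
                if best is None or key > best[0]:
                    best = (
                        key,
                        span,
                        min(left.stem_length, right.stem_length),
                    )
    if best is None:
        a = occurrences[0]
        return FeatureHit(
            kind="TWJ",
            interval=(a + 1, a + 4),
            score=0.0,
            evidence="sequence-only",
        )
    _, span, strength = best
    return FeatureHit(
        kind="TWJ",
        interval=span,
        score=float(strength),
        evidence="AATA with flanking hairpins",
    )


# ---------------------------------------------------------------------------
# full candidate annotation


def _feature_order_ok(feats: dict[str, FeatureHit]) -> bool:
    order = ["KU", "TEMPLATE", "EST1", "TWJ", "SM1"]
    present = [feats[k] for k in order if k in feats]
    return all(
        a.interval[1] < b.interval[0] for a, b in zip(present, present[1:])
    )


def _enforce_order(feats: dict[str, FeatureHit]) -> dict[str, FeatureHit]:
    """Drop the lowest-scoring feature until transcript order holds."""
    feats = dict(feats)
    while not _feature_order_ok(feats):
        order = ["KU", "TEMPLATE", "EST1", "TWJ", "SM1"]
        present = [(k, feats[k]) for k in order if k in feats]
        violators = set()
        for (ka, a), (kb, b) in zip(present, present[1:]):
            if a.interval[1] >= b.interval[0]:
                violators.update((ka, kb))
        worst = min(violators, key=lambda k: feats[k].score)
        logger.warning("feature order violation; dropping %s", worst)
        del feats[worst]
    return feats


def feature_profile(ann: TerAnnotation) -> dict[str, float]:
    """Relative transcript-order positions of Est1/TWJ in an annotated TER,
    as midpoint fractions of the template-end -> Sm-start span; used to
    steer the structural search in a homologous candidate."""
    if ann.template is None or ann.sm1 is None:
        return {}
    if ann.strand == "pos":
        t_end = ann.template[1]
        s_start = ann.sm1[0]
        span = s_start - t_end

        def frac(iv):
            return ((iv[0] + iv[1]) / 2 - t_end) / span

    else:
        t_end = ann.template[0]
        s_start = ann.sm1[1]
        span = t_end - s_start

        def frac(iv):
            return (t_end - (iv[0] + iv[1]) / 2) / span

    out: dict[str, float] = {}
    if span > 40:
        if ann.est1 is not None:
            out["est1_frac"] = frac(ann.est1)
        if ann.twj is not None:
            out["twj_frac"] = frac(ann.twj)
            out["twj_span"] = float(ann.twj[1] - ann.twj[0] + 1)
    return out


def _annotate_oriented(
    ts: str, template_hit, repeat, cfg: FeatureConfig, profile=None
) -> dict[str, FeatureHit]:
    """Find features on a transcript-oriented candidate sequence."""
    feats: dict[str, FeatureHit] = {}
    t_iv = None
    if template_hit is not None:
        t_iv = template_hit
        feats["TEMPLATE"] = FeatureHit(
            kind="TEMPLATE",
            interval=t_iv,
            score=1.0,
            evidence="telomere-repeat template",
        )
    sm_from = t_iv[1] + 1 if t_iv else 1
    sm_to = min(len(ts), (t_iv[1] + cfg.sm_search_downstream) if t_iv else len(ts))
    sm_hits = [
        h
        for h in scan_sm(ts, cfg.sm_max_mismatch)
        if sm_from <= h.interval[0] and h.interval[1] <= sm_to
    ]
    if sm_hits:
        best_score = max(h.score for h in sm_hits)
        sm = max(
            (h for h in sm_hits if h.score == best_score),
            key=lambda h: h.interval[0],  # Sm sits near the 3' end
        )
        feats["SM1"] = sm
    ku = find_ku_hairpin(
        ts,
        t_iv[0] if t_iv else None,
        window=cfg.ku_window,
        min_stem=cfg.ku_min_stem,
        max_bulges=cfg.ku_max_bulges,
    )
    if ku:
        feats["KU"] = ku
    inner_lo = (t_iv[1] + 1) if t_iv else 1
    inner_hi = (feats["SM1"].interval[0] - 1) if "SM1" in feats else len(ts)
    profile = profile or {}
    span = inner_hi - inner_lo
    if span >= 40:
        exp_est1 = (
            int(inner_lo + profile["est1_frac"] * span)
            if "est1_frac" in profile
            else None
        )
        est1 = find_est1(
            ts,
            (inner_lo, inner_hi),
            min_stem=cfg.est1_min_stem,
            pairing_threshold=cfg.est1_pairing_threshold,
            expected_mid=exp_est1,
        )
        if est1:
            feats["EST1"] = est1
        twj_lo = est1.interval[1] + 1 if est1 else inner_lo
        if inner_hi - twj_lo >= 4:
            exp_twj = (
                int(inner_lo + profile["twj_frac"] * span)
                if "twj_frac" in profile
                else None
            )
            twj = find_twj(
                ts,
                (twj_lo, inner_hi),
                min_stem=cfg.twj_min_stem,
                flank=cfg.twj_flank,
                expected_mid=exp_twj,
                expected_span=(
                    int(profile["twj_span"]) if "twj_span" in profile else None
                ),
            )
            if twj:
                feats["TWJ"] = twj
    return _enforce_order(feats)


def annotate_ter(
    seq: str,
    repeat: TelomereRepeat | None,
    species: str,
    contig: str,
    offset: int = 1,
    contig_length: int | None = None,
    config: FeatureConfig | None = None,
    profile: dict[str, float] | None = None,
) -> TerAnnotation | None:
    """Annotate a candidate region (forward-strand slice of a contig).

    The transcript orientation is resolved from the template hit when the
    telomeric repeat is known, otherwise by which orientation yields more
    features. A candidate without template and without Sm evidence is
    rejected (returns None). All reported intervals are forward-strand
    genomic coordinates; the approximate 5' end extends a fixed margin
    upstream of the first feature, flagged ``approximate_5p``.
    """
    cfg = config or FeatureConfig()
    L = len(seq)
    if L == 0:
        return None
    template_by_strand: dict[str, Interval | None] = {"pos": None, "neg": None}
    template_verified = False
    if repeat is not None:
        hits = find_template(seq, repeat)
        if hits:
            h = hits[0]
            template_verified = h.end_repeat_length >= 3
            # convert forward-strand interval to transcript-local interval
            if h.strand == "pos":
                template_by_strand["pos"] = h.interval
            else:
                template_by_strand["neg"] = (
                    L - h.interval[1] + 1,
                    L - h.interval[0] + 1,
                )
    results = {}
    for strand in ("pos", "neg"):
        ts = seq if strand == "pos" else revcomp(seq)
        if repeat is not None and template_by_strand[strand] is None and any(
            template_by_strand.values()
        ):
            continue  # template fixed the orientation
        results[strand] = _annotate_oriented(
            ts, template_by_strand[strand], repeat, cfg, profile
        )
    if not results:
        return None
    strand = max(
        results,
        key=lambda s: (
            len(results[s]),
            sum(h.score for h in results[s].values()),
            s == "pos",
        ),
    )
    feats = results[strand]
    # credibility gate: an Sm motif, or a template whose 3'-end repetition
    # verified — an unverified periodic window alone is not evidence
    credible = "SM1" in feats or ("TEMPLATE" in feats and template_verified)
    if not credible:
        return None
    inverted = strand == "neg"

    def to_genomic(iv: Interval) -> Interval:
        return local_interval_to_genomic(iv, offset, L, inverted)

    genomic = {
        k: tuple(int(x) for x in to_genomic(h.interval)) for k, h in feats.items()
    }
    flags = {"approximate_5p"}
    if "SM1" in feats:
        three_prime = assign_three_prime(
            genomic["SM1"], strand, contig_length, cfg.three_prime_offset
        )
    else:
        three_prime = None
        flags.add("incomplete")
    if "TEMPLATE" not in feats:
        flags.add("incomplete")
    first_local = min(h.interval[0] for h in feats.values())
    five_prime_local = max(1, first_local - cfg.five_prime_margin)
    five_prime = local_interval_to_genomic(
        (five_prime_local, five_prime_local), offset, L, inverted
    )[0]
    bounds = [iv for iv in genomic.values()]
    lo = min(b[0] for b in bounds)
    hi = max(b[1] for b in bounds)
    if strand == "pos":
        ter = (int(min(five_prime, lo)), int(max(three_prime or hi, hi)))
    else:
        ter = (int(min(three_prime or lo, lo)), int(max(five_prime, hi)))
    kind_map = {"KU": "ku", "TEMPLATE": "template", "EST1": "est1",
                "TWJ": "twj", "SM1": "sm1"}
    return TerAnnotation(
        species=species,
        accession=contig,
        strand=strand,
        ter=ter,
        coord_citation=False,
        flags=frozenset(flags),
        **{kind_map[k]: genomic[k] for k in feats},
    )
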