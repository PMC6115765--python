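"""Internal BLAST-like search: seed-and-extend local alignment, hit
filtering, empirical false-positive-rate estimation and the homology graph.

Scoring follows the canonical nucleotide-BLAST defaults (+2 match, -3
mismatch, gap open 5, gap extend 2). E-values use the ungapped
Karlin-Altschul statistics E = K m n e^{-lambda S}: lambda is the root of
sum_ij p_i p_j e^{lambda s_ij} = 1 at uniform background, solved
numerically; K is frozen from a Monte-Carlo extreme-value calibration (see
:func:`calibrate_karlin_k`). The lenient downstream filter (E < 0.1 with
length and identity floors) makes the search insensitive to the residual
approximation in K.

The heuristic searcher seeds on exact words, extends them ungapped with an
X-drop, chains compatible segments and stitches the gaps with an exact
affine alignment; :func:`smith_waterman` provides the optimal local
alignment it is benchmarked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .intervals import Interval, overlaps, revcomp

#: Monte-Carlo-calibrated ungapped K for the default +2/-3 scheme at
#: uniform background; recomputable with :func:`calibrate_karlin_k`.
DEFAULT_K = 0.39


def karlin_lambda(match: int, mismatch: int, p: float = 0.25) -> float:
    """Positive root of sum_ij p_i p_j e^{lambda s_ij} = 1 (uniform bg)."""

    def f(lam):
        return 4 * p * p * (math.exp(lam * match) + 3 * math.exp(lam * mismatch)) - 1

    return brentq(f, 1e-9, 10.0)


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5  # cost of opening a gap (first gapped position adds open+extend)
    gap_extend: int = 2
    lam: float = None
    K: float = None

    def __post_init__(self):
        if self.lam is None:
            object.__setattr__(self, "lam", karlin_lambda(self.match, self.mismatch))
        if self.K is None:
            object.__setattr__(self, "K", DEFAULT_K)
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def score_pair(self, a: str, b: str) -> int:
        if a == b and a in "ACGT":
            return self.match
        return self.mismatch


def calibrate_karlin_k(
    scheme: ScoringScheme, rng, n_pairs: int = 60, length: int = 1000
) -> float:
    """Monte-Carlo estimate of K from the extreme-value fit
    E[M] = (ln(K m n) + gamma) / lambda of the maximal ungapped segment
    score M over random sequence pairs."""
    best_scores = []
    for _ in range(n_pairs):
        a = rng.integers(0, 4, length)
        b = rng.integers(0, 4, length)
        best = 0.0
        for d in range(-(length - 1), length):
            i0 = max(0, -d)
            j0 = i0 + d
            L = length - max(i0, j0)
            if L < 5:
                continue
            s = np.where(
                a[i0 : i0 + L] == b[j0 : j0 + L],
                float(scheme.match),
                float(scheme.mismatch),
            )
            c = np.cumsum(s)
            m = np.max(c - np.minimum.accumulate(np.concatenate(([0.0], c[:-1]))))
            if m > best:
                best = m
        best_scores.append(best)
    gamma = 0.5772156649015329
    return float(
        math.exp(scheme.lam * np.mean(best_scores) - gamma) / (length * length)
    )


def evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul E = K m n e^{-lambda S}; strictly decreasing in the
    score and linear in each search-space dimension. Non-positive scores
    simply report E >= K m n (never clamped)."""
    if m <= 0 or n <= 0:
        raise ValueError("search space dimensions must be positive")
    return scheme.K * m * n * math.exp(-scheme.lam * score)


@dataclass
class LocalHit:
    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str  # +: target forward strand; -: reverse
    aln_length: int  # alignment columns including gaps
    identity: float  # matched columns / aln_length
    score: int
    evalue: float = math.inf

    def __post_init__(self):
        if self.aln_length < max(
            self.q_end - self.q_start + 1, self.t_end - self.t_start + 1
        ):
            raise ValueError("aln_length shorter than an aligned interval")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")

    @property
    def q_interval(self) -> Interval:
        return (self.q_start, self.q_end)

    @property
    def t_interval(self) -> Interval:
        return (self.t_start, self.t_end)


def _clean(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in "ACGTN" else "N" for c in seq)


@lru_cache(maxsize=8)
def _substitution_matrix(match: int, mismatch: int):
    from Bio.Align import substitution_matrices

    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            m[a, b] = match if (a == b and a != "N") else mismatch
    return m


def _pairwise_aligner(scheme: ScoringScheme, mode: str, free_end: bool = False):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _substitution_matrix(scheme.match, scheme.mismatch)
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    if free_end:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def smith_waterman(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> LocalHit | None:
    """Optimal local alignment of query a against target b under affine
    gaps. Serves as the exact reference for the heuristic searcher; returns
    None when no positive-scoring alignment exists. The reported alignment
    is the aligner's canonical first traceback among co-optimal paths."""
    if scheme is None:
        scheme = ScoringScheme()
    a = _clean(a)
    b = _clean(b)
    if not a or not b:
        return None
    aligner = _pairwise_aligner(scheme, "local")
    score = aligner.score(a, b)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(a, b)))
    blocks_a, blocks_b = aln.aligned
    qs, qe = blocks_a[0][0], blocks_a[-1][1]
    ts, te = blocks_b[0][0], blocks_b[-1][1]
    counts = aln.counts()
    columns = aln.length
    return LocalHit(
        query_id="a",
        target_id="b",
        q_start=qs + 1,
        q_end=qe,
        t_start=ts + 1,
        t_end=te,
        strand="+",
        aln_length=columns,
        identity=counts.identities / columns,
        score=int(score),
        evalue=evalue(score, len(a), len(b), scheme),
    )


# ---------------------------------------------------------------------------
# seed-and-extend heuristic


def _nw_affine(a: str, b: str, scheme: ScoringScheme):
    """Exact global affine alignment of two short segments.

    Returns (score, columns, matches). Used to stitch the inter-segment
    gaps of a chained alignment; inputs are at most a few hundred nt."""
    n, m = len(a), len(b)
    go = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    if n == 0 and m == 0:
        return 0, 0, 0
    if n == 0:
        return -(scheme.gap_open + ge * m), m, 0
    if m == 0:
        return -(scheme.gap_open + ge * n), n, 0
    NEG = -(10**9)
    # M: a[i] aligned to b[j]; X: gap in b (consume a); Y: gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr = {}
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = -(scheme.gap_open + ge * i)
    for j in range(1, m + 1):
        Y[0][j] = -(scheme.gap_open + ge * j)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = scheme.score_pair(ai, b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge)
    score = max(M[n][m], X[n][m], Y[n][m])
    # traceback for columns/matches
    i, j = n, m
    state = max(
        (("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m])), key=lambda kv: kv[1]
    )[0]
    columns = matches = 0
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            s = scheme.score_pair(a[i - 1], b[j - 1])
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                matches += 1
            columns += 1
            prev = max(
                (("M", M[i - 1][j - 1]), ("X", X[i - 1][j - 1]), ("Y", Y[i - 1][j - 1])),
                key=lambda kv: kv[1],
            )[0]
            i, j = i - 1, j - 1
            state = prev
        elif state == "X" and i > 0:
            columns += 1
            state = "M" if M[i - 1][j] - go >= X[i - 1][j] - ge else "X"
            i -= 1
        elif state == "Y" and j > 0:
            columns += 1
            state = "M" if M[i][j - 1] - go >= Y[i][j - 1] - ge else "Y"
            j -= 1
        else:  # boundary
            if i > 0:
                columns += 1
                i -= 1
            else:
                columns += 1
                j -= 1
    return score, columns, matches


@dataclass
class _Hsp:
    qs: int  # 0-based inclusive
    qe: int  # 0-based inclusive
    ts: int
    te: int
    score: int
    matches: int

    @property
    def diag(self):
        return self.ts - self.qs


def _xdrop_extend(q: str, t: str, qs: int, ts: int, length: int, scheme, xdrop):
    """Extend an exact seed (q[qs:qs+length] == t[ts:ts+length]) ungapped in
    both directions with an X-drop; returns an _Hsp."""
    m = scheme.match
    score = m * length
    matches = length
    # right
    best = 0
    cur = 0
    bi = 0
    i = 0
    while qs + length + i < len(q) and ts + length + i < len(t):
        cur += scheme.score_pair(q[qs + length + i], t[ts + length + i])
        i += 1
        if cur > best:
            best = cur
            bi = i
        if cur < best - xdrop:
            break
    right_matches = sum(
        1
        for x in range(bi)
        if q[qs + length + x] == t[ts + length + x] and q[qs + length + x] != "N"
    )
    score += best
    matches += right_matches
    qe = qs + length + bi - 1
    te = ts + length + bi - 1
    # left
    best = 0
    cur = 0
    bi = 0
    i = 1
    while qs - i >= 0 and ts - i >= 0:
        cur += scheme.score_pair(q[qs - i], t[ts - i])
        if cur > best:
            best = cur
            bi = i
        if cur < best - xdrop:
            break
        i += 1
    left_matches = sum(
        1 for x in range(1, bi + 1) if q[qs - x] == t[ts - x] and q[qs - x] != "N"
    )
    score += best
    matches += left_matches
    return _Hsp(qs - bi, qe, ts - bi, te, score, matches)


def _find_hsps(q: str, t: str, scheme, word_size, xdrop, min_score):
    index: dict[str, list[int]] = {}
    for i in range(len(q) - word_size + 1):
        w = q[i : i + word_size]
        if "N" in w:
            continue
        index.setdefault(w, []).append(i)
    seen_diag: dict[int, int] = {}  # diag -> rightmost q end already covered
    hsps = []
    for j in range(len(t) - word_size + 1):
        w = t[j : j + word_size]
        positions = index.get(w)
        if not positions:
            continue
        for i in positions:
            d = j - i
            if seen_diag.get(d, -1) >= i:
                continue
            hsp = _xdrop_extend(q, t, i, j, word_size, scheme, xdrop)
            seen_diag[d] = hsp.qe
            if hsp.score >= min_score:
                hsps.append(hsp)
    return hsps


def _chain_hsps(hsps, scheme, band=60):
    """Greedy best-first chaining of collinear HSPs; returns chains as HSP
    lists, best chain first."""
    hsps = sorted(hsps, key=lambda h: (h.qs, h.ts))
    n = len(hsps)
    dp = [h.score for h in hsps]
    back = [-1] * n
    for i in range(n):
        for j in range(i):
            hj, hi = hsps[j], hsps[i]
            if hj.qe >= hi.qe or hj.te >= hi.te:
                continue
            if hi.qs - hj.qe > 400 or hi.ts - hj.te > 400:
                continue
            shift = abs(hi.diag - hj.diag)
            if shift > band:
                continue
            gap_pen = (scheme.gap_open + scheme.gap_extend * shift) if shift else 0
            cand = dp[j] + hsps[i].score - gap_pen
            if cand > dp[i]:
                dp[i] = cand
                back[i] = j
    used = [False] * n
    chains = []
    for i in sorted(range(n), key=lambda i: -dp[i]):
        if used[i]:
            continue
        chain = []
        j = i
        clash = False
        while j != -1:
            if used[j]:
                clash = True
                break
            chain.append(j)
            j = back[j]
        if clash:
            continue
        for j in chain:
            used[j] = True
        chains.append([hsps[j] for j in reversed(chain)])
    return chains


def _stitch_chain(q, t, chain, scheme):
    """Turn a chain of HSPs into one gapped hit by exact alignment of the
    inter-HSP gaps; returns (score, columns, matches, qs, qe, ts, te)."""
    # trim overlaps between consecutive HSPs
    trimmed = [replace(chain[0])]
    for h in chain[1:]:
        prev = trimmed[-1]
        h = replace(h)
        d_q = prev.qe - h.qs + 1
        d_t = prev.te - h.ts + 1
        d = max(d_q, d_t, 0)
        if d > 0:
            if d >= h.qe - h.qs or d >= h.te - h.ts:
                continue
            # approximate: assume trimmed prefix was matches
            h.qs += d
            h.ts += d
            h.score -= scheme.match * d
            h.matches -= d
        trimmed.append(h)
    score = columns = matches = 0
    for idx, h in enumerate(trimmed):
        seg_cols = h.qe - h.qs + 1
        score += h.score
        columns += seg_cols
        matches += h.matches
        if idx:
            prev = trimmed[idx - 1]
            gq = q[prev.qe + 1 : h.qs]
            gt = t[prev.te + 1 : h.ts]
            gs, gc, gm = _nw_affine(gq, gt, scheme)
            score += gs
            columns += gc
            matches += gm
    return (
        score,
        columns,
        matches,
        trimmed[0].qs,
        trimmed[-1].qe,
        trimmed[0].ts,
        trimmed[-1].te,
    )


def seed_extend_search(
    query: str,
    target: str,
    scheme: ScoringScheme | None = None,
    word_size: int = 11,
    xdrop: int = 20,
    min_raw_score: int = 20,
    query_id: str = "query",
    target_id: str = "target",
    max_hits: int = 25,
) -> list[LocalHit]:
    """Heuristic local search of query against both strands of target.

    Exact word seeds are extended ungapped under an X-drop, collinear
    segments are chained, and gaps are closed with an exact affine
    alignment; overlapping results keep the best score. Minus-strand hits
    report forward-strand target coordinates. Results carry Karlin-Altschul
    E-values over the m x n search space per strand.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    q = _clean(query)
    hits: list[LocalHit] = []
    n = len(target)
    for strand in "+-":
        t = _clean(target) if strand == "+" else _clean(revcomp(target))
        if not q or not t:
            continue
        hsps = _find_hsps(q, t, scheme, word_size, xdrop, min_score=word_size + 7)
        for chain in _chain_hsps(hsps, scheme):
            score, columns, matches, qs, qe, ts, te = _stitch_chain(
                q, t, chain, scheme
            )
            if score < min_raw_score or columns <= 0:
                continue
            if strand == "-":
                ts_f, te_f = n - te - 1, n - ts - 1
            else:
                ts_f, te_f = ts, te
            hits.append(
                LocalHit(
                    query_id=query_id,
                    target_id=target_id,
                    q_start=qs + 1,
                    q_end=qe + 1,
                    t_start=ts_f + 1,
                    t_end=te_f + 1,
                    strand=strand,
                    aln_length=columns,
                    identity=matches / columns,
                    score=score,
                    evalue=evalue(score, len(q), len(t), scheme),
                )
            )
    # merge overlapping hits, keep best score
    hits.sort(key=lambda h: (-h.score, h.t_start, h.q_start))
    kept: list[LocalHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if (
                k.strand == h.strand
                and overlaps(k.q_interval, h.q_interval)
                and overlaps(k.t_interval, h.t_interval)
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
        if len(kept) >= max_hits:
            break
    return kept


# ---------------------------------------------------------------------------
# filtering, FPR, homology graph


def filter_hits(
    hits: list[LocalHit],
    max_e: float = 0.1,
    min_len: int = 25,
    min_id: float = 0.60,
    telomere_mask: dict[str, list[Interval]] | None = None,
) -> list[LocalHit]:
    """Keep hits with E < max_e, alignment length >= min_len and identity >=
    min_id whose target interval does not touch a masked telomeric region
    (overlap = at least one shared position). Order-preserving and
    idempotent."""
    telomere_mask = telomere_mask or {}
    out = []
    for h in hits:
        if not (h.evalue < max_e):
            continue
        if h.aln_length < min_len:
            continue
        if h.identity + 1e-9 < min_id:
            continue
        if any(
            overlaps(h.t_interval, iv) for iv in telomere_mask.get(h.target_id, [])
        ):
            continue
        out.append(h)
    return out


@dataclass(frozen=True)
class FprRow:
    length_threshold: int
    n_hits: int
    n_false: int
    fpr: float


@dataclass(frozen=True)
class FprTable:
    rows: tuple

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.rows])


def estimate_fpr_by_length(
    hits: list[LocalHit],
    truth_loci: dict[str, list[Interval]],
    thresholds=range(25, 201, 5),
) -> FprTable:
    """Empirical false positive rate among hits of length >= L, for a grid
    of length thresholds; a hit is true iff its target interval overlaps a
    known locus of its target. Thresholds with no hits are omitted."""
    rows = []
    for L in thresholds:
        sub = [h for h in hits if h.aln_length >= L]
        if not sub:
            continue
        n_false = sum(
            1
            for h in sub
            if not any(
                overlaps(h.t_interval, iv) for iv in truth_loci.get(h.target_id, [])
            )
        )
        rows.append(FprRow(L, len(sub), n_false, n_false / len(sub)))
    return FprTable(tuple(rows))


OUTFMT6_COLUMNS = (
    "qid", "tid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "tstart", "tend", "evalue", "bitscore",
)


def hits_to_outfmt6(hits: list[LocalHit]):
    """Hits as a BLAST outfmt-6-style DataFrame (percent identity, 1-based
    coordinates, minus-strand hits with tstart > tend)."""
    import pandas as pd

    rows = []
    for h in hits:
        matches = round(h.identity * h.aln_length)
        ts, te = (h.t_start, h.t_end) if h.strand == "+" else (h.t_end, h.t_start)
        rows.append(
            {
                "qid": h.query_id, "tid": h.target_id,
                "pident": round(100.0 * h.identity, 2),
                "length": h.aln_length,
                "mismatch": h.aln_length - matches,
                "gapopen": 0,
                "qstart": h.q_start, "qend": h.q_end,
                "tstart": ts, "tend": te,
                "evalue": h.evalue, "bitscore": h.score,
            }
        )
    return pd.DataFrame(rows, columns=list(OUTFMT6_COLUMNS))


def read_outfmt6(path) -> list[LocalHit]:
    """Ingest a (headerless, tab-separated) BLAST outfmt-6 file as
    LocalHits; tstart > tend marks a minus-strand hit."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", names=list(OUTFMT6_COLUMNS), comment="#")
    hits = []
    for r in df.itertuples():
        strand = "+" if r.tstart <= r.tend else "-"
        ts, te = sorted((int(r.tstart), int(r.tend)))
        hits.append(
            LocalHit(
                query_id=str(r.qid), target_id=str(r.tid),
                q_start=int(r.qstart), q_end=int(r.qend),
                t_start=ts, t_end=te, strand=strand,
                aln_length=int(r.length),
                identity=float(r.pident) / 100.0,
                score=int(r.bitscore), evalue=float(r.evalue),
            )
        )
    return hits


def build_homology_graph(
    pairwise_best_hits: list[LocalHit], node_status: dict[str, str]
) -> nx.Graph:
    """Undirected graph over TER loci: an edge joins two loci linked by a
    filtered hit, weighted by the inverse of the longest linking alignment.
    Node statuses distinguish literature loci, loci identified by the
    survey, and unvalidated candidates."""
    g = nx.Graph()
    for node, status in node_status.items():
        g.add_node(node, status=status)
    best: dict[tuple, LocalHit] = {}
    for h in pairwise_best_hits:
        if h.query_id == h.target_id:
            continue
        key = tuple(sorted((h.query_id, h.target_id)))
        if key not in best or h.aln_length > best[key].aln_length:
            best[key] = h
    for (u, v), h in best.items():
        g.add_edge(u, v, weight=1.0 / h.aln_length, aln_length=h.aln_length)
    return g
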