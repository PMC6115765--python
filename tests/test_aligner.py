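import math

import numpy as np
import pytest

from tersurvey.aligner import (
    FprTable,
    LocalHit,
    ScoringScheme,
    build_homology_graph,
    calibrate_karlin_k,
    estimate_fpr_by_length,
    evalue,
    filter_hits,
    karlin_lambda,
    seed_extend_search,
    smith_waterman,
)
from tersurvey.intervals import revcomp
from tersurvey.simulate import make_decoy_set

SCHEME = ScoringScheme()


def _sw_oracle(a, b, scheme):
    """Independent quadratic affine local DP (score only)."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    go = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    best = 0
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _mutate(seq, rng, sub=0.10, indel=0.008):
    out = []
    i = 0
    while i < len(seq):
        c = seq[i]
        if rng.random() < sub:
            c = "ACGT"[rng.integers(4)]
        if rng.random() < indel:
            if rng.random() < 0.5:
                i += int(rng.geometric(1 / 3)) + 1
                continue
            out.extend(rng.choice(list("ACGT"), int(rng.geometric(1 / 3))))
        out.append(c)
        i += 1
    return "".join(out)


class TestSmithWaterman:
    def test_identical_sequences(self):
        h = smith_waterman("ACGTACGT", "ACGTACGT", SCHEME)
        assert h.score == 16 and h.identity == 1.0 and h.aln_length == 8

    def test_no_positive_alignment(self):
        assert smith_waterman("AAAA", "TTTT", SCHEME) is None
        assert smith_waterman("", "ACGT", SCHEME) is None

    def test_matches_independent_dp(self):
        """50 random pairs up to 60 nt: score equals an exhaustive affine
        local DP written independently of the implementation."""
        for trial in range(50):
            r = np.random.default_rng(trial)
            a = "".join(r.choice(list("ACGT"), int(r.integers(10, 61))))
            b = "".join(r.choice(list("ACGT"), int(r.integers(10, 61))))
            expected = _sw_oracle(a, b, SCHEME)
            got = smith_waterman(a, b, SCHEME)
            assert (got.score if got else 0) == expected


class TestSeedExtend:
    def test_planted_exact_copy(self, rng):
        q = "".join(rng.choice(list("ACGT"), 100))
        t = "".join(rng.choice(list("ACGT"), 100000))
        target = t[:50000] + q + t[50000:]
        hits = seed_extend_search(q, target, SCHEME)
        assert hits[0].identity == 1.0
        assert hits[0].aln_length == 100
        assert hits[0].t_start == 50001

    def test_strand_symmetry(self, rng):
        q = "".join(rng.choice(list("ACGT"), 150))
        t = "".join(rng.choice(list("ACGT"), 2000)) + q + "".join(
            rng.choice(list("ACGT"), 2000)
        )
        fwd = seed_extend_search(q, t, SCHEME)
        rev = seed_extend_search(q, revcomp(t), SCHEME)
        assert fwd[0].score == rev[0].score
        assert rev[0].strand == "-"

    def test_query_target_symmetry(self, rng):
        for trial in range(5):
            r = np.random.default_rng(100 + trial)
            a = "".join(r.choice(list("ACGT"), 500))
            b = _mutate(a, r) + "".join(r.choice(list("ACGT"), 300))
            s1 = seed_extend_search(a, b, SCHEME)
            s2 = seed_extend_search(b, a, SCHEME)
            assert s1 and s2
            assert s1[0].score == pytest.approx(s2[0].score, rel=0.05)

    def test_word_size_precondition(self):
        with pytest.raises(ValueError):
            seed_extend_search("ACGT" * 10, "ACGT" * 10, SCHEME, word_size=3)

    def test_within_5_percent_of_optimal(self):
        """20 seeded gapped homologies (<= 2 kb): heuristic best score is
        at least 95% of the Smith-Waterman optimum, and equal when the
        alignment needs no gaps."""
        ratios = []
        for trial in range(20):
            r = np.random.default_rng(trial)
            a = "".join(r.choice(list("ACGT"), 1200))
            emb = (
                "".join(r.choice(list("ACGT"), 300))
                + _mutate(a, r)
                + "".join(r.choice(list("ACGT"), 300))
            )
            opt = smith_waterman(a, emb, SCHEME).score
            heur = max(h.score for h in seed_extend_search(a, emb, SCHEME))
            ratios.append(heur / opt)
        assert min(ratios) >= 0.95
        # gap-free planted copies are recovered exactly
        for trial in range(5):
            r = np.random.default_rng(500 + trial)
            q = "".join(r.choice(list("ACGT"), 300))
            emb = "".join(r.choice(list("ACGT"), 500)) + q + "".join(
                r.choice(list("ACGT"), 500)
            )
            assert (
                seed_extend_search(q, emb, SCHEME)[0].score
                == smith_waterman(q, emb, SCHEME).score
            )


class TestEvalue:
    def test_linear_in_search_space(self):
        assert evalue(10, 100, 200, SCHEME) == pytest.approx(
            2 * evalue(10, 100, 100, SCHEME)
        )
        assert evalue(10, 200, 100, SCHEME) == pytest.approx(
            2 * evalue(10, 100, 100, SCHEME)
        )

    def test_score_step_ratio(self):
        ratio = evalue(10, 100, 100, SCHEME) / evalue(11, 100, 100, SCHEME)
        assert ratio == pytest.approx(math.exp(SCHEME.lam))

    def test_nonpositive_score_not_clamped(self):
        assert evalue(0, 50, 50, SCHEME) >= SCHEME.K * 2500

    def test_lambda_against_bisection(self):
        """lambda solves sum p_i p_j e^{lambda s_ij} = 1 (uniform bg):
        verified against an independent bisection."""

        def f(lam):
            return 0.25 * math.exp(2 * lam) + 0.75 * math.exp(-3 * lam) - 1

        lo, hi = 1e-9, 5.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        assert karlin_lambda(2, -3) == pytest.approx(lo, abs=1e-6)
        assert SCHEME.lam == pytest.approx(lo, abs=1e-6)

    def test_calibrated_k_order_of_magnitude(self):
        k = calibrate_karlin_k(SCHEME, np.random.default_rng(0), n_pairs=10,
                               length=400)
        assert 0.05 < k < 2.0

    def test_decoy_evalue_calibration(self, rng):
        """On dinucleotide-shuffled decoys, hits below an E-value cutoff
        stay within an order of magnitude of the cutoff's expectation."""
        src = "".join(rng.choice(list("ACGT"), 500))
        query = "".join(rng.choice(list("ACGT"), 500))
        decoys = make_decoy_set([src], 48, np.random.default_rng(7))
        for e in (0.05, 0.01):
            total = 0
            for d in decoys:
                hits = seed_extend_search(query, d, SCHEME)
                total += sum(1 for h in hits if h.evalue < e)
            assert total <= max(1, 10 * e * len(decoys))


def _hit(length, identity=1.0, e=1e-12, t_start=1000, tid="t"):
    return LocalHit(
        query_id="q", target_id=tid, q_start=1, q_end=length,
        t_start=t_start, t_end=t_start + length - 1, strand="+",
        aln_length=length, identity=identity, score=2 * length, evalue=e,
    )


class TestFilterHits:
    def test_length_boundary(self):
        assert filter_hits([_hit(24)]) == []
        assert len(filter_hits([_hit(25)])) == 1

    def test_identity_boundary(self):
        assert filter_hits([_hit(40, identity=0.59)]) == []
        assert len(filter_hits([_hit(40, identity=0.60)])) == 1

    def test_evalue_boundary(self):
        assert filter_hits([_hit(40, e=0.1)]) == []
        assert len(filter_hits([_hit(40, e=0.099)])) == 1

    def test_telomere_mask_single_position_overlap(self):
        h = _hit(30, t_start=1000)  # target 1000-1029
        assert filter_hits([h], telomere_mask={"t": [(1029, 1100)]}) == []
        assert len(filter_hits([h], telomere_mask={"t": [(1030, 1100)]})) == 1

    def test_idempotent_and_order_preserving(self):
        hits = [_hit(30), _hit(50), _hit(24), _hit(40, identity=0.3)]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert [h.aln_length for h in once] == [30, 50]


class TestFprTable:
    def test_all_true(self):
        hits = [_hit(100, t_start=50) for _ in range(10)]
        table = estimate_fpr_by_length(hits, {"t": [(40, 200)]})
        assert all(row.fpr == 0.0 for row in table.rows)

    def test_hand_counted_mixture(self):
        true_hits = [_hit(100, t_start=50) for _ in range(5)]
        false_hits = [_hit(30, t_start=5000) for _ in range(5)]
        table = estimate_fpr_by_length(true_hits + false_hits, {"t": [(40, 200)]})
        by_thr = {r.length_threshold: r for r in table.rows}
        assert by_thr[25].fpr == 0.5
        assert by_thr[50].fpr == 0.0
        assert by_thr[25].n_hits == 10 and by_thr[25].n_false == 5

    def test_matches_brute_force_recount(self, rng):
        hits = [
            _hit(int(rng.integers(25, 150)), t_start=int(rng.integers(1, 9000)))
            for _ in range(60)
        ]
        truth = {"t": [(500, 1500), (4000, 4500)]}
        table = estimate_fpr_by_length(hits, truth)
        for row in table.rows:
            sub = [h for h in hits if h.aln_length >= row.length_threshold]
            nf = sum(
                1
                for h in sub
                if not any(
                    h.t_start <= e and s <= h.t_end for s, e in truth["t"]
                )
            )
            assert (row.n_hits, row.n_false) == (len(sub), nf)
            assert row.fpr == pytest.approx(nf / len(sub))

    def test_empty(self):
        assert estimate_fpr_by_length([], {}) == FprTable(())


class TestOutfmt6:
    def test_round_trip(self, rng, tmp_path):
        q = "".join(rng.choice(list("ACGT"), 200))
        t = "".join(rng.choice(list("ACGT"), 800)) + q + "".join(
            rng.choice(list("ACGT"), 800)
        )
        from tersurvey.aligner import hits_to_outfmt6, read_outfmt6
        from tersurvey.intervals import revcomp

        hits = seed_extend_search(q, revcomp(t), SCHEME)
        frame = hits_to_outfmt6(hits)
        p = tmp_path / "hits.tsv"
        frame.to_csv(p, sep="\t", header=False, index=False)
        back = read_outfmt6(p)
        assert len(back) == len(hits)
        for a, b in zip(hits, back):
            assert (a.strand, a.t_interval, a.q_interval) == (
                b.strand, b.t_interval, b.q_interval
            )
            assert b.identity == pytest.approx(a.identity, abs=0.005)


class TestHomologyGraph:
    def test_edge_weight_is_inverse_length(self):
        h = _hit(50)
        h.query_id, h.target_id = "A", "B"
        g = build_homology_graph([h], {"A": "literature", "B": "identified"})
        assert g["A"]["B"]["weight"] == pytest.approx(0.02)
        assert g.nodes["A"]["status"] == "literature"

    def test_no_hit_no_edge_no_self_loop(self):
        h = _hit(50)
        h.query_id = h.target_id = "A"
        g = build_homology_graph([h], {"A": "literature", "B": "candidate"})
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"A", "B"}

    def test_best_hit_kept(self):
        h1, h2 = _hit(40), _hit(80)
        for h in (h1, h2):
            h.query_id, h.target_id = "A", "B"
        g = build_homology_graph([h1, h2], {"A": "x", "B": "y"})
        assert g["A"]["B"]["aln_length"] == 80

    def test_edges_thin_out_with_divergence(self, divergence_grid):
        """The homology graph is connected at low divergence and loses
        edges as divergence rises (the homology-decay phenomenon)."""
        import networkx as nx

        low = divergence_grid[1.0]["graphs"]
        high = divergence_grid[20.0]["graphs"]
        assert np.mean([nx.is_connected(g) for g in low]) >= 0.8
        mean_edges = [
            np.mean([g.number_of_edges() for g in divergence_grid[m]["graphs"]])
            for m in (1.0, 3.0, 8.0, 20.0)
        ]
        assert mean_edges[0] > mean_edges[-1]
        assert all(a >= b for a, b in zip(mean_edges, mean_edges[1:]))
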