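import math
from collections import Counter

import numpy as np
import pytest

from tersurvey.intervals import revcomp
from tersurvey.simulate import (
    SM_MOTIF,
    CladeSimConfig,
    dinucleotide_shuffle,
    evolve_sequence,
    generate_ancestor,
    make_decoy_set,
    simulate_clade,
)


def _sm_sequence(genome, truth):
    seq = genome.contigs[truth.contig_id][truth.sm1[0] - 1 : truth.sm1[1]]
    return seq if truth.strand == "pos" else revcomp(seq)


class TestAncestor:
    def test_planted_layout(self, rng):
        cfg = CladeSimConfig(seed=7)
        genome, truths = generate_ancestor(cfg, np.random.default_rng(7))
        contig = genome.contigs[truths[0].contig_id]
        # telomere arrays at both contig ends
        assert contig.startswith(cfg.telomere_unit * 8)
        assert contig.endswith(cfg.telomere_unit * 8)
        tr = truths[0]
        assert _sm_sequence(genome, tr) == SM_MOTIF
        # 3' end sits exactly 10 nt downstream of the Sm motif
        if tr.strand == "pos":
            assert tr.ter[1] - tr.sm1[1] == 10
        else:
            assert tr.sm1[0] - tr.ter[0] == 10
        # transcript-order nesting of all features
        feats = [tr.ku, tr.template, tr.est1, tr.twj, tr.sm1]
        for iv in feats:
            assert tr.ter[0] <= iv[0] <= iv[1] <= tr.ter[1]

    def test_template_structure(self):
        cfg = CladeSimConfig(seed=11)
        genome, truths = generate_ancestor(cfg, np.random.default_rng(11))
        tr = truths[0]
        t = genome.contigs[tr.contig_id][tr.template[0] - 1 : tr.template[1]]
        if tr.strand == "neg":
            t = revcomp(t)
        # reverse complement of 1.5 repeat units plus its first 3 nt again
        core = revcomp((cfg.telomere_unit * 3)[: math.ceil(1.5 * len(cfg.telomere_unit))])
        assert t == core + core[:3]

    def test_contig_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            cfg = CladeSimConfig(seed=0, contig_length=2000)
            generate_ancestor(cfg, np.random.default_rng(0))


class TestEvolve:
    def test_zero_branch_is_identity(self, make_seq):
        cfg = CladeSimConfig()
        seq = make_seq(500)
        out, islands = evolve_sequence(seq, 0.0, [(100, 150)], cfg, np.random.default_rng(1))
        assert out == seq and islands == [(100, 150)]

    def test_negative_branch_rejected(self, make_seq):
        with pytest.raises(ValueError):
            evolve_sequence(make_seq(50), -1.0, [], CladeSimConfig(), np.random.default_rng(0))

    def test_jukes_cantor_expectation(self, make_seq):
        """Observed substitutions match the closed-form Jukes-Cantor
        expected difference 3/4(1 - e^{-4/3 r t}) within 3 sigma."""
        L, rate, t = 10000, 0.5, 1.0
        cfg = CladeSimConfig(background_sub_rate=rate, island_sub_rate=0.0,
                             indel_rate=0.0)
        seq = make_seq(L)
        out, _ = evolve_sequence(seq, t, [], cfg, np.random.default_rng(2))
        p = 0.75 * (1 - math.exp(-4.0 / 3.0 * rate * t))
        observed = sum(a != b for a, b in zip(seq, out))
        sigma = math.sqrt(L * p * (1 - p))
        assert abs(observed - L * p) < 3 * sigma

    def test_zero_rate_island_survives_verbatim(self, make_seq):
        cfg = CladeSimConfig(background_sub_rate=1.0, island_sub_rate=0.0,
                             indel_rate=0.1)
        seq = make_seq(4000)
        island = (1501, 1700)
        out, islands = evolve_sequence(seq, 2.0, [island], cfg, np.random.default_rng(3))
        s, e = islands[0]
        assert out[s - 1 : e] == seq[island[0] - 1 : island[1]]

    def test_conservation_gradient(self, make_seq):
        """Islands stay closer to the ancestor than background, for any
        config with island rate below background rate (20 seeds)."""
        cfg = CladeSimConfig(background_sub_rate=1.0, island_sub_rate=0.1,
                             indel_rate=0.0)
        island = (1001, 1400)
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            seq = "".join(r.choice(list("ACGT"), 3000))
            out, _ = evolve_sequence(seq, 0.5, [island], cfg, r)
            def ident(a, b):
                return sum(x == y for x, y in zip(a, b)) / len(a)
            isl = ident(seq[1000:1400], out[1000:1400])
            bg = ident(seq[:1000], out[:1000])
            diffs.append(isl - bg)
        assert np.mean(diffs) > 0
        assert np.mean([d > 0 for d in diffs]) >= 0.95


class TestClade:
    def test_all_rates_zero_identity(self):
        cfg = CladeSimConfig(seed=5, background_sub_rate=0.0,
                             island_sub_rate=0.0, indel_rate=0.0)
        genomes, truths = simulate_clade(cfg)
        anc, anc_truths = generate_ancestor(cfg, np.random.default_rng(5))
        for g in genomes:
            assert list(g.contigs.values()) == list(anc.contigs.values())

    def test_determinism(self):
        cfg = CladeSimConfig(seed=9)
        g1, t1 = simulate_clade(cfg)
        g2, t2 = simulate_clade(cfg)
        assert t1 == t2
        assert all(a.contigs == b.contigs for a, b in zip(g1, g2))

    def test_truth_valid_after_indels(self, default_clade):
        cfg, genomes, truths = default_clade
        assert len(genomes) == 6 and len(truths) == 6
        by_sp = {g.species_id: g for g in genomes}
        for tr in truths:
            contig = by_sp[tr.species_id].contigs[tr.contig_id]
            assert 1 <= tr.ter[0] <= tr.ter[1] <= len(contig)
            for iv in (tr.ku, tr.template, tr.est1, tr.twj, tr.sm1):
                assert tr.ter[0] <= iv[0] <= iv[1] <= tr.ter[1]
            # Sm island stays within 1 edit of the motif at low divergence
            sm = _sm_sequence(by_sp[tr.species_id], tr)
            assert sum(a != b for a, b in zip(sm, SM_MOTIF)) <= 1


def _dinucs(s):
    return Counter(s[i : i + 2] for i in range(len(s) - 1))


class TestDecoys:
    def test_default_ratio_24_to_48(self, make_seq):
        positives = [make_seq(60) for _ in range(24)]
        decoys = make_decoy_set(positives, rng=np.random.default_rng(1))
        assert len(decoys) == 48

    def test_dinucleotide_composition_preserved(self, make_seq):
        positives = [make_seq(80) for _ in range(5)]
        decoys = make_decoy_set(positives, 3, np.random.default_rng(2))
        for i, pos in enumerate(positives):
            for d in decoys[3 * i : 3 * i + 3]:
                assert len(d) == len(pos)
                assert Counter(d) == Counter(pos)
                assert _dinucs(d) == _dinucs(pos)

    def test_single_state_shuffle(self):
        assert dinucleotide_shuffle("AAAA", np.random.default_rng(0)) == "AAAA"

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            make_decoy_set(["AC"], rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            make_decoy_set([], rng=np.random.default_rng(0))


class TestConfigValidation:
    def test_island_rate_above_background_rejected(self):
        with pytest.raises(ValueError):
            CladeSimConfig(background_sub_rate=0.1, island_sub_rate=0.5)

    def test_ter_length_range_bounds(self):
        with pytest.raises(ValueError):
            CladeSimConfig(ter_length_range=(100, 2000))
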