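import numpy as np
import pytest

from tersurvey.features import (
    FeatureHit,
    _enforce_order,
    annotate_ter,
    assign_three_prime,
    feature_profile,
    find_est1,
    find_ku_hairpin,
    find_twj,
    scan_sm,
)
from tersurvey.intervals import revcomp
from tersurvey.simulate import (
    CladeSimConfig,
    dinucleotide_shuffle,
    simulate_clade,
)
from tersurvey.telomere import TelomereRepeat, canonical_unit

SM = "AATTTTTGG"
REPEAT = TelomereRepeat(canonical_unit("TTAGGG"))


def _hamming_scan(seq, motif, max_mm):
    out = []
    for i in range(len(seq) - len(motif) + 1):
        mm = sum(
            a != b or a == "N" for a, b in zip(seq[i : i + len(motif)], motif)
        )
        if mm <= max_mm:
            out.append((i + 1, mm))
    return out


class TestScanSm:
    def test_exact_hit(self):
        seq = "G" * 40 + SM + "G" * 20
        hits = scan_sm(seq, 0)
        assert hits[0].interval == (41, 49) and hits[0].score == 1.0

    def test_poly_c_has_no_hits(self):
        assert scan_sm("C" * 200, 2) == []

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_matches_exhaustive_hamming_scan(self, rng, max_mm):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGTN"), 300, p=[0.24] * 4 + [0.04]))
            got = {(h.interval[0], round(9 * (1 - h.score))) for h in scan_sm(seq, max_mm)}
            assert got == set(_hamming_scan(seq, SM, max_mm))

    def test_invalid_mismatch_budget(self):
        with pytest.raises(ValueError):
            scan_sm("ACGT", 3)


class TestThreePrimeRule:
    def test_both_strands(self):
        assert assign_three_prime((991, 1000), "pos") == 1010
        assert assign_three_prime((1000, 1009), "neg") == 990

    def test_mirror_symmetry(self, rng):
        for _ in range(20):
            s = int(rng.integers(100, 10000))
            iv = (s, s + 8)
            assert assign_three_prime(iv, "pos") - iv[1] == 10
            assert iv[0] - assign_three_prime(iv, "neg") == 10

    def test_clamping(self):
        assert assign_three_prime((3, 11), "neg") == 1
        assert assign_three_prime((90, 98), "pos", contig_length=100) == 100


def _hairpin(rng, stem, loop):
    arm = "".join(rng.choice(list("ACGT"), stem))
    return arm + loop + revcomp(arm)


def _ac_filler(rng, n):
    """A/C-only sequence: cannot form Watson-Crick or wobble pairs."""
    return "".join(rng.choice(list("AC"), n))


class TestKuHairpin:
    def test_no_gcta_in_window_means_no_call(self, rng):
        window = _ac_filler(rng, 400)
        template_start = len(window) + 1
        assert find_ku_hairpin(window + "CCCTAA", template_start) is None

    def test_planted_recovery(self):
        r = np.random.default_rng(5)
        hp = _hairpin(r, 10, "AG" + "GCTA" + "CT")
        seq = "".join(r.choice(list("ACGT"), 200)) + hp + "".join(
            r.choice(list("ACGT"), 100)
        )
        template_start = len(seq) + 1
        hit = find_ku_hairpin(seq, template_start)
        planted = (201, 200 + len(hp))
        assert hit is not None
        assert abs(hit.interval[0] - planted[0]) <= 3
        assert abs(hit.interval[1] - planted[1]) <= 3

    def test_shuffled_windows_mostly_null(self):
        """Dinucleotide-shuffled Ku windows yield no call in >= 90% of
        100 shuffles (empirical specificity)."""
        r = np.random.default_rng(6)
        hp = _hairpin(r, 10, "AGGCTACT")
        window = (
            "".join(r.choice(list("ACGT"), 300))
            + hp
            + "".join(r.choice(list("ACGT"), 272))
        )
        nulls = 0
        for i in range(100):
            shuf = dinucleotide_shuffle(window, np.random.default_rng(i))
            if find_ku_hairpin(shuf, len(shuf) + 1) is None:
                nulls += 1
        assert nulls >= 90


class TestEst1:
    def test_planted_recovery(self):
        r = np.random.default_rng(8)
        hp = _hairpin(r, 12, "ACGTAC")
        seq = _ac_filler(r, 150) + hp + _ac_filler(r, 150)
        hit = find_est1(seq, (1, len(seq)))
        planted = (151, 150 + len(hp))
        assert hit is not None
        assert abs(hit.interval[0] - planted[0]) <= 5
        assert abs(hit.interval[1] - planted[1]) <= 5
        assert hit.score >= 0.6

    def test_poly_a_region_null(self):
        assert find_est1("A" * 300, (1, 300)) is None

    def test_short_region_null(self):
        assert find_est1("ACGT" * 100, (1, 30)) is None

    def test_specificity_on_shuffles(self):
        """Planted hairpins are detected far more often than hairpin calls
        arise in shuffled copies of the same region."""
        r = np.random.default_rng(9)
        hp = _hairpin(r, 12, "ACGTAC")
        region = "".join(r.choice(list("ACGT"), 120)) + hp + "".join(
            r.choice(list("ACGT"), 120)
        )
        planted_hit = find_est1(region, (1, len(region)))
        assert planted_hit is not None
        false_calls = 0
        for i in range(30):
            shuf = dinucleotide_shuffle(region, np.random.default_rng(200 + i))
            if find_est1(shuf, (1, len(shuf))) is not None:
                false_calls += 1
        assert false_calls <= 15  # chance stems do occur, but far from always


class TestTwj:
    def test_planted_structural_call(self):
        r = np.random.default_rng(10)
        cassette = (
            _hairpin(r, 8, "ACGTA") + "CACAC" + "AATA" + "CACCA"
            + _hairpin(r, 8, "ACGTA")
        )
        seq = _ac_filler(r, 100) + cassette + _ac_filler(r, 100)
        hit = find_twj(seq, (1, len(seq)))
        assert hit is not None and hit.evidence == "AATA with flanking hairpins"
        planted = (101, 100 + len(cassette))
        assert abs(hit.interval[0] - planted[0]) <= 5
        assert abs(hit.interval[1] - planted[1]) <= 5

    def test_no_aata_no_call(self, rng):
        assert find_twj("C" * 300, (1, 300)) is None

    def test_sequence_only_when_structure_destroyed(self):
        r = np.random.default_rng(11)
        seq = _ac_filler(r, 120) + "AATA" + _ac_filler(r, 120)
        hit = find_twj(seq, (1, len(seq)))
        assert hit is not None
        assert hit.evidence == "sequence-only" and hit.score == 0.0
        assert hit.interval == (121, 124)


class TestOrderEnforcement:
    def test_lowest_scoring_violator_dropped(self):
        feats = {
            "TEMPLATE": FeatureHit("TEMPLATE", (100, 111), 1.0, "t"),
            "EST1": FeatureHit("EST1", (90, 140), 0.3, "weak overlap"),
            "SM1": FeatureHit("SM1", (300, 308), 1.0, "exact"),
        }
        fixed = _enforce_order(feats)
        assert "EST1" not in fixed
        assert set(fixed) == {"TEMPLATE", "SM1"}


class TestAnnotateTer:
    def test_end_to_end_recovery_low_divergence(self, default_clade):
        """All five features recovered within a few nt of truth on the
        default clade, candidate = truth locus plus 400 nt flanks."""
        cfg, genomes, truths = default_clade
        by_sp = {g.species_id: g for g in genomes}
        errs = []
        for i, tr in enumerate(truths):
            ref = truths[(i + 1) % len(truths)]
            seq = by_sp[tr.species_id].contigs[tr.contig_id]
            a, b = tr.ter[0] - 400, tr.ter[1] + 400
            ann = annotate_ter(
                seq[a - 1 : b], REPEAT, tr.species_id, tr.contig_id, offset=a,
                contig_length=len(seq), profile=feature_profile(ref.to_annotation()),
            )
            assert ann is not None and ann.strand == tr.strand
            for kind in ("ku", "template", "est1", "twj", "sm1"):
                ti, pi = getattr(tr, kind), getattr(ann, kind)
                if pi is not None:
                    errs.append(max(abs(ti[0] - pi[0]), abs(ti[1] - pi[1])))
            # output respects the nesting invariant by construction
            for iv in ann.features().values():
                if iv is not None:
                    assert ann.ter[0] <= iv[0] <= iv[1] <= ann.ter[1]
        assert np.mean(errs) <= 5.0

    def test_rejected_without_template_or_sm(self, make_seq):
        assert (
            annotate_ter(make_seq(800), REPEAT, "sp", "c1") is None
        )

    def test_incomplete_flag_without_sm(self, make_seq):
        r = np.random.default_rng(12)
        core = revcomp("TTAGGGTTA")
        template = core + core[:3]  # end repetition verifies the hit
        seq = _ac_filler(r, 300) + template + _ac_filler(r, 1200)
        ann = annotate_ter(seq, REPEAT, "sp", "c1")
        assert ann is not None
        assert ann.sm1 is None
        assert "incomplete" in ann.flags

    def test_transcript_order_always_respected(self, default_clade):
        cfg, genomes, truths = default_clade
        by_sp = {g.species_id: g for g in genomes}
        for tr in truths:
            seq = by_sp[tr.species_id].contigs[tr.contig_id]
            a, b = tr.ter[0] - 400, tr.ter[1] + 400
            ann = annotate_ter(
                seq[a - 1 : b], REPEAT, tr.species_id, tr.contig_id, offset=a,
                contig_length=len(seq),
            )
            present = [
                iv for iv in (ann.ku, ann.template, ann.est1, ann.twj, ann.sm1)
                if iv is not None
            ]
            ordered = sorted(present)
            if ann.strand == "neg":
                ordered = ordered[::-1]
                present = sorted(present, key=lambda iv: -iv[0])
            assert present == ordered
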