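"""Synthetic clades with planted TER loci.

The generator emulates the regime that makes telomerase RNAs hard to find:
a clade of small genomes whose protein-coding anchor genes and short
functional islands (Ku hairpin, template, Est1 hairpin, three-way junction,
Sm motif) stay recognizable while the surrounding sequence diverges rapidly.
Sequences evolve under Jukes-Cantor substitutions plus geometric-length
indels; islands are indel-free so that planted truth coordinates stay exact,
and all tracked coordinates are remapped across upstream indels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .intervals import Interval, revcomp
from .io import GeneAnnotation, Genome, TerAnnotation

SM_MOTIF = "AATTTTTGG"

#: Six leaves, branch lengths giving leaf-to-leaf path lengths of
#: 0.12-0.34; with the default background rate this spans the "closely
#: related yeasts" regime where synteny plus local alignment still works.
DEFAULT_TREE = (
    "(((sp1:0.06,sp2:0.06):0.05,(sp3:0.06,sp4:0.06):0.05):0.04,"
    "(sp5:0.08,sp6:0.08):0.11);"
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CladeSimConfig:
    """Study conditions for one simulated clade.

    Rates are substitutions (or indel events) per site per unit branch
    length. ``island_sub_rate`` applies inside planted functional islands
    and must not exceed ``background_sub_rate``; islands never receive
    indels.
    """

    tree: str = DEFAULT_TREE
    n_contigs: int = 1
    contig_length: int = 30000
    background_sub_rate: float = 1.0
    island_sub_rate: float = 0.02
    indel_rate: float = 0.05
    mean_indel_len: float = 3.0
    ter_length_range: tuple[int, int] = (750, 2000)
    telomere_unit: str = "TTAGGG"
    anchor_gene_length: int = 900
    n_genes_per_contig: int = 6
    telomere_copies: int = 12
    inverted_ter_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.island_sub_rate > self.background_sub_rate:
            raise ValueError("island_sub_rate must not exceed background_sub_rate")
        lo, hi = self.ter_length_range
        if not (200 <= lo <= hi <= 5000):
            raise ValueError("ter_length_range must lie within [200, 5000]")
        if self.telomere_copies < 8:
            raise ValueError("telomeres need >= 8 repeat copies")


@dataclass(frozen=True)
class TruthRecord:
    """Planted-feature coordinates for recovery scoring (forward strand)."""

    species_id: str
    contig_id: str
    ter: Interval
    strand: str  # pos | neg
    ku: Interval
    template: Interval
    est1: Interval
    twj: Interval
    sm1: Interval
    anchor_left: str
    anchor_right: str

    def to_annotation(self) -> TerAnnotation:
        return TerAnnotation(
            species=self.species_id,
            accession=self.contig_id,
            strand=self.strand,
            ter=self.ter,
            ku=self.ku,
            template=self.template,
            est1=self.est1,
            twj=self.twj,
            sm1=self.sm1,
            coord_citation=False,
        )


# ---------------------------------------------------------------------------
# internal tracked-interval machinery (0-based half-open during simulation)


@dataclass
class _Tracked:
    start: int  # 0-based
    end: int  # exclusive
    kind: str  # telomere | gene | ter | ku | template | est1 | twj | sm1
    rate: float  # substitution rate multiplier source (absolute rate)
    indel_free: bool
    meta: dict = field(default_factory=dict)


@dataclass
class _Contig:
    seq: np.ndarray  # uint8 codes 0..3
    tracked: list


def _random_seq(rng, n) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _encode(s: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    arr = lut[np.frombuffer(s.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _rc_arr(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def _has_phase_window(s: str, unit: str, min_len: int = 8, max_mm: int = 1) -> bool:
    from .telomere import _periodic_windows

    pat = revcomp(unit)
    for text in (s, revcomp(s)):
        if _periodic_windows(pat, text, min_len, max_mm):
            return True
    return False


def _random_spacer(rng, n: int, avoid_unit: str | None = None) -> np.ndarray:
    """Random sequence screened against an accidental exact Sm motif and,
    near the TER cassette, against chance telomere-repeat-phase tracts that
    would make the planted template ambiguous."""
    for _ in range(30):
        arr = _random_seq(rng, n)
        s = _decode(arr)
        if SM_MOTIF in s or SM_MOTIF in revcomp(s):
            continue
        if avoid_unit is not None and _has_phase_window(s, avoid_unit):
            continue
        return arr
    return arr  # vanishingly unlikely; accept rather than loop forever


def _hairpin(rng, stem: int, loop_seq: np.ndarray) -> np.ndarray:
    arm = _random_seq(rng, stem)
    return np.concatenate([arm, loop_seq, _rc_arr(arm)])


def _build_ter_cassette(cfg: CladeSimConfig, rng):
    """Return (sequence array, feature offsets dict) in transcript order.

    Rebuilds until the planted elements are unambiguous in the unevolved
    cassette: no chance telomere-phase tract outside the template, and the
    Ku/Est1/TWJ structure detectors recover the planted hairpins as their
    unique optimum (so divergence, not generator luck, governs recovery)."""
    for _ in range(40):
        arr, offsets = _build_ter_cassette_once(cfg, rng)
        s = list(_decode(arr))
        t0, t1 = offsets["template"]
        s[t0:t1] = "N" * (t1 - t0)
        if _has_phase_window("".join(s), cfg.telomere_unit.upper()):
            continue
        if _cassette_detectable(_decode(arr), offsets):
            return arr, offsets
    return arr, offsets


def _cassette_detectable(ts: str, offsets, tol: int = 2) -> bool:
    from .features import find_est1, find_ku_hairpin, find_twj

    def close(hit, name):
        s, e = offsets[name]
        return (
            hit is not None
            and abs(hit.interval[0] - (s + 1)) <= tol
            and abs(hit.interval[1] - e) <= tol
        )

    t0, t1 = offsets["template"]
    sm0, _ = offsets["sm1"]
    ku = find_ku_hairpin(ts, t0 + 1)
    if not close(ku, "ku"):
        return False
    est1 = find_est1(ts, (t1 + 1, sm0))
    if not close(est1, "est1"):
        return False
    e1 = offsets["est1"][1]
    twj = find_twj(ts, (e1 + 1, sm0))
    return close(twj, "twj") and twj.evidence != "sequence-only"


def _build_ter_cassette_once(cfg: CladeSimConfig, rng):
    unit = cfg.telomere_unit.upper()
    k = len(unit)
    total = int(rng.integers(cfg.ter_length_range[0], cfg.ter_length_range[1] + 1))

    # fixed-size elements
    margin5 = 30
    ku_loop = np.concatenate(
        [_random_seq(rng, 2), _encode("GCTA"), _random_seq(rng, 2)]
    )
    ku = _hairpin(rng, 10, ku_loop)  # 28 nt
    t_core = revcomp((unit * 3)[: math.ceil(1.5 * k)])
    template = _encode(t_core + t_core[:3])
    est1 = _hairpin(rng, 12, _random_seq(rng, 6))  # 30 nt
    twj = np.concatenate(
        [
            _hairpin(rng, 8, _random_seq(rng, 5)),
            _random_seq(rng, 5),
            _encode("AATA"),
            _random_seq(rng, 5),
            _hairpin(rng, 8, _random_seq(rng, 5)),
        ]
    )  # 56 nt
    sm = _encode(SM_MOTIF)
    tail = 10

    fixed = margin5 + len(ku) + len(template) + len(est1) + len(twj) + len(sm) + tail
    slack = max(total - fixed, 80)
    wa, wb, wc, wd = 0.35, 0.25, 0.25, 0.15
    sa = max(20, int(slack * wa))
    sb = max(20, int(slack * wb))
    sc = max(20, int(slack * wc))
    sd = max(20, slack - sa - sb - sc)

    # Terminate the telomere-repeat phase at the template boundaries: force
    # two off-phase bases in the 3 nt on either side so the planted template
    # (core + its 3'-end repetition) is the unique maximal periodic match,
    # as in genuine loci where the repeat tract stops at the template.
    spacer_a = _random_spacer(rng, sa)
    spacer_b = _random_spacer(rng, sb)
    t_core_arr = _encode(t_core)

    def _off_phase(expected: int) -> int:
        return int((expected + 1 + rng.integers(0, 3)) % 4)

    for back in (1, 3):  # positions -1 and -3 relative to template start
        expected = int(t_core_arr[(-back) % k])
        spacer_a[-back] = _off_phase(expected)
    # after the end repetition (= core[:3]) the phase would continue with
    # core[3:]; break it at offsets 0 and 2
    for fwd in (0, 2):
        expected = int(t_core_arr[(3 + fwd) % k])
        spacer_b[fwd] = _off_phase(expected)

    parts = [
        ("margin5", _random_spacer(rng, margin5)),
        ("ku", ku),
        ("spacer_a", spacer_a),
        ("template", template),
        ("spacer_b", spacer_b),
        ("est1", est1),
        ("spacer_c", _random_spacer(rng, sc)),
        ("twj", twj),
        ("spacer_d", _random_spacer(rng, sd)),
        ("sm1", sm),
        ("tail", _random_spacer(rng, tail)),
    ]
    offsets = {}
    pos = 0
    chunks = []
    for name, arr in parts:
        offsets[name] = (pos, pos + len(arr))
        chunks.append(arr)
        pos += len(arr)
    return np.concatenate(chunks), offsets


def generate_ancestor(config: CladeSimConfig, rng) -> tuple[Genome, list[TruthRecord]]:
    """Build the clade ancestor: telomere-capped contigs, anchor genes with
    unique ortholog groups, and one TER cassette between a designated anchor
    pair on the first contig."""
    genome, truths, _ = _generate_ancestor_state(config, rng)
    return genome, truths


def _generate_ancestor_state(config: CladeSimConfig, rng):
    unit_arr = _encode(config.telomere_unit.upper())
    tel = np.tile(unit_arr, config.telomere_copies)
    contigs: list[_Contig] = []
    for ci in range(config.n_contigs):
        tracked: list[_Tracked] = []
        chunks: list[np.ndarray] = []
        pos = 0

        def emit(arr, kind=None, rate=None, indel_free=False, meta=None):
            nonlocal pos
            chunks.append(arr)
            if kind is not None:
                tracked.append(
                    _Tracked(pos, pos + len(arr), kind, rate, indel_free, meta or {})
                )
            pos += len(arr)

        emit(tel.copy(), "telomere", 0.0, True)
        emit(_random_spacer(rng, 400))
        ter_after_gene = config.n_genes_per_contig // 2 - 1  # 0-based index
        for gi in range(config.n_genes_per_contig):
            emit(
                _random_spacer(rng, config.anchor_gene_length),
                "gene",
                config.island_sub_rate,
                True,
                {
                    "name": f"g{ci}_{gi}",
                    "og": f"OG{ci}_{gi}",
                    "strand": "+" if rng.random() < 0.5 else "-",
                },
            )
            if ci == 0 and gi == ter_after_gene:
                emit(_random_spacer(rng, 400, avoid_unit=config.telomere_unit))
                cassette, offsets = _build_ter_cassette(config, rng)
                inverted = bool(rng.random() < config.inverted_ter_prob)
                meta_ter = {"strand": "neg" if inverted else "pos"}
                L = len(cassette)
                if inverted:
                    cassette = _rc_arr(cassette)
                ter_start = pos
                # the whole-locus span is tracked soft (indels allowed
                # outside islands); features are hard islands
                tracked.append(
                    _Tracked(pos, pos + L, "ter", config.background_sub_rate,
                             False, meta_ter)
                )
                for name in ("ku", "template", "est1", "twj", "sm1"):
                    s, e = offsets[name]
                    if inverted:
                        s, e = L - e, L - s
                    tracked.append(
                        _Tracked(ter_start + s, ter_start + e, name,
                                 config.island_sub_rate, True, meta_ter)
                    )
                emit(cassette)
                emit(_random_spacer(rng, 400, avoid_unit=config.telomere_unit))
            else:
                emit(_random_spacer(rng, 600))
        pad = config.contig_length - pos - len(tel)
        if pad < 0:
            raise ValueError(
                f"contig_length {config.contig_length} too short to host all "
                f"elements (need >= {pos + len(tel)})"
            )
        if pad:
            emit(_random_spacer(rng, pad))
        emit(tel.copy(), "telomere", 0.0, True)
        contigs.append(_Contig(np.concatenate(chunks), tracked))

    genome, truths = _state_to_genome("ancestor", contigs, config)
    return genome, truths, contigs


def _state_to_genome(species_id, contigs, config):
    seqs = {}
    genes = []
    truths = []
    for ci, c in enumerate(contigs):
        cid = f"{species_id}_c{ci}"
        seqs[cid] = _decode(c.seq)
        feats = {}
        ter = None
        anchors = []
        for t in c.tracked:
            if t.kind == "gene":
                genes.append(
                    GeneAnnotation(
                        gene_id=f"{species_id}_{t.meta['name']}",
                        contig_id=cid,
                        start=t.start + 1,
                        end=t.end,
                        strand=t.meta["strand"],
                        ortholog_group=t.meta["og"],
                    )
                )
            elif t.kind == "ter":
                ter = t
            elif t.kind in ("ku", "template", "est1", "twj", "sm1"):
                feats[t.kind] = (t.start + 1, t.end)
        if ter is not None:
            gs = [g for g in genes if g.contig_id == cid]
            left = max(
                (g for g in gs if g.end < ter.start + 1),
                key=lambda g: g.end,
            )
            right = min(
                (g for g in gs if g.start > ter.end),
                key=lambda g: g.start,
            )
            truths.append(
                TruthRecord(
                    species_id=species_id,
                    contig_id=cid,
                    ter=(ter.start + 1, ter.end),
                    strand=ter.meta["strand"],
                    anchor_left=left.gene_id,
                    anchor_right=right.gene_id,
                    **feats,
                )
            )
    return Genome(species_id=species_id, contigs=seqs, genes=genes), truths


# ---------------------------------------------------------------------------
# evolution


def _substitute(seq, tracked, t, config, rng):
    rates = np.full(len(seq), config.background_sub_rate)
    for tr in tracked:
        if tr.kind != "ter":
            rates[tr.start : tr.end] = tr.rate
    # Jukes-Cantor: P(site differs) = 3/4 (1 - e^{-4/3 r t})
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rates * t))
    hit = rng.random(len(seq)) < p
    n = int(hit.sum())
    if n:
        seq = seq.copy()
        seq[hit] = (seq[hit] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return seq


def _shift_for_insertion(tr: _Tracked, k: int, d: int) -> None:
    if k <= tr.start:
        tr.start += d
        tr.end += d
    elif k < tr.end:
        tr.end += d  # only reachable for soft (ter) intervals


def _shift_for_deletion(tr: _Tracked, k: int, d: int) -> None:
    def remap(c):
        if c >= k + d:
            return c - d
        if c >= k:
            return k
        return c

    tr.start = remap(tr.start)
    tr.end = remap(tr.end)


def _apply_indels(seq, tracked, t, config, rng):
    lam = config.indel_rate * t * len(seq)
    n_events = int(rng.poisson(lam)) if lam > 0 else 0
    for _ in range(n_events):
        d = int(rng.geometric(1.0 / config.mean_indel_len))
        insert = rng.random() < 0.5
        ok = False
        for _attempt in range(50):
            k = int(rng.integers(0, len(seq) + 1 if insert else max(len(seq) - d, 1)))
            if insert:
                bad = any(
                    tr.indel_free and tr.start < k < tr.end for tr in tracked
                )
            else:
                bad = any(
                    tr.indel_free and tr.start < k + d and k < tr.end
                    for tr in tracked
                )
            if not bad:
                ok = True
                break
        if not ok:
            continue
        if insert:
            seq = np.concatenate([seq[:k], _random_seq(rng, d), seq[k:]])
            for tr in tracked:
                _shift_for_insertion(tr, k, d)
        else:
            seq = np.concatenate([seq[:k], seq[k + d :]])
            for tr in tracked:
                _shift_for_deletion(tr, k, d)
    return seq, tracked


def _evolve_contig(contig: _Contig, t: float, config: CladeSimConfig, rng) -> _Contig:
    if t < 0:
        raise ValueError("negative branch length")
    tracked = [replace(tr, meta=dict(tr.meta)) for tr in contig.tracked]
    seq = _substitute(contig.seq, tracked, t, config, rng)
    seq, tracked = _apply_indels(seq, tracked, t, config, rng)
    return _Contig(seq, tracked)


def evolve_sequence(
    seq: str,
    branch_length: float,
    island_map: list[Interval],
    config: CladeSimConfig,
    rng,
) -> tuple[str, list[Interval]]:
    """Evolve one sequence; islands (1-based inclusive intervals) substitute
    at ``island_sub_rate`` and never receive indels. Returns the evolved
    sequence and the islands' updated coordinates."""
    if branch_length < 0:
        raise ValueError("negative branch length")
    tracked = [
        _Tracked(s - 1, e, "island", config.island_sub_rate, True)
        for s, e in island_map
    ]
    contig = _Contig(_encode(seq.upper()), tracked)
    out = _evolve_contig(contig, branch_length, config, rng)
    return _decode(out.seq), [(tr.start + 1, tr.end) for tr in out.tracked]


def simulate_clade(
    config: CladeSimConfig,
) -> tuple[list[Genome], list[TruthRecord]]:
    """Evolve one ancestor along the configured tree; one genome per leaf.

    Fully reproducible from ``config.seed``: the tree is traversed in
    newick order with a single random stream.
    """
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    _, _, anc_contigs = _generate_ancestor_state(config, rng)

    genomes: list[Genome] = []
    truths: list[TruthRecord] = []

    def walk(node, contigs):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            evolved = [_evolve_contig(c, t, config, rng) for c in contigs]
            if child.is_leaf():
                label = child.taxon.label.replace(" ", "_")
                g, tr = _state_to_genome(label, evolved, config)
                genomes.append(g)
                truths.extend(tr)
            else:
                walk(child, evolved)

    walk(tree.seed_node, anc_contigs)
    return genomes, truths


# ---------------------------------------------------------------------------
# decoys


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Altschul-Erikson shuffle: a uniform random sequence with exactly the
    source's dinucleotide (hence mononucleotide) composition."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 nt cannot be shuffled")
    chars = list(seq)
    verts = sorted(set(chars))
    edges = {v: [] for v in verts}
    for a, b in zip(chars, chars[1:]):
        edges[a].append(b)
    last = chars[-1]
    for _ in range(2000):
        lastedge = {}
        for v in verts:
            if v == last or not edges[v]:
                continue
            lastedge[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in lastedge:
            seen = set()
            u = v
            while u != last and u in lastedge and u not in seen:
                seen.add(u)
                u = lastedge[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - Eulerian path always exists
        raise RuntimeError("failed to sample a valid shuffle")
    walk_edges = {}
    for v in verts:
        rest = list(edges[v])
        if v in lastedge:
            rest.remove(lastedge[v])
        rng.shuffle(rest)
        if v in lastedge:
            rest.append(lastedge[v])
        walk_edges[v] = rest
    out = [chars[0]]
    ptr = {v: 0 for v in verts}
    v = chars[0]
    while ptr[v] < len(walk_edges[v]):
        u = walk_edges[v][ptr[v]]
        ptr[v] += 1
        out.append(u)
        v = u
    return "".join(out)


def make_decoy_set(
    positives: list[str], decoys_per_positive: int = 2, rng=None
) -> list[str]:
    """Dinucleotide-preserving shuffles of each positive sequence; the
    default ratio of 2 decoys per positive mirrors a 24-positive /
    48-negative benchmark design."""
    if not positives:
        raise ValueError("positives must be non-empty")
    if decoys_per_positive < 1:
        raise ValueError("decoys_per_positive must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for seq in positives:
        for _ in range(decoys_per_positive):
            out.append(dinucleotide_shuffle(seq, rng))
    return out


# ---------------------------------------------------------------------------
# export


def write_clade(genomes, truths, outdir) -> None:
    """Emit FASTA + GFF3 + per-genome ortholog TSV + truth table TSV."""
    from pathlib import Path

    from .io import write_annotations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        with open(outdir / f"{g.species_id}.fa", "w") as fh:
            for cid, seq in g.contigs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(outdir / f"{g.species_id}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in g.genes:
                fh.write(
                    "\t".join(
                        [
                            gene.contig_id,
                            "tersurvey_sim",
                            "gene",
                            str(gene.start),
                            str(gene.end),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={gene.gene_id}",
                        ]
                    )
                    + "\n"
                )
        with open(outdir / f"{g.species_id}.orthologs.tsv", "w") as fh:
            fh.write("gene_id\tortholog_group\n")
            for gene in g.genes:
                fh.write(f"{gene.gene_id}\t{gene.ortholog_group}\n")
    write_annotations([t.to_annotation() for t in truths], outdir / "truth.tsv", "TSV")
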