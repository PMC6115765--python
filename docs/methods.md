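# Methods

This note documents the models, heuristics, parameter choices and known
limitations behind `tersurvey`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate conventions

All genomic coordinates are 1-based inclusive on the forward strand,
matching GFF3 and the packaged annotation table; feature intervals of a
TER locus are forward-strand coordinates regardless of the transcribed
strand, and nest inside the locus interval (enforced at construction).
BED export is the only place 0-based half-open coordinates appear. `N`
characters are legal in sequences but never match any motif, alignment
position, or base pair.

## The packaged annotation table

`data/ter_table_saccharomycetaceae.tsv` transcribes a survey of conserved
TER substructures in 46 Saccharomycetaceae species: locus interval, strand
and per-feature intervals (Ku hairpin, template, Est1 site, three-way
junction, Sm site), plus a flag marking rows whose locus coordinates were
reported in prior literature (16 rows; the remaining 30 are first-time
annotations). Two obvious comma-misplacement typos in the printed source
were normalized; they are listed in the file header rather than silently
corrected. An "absent" feature annotation is encoded as an empty cell.

## Synthetic clades

The simulator generates a clade ancestor and evolves it along a rooted
newick tree, one genome per leaf.

**Ancestor layout.** Each contig is capped at both ends by tandem arrays
of the telomeric unit (default `TTAGGG`, 12 copies) and carries 6 anchor
genes (900 nt) with clade-unique ortholog groups. One TER cassette is
planted between the middle anchor pair of the first contig, inverted with
probability 0.5. In transcript order the cassette holds: a 30 nt 5'
margin, a Ku hairpin (10 bp stem, 8 nt loop containing `GCTA`), the
template — reverse complement of 1.5 telomere units with its first 3 nt
repeated at its end — an Est1 hairpin (12 bp stem), a three-way-junction
cassette (two 8 bp hairpins flanking `AATA`), the Sm motif `AATTTTTGG`,
and a 10 nt tail so the 3' end falls exactly 10 nt after the Sm motif.
Total locus length is drawn from 750–2000 nt; the slack is distributed
over the inter-feature spacers.

**Generator contract (important).** Cassettes are rejection-sampled until
the planted elements are unambiguous in the *unevolved* ancestor: spacers
are screened against chance occurrences of the exact Sm motif and against
chance telomere-repeat-phase tracts; the repeat phase is explicitly broken
at the template boundaries; and the package's own structure detectors must
recover the planted Ku/Est1/TWJ hairpins within ±2 nt on the pristine
cassette. Recovery tests therefore measure how *evolutionary divergence*
erodes detectability — not how often the generator happens to plant an
ambiguous locus. Real loci carry no such guarantee; chance structure in
real flanking DNA will produce some additional boundary error that these
tests do not capture.

**Evolution.** Substitutions follow Jukes–Cantor: each site differs after
branch length t with probability ¾(1 − e^(−4/3·r·t)). The background rate
defaults to 1.0 substitutions/site per unit branch length, and the default
tree's leaf-to-leaf path lengths of 0.12–0.34 put background identity at
roughly 72–88% between leaves — divergent enough that naive whole-genome
search is unreliable, close enough that synteny plus local alignment
works. Functional islands (the five features, genes, telomere arrays)
substitute at `island_sub_rate` (default 0.02, reflecting the near-perfect
conservation of the Sm motif and template between close relatives: at
0.02 the simulated Sm motif is exact in ~96% of leaves with occasional
single-substitution variants) and never receive indels, which keeps truth
bookkeeping exact; telomere arrays use rate 0 (maintained by telomerase).
Indels elsewhere arrive at 0.05 events/site per unit branch with geometric
lengths (mean 3), insertion/deletion equiprobable; all tracked coordinates
are remapped across each event. Islands are indel-free by design — the
conserved features are short and alignable — so the simulation cannot
probe indel tolerance inside features.

**Decoys.** Negative sets are Altschul–Erikson dinucleotide-preserving
shuffles (random Eulerian-path resampling of the dinucleotide transition
multigraph), the standard null for RNA motif work; the default ratio is
two decoys per positive.

## Telomere repeats and the template

Repeat units are identified from terminal windows (default 500 nt) as
primitive tandem runs of period 2–30 with at least 4 consecutive copies in
some terminus; among qualifying units the one covering the most terminal
sequence wins. Units are stored canonically: the strand with more G
(ties lexicographic), rotated to the lexicographic minimum — so inference
is invariant under reverse-complementing the assembly.

Template search matches the periodic extension of the unit's reverse
complement (equivalently, a doubled-unit query, which contains every
rotation) against both strands, as maximal windows tolerating one mismatch
per 9 nt of the minimum match (default 1.5 unit lengths), with window
edges anchored on 3 consecutive matches. Each core match is then checked
for the template's signature 3'-terminal repetition of its first ≥ 3 nt,
tolerating up to 2 nt of window over-extension. Hits are ranked
verified-first, then by matched span plus repetition length, then by
exact matches — chance repeat-phase windows of the same core length almost
always spend the mismatch budget and lack the repetition, so the genuine
template ranks first. On simulated clades at default divergence the top
hit matches the planted template within 2 nt in ≥ 95% of leaves.

## The internal aligner

Scoring is the canonical nucleotide-BLAST default (+2/−3, gap open 5,
extend 2). E-values use ungapped Karlin–Altschul statistics
E = K·m·n·e^(−λS): λ ≈ 0.63373 is solved numerically from
Σ pᵢpⱼe^(λsᵢⱼ) = 1 at uniform background; K defaults to 0.39, frozen from
a Monte-Carlo extreme-value calibration (mean maximal ungapped segment
score over random 1 kb pairs; `calibrate_karlin_k` recomputes it). The
ungapped-statistics approximation is acceptable here because the
downstream filter is lenient (E < 0.1) and alignment length and identity
dominate the decision.

The heuristic searcher seeds on exact 11-mers, extends ungapped with an
X-drop of 20, chains collinear segments (diagonal drift ≤ 60), and closes
inter-segment gaps with an exact affine Needleman–Wunsch on the short gap
sequences; overlapping results keep the best score, and raw scores below
20 are dropped. On seeded test cases (≤ 2 kb, ~10% substitutions plus
indels) its best score is ≥ 95% of the Smith–Waterman optimum and exact
when no gaps are required. `smith_waterman` itself is backed by
Biopython's C pairwise aligner, with co-optimal ties resolved by the
aligner's canonical first traceback; tests cross-check it against an
independent pure-python dynamic program.

Hit filtering keeps E < 0.1, alignment length ≥ 25 nt, identity ≥ 60%
(compared with a 1e-9 tolerance so 0.60 passes exactly), and discards any
hit sharing even one position with a masked telomeric interval. The
empirical false-positive-rate table bins filtered hits by length
thresholds 25–200 in steps of 5. The homology graph joins loci linked by
a filtered hit with weight 1/(longest linking alignment).

## Synteny projection

Candidates are delimited by ortholog-table anchoring alone (no
whole-genome alignment): the nearest ortholog-labelled genes on each side
of a locus are projected into the target; if both orthologs share a
contig with at most 3 intervening genes, the inter-anchor interval
expanded by 500 nt of slack is the candidate, else synteny is declared
broken. Orientation combines anchor order and strand agreement;
conflicting signals are treated as inverted with a warning, and mixed
strand signals defer to order. Ambiguous ortholog groups resolve to the
closest pair, with a warning.

## Feature annotation

The Sm motif is scanned with ≤ 1 mismatch by default — species-specific
variants are handled as mismatch tolerance rather than an enumerated
variant list. The 3' end is an exact affine map: Sm end + 10 on the plus
strand, Sm start − 10 on the minus strand, clamped to the contig with a
warning.

Hairpins are found by maximal complementary-arm extension rather than
thermodynamic folding (an optional folding backend could replace this
behind the same contract). Watson–Crick pairs score 1, G·U wobble scores
½ (at full weight, chance pairing at 6/16 per rung builds spurious
stems); an internal 1×1 mismatch costs 1, a bulge of up to 3 nt costs 2,
at most 2 defects per stem; and after any defect the extension must
re-anchor with 4 consecutive Watson–Crick pairs before the stem may grow —
without this rule stems wander into chance complementarity in random
flanks. Calls are gated on the defect-penalized score (Ku ≥ 8, Est1 ≥ 10
with pairing fraction ≥ 0.6, TWJ flanks ≥ 6), not raw pair counts.

Ku requires `GCTA` in the loop within 600 nt upstream of the template —
no `GCTA` in the window means no Ku call, the logic used to classify a
species as Ku-less. The TWJ surrogate is an `AATA` flanked within 120 nt
by two hairpins; a lone `AATA` without flanking structure is reported as
"sequence-only" with score 0. When a homologous reference annotation is
available, its proportional Est1/TWJ positions (fractions of the
template→Sm span) and TWJ width bias the structural search — the
homology-guided analogue of anchoring covariance models on known loci —
which is what suppresses rare large misassignments to chance structure.

A candidate is credible iff it has an Sm motif or a *verified* template
(3'-end repetition present); unverified periodic windows alone occur by
chance in random sequence and are not evidence. Transcript order
KU < TEMPLATE < EST1 < TWJ < SM1 is enforced by dropping the
lowest-scoring violator. The 5' end is approximate by construction
(200 nt upstream of the first feature, flagged `approximate_5p`); it is
never used in scoring.

## Boundary refinement and contamination flags

Refinement aligns the candidate to the nearest known TER globally with
free end gaps (Biopython's aligner with terminal gap scores of 0), trims
to the aligned core ± 25 nt, and repeats until the interval moves < 10 nt
or 5 iterations; the final estimate is the aligned core itself. Scores
below a floor of 100 (about what a ~35 nt perfect match earns; random
~1 kb pairs reach ~20–30) leave the input interval unchanged and mark the
trace unconverged. A query edge is flagged as contaminated when hits from
≥ 2 genomes are confined to that edge's 100 nt window and overlap
annotated coding genes — the signature of a query that swallowed a
neighboring coding fragment.

## The survey

The survey walks outward from the seeded species: it always processes
next the unannotated genome closest (by guide-tree distance) to an
annotated one, projects the candidate from that relative, orients it,
refines boundaries against the relative's TER (keeping a 60 nt pad around
the refined core so feature edges survive), annotates, and — if credible —
promotes the new annotation into the reference set. Telomere units come
from a catalog if given, else from chromosome-end inference, else from the
nearest species with a known unit. Finally all annotated TER sequences
are aligned pairwise, filtered, and assembled into the homology graph
(seed species labelled `literature`, new ones `identified`). The whole
run is deterministic for a fixed configuration.

Recovery scoring counts a locus as found at reciprocal overlap ≥ 0.5 on
the same contig; a feature is recovered when both boundaries lie within
10 nt of truth, and coordinate error averages over recovered features.

## Problem sizes used in the tests

The recovery suite uses 6-leaf clades with one 30 kb contig per genome,
10 replicate seeds per condition, and a divergence grid at 1×, 3×, 8× and
20× the default rates (all rates scaled together; indel rate capped at
0.3). These sizes keep a full run of the suite within a couple of
minutes while leaving each grid point with 50 scored loci. At 1× the
measured locus recall is 1.0 with sub-5 nt mean feature error; recall
declines monotonically along the grid and the homology graph loses edges,
reproducing the homology-decay phenomenon that motivates synteny-guided
search in the first place.

## Known limitations

* No genome rearrangements, realistic coding content, or RNA-structure-
  aware evolution in the simulator; synteny-breakage behaviour is probed
  by explicit anchor translocation in the tests instead.
* Structural detection is pattern/complementarity-based, not
  thermodynamic or covariation-aware; pseudoknots, the template boundary
  element and the ARC are out of scope (no operational sequence rule).
* Ungapped Karlin–Altschul statistics stand in for gapped E-values.
* The 5' end is approximate by design; only the 3'-end rule is exact.
* The generator's unambiguity contract (above) means planted-truth tests
  bound divergence-driven error, not chance-structure error on real
  genomes.
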