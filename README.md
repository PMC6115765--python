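# tersurvey

Synteny-guided homology search and annotation of telomerase RNA (TER)
genes in budding-yeast genomes.

## The problem

The RNA subunit of telomerase carries the template that the telomerase
reverse transcriptase copies into telomeric DNA. In Saccharomycetes these
RNAs are long (typically > 1000 nt), evolve extremely fast at the sequence
level, vary widely in length, and are structurally plastic — which is why
they remain unannotated in most budding-yeast genomes: direct BLAST or
covariance-model searches find homologs only between very close relatives.
What does survive is context and a handful of short functional islands:

* TER loci sit between protein-coding genes whose orthologs are syntenic
  in close relatives, so orthologous flanking genes delimit a candidate
  interval of a few kb instead of a whole genome;
* the **template** is the reverse complement of the telomeric repeat
  (fungal consensus `TTAGGG`) and typically repeats a few of its first
  nucleotides at its end — a built-in verification signature;
* the **Sm binding motif** `AATTTTTGG` near the 3' end is almost perfectly
  conserved, and the mature 3' end lies ~10 nt downstream of it;
* a **Ku-binding hairpin** (conserved `GCUA` in its loop), an
  **Est1-binding hairpin** (P3-like), and a **three-way junction** region
  (conserved `AATA`) complete the recognizable feature set.

`tersurvey` implements this search as a reusable, tested pipeline for
people who annotate non-coding RNAs in fungal (or similarly structured)
genomes: candidate delimitation by ortholog-anchored synteny projection, a
seed-and-extend local aligner with Karlin–Altschul E-values and the
standard hit filter (E < 0.1, alignment ≥ 25 nt, identity ≥ 60%, telomeric
regions masked), telomere-repeat and template localization, motif/hairpin
feature annotation, iterative boundary refinement against the nearest
known TER by free-end-gap global alignment, and a clade-wide survey that
expands its query set as it annotates — reporting an annotation table, a
homology graph whose edges are weighted by the inverse alignment length,
and recovery metrics. A synthetic-clade simulator with planted TER loci
(Jukes–Cantor substitutions plus indels, conserved islands inside rapidly
diverging background) makes every stage testable without downloading
genomes.

The package also ships a transcribed annotation table of conserved TER
substructures in 46 Saccharomycetaceae species (loaded by
`load_ter_table()`), 30 of which lack prior literature coordinates.

## Worked example

Simulate a six-species clade with one planted TER per genome, survey it
seeded with a single known annotation, and score recovery against the
generator's truth:

```bash
tersurvey simulate --seed 1 --out sim1
# ... write sim1/known.tsv with the sp1 row of sim1/truth.tsv, then:
tersurvey survey --config survey.yml --out out1
# annotated 6 species (6 newly identified); outputs in out1
tersurvey score --pred out1/annotations.tsv --truth sim1/truth.tsv
```

which prints

```json
{"locus_recall": 1.0, "false_loci": 0,
 "per_feature_recall": {"ku": 1.0, "template": 1.0, "est1": 1.0, "twj": 1.0, "sm1": 1.0},
 "per_feature_mean_error": {"ku": 1.33, "template": 0.33, "est1": 2.25, "twj": 0.67, "sm1": 0.0},
 "n_truth": 6}
```

— all six planted loci found (`locus_recall` is the fraction of truth loci
matched with reciprocal overlap ≥ 0.5), every conserved substructure
recovered, with mean boundary errors of 0–2 nt. `out1/annotations.tsv` is
in the same schema as the packaged survey table:

```
species  accession  strand  ter        ku         template   est1       twj        sm1        coord_citation
sp1      sp1_c0     pos     4791-5590  4821-4848  5059-5070  5237-5266  5422-5477  5572-5580  false
```

and `out1/graph_edges.tsv` holds the homology graph (for this closely
related clade it is a complete graph on 6 nodes; an edge like
`sp1  sp2  0.00124  807` means the best filtered alignment between those
two TERs spans 807 columns, giving edge weight 1/807). As simulated
divergence grows, recall falls and the graph sheds edges — the same decay
that limits sequence-based homology search on real yeast TERs.

In Python the same objects are available directly:

```python
from tersurvey import load_ter_table, summarize_table
s = summarize_table(load_ter_table())
s.n_species_with_ter, s.n_novel   # (46, 30)
s.per_feature_counts              # {'ku': 28, 'template': 33, 'est1': 37, 'twj': 20, 'sm1': 42}
```

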