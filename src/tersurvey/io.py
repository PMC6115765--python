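"""Genome and annotation I/O plus the packaged Saccharomycetaceae TER table.

The survey's internal containers are deliberately small: a :class:`Genome`
bundles contig sequences with gene annotations and ortholog labels, and a
:class:`TerAnnotation` is one row of the telomerase-RNA (TER) annotation
table — forward-strand coordinates for the locus and for each conserved
substructure (Ku hairpin, template, Est1 site, three-way junction, Sm site).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .intervals import Interval, contains, to_bed

FEATURE_KINDS = ("ku", "template", "est1", "twj", "sm1")

TER_TABLE_COLUMNS = (
    "species",
    "accession",
    "strand",
    "ter",
    *FEATURE_KINDS,
    "coord_citation",
)

_INTERVAL_RE = re.compile(r"^\s*(\d[\d,]*)\s*[-–]\s*(\d[\d,]*)\s*$")


@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene on the forward strand coordinate system."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    ortholog_group: str | None = None

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval {self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass
class Genome:
    species_id: str
    contigs: dict[str, str]
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid} is empty")
        for g in self.genes:
            if g.contig_id not in self.contigs:
                raise ValueError(
                    f"gene {g.gene_id} references unknown contig {g.contig_id}"
                )
            if g.end > len(self.contigs[g.contig_id]):
                raise ValueError(
                    f"gene {g.gene_id} interval {g.start}-{g.end} exceeds "
                    f"contig {g.contig_id} length {len(self.contigs[g.contig_id])}"
                )

    def genes_on(self, contig_id: str) -> list[GeneAnnotation]:
        return sorted(
            (g for g in self.genes if g.contig_id == contig_id),
            key=lambda g: g.start,
        )


@dataclass(frozen=True)
class TerAnnotation:
    """One annotated TER locus.

    All intervals are 1-based inclusive forward-strand coordinates
    regardless of the transcribed strand; feature intervals nest inside
    ``ter``. ``coord_citation`` is True iff the locus coordinates were
    reported in prior literature.
    """

    species: str
    accession: str
    strand: str  # "pos" | "neg"
    ter: Interval
    ku: Interval | None = None
    template: Interval | None = None
    est1: Interval | None = None
    twj: Interval | None = None
    sm1: Interval | None = None
    coord_citation: bool = False
    flags: frozenset = field(default_factory=frozenset, compare=False)

    def __post_init__(self):
        if self.strand not in ("pos", "neg"):
            raise ValueError(f"{self.species}: strand must be pos or neg")
        if self.ter[0] > self.ter[1]:
            raise ValueError(f"{self.species}: invalid ter interval {self.ter}")
        for kind in FEATURE_KINDS:
            iv = getattr(self, kind)
            if iv is not None and not contains(self.ter, iv):
                raise ValueError(
                    f"{self.species}: feature {kind} {iv} not nested in ter {self.ter}"
                )

    def features(self) -> dict[str, Interval | None]:
        return {kind: getattr(self, kind) for kind in FEATURE_KINDS}


@dataclass(frozen=True)
class SurveySummary:
    n_species_with_ter: int
    n_novel: int
    per_feature_counts: dict

    def __post_init__(self):
        if self.n_novel > self.n_species_with_ter:
            raise ValueError("n_novel cannot exceed n_species_with_ter")


def packaged_ter_table() -> Path:
    """Path to the packaged Saccharomycetaceae TER annotation table."""
    return Path(
        resources.files("tersurvey.data") / "ter_table_saccharomycetaceae.tsv"
    )


def load_genome(
    fasta_path,
    gff3_path,
    ortholog_tsv_path=None,
    species_id: str | None = None,
) -> Genome:
    """Load contigs (FASTA), genes (GFF3) and ortholog labels (TSV).

    The ortholog TSV has two columns, gene_id and ortholog_group. Gene ids
    in the TSV that do not occur in the GFF3 are ignored with a warning; a
    gene record referencing a contig absent from the FASTA is a hard error.
    """
    import gffutils

    fasta_path = Path(fasta_path)
    if species_id is None:
        species_id = fasta_path.stem
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }

    ortho: dict[str, str] = {}
    if ortholog_tsv_path is not None:
        df = pd.read_csv(
            ortholog_tsv_path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
        ortho = dict(zip(df["gene_id"], df["ortholog_group"]))

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.seqid not in contigs:
            raise ValueError(
                f"gene {gene_id} references contig {feat.seqid} absent from FASTA"
            )
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                ortholog_group=ortho.get(gene_id),
            )
        )
    known = {g.gene_id for g in genes}
    unknown = [gid for gid in ortho if gid not in known]
    if unknown:
        warnings.warn(
            f"{len(unknown)} ortholog-table gene ids not in {gff3_path} "
            f"(e.g. {unknown[:3]}); ignored",
            stacklevel=2,
        )
    return Genome(species_id=species_id, contigs=contigs, genes=genes)


def _parse_interval(cell: str, row_no: int) -> Interval | None:
    if cell is None or cell.strip() == "":
        return None
    m = _INTERVAL_RE.match(cell)
    if not m:
        raise ValueError(f"row {row_no}: malformed interval {cell!r}")
    start = int(m.group(1).replace(",", ""))
    end = int(m.group(2).replace(",", ""))
    return (start, end)


def load_ter_table(tsv_path=None) -> list[TerAnnotation]:
    """Read a TER annotation table; defaults to the packaged survey table."""
    if tsv_path is None:
        tsv_path = packaged_ter_table()
    df = pd.read_csv(
        tsv_path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    missing = set(TER_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TER table missing columns: {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        row_no = idx + 2  # header is row 1
        kwargs = {
            kind: _parse_interval(row[kind], row_no) for kind in FEATURE_KINDS
        }
        ter = _parse_interval(row["ter"], row_no)
        if ter is None:
            raise ValueError(f"row {row_no}: missing ter interval")
        records.append(
            TerAnnotation(
                species=row["species"],
                accession=row["accession"],
                strand=row["strand"],
                ter=ter,
                coord_citation=row["coord_citation"].strip().lower()
                in ("true", "1", "yes"),
                **kwargs,
            )
        )
    return records


def summarize_table(records: list[TerAnnotation]) -> SurveySummary:
    counts = {kind: 0 for kind in FEATURE_KINDS}
    for rec in records:
        for kind, iv in rec.features().items():
            if iv is not None:
                counts[kind] += 1
    return SurveySummary(
        n_species_with_ter=len(records),
        n_novel=sum(not r.coord_citation for r in records),
        per_feature_counts=counts,
    )


def _interval_str(iv: Interval | None) -> str:
    return "" if iv is None else f"{iv[0]}-{iv[1]}"


def write_annotations(records: list[TerAnnotation], path, fmt: str = "TSV") -> None:
    """Write annotations as TSV (table schema), GFF3 or BED.

    TSV round-trips losslessly through :func:`load_ter_table`. BED output
    converts to 0-based half-open coordinates; one line per locus plus one
    per present feature.
    """
    fmt = fmt.upper()
    path = Path(path)
    if fmt == "TSV":
        rows = []
        for r in records:
            row = {
                "species": r.species,
                "accession": r.accession,
                "strand": r.strand,
                "ter": _interval_str(r.ter),
                "coord_citation": "true" if r.coord_citation else "false",
            }
            row.update({k: _interval_str(iv) for k, iv in r.features().items()})
            rows.append(row)
        pd.DataFrame(rows, columns=TER_TABLE_COLUMNS).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "GFF3":
        strand_map = {"pos": "+", "neg": "-"}
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, r in enumerate(records):
                gid = f"TER{i + 1:03d}"
                fh.write(
                    "\t".join(
                        [
                            r.accession,
                            "tersurvey",
                            "ncRNA_gene",
                            str(r.ter[0]),
                            str(r.ter[1]),
                            ".",
                            strand_map[r.strand],
                            ".",
                            f"ID={gid};Name=TER;species={r.species}",
                        ]
                    )
                    + "\n"
                )
                for kind, iv in r.features().items():
                    if iv is None:
                        continue
                    fh.write(
                        "\t".join(
                            [
                                r.accession,
                                "tersurvey",
                                "sequence_feature",
                                str(iv[0]),
                                str(iv[1]),
                                ".",
                                strand_map[r.strand],
                                ".",
                                f"ID={gid}.{kind};Parent={gid};feature={kind}",
                            ]
                        )
                        + "\n"
                    )
    elif fmt == "BED":
        strand_map = {"pos": "+", "neg": "-"}
        with open(path, "w") as fh:
            for r in records:
                b0, b1 = to_bed(r.ter)
                fh.write(
                    f"{r.accession}\t{b0}\t{b1}\t{r.species}:TER\t0\t"
                    f"{strand_map[r.strand]}\n"
                )
                for kind, iv in r.features().items():
                    if iv is None:
                        continue
                    b0, b1 = to_bed(iv)
                    fh.write(
                        f"{r.accession}\t{b0}\t{b1}\t{r.species}:{kind}\t0\t"
                        f"{strand_map[r.strand]}\n"
                    )
    else:
        raise ValueError(f"unknown annotation format: {fmt}")
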