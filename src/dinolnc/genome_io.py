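"""Genome, annotation and count-table I/O.

Internal coordinate convention: 0-based, half-open intervals on the
plus-strand genome axis; strand is stored separately.  GFF3 input/output
(1-based, inclusive) is converted at the boundary.  Promoters are defined
as the region immediately upstream (strand-aware) of a gene's first CDS
base, up to ``length_nt`` (default 1 kb), truncated at scaffold edges.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from ._util import VALID_ALPHABET, check_alphabet, revcomp, warn

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# Genome


@dataclass
class Genome:
    """A set of scaffold sequences (alphabet A, C, G, T, N)."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("genome has no scaffolds")
        for name, seq in self.records.items():
            if not name:
                raise ValueError("empty scaffold id")
            if len(seq) < 1:
                raise ValueError(f"scaffold {name!r} is empty")
            check_alphabet(seq, f"scaffold {name!r}")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate scaffold id {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
        return cls(records)

    def to_fasta(self, path: str | os.PathLike) -> None:
        recs = [SeqRecord(Seq(s), id=n, description="") for n, s in self.records.items()]
        SeqIO.write(recs, str(path), "fasta")

    def __getitem__(self, scaffold: str) -> str:
        return self.records[scaffold]

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.records

    def slice(self, scaffold: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.records[scaffold][start:end]
        return seq if strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# Gene models and annotation


def _check_sorted_disjoint(ivs: tuple[Interval, ...], what: str, owner: str) -> None:
    for (s, e) in ivs:
        if not (0 <= s < e):
            raise ValueError(f"{what} interval ({s},{e}) of {owner} is invalid")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"{what} intervals of {owner} overlap or are unsorted")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        object.__setattr__(self, "exons", tuple(sorted(tuple(x) for x in self.exons)))
        object.__setattr__(self, "cds", tuple(sorted(tuple(x) for x in self.cds)))
        _check_sorted_disjoint(self.exons, "exon", self.gene_id)
        _check_sorted_disjoint(self.cds, "CDS", self.gene_id)
        for (cs, ce) in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"gene {self.gene_id}: CDS ({cs},{ce}) outside exons")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def spliced_sequence(self, genome: Genome) -> str:
        seq = "".join(genome[self.scaffold][s:e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1


class Annotation:
    """Indexed collection of gene models with span-overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self.genes[g.gene_id] = g
            s, e = g.span
            self._trees.setdefault(g.scaffold, IntervalTree()).addi(s, e, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def overlapping(self, scaffold: str, start: int, end: int) -> list[GeneModel]:
        """All genes whose span intersects [start, end) by >= 1 bp."""
        tree = self._trees.get(scaffold)
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        return sorted((self.genes[h.data] for h in hits), key=lambda g: (g.start, g.gene_id))

    def on_scaffold(self, scaffold: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes.values() if g.scaffold == scaffold),
            key=lambda g: (g.start, g.gene_id),
        )

    def write_gff3(self, path: str | os.PathLike) -> None:
        write_gff3(self, path)


def parse_annotation(gff3_path: str | os.PathLike, genome: Genome | None = None) -> Annotation:
    """Parse a GFF3 file with gene/mRNA/exon/CDS features into an Annotation.

    Coordinates are converted from 1-based inclusive to the internal 0-based
    half-open convention.  Malformed lines raise with their line number; an
    exon outside its gene's span raises naming the gene.
    """
    path = str(gff3_path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line (expected 9 fields)")

    try:
        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True, force=True
        )
    except gffutils.exceptions.EmptyInputError:
        return Annotation([])
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        exons = sorted((f.start - 1, f.end) for f in db.children(gf, featuretype="exon"))
        cds = sorted((f.start - 1, f.end) for f in db.children(gf, featuretype="CDS"))
        if not exons:
            exons = [(gf.start - 1, gf.end)]
        gspan = (gf.start - 1, gf.end)
        for s, e in exons:
            if s < gspan[0] or e > gspan[1]:
                raise ValueError(
                    f"gene {gf.id}: exon ({s},{e}) outside gene span {gspan}"
                )
        if genome is not None:
            if gf.seqid not in genome:
                raise ValueError(f"gene {gf.id}: unknown scaffold {gf.seqid!r}")
            if gspan[1] > len(genome[gf.seqid]):
                raise ValueError(f"gene {gf.id}: span exceeds scaffold length")
        genes.append(
            GeneModel(gene_id=gf.id, scaffold=gf.seqid, strand=gf.strand,
                      exons=tuple(exons), cds=tuple(cds))
        )
    return Annotation(genes)


def write_gff3(annotation: Annotation, path: str | os.PathLike) -> None:
    """Write an Annotation in canonical GFF3 (gene/mRNA/exon/CDS, sorted)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        order = sorted(annotation, key=lambda g: (g.scaffold, g.start, g.gene_id))
        for g in order:
            s, e = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.scaffold}\tdinolnc\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            mid = f"{g.gene_id}.mRNA"
            fh.write(
                f"{g.scaffold}\tdinolnc\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tdinolnc\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )
            for i, (cs, ce) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.scaffold}\tdinolnc\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                    f"ID={mid}.cds{i};Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# Promoters


@dataclass(frozen=True)
class PromoterRegion:
    """Strand-oriented region immediately upstream of a gene's first CDS base."""

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_promoters(
    annotation: Annotation,
    genome: Genome,
    length_nt: int = 1000,
    min_length: int = 20,
) -> list[PromoterRegion]:
    """Promoter = up to ``length_nt`` immediately upstream of the CDS start.

    For + strand genes the interval is [cds_start - length, cds_start); for
    - strand genes [cds_end, cds_end + length) with the sequence
    reverse-complemented.  Regions are truncated at scaffold edges; regions
    shorter than ``min_length`` after truncation are dropped (too short to
    host any triplex target site).  Genes without CDS are skipped.
    """
    out: list[PromoterRegion] = []
    skipped = 0
    for g in sorted(annotation, key=lambda g: (g.scaffold, g.start, g.gene_id)):
        if not g.cds:
            skipped += 1
            continue
        scaf_len = len(genome[g.scaffold])
        if g.strand == "+":
            cds_start = g.cds[0][0]
            start, end = max(0, cds_start - length_nt), cds_start
        else:
            cds_end = g.cds[-1][1]
            start, end = cds_end, min(scaf_len, cds_end + length_nt)
        if end - start < min_length:
            continue
        seq = genome.slice(g.scaffold, start, end, g.strand)
        out.append(PromoterRegion(g.gene_id, g.scaffold, g.strand, start, end, seq))
    if skipped:
        warn(f"extract_promoters: skipped {skipped} gene(s) without CDS")
    return out


def write_promoters_fasta(promoters: Iterable[PromoterRegion], path: str | os.PathLike) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.gene_id,
                  description=f"{p.scaffold}:{p.start}-{p.end}({p.strand})")
        for p in promoters
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Count matrices


@dataclass
class CountMatrix:
    """Integer feature x sample counts plus per-sample factor metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not all(pd.api.types.is_integer_dtype(t) for t in c.dtypes):
            raise ValueError("counts must be integers")
        if self.metadata.shape == (0, 0):
            self.metadata = pd.DataFrame(index=c.columns)
        missing = set(c.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        extra = set(self.metadata.index) - set(c.columns)
        if extra:
            raise ValueError(f"metadata samples absent from counts: {sorted(extra)}")
        self.metadata = self.metadata.loc[c.columns]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)


def load_count_table(
    tsv_path: str | os.PathLike, metadata_path: str | os.PathLike | None = None
) -> CountMatrix:
    counts = pd.read_csv(tsv_path, sep="\t", index_col=0)
    for col in counts.columns:
        vals = counts[col]
        if not pd.api.types.is_integer_dtype(vals):
            if pd.api.types.is_float_dtype(vals) and (vals % 1 == 0).all():
                counts[col] = vals.astype(int)
            else:
                raise ValueError(f"non-integer counts in sample {col!r}")
    meta = (
        pd.read_csv(metadata_path, sep="\t", index_col=0)
        if metadata_path is not None
        else pd.DataFrame(index=counts.columns)
    )
    return CountMatrix(counts, meta)


def write_count_table(
    cm: CountMatrix, tsv_path: str | os.PathLike, metadata_path: str | os.PathLike | None = None
) -> None:
    cm.counts.to_csv(tsv_path, sep="\t", index_label="feature_id")
    if metadata_path is not None:
        cm.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
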