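"""Readers and writers for the standard formats the pipeline speaks.

FASTA is accessed through :mod:`pyfaidx` (indexed, lazy), gene models
through :mod:`gffutils`, and BED6 / TSV tables through :mod:`pandas`.
Coordinate dialects follow the formats: BED is half-open 0-based,
GFF3 is 1-based closed.  All in-memory coordinates in this package are
half-open 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pyfaidx

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class GeneModel:
    """A protein-coding gene with one transcript, in 0-based half-open coords."""

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    utr5: tuple[int, int] | None  # genomic interval of the 5'UTR, or None
    cds_exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Annotated transcript start (most 5' base in transcript orientation)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def first_cds_exon(self) -> tuple[int, int] | None:
        if not self.cds_exons:
            return None
        exons = sorted(self.cds_exons)
        return exons[0] if self.strand == "+" else exons[-1]


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6 file into a DataFrame; raises on malformed lines.

    The error message carries the 1-based line number of the offending row.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BED fields, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end < start:
                raise ValueError(f"{path}: line {lineno}: end < start")
            if parts[5] not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: strand must be '+' or '-'")
            rows.append((parts[0], start, end, parts[3], parts[4], parts[5]))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLUMNS)


def read_fasta(path: str | os.PathLike) -> pyfaidx.Fasta:
    """Open an indexed FASTA for random access."""
    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def write_fasta(records: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch(genome, scaffold: str, start: int, end: int) -> str:
    """Slice ``[start, end)`` from a scaffold, N-padding out-of-range flanks.

    ``genome`` may be a ``pyfaidx.Fasta`` or a plain ``dict`` of strings.
    """
    if scaffold not in genome:
        raise KeyError(f"scaffold {scaffold!r} not present in genome")
    ref = genome[scaffold]
    length = len(ref)
    lo, hi = max(start, 0), min(end, length)
    core = str(ref[lo:hi]) if hi > lo else ""
    return "N" * (lo - start) + core.upper() + "N" * (end - hi)


def scaffold_lengths(genome) -> dict[str, int]:
    return {name: len(genome[name]) for name in genome.keys()}


def write_gff3(genes: list[GeneModel], path: str | os.PathLike, source: str = "promarch") -> None:
    """Write gene/mRNA/five_prime_UTR/CDS features (1-based closed coordinates)."""

    def row(scaf, ftype, start0, end0, strand, attrs, phase="."):
        return "\t".join(
            [scaf, source, ftype, str(start0 + 1), str(end0), ".", strand, phase, attrs]
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(row(g.scaffold, "gene", g.start, g.end, g.strand, f"ID={g.gene_id}") + "\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                row(g.scaffold, "mRNA", g.start, g.end, g.strand, f"ID={mrna_id};Parent={g.gene_id}")
                + "\n"
            )
            if g.utr5 is not None:
                fh.write(
                    row(g.scaffold, "five_prime_UTR", g.utr5[0], g.utr5[1], g.strand, f"Parent={mrna_id}")
                    + "\n"
                )
            for start, end in sorted(g.cds_exons):
                fh.write(
                    row(g.scaffold, "CDS", start, end, g.strand, f"Parent={mrna_id}", phase="0") + "\n"
                )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models back out of a GFF3 file (via gffutils, in memory)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        utr5 = None
        cds: list[tuple[int, int]] = []
        for child in db.children(gene.id, level=None):
            iv = (child.start - 1, child.end)  # back to 0-based half-open
            if child.featuretype == "five_prime_UTR":
                utr5 = iv
            elif child.featuretype == "CDS":
                cds.append(iv)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                scaffold=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                utr5=utr5,
                cds_exons=sorted(cds),
            )
        )
    return genes


def read_go_map(path: str | os.PathLike) -> pd.DataFrame:
    """Gene-to-GO annotations: two tab-separated columns, one pair per row."""
    return pd.read_csv(path, sep="\t", names=["gene_id", "go_term"], comment="#")


def write_go_map(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=["gene_id", "go_term"])
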