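"""Insertion-site I/O and the TA-dinucleotide genome model.

Sleeping Beauty (SB) transposons reintegrate at TA dinucleotides. The
pipeline's universal currency is the *insertion table*: a pandas DataFrame
with one row per sequenced insertion call and columns

    specimen_id  str   opaque specimen label
    chrom        str   chromosome name
    pos          int   1-based coordinate of the first base of the TA
    strand       str   '+' or '-', orientation of the integrated transposon
    read_count   int   sequencing read depth supporting the site

On disk the dialect is 6-column BED (chrom, start, end, name=specimen_id,
score=read_count, strand), 0-based half-open; internally coordinates are
1-based inclusive.

The genome model indexes every TA position per chromosome (overlapping
pairs counted: "TATA" has TA sites at 1 and 3) and records per-gene TA
counts, the target sizes of the statistical background used by the driver
analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "INSERTION_COLUMNS",
    "GenomeModel",
    "InsertionFormatError",
    "read_insertion_bed",
    "write_insertion_bed",
    "collapse_to_sites",
    "find_ta_sites",
    "build_genome_model",
    "genome_model_from_arrays",
    "read_gene_annotation",
    "assign_insertions_to_genes",
]

INSERTION_COLUMNS = ["specimen_id", "chrom", "pos", "strand", "read_count"]

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "gene_strand", "ta_count"]


class InsertionFormatError(ValueError):
    """Malformed insertion BED content (missing columns, bad values)."""


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "specimen_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "read_count": pd.Series(dtype=np.int64),
        }
    )


def read_insertion_bed(path: str | Path) -> pd.DataFrame:
    """Read the SB insertion BED dialect into an insertion table.

    Columns on disk: chrom, start (0-based), end, specimen_id, read_count,
    strand. ``pos`` is returned 1-based (= start + 1). Input order is
    preserved. Raises :class:`InsertionFormatError` naming the offending
    line for non-integer coordinates/read counts or invalid strands.
    """
    path = Path(path)
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise InsertionFormatError(
                    f"{path}:{lineno}: expected 6 columns "
                    "(chrom, start, end, specimen_id, read_count, strand), "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError:
                raise InsertionFormatError(
                    f"{path}:{lineno}: non-integer coordinate "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            try:
                read_count = int(score_s)
            except ValueError:
                raise InsertionFormatError(
                    f"{path}:{lineno}: non-integer read_count {score_s!r}"
                ) from None
            if strand not in ("+", "-"):
                raise InsertionFormatError(
                    f"{path}:{lineno}: invalid strand {strand!r} "
                    "(must be '+' or '-')"
                )
            if start < 0 or end <= start:
                raise InsertionFormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            if read_count < 0:
                raise InsertionFormatError(
                    f"{path}:{lineno}: negative read_count {read_count}"
                )
            rows.append((name, chrom, start + 1, strand, read_count))
    if not rows:
        return _empty_table()
    table = pd.DataFrame(rows, columns=INSERTION_COLUMNS)
    table["pos"] = table["pos"].astype(np.int64)
    table["read_count"] = table["read_count"].astype(np.int64)
    return table


def write_insertion_bed(table: pd.DataFrame, path: str | Path) -> None:
    """Write an insertion table as 6-column BED, sorted by (chrom, pos, specimen)."""
    out = table[INSERTION_COLUMNS].sort_values(
        ["chrom", "pos", "specimen_id"], kind="mergesort"
    )
    bed = pd.DataFrame(
        {
            "chrom": out["chrom"],
            "start": out["pos"] - 1,
            "end": out["pos"] + 1,
            "name": out["specimen_id"],
            "score": out["read_count"],
            "strand": out["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def collapse_to_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate calls to one record per (specimen, chrom, pos).

    Read counts are summed over duplicates. The strand of the collapsed
    record is the strand of the highest-read duplicate ('+' on ties).
    Idempotent; total read count is conserved.
    """
    if table.empty:
        return table.copy()

    def _strand(group: pd.DataFrame) -> str:
        best = group["read_count"].max()
        strands = set(group.loc[group["read_count"] == best, "strand"])
        return "+" if "+" in strands else "-"

    keys = ["specimen_id", "chrom", "pos"]
    grouped = table.groupby(keys, sort=False)
    counts = grouped["read_count"].sum()
    strands = grouped[["strand", "read_count"]].apply(_strand)
    out = counts.reset_index()
    out["strand"] = strands.values
    return out[INSERTION_COLUMNS].reset_index(drop=True)


def find_ta_sites(seq: str) -> np.ndarray:
    """1-based positions p with seq[p-1:p+1] == 'TA' (case-insensitive).

    Every position where the pair reads TA is counted, including positions
    that overlap a previous match ("TATA" -> [1, 3]).
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    hits = np.flatnonzero((arr[:-1] == b"T") & (arr[1:] == b"A"))
    return (hits + 1).astype(np.int64)


@dataclass
class GenomeModel:
    """Chromosome lengths, indexed TA sites, and gene footprints.

    ``genes`` holds one row per gene: gene_id, chrom, start, end (1-based
    inclusive), gene_strand, ta_count (TA sites within the footprint).
    """

    chrom_lengths: dict[str, int]
    ta_index: dict[str, np.ndarray]
    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS)
    )

    @property
    def total_ta(self) -> int:
        return int(sum(len(v) for v in self.ta_index.values()))

    def ta_count_in(self, chrom: str, start: int, end: int) -> int:
        """TA sites with position in [start, end] on ``chrom``."""
        idx = self.ta_index.get(chrom)
        if idx is None or idx.size == 0:
            return 0
        lo = np.searchsorted(idx, start, side="left")
        hi = np.searchsorted(idx, end, side="right")
        return int(hi - lo)

    def gene_trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees over gene footprints."""
        trees: dict[str, IntervalTree] = {}
        for row in self.genes.itertuples():
            trees.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end + 1, row.Index
            )
        return trees


_GFF_ID_RE = re.compile(r"(?:^|;)\s*(?:ID|Name|gene_id|gene_name)=([^;]+)")


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene footprints from BED (4+ cols) or GFF3.

    Returns a DataFrame with gene_id, chrom, start, end, gene_strand
    (1-based inclusive coordinates). GFF3 rows are filtered to type
    'gene' when present, otherwise all rows are used.
    """
    path = Path(path)
    genes = []
    is_gff = path.suffix.lower() in {".gff", ".gff3", ".gtf"}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if is_gff:
                chrom, _src, ftype, start, end, _score, strand = f[:7]
                attrs = f[8] if len(f) > 8 else ""
                m = _GFF_ID_RE.search(attrs)
                gene_id = m.group(1) if m else f"{chrom}:{start}-{end}"
                genes.append((gene_id, chrom, int(start), int(end), strand, ftype))
            else:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                gene_id = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
                strand = f[5] if len(f) > 5 else "+"
                genes.append((gene_id, chrom, start + 1, end, strand, "gene"))
    df = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "start", "end", "gene_strand", "ftype"]
    )
    if is_gff and (df["ftype"] == "gene").any():
        df = df[df["ftype"] == "gene"]
    return df.drop(columns="ftype").reset_index(drop=True)


def genome_model_from_arrays(
    sequences: dict[str, str],
    genes: pd.DataFrame | None = None,
    upstream_pad: int = 0,
    exclude_chroms: tuple[str, ...] = ("chrM", "MT"),
) -> GenomeModel:
    """Build a :class:`GenomeModel` from in-memory sequences and gene rows."""
    chrom_lengths = {
        c: len(s) for c, s in sequences.items() if c not in exclude_chroms
    }
    ta_index = {c: find_ta_sites(sequences[c]) for c in chrom_lengths}
    model = GenomeModel(chrom_lengths=chrom_lengths, ta_index=ta_index)
    if genes is None or len(genes) == 0:
        return model
    genes = genes.copy()
    unknown = set(genes["chrom"]) - set(chrom_lengths)
    if unknown:
        bad = genes.loc[genes["chrom"].isin(unknown), "gene_id"].iloc[0]
        raise ValueError(
            f"gene {bad!r} lies on a chromosome absent from the genome: "
            f"{sorted(unknown)}"
        )
    if upstream_pad:
        plus = genes["gene_strand"] == "+"
        genes.loc[plus, "start"] = (genes.loc[plus, "start"] - upstream_pad).clip(lower=1)
        genes.loc[~plus, "end"] = genes.loc[~plus, "end"] + upstream_pad
    genes["ta_count"] = [
        model.ta_count_in(r.chrom, r.start, r.end) for r in genes.itertuples()
    ]
    model.genes = genes[GENE_COLUMNS].reset_index(drop=True)
    return model


def build_genome_model(
    fasta: str | Path,
    annotation: str | Path | None = None,
    upstream_pad: int = 0,
    exclude_chroms: tuple[str, ...] = ("chrM", "MT"),
) -> GenomeModel:
    """Build the TA-site genome model from a FASTA and a gene BED/GFF."""
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
    }
    genes = read_gene_annotation(annotation) if annotation is not None else None
    return genome_model_from_arrays(
        sequences, genes, upstream_pad=upstream_pad, exclude_chroms=exclude_chroms
    )


def assign_insertions_to_genes(
    table: pd.DataFrame, model: GenomeModel
) -> pd.DataFrame:
    """Annotate insertions with gene, relative orientation, and position.

    Each insertion is matched against every overlapping gene footprint
    (one annotated row per gene; ``multi_hit`` flags insertions inside
    more than one gene). Intergenic insertions are kept with gene_id NA.

    relative_orientation is 'sense' when the transposon strand equals the
    gene strand, 'antisense' otherwise, 'intergenic' outside genes.
    relative_position is the fractional position along the gene measured
    from its transcription start (0 = 5' end of the gene).
    """
    trees = model.gene_trees()
    genes = model.genes
    out_rows = []
    for row in table.itertuples():
        tree = trees.get(row.chrom)
        hits = sorted(tree[row.pos]) if tree is not None else []
        if not hits:
            out_rows.append(
                (
                    row.specimen_id, row.chrom, row.pos, row.strand,
                    row.read_count, pd.NA, "intergenic", np.nan, False,
                )
            )
            continue
        multi = len(hits) > 1
        for iv in hits:
            g = genes.iloc[iv.data]
            orient = "sense" if row.strand == g.gene_strand else "antisense"
            span = g.end - g.start
            if span == 0:
                relpos = 0.0
            elif g.gene_strand == "+":
                relpos = (row.pos - g.start) / span
            else:
                relpos = (g.end - row.pos) / span
            out_rows.append(
                (
                    row.specimen_id, row.chrom, row.pos, row.strand,
                    row.read_count, g.gene_id, orient, float(relpos), multi,
                )
            )
    return pd.DataFrame(
        out_rows,
        columns=INSERTION_COLUMNS
        + ["gene_id", "relative_orientation", "relative_position", "multi_hit"],
    )
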