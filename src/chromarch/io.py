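"""Readers and writers for the package's plain-text interchange formats.

BED is 0-based half-open; TRASH-style array CSVs are 1-based inclusive on
disk and converted to 0-based half-open in memory.  Contact matrices
travel as a dense TSV plus a bin table.  All writers emit stable float
formatting and ``\\n`` newlines so identical analyses produce
byte-identical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ContactMatrix, MalformedInputError
from .muller import AlignmentHit

FLOAT_FORMAT = "%.8g"


def _write_df(df: pd.DataFrame, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n", **kwargs)


# --------------------------------------------------------------------- FASTA


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ----------------------------------------------------------------------- BED


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["element", "start", "end"] + (extra_cols or [])
    _write_df(df[cols], path, header=False)


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    names = ["element", "start", "end"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# ------------------------------------------------------------ TRASH-style CSV

TRASH_COLUMNS = [
    "start",
    "end",
    "width",
    "repeat_length",
    "consensus",
    "class",
    "strand",
    "scaffold",
]


def write_trash_csv(arrays: pd.DataFrame, path) -> None:
    """Write the array table with 1-based inclusive coordinates.

    ``scaffold`` holds the element name; extra columns (array_id, species,
    repeat_count) ride along after the standard eight.
    """
    out = arrays.copy()
    out["scaffold"] = out["element"]
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)  # half-open end == inclusive end
    extras = [c for c in ("array_id", "species", "repeat_count") if c in out.columns]
    out[TRASH_COLUMNS + extras].to_csv(
        path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


def read_trash_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRASH_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedInputError(f"array table misses columns {sorted(missing)}")
    df["element"] = df["scaffold"]
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    if "array_id" not in df.columns:
        df["array_id"] = [f"arr{i + 1:05d}" for i in range(len(df))]
    return df


# ------------------------------------------------------------ contact matrix


def write_contacts(matrix: ContactMatrix, prefix) -> None:
    prefix = Path(prefix)
    bins = matrix.bins.copy()
    if "bin_id" not in bins.columns:
        bins.insert(0, "bin_id", np.arange(len(bins)))
    _write_df(bins, prefix.with_suffix(".bins.tsv"))
    with open(prefix.with_suffix(".matrix.tsv"), "w", newline="\n") as fh:
        for row in matrix.counts:
            fh.write("\t".join(FLOAT_FORMAT % x for x in row) + "\n")


def read_contacts(prefix) -> ContactMatrix:
    prefix = Path(prefix)
    bins = pd.read_csv(prefix.with_suffix(".bins.tsv"), sep="\t")
    counts = np.loadtxt(prefix.with_suffix(".matrix.tsv"))
    return ContactMatrix(np.atleast_2d(counts), bins)


# -------------------------------------------------------------------- newick


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n")


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# --------------------------------------------------------------- gene orders


def write_gene_orders(orderset, path, midpoints: dict[str, int] | None = None) -> None:
    rows = []
    for sp in orderset.species:
        for el in orderset.elements:
            for rank, (gene, strand) in enumerate(orderset.orders[sp][el]):
                mid = midpoints.get(gene, -1) if midpoints else -1
                rows.append((sp, el, rank, gene, strand, mid))
    _write_df(
        pd.DataFrame(
            rows,
            columns=["species", "element", "rank", "gene_id", "strand", "midpoint"],
        ),
        path,
    )


def read_gene_orders(
    path,
) -> tuple[dict[str, dict[str, list[tuple[str, str]]]], dict[str, int]]:
    """Returns (orders, gene midpoint map; empty if midpoints were absent)."""
    df = pd.read_csv(path, sep="\t")
    orders: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for (sp, el), sub in df.groupby(["species", "element"], sort=False):
        sub = sub.sort_values("rank", kind="stable")
        orders.setdefault(sp, {})[el] = list(zip(sub["gene_id"], sub["strand"]))
    midpoints: dict[str, int] = {}
    if "midpoint" in df.columns:
        for gene, mid in zip(df["gene_id"], df["midpoint"]):
            if mid >= 0:
                midpoints[gene] = int(mid)
    return orders, midpoints


def write_ortholog_map(mapping: dict[str, str], path) -> None:
    _write_df(
        pd.DataFrame(sorted(mapping.items()), columns=["gene_a", "gene_b"]), path
    )


def read_ortholog_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------- alignment tables


def read_alignment_hits(path) -> list[AlignmentHit]:
    """Parse 12-column tabular nucleotide-alignment output (blastn -outfmt 6).

    Subject coordinates with start > end indicate a minus-strand hit.
    """
    names = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        sstart, send = int(row.sstart), int(row.send)
        strand = "+" if send >= sstart else "-"
        lo, hi = min(sstart, send), max(sstart, send)
        hits.append(
            AlignmentHit(
                scaffold_id=str(row.qseqid),
                ref_chrom=str(row.sseqid),
                scaffold_start=int(row.qstart) - 1,
                scaffold_end=int(row.qend),
                ref_start=lo - 1,
                ref_end=hi,
                aligned_length=int(row.length),
                strand=strand,
            )
        )
    return hits


def write_matrix_tsv(matrix: np.ndarray, path, labels: list[str] | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        if labels is not None:
            fh.write("\t".join(labels) + "\n")
        for row in np.atleast_2d(matrix):
            fh.write("\t".join(FLOAT_FORMAT % x for x in row) + "\n")
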