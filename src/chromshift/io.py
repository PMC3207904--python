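"""Readers and writers for every external representation the pipeline touches.

Coordinate conventions are fixed package-wide: 0-based half-open spans
(BED-native) on every input and output, never shifted.  A gene's TSS is the
strand-dependent 5' base of its span: ``start`` on the plus strand,
``end - 1`` on the minus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "strand"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line or cell."""


@dataclass
class MappedReadSet:
    """Strand-aware mapped read positions for one sample.

    ``total_mapped`` is the per-million denominator: the number of uniquely
    mapped reads in the library.  It may exceed the number of stored reads
    (the stored reads can be a genomic subset of the library) but must be
    positive.
    """

    sample_id: str
    reads: pd.DataFrame  # columns: chrom, start, end, strand
    total_mapped: int
    _fp_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.total_mapped <= 0:
            raise ValueError(f"total_mapped must be positive, got {self.total_mapped}")
        if len(self.reads) and not (self.reads["start"] < self.reads["end"]).all():
            raise ValueError("every read must satisfy start < end")

    def __len__(self) -> int:
        return len(self.reads)

    def five_prime(self, mode: str = "5prime") -> dict[str, np.ndarray]:
        """Sorted read anchor positions per chromosome.

        mode='5prime' anchors each read at its 5' mapped base (start on +,
        end-1 on -); mode='midpoint' at the fragment midpoint.
        """
        if mode not in ("5prime", "midpoint"):
            raise ValueError(f"unknown read-counting mode {mode!r}")
        if mode in self._fp_index:
            return self._fp_index[mode]
        out: dict[str, np.ndarray] = {}
        if len(self.reads):
            start = self.reads["start"].to_numpy(np.int64)
            end = self.reads["end"].to_numpy(np.int64)
            if mode == "5prime":
                minus = (self.reads["strand"] == "-").to_numpy()
                pos = np.where(minus, end - 1, start)
            else:
                pos = (start + end) // 2
            chroms = self.reads["chrom"].to_numpy()
            for c in pd.unique(chroms):
                out[str(c)] = np.sort(pos[chroms == c])
        self._fp_index[mode] = out
        return out


@dataclass
class GeneAnnotation:
    """Gene spans with one strand-defined TSS per gene."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end, strand, tss

    def __post_init__(self) -> None:
        g = self.genes
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if len(g) and not (g["start"] < g["end"]).all():
            raise ValueError("every gene must satisfy start < end")
        if "tss" not in g.columns:
            self.genes = g.assign(tss=compute_tss(g))

    def __len__(self) -> int:
        return len(self.genes)


def compute_tss(genes: pd.DataFrame) -> np.ndarray:
    start = genes["start"].to_numpy(np.int64)
    end = genes["end"].to_numpy(np.int64)
    return np.where(genes["strand"].to_numpy() == "-", end - 1, start)


@dataclass
class ExpressionMatrix:
    """Non-negative per-gene scores, one row per sample (samples x genes)."""

    scores: pd.DataFrame  # index: sample ids, columns: gene ids

    def __post_init__(self) -> None:
        if self.scores.isna().any().any():
            raise ValueError("expression matrix has missing cells")
        if (self.scores.to_numpy() < 0).any():
            raise ValueError("expression scores must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.scores.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# readers


def read_bed_reads(path, sample_id: str | None = None,
                   total_mapped: int | None = None) -> MappedReadSet:
    """Parse a BED3+ file of mapped reads (optional strand in column 6).

    '.' strand is stored as '+' (read strand is cosmetic for 5'-anchored
    counting of short single-end reads).  When ``total_mapped`` is absent it
    defaults to the number of records.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            strand = parts[5] if len(parts) >= 6 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            if strand == ".":
                strand = "+"
            rows.append((parts[0], start, end, strand))
    df = pd.DataFrame(rows, columns=READ_COLUMNS) if rows else pd.DataFrame(
        {c: pd.Series(dtype=t) for c, t in
         zip(READ_COLUMNS, [str, np.int64, np.int64, str])})
    if total_mapped is None:
        total_mapped = len(df)
    if sample_id is None:
        sample_id = str(path)
    return MappedReadSet(sample_id=sample_id, reads=df, total_mapped=int(total_mapped))


def read_gene_annotation(path) -> GeneAnnotation:
    """Parse a TSV of gene_id, chrom, start, end, strand (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts == GENE_COLUMNS:  # optional header
                continue
            if len(parts) < 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns")
            gid, chrom, s, e, strand = parts[:5]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            rows.append((gid, chrom, start, end, strand))
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    return GeneAnnotation(genes=df)


def read_expression_table(path) -> ExpressionMatrix:
    """Parse a TSV with a header row of sample ids and gene ids in column 1."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for sample in df.columns:
        col = pd.to_numeric(df[sample], errors="coerce")
        if col.isna().any():
            gene = col.index[col.isna()][0]
            raise ParseError(f"{path}: non-numeric score at gene {gene!r}, "
                             f"sample {sample!r}")
        if (col < 0).any():
            gene = col.index[col < 0][0]
            raise ParseError(f"{path}: negative score at gene {gene!r}, "
                             f"sample {sample!r}")
        numeric[sample] = col
    # stored genes-as-rows on disk; in memory samples are rows
    return ExpressionMatrix(scores=numeric.T)


# ---------------------------------------------------------------------------
# writers (deterministic row/column order)


def write_reads_bed(readset: MappedReadSet, path) -> None:
    df = readset.reads.sort_values(["chrom", "start", "end", "strand"],
                                   kind="mergesort")
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                     f"r{i}\t0\t{row.strand}\n")


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    df = annotation.genes.sort_values("gene_id", kind="mergesort")
    df[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    # genes as rows on disk, gene order sorted for determinism
    out = matrix.scores.T.sort_index()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_table(df: pd.DataFrame, path, sort_by: str | list[str] = "gene_id") -> None:
    """Write any result table as TSV with deterministic row order."""
    keys = [sort_by] if isinstance(sort_by, str) else list(sort_by)
    keys = [k for k in keys if k in df.columns]
    if keys:
        df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sites_bed(sites: pd.DataFrame, path) -> None:
    """Write called binding sites as BED6 with the summit encoded in the name.

    Name field: ``<site_id>|summit=<pos>|reads=<n>``; score column carries the
    summit-window RPM.
    """
    df = sites.sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            name = f"{row.site_id}|summit={row.summit}|reads={row.n_reads}"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t"
                     f"{row.score:.6g}\t+\n")


def read_sites_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected BED6")
            meta = dict(kv.split("=") for kv in parts[3].split("|")[1:])
            rows.append((parts[0], int(parts[1]), int(parts[2]),
                         parts[3].split("|")[0], int(meta["summit"]),
                         float(parts[4]), int(meta["reads"])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "site_id",
                                       "summit", "score", "n_reads"])


def write_profile(offsets: np.ndarray, values: np.ndarray, path) -> None:
    """Two-column offset/value text for TSS metaprofiles."""
    with open(path, "w") as fh:
        fh.write("offset\trpm\n")
        for o, v in zip(offsets, values):
            fh.write(f"{int(o)}\t{v:.10g}\n")


def read_profile(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["offset"].to_numpy(np.int64), df["rpm"].to_numpy(float)
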