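"""Readers and writers for the formats the pipeline consumes and emits.

Internal convention is BED-native throughout: 0-based half-open intervals.
GFF3 (1-based, end-inclusive) is converted on read and restored on write.

Formats: 10x-style fragments TSV, BED3/BED6, BEDPE, GFF3, FASTA, bedGraph,
JASPAR PFM text, and sparse triplet matrices with row/column name sidecars.
"""

from __future__ import annotations

import gzip

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse


class FormatError(ValueError):
    """Malformed input; message carries the 1-based line number."""


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- fragments

FRAGMENT_COLS = ["chrom", "start", "end", "barcode", "count"]


def read_fragments(path) -> pd.DataFrame:
    """Read a 10x-dialect fragments TSV (chrom, start, end, barcode, count)."""
    df = pd.read_csv(
        path, sep="\t", names=FRAGMENT_COLS, comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "barcode": str, "count": np.int64},
    )
    bad = df.index[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        raise FormatError(f"fragments: invalid interval at line {bad[0] + 1}")
    return df


def write_fragments(df: pd.DataFrame, path) -> None:
    df[FRAGMENT_COLS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------- BED / BEDPE

def read_bed(path, n_cols: int | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if n_cols is not None:
        df = df.iloc[:, :n_cols]
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise FormatError(f"BED: empty/negative interval at line {bad[0] + 1}")
    return df


def write_bed(df: pd.DataFrame, path, cols=("chrom", "start", "end")) -> None:
    use = [c for c in cols if c in df.columns]
    df[use].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> pd.DataFrame:
    names = ["chromA", "startA", "endA", "chromB", "startB", "endB", "name", "fdr"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bedpe(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------- GFF3

def read_gff3_genes(path) -> pd.DataFrame:
    """Extract gene features; 1-based inclusive → 0-based half-open."""
    rows = []
    with _open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"GFF3: expected 9 columns at line {ln}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            gene_id = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            rows.append((chrom, int(start) - 1, int(end), strand, gene_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    if len(df) and (df["start"] >= df["end"]).any():
        raise FormatError("GFF3: gene with non-positive length")
    return df


def write_gff3_genes(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in df.itertuples():
            fh.write(
                f"{r.chrom}\tcreevo\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\tID={r.gene_id}\n"
            )


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(chrom: str, values: np.ndarray, path, append: bool = False) -> None:
    """Run-length encode a per-base track."""
    values = np.asarray(values)
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [values.size]])
    with open(path, "a" if append else "w") as fh:
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------- JASPAR PFM

def read_jaspar_pfms(path) -> dict[str, np.ndarray]:
    """JASPAR text PFMs → {motif_id: 4×L count matrix (A,C,G,T rows)}."""
    out: dict[str, np.ndarray] = {}
    with _open(path) as fh:
        name = None
        rows: list[list[float]] = []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name and len(rows) == 4:
                    out[name] = np.array(rows)
                name = line[1:].split()[0]
                rows = []
            elif line:
                body = line
                for ch in "ACGT[]":
                    body = body.replace(ch, " ")
                rows.append([float(x) for x in body.split()])
        if name and len(rows) == 4:
            out[name] = np.array(rows)
    return out


def write_jaspar_pfms(pfms: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for name, m in pfms.items():
            fh.write(f">{name}\n")
            for base, row in zip("ACGT", np.asarray(m)):
                fh.write(f"{base}  [ " + "  ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------- sparse matrix

def write_sparse_matrix(mat, row_names, col_names, prefix) -> None:
    """Triplet TSV (row, col, value; 0-based indices) + name sidecars."""
    prefix = Path(prefix)
    coo = sparse.coo_matrix(mat)
    pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data}).to_csv(
        f"{prefix}.triplets.tsv", sep="\t", index=False
    )
    pd.Series(list(row_names)).to_csv(f"{prefix}.rows.tsv", index=False, header=False)
    pd.Series(list(col_names)).to_csv(f"{prefix}.cols.tsv", index=False, header=False)


def read_sparse_matrix(prefix):
    prefix = Path(prefix)
    trip = pd.read_csv(f"{prefix}.triplets.tsv", sep="\t")
    rows = pd.read_csv(f"{prefix}.rows.tsv", header=None)[0].tolist()
    cols = pd.read_csv(f"{prefix}.cols.tsv", header=None)[0].tolist()
    mat = sparse.coo_matrix(
        (trip["value"], (trip["row"], trip["col"])), shape=(len(rows), len(cols))
    ).tocsr()
    return mat, rows, cols
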