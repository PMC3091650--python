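"""Flat-file I/O: BED6 intervals, FASTA, mismatch tables.

Coordinates are 0-based half-open everywhere in memory and in BED files;
1-based coordinates appear only inside CT records and human-readable
reports.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

MISMATCH_COLUMNS = ["rna_id", "chrom", "pos", "strand", "ref", "alt", "tissue_tag"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (3-6 columns) into a DataFrame with BED6 columns."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS)
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df[df["end"] < df["start"]]
    if not bad.empty:
        raise ValueError(f"BED interval with end < start at row {bad.index[0]}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_mismatches(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tissue_tag": str})
    missing = set(MISMATCH_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"mismatch table missing columns: {sorted(missing)}")
    if "tissue_tag" not in df.columns:
        df["tissue_tag"] = ""
    return df


def write_mismatches(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sites_table(path) -> pd.DataFrame:
    """Read an annotated-sites TSV, preserving the ``n/a`` opNuc sentinel
    (which pandas would otherwise turn into NaN)."""
    return pd.read_csv(
        path, sep="\t", keep_default_na=False, na_values=[""], low_memory=False
    )


def write_fasta(records, path, width: int = 70) -> None:
    """Write (name, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a whole FASTA file into a name -> sequence dict."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                out[name] = "".join(chunks)
            name = line[1:].strip()
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        out[name] = "".join(chunks)
    return out
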