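"""TSV readers and writers for the tabular formats used across the package.

All tables are tab-separated UTF-8 with a header row and '.' decimals.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .quant import CountTable, ValidationError

CATALOG_COLUMNS = ["gene_id", "symbol", "protein_length_aa", "gene_length_nt"]


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a gene catalog (gene_id, symbol, protein_length_aa, gene_length_nt)."""
    cat = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
    missing = [c for c in CATALOG_COLUMNS if c not in cat.columns]
    if missing:
        raise ValidationError(f"catalog {path} missing columns {missing}")
    return cat.set_index("gene_id", drop=False)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog[CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_count_table(
    counts_path: str | Path,
    catalog: pd.DataFrame | str | Path,
    length_col: str = "protein_length_aa",
) -> CountTable:
    """Read a features × samples count TSV, taking lengths from a catalog.

    The first column of the count TSV is the feature identifier; remaining
    columns are samples.
    """
    if not isinstance(catalog, pd.DataFrame):
        catalog = read_catalog(catalog)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = catalog.set_index("gene_id")[length_col]
    return CountTable(counts=counts, lengths=lengths)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_detection(path: str | Path) -> set[str]:
    """Read a one-column detection TSV (header ``gene_id``) into a set."""
    col = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in col.columns:
        raise ValidationError(f"detection file {path} lacks a gene_id column")
    return set(col["gene_id"].dropna())

def write_detection(genes, path: str | Path) -> None:
    pd.DataFrame({"gene_id": sorted(genes)}).to_csv(path, sep="\t", index=False)


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column source→target identifier mapping table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"mapping file {path} needs two columns")
    src, tgt = df.columns[:2]
    pairs = df[[src, tgt]].dropna()
    if (pairs == "").any().any():
        raise ValidationError(f"mapping file {path} contains empty identifiers")
    return dict(zip(pairs[src], pairs[tgt]))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
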