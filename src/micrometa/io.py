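"""Reading and writing count tables and sample metadata.

The canonical on-disk form is a tab-delimited taxa x samples matrix whose
first column holds taxon identifiers and whose header row holds sample
identifiers. Lines starting with ``#`` are metadata comments (seed, parameters)
and are ignored on read. A sparse triplet form (taxon, sample, count — one row
per non-zero cell) is supported for large, mostly-empty tables.
"""

from __future__ import annotations

import pandas as pd


def _comment_header(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def read_count_table(path) -> pd.DataFrame:
    """Read a dense taxa x samples count table (TSV, ``#`` comments allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df = df.astype(int)
    if df.index.has_duplicates:
        raise ValueError("duplicate taxon identifiers in count table")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in count table")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts in count table")
    return df


def write_count_table(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a dense count table as TSV with optional ``#`` header metadata."""
    with open(path, "w") as fh:
        fh.write(_comment_header(meta))
        table.to_csv(fh, sep="\t", index_label="taxon_id")


def read_sparse_count_table(path) -> pd.DataFrame:
    """Read a sparse triplet table (taxon_id, sample_id, count) into dense form."""
    trip = pd.read_csv(path, sep="\t", comment="#", dtype={"count": int})
    dense = trip.pivot_table(index="taxon_id", columns="sample_id", values="count", fill_value=0)
    dense.columns.name = None
    return dense.astype(int)


def write_sparse_count_table(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write only the non-zero cells of a count table as a triplet TSV."""
    stacked = table.stack()
    nz = stacked[stacked > 0].rename("count").rename_axis(["taxon_id", "sample_id"]).reset_index()
    with open(path, "w") as fh:
        fh.write(_comment_header(meta))
        nz.to_csv(fh, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read a per-sample (or per-host) metadata table indexed by its first column."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_metadata(metadata: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(meta))
        metadata.to_csv(fh, sep="\t")


def validate_inputs(table: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Check that every sample in the count table has a metadata record."""
    missing = set(table.columns) - set(metadata.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}")
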