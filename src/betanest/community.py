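"""Count-table I/O, rarefaction and presence/absence conversion.

Count tables are taxa × samples DataFrames of nonnegative integers with
unique row (taxon) and column (sample) ids, written/read as tab-delimited
UTF-8 text whose first header cell is blank or ``#OTU ID``.  Incidence
matrices are samples × species boolean DataFrames.  Sample metadata holds
one row per sample with its block, dose level (g N m⁻²) and organism
group (plant | bacteria | fungi).

Rarefaction subsamples each sample's reads to a fixed common depth
without replacement (multivariate hypergeometric draw), the standard way
of equalising sequencing effort before incidence-based analyses; samples
shallower than the target depth are dropped with a logged warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_env_table",
    "validate_count_table",
    "validate_metadata",
    "rarefy",
    "to_incidence",
]

logger = logging.getLogger(__name__)

_HEADER_CELLS = {"", "#OTU ID", "#otu id", "taxon", "otu"}


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check ids are unique and all entries are nonnegative integers."""
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxa ids: {dups}")
    if table.columns.has_duplicates:
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    arr = table.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac, _ = np.modf(arr.astype(float))
        bad = np.argwhere(frac != 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-integer count at taxon {table.index[i]!r}, "
                f"sample {table.columns[j]!r}: {arr[i, j]!r}"
            )
    neg = np.argwhere(arr < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative count at taxon {table.index[i]!r}, "
            f"sample {table.columns[j]!r}: {arr[i, j]!r}"
        )
    return table.astype(np.int64)


def read_count_table(path, orientation: str = "taxa_by_sample") -> pd.DataFrame:
    """Read a TSV count table; returns a taxa × samples integer DataFrame.

    ``orientation`` states what the file rows are: ``"taxa_by_sample"``
    (rows are taxa, the written default) or ``"sample_by_taxa"`` (rows
    are samples; the table is transposed on read).
    """
    if orientation not in ("taxa_by_sample", "sample_by_taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=object, comment=None)
    df.index = df.index.astype(str)
    df.index.name = None
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
    if orientation == "sample_by_taxa":
        df = df.T
    return validate_count_table(df)


def write_count_table(table: pd.DataFrame, path) -> None:
    """Write a taxa × samples count table as TSV (header cell ``#OTU ID``)."""
    out = table.copy()
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns sample, block, n_level[, group]."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str, "block": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "block", "n_level"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample"].duplicated().any():
        dups = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    key_cols = ["block", "n_level"] + (["group"] if "group" in meta.columns else [])
    if meta.duplicated(subset=key_cols).any():
        raise ValueError(
            "more than one sample per (block, n_level"
            + (", group)" if "group" in meta.columns else ")")
        )
    return meta


def read_env_table(path) -> pd.DataFrame:
    """Read a per-sample environmental covariate TSV (sample + covariates)."""
    env = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in env.columns:
        raise ValueError("environmental table must have a 'sample' column")
    return env


def rarefy(table: pd.DataFrame, depth: int, seed=None) -> pd.DataFrame:
    """Rarefy each sample (column) to ``depth`` reads without replacement.

    Every retained sample's column sum equals ``depth`` exactly; samples
    with fewer total reads than ``depth`` are dropped with a logged
    warning naming them.  A sample whose total equals ``depth`` is
    returned unchanged (the draw is exhaustive).

    Parameters
    ----------
    table : taxa × samples integer DataFrame
    depth : target reads per sample, ≥ 1
    seed : int or numpy Generator, optional
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    table = validate_count_table(table)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    totals = table.sum(axis=0)
    shallow = totals.index[totals < depth].tolist()
    if shallow:
        logger.warning(
            "dropping %d sample(s) below rarefaction depth %d: %s",
            len(shallow), depth, ", ".join(map(str, shallow)),
        )
    kept = [s for s in table.columns if s not in set(shallow)]
    out = {}
    for s in kept:
        col = table[s].to_numpy()
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(out, index=table.index, dtype=np.int64)


def to_incidence(table: pd.DataFrame) -> pd.DataFrame:
    """Convert a taxa × samples count table to samples × species incidence.

    An entry is True iff the count is ≥ 1 (no minimum-abundance filter).
    """
    return (table.T > 0)
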