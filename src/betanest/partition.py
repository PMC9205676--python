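"""Additive partitioning of pairwise Sørensen dissimilarity.

Incidence-based β-diversity between two communities is measured by the
Sørensen dissimilarity

    βsor = (b + c) / (2a + b + c)

where ``a`` is the number of species shared by the two communities and
``b``, ``c`` are the numbers of species unique to each.  βsor decomposes
additively into a turnover (replacement) component, the Simpson
dissimilarity

    βsim = min(b, c) / (a + min(b, c))

and a nestedness-resultant component βnes = βsor − βsim.  βsim is
insensitive to richness differences: it is zero exactly when the poorer
community is a subset of the richer one, in which case all dissimilarity
is nestedness.  Both components are symmetric in the two communities.

This module computes the partition for single pairs, for all pairs of an
incidence matrix, and for the treatment-vs-ambient design of a blocked
dose-gradient experiment, and performs species-pool occupancy accounting
(species loss / colonisation) against the ambient species pool.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "PartitionResult",
    "EmptyPairError",
    "shared_unique_counts",
    "partition_pair",
    "partition_matrix",
    "treatment_vs_ambient",
    "species_pool_accounting",
]


class EmptyPairError(ValueError):
    """Both communities are empty: the Sørensen index is undefined (0/0)."""


class PartitionResult(NamedTuple):
    """Partition of one pairwise comparison.

    Attributes
    ----------
    a : int
        Number of shared species.
    b, c : int
        Numbers of species unique to the first / second community.
    beta_sor : float
        Total Sørensen dissimilarity, in [0, 1].
    beta_sim : float
        Turnover (Simpson) component, in [0, beta_sor].
    beta_nes : float
        Nestedness-resultant component, beta_sor − beta_sim.
    """

    a: int
    b: int
    c: int
    beta_sor: float
    beta_sim: float
    beta_nes: float


def _as_bool_vector(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"incidence vector must be 1-D, got shape {arr.shape}")
    return arr.astype(bool)


def shared_unique_counts(x, y) -> tuple[int, int, int]:
    """Return (a, b, c): shared, unique-to-x and unique-to-y species counts.

    ``x`` and ``y`` are boolean incidence vectors over the same species
    ordering.
    """
    xb = _as_bool_vector(x)
    yb = _as_bool_vector(y)
    if xb.shape != yb.shape:
        raise ValueError(
            f"incidence vectors differ in length: {xb.size} vs {yb.size}"
        )
    a = int(np.count_nonzero(xb & yb))
    b = int(np.count_nonzero(xb & ~yb))
    c = int(np.count_nonzero(~xb & yb))
    return a, b, c


def partition_from_counts(a: int, b: int, c: int) -> PartitionResult:
    """Partition dissimilarity from shared/unique counts directly."""
    if a < 0 or b < 0 or c < 0:
        raise ValueError("a, b, c must be nonnegative")
    if a + b + c == 0:
        raise EmptyPairError(
            "both communities are empty; Sørensen dissimilarity is undefined"
        )
    m = min(b, c)
    beta_sor = (b + c) / (2 * a + b + c)
    beta_sim = m / (a + m) if (a + m) > 0 else 0.0
    # a + min(b,c) == 0 only when a == 0 and min(b,c) == 0, i.e. one
    # community empty: pure nestedness, turnover 0.
    return PartitionResult(a, b, c, beta_sor, beta_sim, beta_sor - beta_sim)


def partition_pair(x, y) -> PartitionResult:
    """Partition the Sørensen dissimilarity between two incidence vectors."""
    a, b, c = shared_unique_counts(x, y)
    return partition_from_counts(a, b, c)


def partition_matrix(
    incidence: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs partition of a samples × species incidence matrix.

    Returns three symmetric zero-diagonal DataFrames (βsor, βsim, βnes)
    indexed by sample id.  Species present in no sample are ignored (they
    cannot contribute to a, b or c).

    Raises
    ------
    EmptyPairError
        If two samples both have empty communities.
    ValueError
        If fewer than 2 samples are given.
    """
    if incidence.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = incidence.to_numpy(dtype=bool).astype(np.int64)
    richness = X.sum(axis=1)
    if np.count_nonzero(richness == 0) >= 2:
        empty = list(incidence.index[richness == 0])
        raise EmptyPairError(f"multiple empty communities: {empty}")
    A = X @ X.T                       # shared counts
    B = richness[:, None] - A         # unique to row sample
    C = richness[None, :] - A         # unique to column sample
    M = np.minimum(B, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        sor = (B + C) / (2 * A + B + C)
        sim = np.where(A + M > 0, M / (A + M), 0.0)
    np.fill_diagonal(sor, 0.0)
    np.fill_diagonal(sim, 0.0)
    nes = sor - sim
    ids = incidence.index
    return (
        pd.DataFrame(sor, index=ids, columns=ids),
        pd.DataFrame(sim, index=ids, columns=ids),
        pd.DataFrame(nes, index=ids, columns=ids),
    )


def _check_meta(incidence: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "block", "n_level"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("sample", drop=False) if meta.index.name != "sample" else meta
    absent = [s for s in incidence.index if s not in meta.index]
    if absent:
        raise ValueError(f"samples without metadata: {absent}")
    return meta


def treatment_vs_ambient(
    incidence: pd.DataFrame,
    meta: pd.DataFrame,
    group: str | None = None,
    ambient_level: float = 0,
) -> pd.DataFrame:
    """Partition each treatment sample against its own block's ambient sample.

    For every (block, non-ambient level) pair the treatment community is
    compared with the ambient (dose ``ambient_level``) community of the
    same block, giving one row of (group, block, n_level, a, b, c,
    beta_sor, beta_sim, beta_nes).  With L dose levels and K blocks this
    yields (L − 1) × K rows per group.

    Raises
    ------
    ValueError
        If any block lacks an ambient sample.
    """
    meta = _check_meta(incidence, meta)
    meta = meta.loc[list(incidence.index)]
    if group is not None:
        meta = meta[meta["group"] == group]
    rows = []
    group_col = meta["group"] if "group" in meta.columns else pd.Series(
        "all", index=meta.index
    )
    for g in pd.unique(group_col):
        sub = meta[group_col == g]
        for block in pd.unique(sub["block"]):
            blk = sub[sub["block"] == block]
            amb = blk[blk["n_level"] == ambient_level]
            if len(amb) == 0:
                raise ValueError(f"block {block!r} has no ambient (level "
                                 f"{ambient_level}) sample for group {g!r}")
            if len(amb) > 1:
                raise ValueError(f"block {block!r} has multiple ambient samples")
            amb_vec = incidence.loc[amb["sample"].iloc[0]].to_numpy(bool)
            trt = blk[blk["n_level"] != ambient_level]
            for _, row in trt.iterrows():
                res = partition_pair(
                    incidence.loc[row["sample"]].to_numpy(bool), amb_vec
                )
                rows.append(
                    {
                        "group": g,
                        "block": block,
                        "n_level": row["n_level"],
                        "sample": row["sample"],
                        "a": res.a,
                        "b": res.b,
                        "c": res.c,
                        "beta_sor": res.beta_sor,
                        "beta_sim": res.beta_sim,
                        "beta_nes": res.beta_nes,
                    }
                )
    out = pd.DataFrame(rows)
    return out.sort_values(["group", "n_level", "block"]).reset_index(drop=True)


def species_pool_accounting(
    incidence: pd.DataFrame,
    meta: pd.DataFrame,
    group: str | None = None,
    ambient_level: float = 0,
) -> pd.DataFrame:
    """Occupancy accounting of pool species and colonisers per dose level.

    The local species pool is the union of species present in any ambient
    replicate (of the given group).  For each non-ambient level with r
    replicate plots the function counts, per occupancy class k = 1..r,

    * ``absent_in_k``   — pool species absent from exactly k replicates,
    * ``present_in_k``  — non-pool (new) species present in exactly k,

    plus ``species_loss`` (pool species absent from all r replicates) and
    ``new_species`` (non-pool species present in all r replicates).
    """
    meta = _check_meta(incidence, meta)
    meta = meta.loc[list(incidence.index)]
    if group is not None:
        meta = meta[meta["group"] == group]
    amb = meta[meta["n_level"] == ambient_level]
    if len(amb) == 0:
        raise ValueError("no ambient replicates present")
    X = incidence.astype(bool)
    pool = X.loc[amb["sample"]].any(axis=0)
    rows = []
    for level in sorted(pd.unique(meta["n_level"])):
        if level == ambient_level:
            continue
        reps = meta[meta["n_level"] == level]["sample"]
        if len(reps) == 0:
            raise ValueError(f"level {level} has zero replicates")
        sub = X.loc[reps]
        r = len(reps)
        present_counts = sub.sum(axis=0)
        absent_counts = r - present_counts
        row: dict = {"n_level": level, "n_replicates": r}
        for k in range(1, r + 1):
            row[f"absent_in_{k}"] = int(
                ((absent_counts == k) & pool).sum()
            )
            row[f"present_in_{k}"] = int(
                ((present_counts == k) & ~pool).sum()
            )
        row["species_loss"] = row[f"absent_in_{r}"]
        row["new_species"] = row[f"present_in_{r}"]
        rows.append(row)
    return pd.DataFrame(rows)
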