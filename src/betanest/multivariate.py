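"""Permutation tests and ordination on dissimilarity matrices.

Implements the incidence-distance toolkit used on Sørensen matrices:

* **PERMANOVA** — one-way permutational multivariate ANOVA.  With N
  samples in g groups, SS_total = (1/N)·Σ_{i<j} d²ᵢⱼ and
  SS_within = Σ_groups (1/n_g)·Σ_{i<j in g} d²ᵢⱼ; the pseudo-F is
  (SS_between/(g−1)) / (SS_within/(N−g)) and the p-value comes from free
  permutation of group labels (observed statistic included in the null
  set, so the smallest attainable p is 1/(n_perm + 1)).

* **PERMDISP** — homogeneity of multivariate dispersion.  Samples are
  embedded by principal-coordinates analysis keeping negative eigen-axes;
  each sample's distance to its group centroid is computed with the
  semi-metric correction d² = (real-axis distance)² − (imaginary-axis
  distance)², then a one-way ANOVA F on those distances is assessed by
  permuting the distances across groups.

* **PCoA** — classical scaling of the double-centred Gower matrix.
  Negative eigenvalues (expected for semi-metric indices like Sørensen)
  are reported, never silently dropped.

* **NMDS** — nonmetric multidimensional scaling minimising Kruskal
  stress-1, sqrt(Σ(d − d̂)² / Σ d²), where the disparities d̂ are the
  isotonic (monotone) regression of configuration distances on the rank
  order of the input dissimilarities (primary/weak treatment of ties).
  Optimisation is SMACOF (Guttman transform) from one PCoA start plus
  random restarts, exposed as a scikit-learn style estimator.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.isotonic import isotonic_regression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PermanovaResult",
    "PermdispResult",
    "PCoAResult",
    "NmdsResult",
    "permanova",
    "permdisp",
    "pcoa",
    "NMDS",
    "nmds",
]


def _check_distance_matrix(D) -> tuple[np.ndarray, list]:
    if isinstance(D, pd.DataFrame):
        ids = list(D.index)
        arr = D.to_numpy(dtype=float)
    else:
        arr = np.asarray(D, dtype=float)
        ids = list(range(arr.shape[0]))
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"distance matrix must be square, got {arr.shape}")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ValueError("distance matrix diagonal is not zero")
    return arr, ids


def _encode_groups(groups, n: int) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(list(groups))
    if labels.size != n:
        raise ValueError(f"{labels.size} group labels for {n} samples")
    uniq, codes = np.unique(labels, return_inverse=True)
    return codes, uniq


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    df_between: int
    df_within: int
    method: str = "free permutation"


@dataclass(frozen=True)
class PermdispResult:
    F: float
    p: float
    n_perm: int
    group_means: pd.Series          # mean distance-to-centroid per group
    distances: pd.Series            # per-sample distance to its centroid


@dataclass(frozen=True)
class PCoAResult:
    eigenvalues: np.ndarray         # all eigenvalues, descending
    coordinates: pd.DataFrame       # samples × positive eigen-axes
    neg_coordinates: pd.DataFrame   # samples × |negative| eigen-axes
    sample_ids: list = field(repr=False, default_factory=list)


@dataclass(frozen=True)
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool
    n_starts: int


def _distinct_assignments(codes: np.ndarray):
    """Yield every distinct assignment of the label multiset to samples.

    Enumerates positions group-by-group via combinations, so the count is
    the multinomial coefficient N! / Π n_g!, not N!.
    """
    n = len(codes)
    groups, counts = np.unique(codes, return_counts=True)

    def rec(positions: tuple, gi: int, current: np.ndarray):
        if gi == len(groups) - 1:
            out = current.copy()
            out[list(positions)] = groups[gi]
            yield out
            return
        for chosen in itertools.combinations(positions, counts[gi]):
            nxt = current.copy()
            nxt[list(chosen)] = groups[gi]
            remaining = tuple(p for p in positions if p not in set(chosen))
            yield from rec(remaining, gi + 1, nxt)

    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=codes.dtype))


def _batched_pseudo_f(D2: np.ndarray, codes: np.ndarray,
                      label_matrix: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of ``label_matrix`` (permuted group codes)."""
    N = D2.shape[0]
    g = codes.max() + 1
    ss_total = D2[np.triu_indices(N, 1)].sum() / N
    ss_within = np.zeros(label_matrix.shape[0])
    for grp in range(g):
        M = (label_matrix == grp).astype(float)      # (P, N)
        n_g = M.sum(axis=1)
        # sum of within-group squared distances (each pair counted twice)
        quad = np.einsum("pi,ij,pj->p", M, D2, M)
        ss_within += quad / (2.0 * n_g)
    ss_between = ss_total - ss_within
    df_b, df_w = g - 1, N - g
    return (ss_between / df_b) / (ss_within / df_w)


def permanova(
    D,
    groups,
    n_perm: int = 999,
    seed=None,
    strata=None,
    permutations: str = "random",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Parameters
    ----------
    D : square symmetric distance matrix (DataFrame or array)
    groups : one label per sample
    n_perm : number of label permutations (ignored for exact enumeration)
    seed : int or Generator for the permutation stream
    strata : optional per-sample stratum labels; labels are then permuted
        only within strata (e.g. within experimental blocks)
    permutations : ``"random"`` (Monte-Carlo) or ``"exact"`` (enumerate
        every distinct label assignment; only feasible for small N)
    """
    arr, _ = _check_distance_matrix(D)
    N = arr.shape[0]
    codes, uniq = _encode_groups(groups, N)
    g = len(uniq)
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if permutations not in ("random", "exact"):
        raise ValueError(f"unknown permutation scheme {permutations!r}")
    D2 = arr ** 2
    f_obs = float(_batched_pseudo_f(D2, codes, codes[None, :])[0])
    ss_total = D2[np.triu_indices(N, 1)].sum() / N
    # recompute R2 from the observed partition
    ss_within = 0.0
    for grp in range(g):
        idx = np.flatnonzero(codes == grp)
        ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    r2 = (ss_total - ss_within) / ss_total

    if permutations == "exact":
        if strata is not None:
            raise ValueError("exact enumeration does not support strata")
        perms = np.array(list(_distinct_assignments(codes)))
        f_perm = _batched_pseudo_f(D2, codes, perms)
        p = float(np.count_nonzero(f_perm >= f_obs - 1e-12) / len(perms))
        n_used = len(perms)
        method = "exact enumeration"
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perms = np.empty((n_perm, N), dtype=codes.dtype)
        if strata is None:
            for i in range(n_perm):
                perms[i] = rng.permutation(codes)
        else:
            strata = np.asarray(list(strata))
            if strata.size != N:
                raise ValueError("strata length mismatch")
            for i in range(n_perm):
                p_row = codes.copy()
                for s in np.unique(strata):
                    idx = np.flatnonzero(strata == s)
                    p_row[idx] = p_row[rng.permutation(idx)]
                perms[i] = p_row
        f_perm = _batched_pseudo_f(D2, codes, perms)
        p = float((1 + np.count_nonzero(f_perm >= f_obs - 1e-12)) / (1 + n_perm))
        n_used = n_perm
        method = "free permutation" if strata is None else "stratified permutation"
    return PermanovaResult(f_obs, float(r2), p, n_used, g - 1, N - g, method)


def pcoa(D) -> PCoAResult:
    """Principal-coordinates analysis (classical scaling).

    Double-centres the Gower matrix −½·J D² J and eigendecomposes it.
    Coordinates are returned separately for positive ("real") and
    negative ("imaginary") eigen-axes, each scaled by sqrt(|λ|); all
    eigenvalues are reported in descending order.
    """
    arr, ids = _check_distance_matrix(D)
    n = arr.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (arr ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(abs(eigvals).max(), 1.0)
    pos = eigvals > tol
    neg = eigvals < -tol
    pos_coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    neg_coords = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return PCoAResult(
        eigenvalues=eigvals,
        coordinates=pd.DataFrame(
            pos_coords, index=ids,
            columns=[f"PCo{i + 1}" for i in range(pos_coords.shape[1])],
        ),
        neg_coordinates=pd.DataFrame(
            neg_coords, index=ids,
            columns=[f"PCoNeg{i + 1}" for i in range(neg_coords.shape[1])],
        ),
        sample_ids=ids,
    )


def _distances_to_centroids(ord_res: PCoAResult, codes: np.ndarray) -> np.ndarray:
    """Per-sample distance to its group centroid with the semi-metric
    correction d² = d²_real − d²_imaginary (negative d² floored at 0)."""
    P = ord_res.coordinates.to_numpy()
    Q = ord_res.neg_coordinates.to_numpy()
    d2 = np.zeros(P.shape[0])
    for grp in np.unique(codes):
        idx = np.flatnonzero(codes == grp)
        cp = P[idx].mean(axis=0)
        d2[idx] = ((P[idx] - cp) ** 2).sum(axis=1)
        if Q.shape[1]:
            cq = Q[idx].mean(axis=0)
            d2[idx] -= ((Q[idx] - cq) ** 2).sum(axis=1)
    return np.sqrt(np.clip(d2, 0.0, None))


def _anova_f(values: np.ndarray, codes: np.ndarray) -> float:
    grand = values.mean()
    ss_b = ss_w = 0.0
    g = codes.max() + 1
    for grp in range(g):
        v = values[codes == grp]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    df_b, df_w = g - 1, len(values) - g
    if ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / df_b) / (ss_w / df_w)


def permdisp(D, groups, n_perm: int = 999, seed=None) -> PermdispResult:
    """Permutation test of homogeneity of multivariate dispersions.

    Tests equality of group mean distances-to-centroid in PCoA space by
    permuting the per-sample distances across groups.
    """
    arr, ids = _check_distance_matrix(D)
    codes, uniq = _encode_groups(groups, arr.shape[0])
    if len(uniq) < 2:
        raise ValueError("PERMDISP needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes == 1).any():
        warnings.warn(
            "group(s) of size 1 contribute no dispersion degrees of freedom",
            stacklevel=2,
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ord_res = pcoa(arr)
    dists = _distances_to_centroids(ord_res, codes)
    f_obs = _anova_f(dists, codes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(dists))
        if _anova_f(dists[perm], codes) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    dist_series = pd.Series(dists, index=ids, name="distance_to_centroid")
    group_means = pd.Series(
        {u: dists[codes == i].mean() for i, u in enumerate(uniq)},
        name="mean_distance",
    )
    return PermdispResult(float(f_obs), float(p), n_perm, group_means, dist_series)


# ---------------------------------------------------------------------------
# NMDS


def _stress1(dists: np.ndarray, disparities: np.ndarray) -> float:
    denom = (dists ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dists - disparities) ** 2).sum() / denom))


def _monotone_disparities(d_obs: np.ndarray, dists: np.ndarray) -> np.ndarray:
    # primary (weak) tie treatment: within blocks of tied observed
    # dissimilarities, order by current configuration distance so ties
    # impose no monotonicity constraint among themselves
    order = np.lexsort((dists, d_obs))
    fitted = isotonic_regression(dists[order])
    disp = np.empty_like(dists)
    disp[order] = fitted
    return disp


def _guttman_update(X: np.ndarray, dists_sq: np.ndarray,
                    disparities_sq: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dists_sq > 0, disparities_sq / dists_sq, 0.0)
    B = -ratio
    np.fill_diagonal(B, 0.0)
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ X) / n


class NMDS(BaseEstimator):
    """Nonmetric multidimensional scaling (Kruskal stress-1, SMACOF).

    Parameters
    ----------
    n_components : embedding dimension k (must satisfy k < N − 1)
    n_starts : random restarts in addition to the PCoA initialisation
    max_iter : maximum SMACOF iterations per start
    tol : stop when the stress decrease falls below this
    random_state : int or Generator seeding the random starts

    Attributes (after ``fit``)
    --------------------------
    embedding_ : (N, k) array, centred and rotated to principal axes
    stress_ : final Kruskal stress-1 of the best start
    converged_ : whether the best start reached ``tol`` within ``max_iter``
    n_iter_ : iterations used by the best start
    stress_history_ : per-iteration stress of the best start (non-increasing)
    """

    def __init__(self, n_components: int = 2, n_starts: int = 20,
                 max_iter: int = 300, tol: float = 1e-7, random_state=None):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _run_start(self, X0: np.ndarray, d_obs: np.ndarray):
        X = X0 - X0.mean(axis=0)
        dists = pdist(X)
        disp = _monotone_disparities(d_obs, dists)
        stress = _stress1(dists, disp)
        history = [stress]
        converged = False
        for _ in range(self.max_iter):
            Xn = _guttman_update(X, squareform(dists), squareform(disp))
            dists_n = pdist(Xn)
            disp_n = _monotone_disparities(d_obs, dists_n)
            stress_n = _stress1(dists_n, disp_n)
            if stress_n > stress + 1e-15:
                # stress-1 can tick up once SMACOF's raw-stress surrogate
                # is exhausted; keep the previous (better) configuration
                converged = True
                break
            X, dists, disp = Xn, dists_n, disp_n
            delta, stress = stress - stress_n, stress_n
            history.append(stress)
            if delta < self.tol:
                converged = True
                break
        return X, stress, history, converged

    def fit(self, D, y=None) -> "NMDS":
        arr, ids = _check_distance_matrix(D)
        n = arr.shape[0]
        k = self.n_components
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k >= n - 1:
            raise ValueError(
                f"n_components={k} must be < n_samples - 1 = {n - 1}"
            )
        d_obs = squareform(arr, checks=False)
        rng = (self.random_state
               if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        ord_res = pcoa(arr)
        P = ord_res.coordinates.to_numpy()
        init = np.zeros((n, k))
        init[:, : min(k, P.shape[1])] = P[:, : min(k, P.shape[1])]
        scale = max(d_obs.max(), 1.0)
        starts = [init] + [
            rng.normal(scale=scale, size=(n, k)) for _ in range(self.n_starts)
        ]
        best = None
        histories = []
        for X0 in starts:
            X, stress, history, converged = self._run_start(X0, d_obs)
            histories.append(np.asarray(history))
            if best is None or stress < best[1]:
                best = (X, stress, history, converged)
        X, stress, history, converged = best
        X = X - X.mean(axis=0)
        # rotate to principal axes (canonical orientation up to reflection)
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        X = X @ Vt.T
        self.embedding_ = X
        self.stress_ = stress
        self.stress_history_ = np.asarray(history)
        self.stress_histories_ = histories  # one per start, PCoA start first
        self.converged_ = converged
        self.n_iter_ = len(history) - 1
        self.sample_ids_ = ids
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_

    def result(self) -> NmdsResult:
        check_is_fitted(self, "embedding_")
        coords = pd.DataFrame(
            self.embedding_,
            index=self.sample_ids_,
            columns=[f"NMDS{i + 1}" for i in range(self.embedding_.shape[1])],
        )
        return NmdsResult(coords, self.stress_, self.converged_,
                          self.n_starts + 1)


def nmds(D, k: int = 2, n_starts: int = 20, max_iter: int = 300,
         tol: float = 1e-7, seed=None) -> NmdsResult:
    """Functional wrapper around the :class:`NMDS` estimator."""
    est = NMDS(n_components=k, n_starts=n_starts, max_iter=max_iter,
               tol=tol, random_state=seed)
    est.fit(D)
    return est.result()
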