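"""Community-level inference: Bray-Curtis, ANOSIM, Mantel, LDA ordination.

ANOSIM and the Mantel test are permutation tests.  Both use the add-one
Monte-Carlo p-value rule p = (1 + #{permuted stat >= observed}) /
(1 + n_permutations), and both switch automatically to exhaustive
enumeration of all distinct label arrangements (ANOSIM) or all object
permutations (Mantel) when that count is below a configurable cap, in
which case the p-value is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sympy.utilities.iterables import multiset_permutations

from .errors import DataError, StatisticalError

_SYMMETRY_TOL = 1e-9


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample labels.

    Validated on construction: symmetry within 1e-9, zero diagonal,
    no negative entries.
    """

    labels: list[str]
    values: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise DataError("label count does not match matrix size")
        if np.abs(v - v.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise DataError("distance matrix is asymmetric beyond 1e-9")
        if np.abs(np.diag(v)).max(initial=0.0) > _SYMMETRY_TOL:
            raise DataError("distance matrix diagonal is not zero")
        if (v < -_SYMMETRY_TOL).any():
            raise DataError("distance matrix has negative entries")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, None)
        self.labels = [str(label) for label in self.labels]

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    seed: int | None
    method: str  # "exhaustive" or "monte-carlo"
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    flavor: str  # "linear" or "rank"
    alternative: str  # "greater" or "two-sided"
    n_permutations: int
    seed: int | None
    method: str


@dataclass(frozen=True)
class LdaOrdination:
    scores: pd.DataFrame  # sample x axis, plus the group column
    explained: np.ndarray  # fraction of discriminant eigenvalue sum per axis
    centroids: pd.DataFrame  # group x axis
    ridge: float


def bray_curtis(matrix: pd.DataFrame, relative: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between the rows of a community matrix.

    d(i,j) = 1 - 2 sum_k min(x_ik, x_jk) / (sum_k x_ik + sum_k x_jk).
    By default rows are converted to relative abundances first, because
    attribute-union row totals are a design artifact (3x particle count);
    set ``relative=False`` to use raw counts.
    """
    x = matrix.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise DataError(
            f"all-zero community rows: {[matrix.index[i] for i in zero]}"
        )
    if relative:
        x = x / totals[:, None]
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(x[i], x[i + 1:]).sum(axis=1)
        denom = x[i].sum() + x[i + 1:].sum(axis=1)
        d[i, i + 1:] = 1.0 - 2.0 * shared / denom
    d = d + d.T
    return DistanceMatrix(
        labels=list(matrix.index.astype(str)), values=d, method="bray-curtis"
    )


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _count_arrangements(sizes: list[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive_cap: int = 10_000,
) -> AnosimResult:
    """Clarke's analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances and mid-ranks on ties; R is 1 when
    every between-group distance exceeds every within-group distance and
    has expectation 0 under random labelling.
    """
    groups = pd.Series(list(groups), index=dist.labels)
    if len(groups) != len(dist):
        raise StatisticalError("group labels do not match the distance matrix")
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise StatisticalError("ANOSIM needs at least 2 groups")
    if (sizes < 2).any():
        singles = list(sizes.index[sizes < 2])
        raise StatisticalError(f"ANOSIM groups of size 1: {singles}")
    warnings: list[str] = []
    if n_permutations < 99:
        warnings.append(
            f"n_permutations={n_permutations} is low; p-value resolution is coarse"
        )
    codes = pd.Categorical(groups).codes.astype(np.int64)
    n = len(codes)
    iu, ju = _pair_indices(n)
    ranks = rankdata(dist.condensed())
    within_obs = codes[iu] == codes[ju]
    r_obs = _anosim_r(ranks, within_obs)

    n_arrangements = _count_arrangements(sizes.tolist())
    if n_arrangements <= exhaustive_cap:
        perms = np.array(list(multiset_permutations(codes.tolist())), dtype=np.int64)
        method = "exhaustive"
        n_used = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = np.array(
            [codes[rng.permutation(n)] for _ in range(n_permutations)],
            dtype=np.int64,
        )
        method = "monte-carlo"
        n_used = n_permutations
    within_perm = perms[:, iu] == perms[:, ju]  # (P, M)
    m = ranks.size
    total = ranks.sum()
    sum_within = within_perm @ ranks
    count_within = within_perm.sum(axis=1).astype(float)
    rw = sum_within / count_within
    rb = (total - sum_within) / (m - count_within)
    r_perm = (rb - rw) / (m / 2.0)
    hits = int(np.sum(r_perm >= r_obs - 1e-12))
    if method == "exhaustive":
        p = hits / n_used
    else:
        p = (1 + hits) / (1 + n_used)
    return AnosimResult(
        r=float(r_obs),
        p_value=float(p),
        n_permutations=n_used,
        group_sizes={str(k): int(v) for k, v in sizes.items()},
        seed=seed,
        method=method,
        warnings=tuple(warnings),
    )


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``a`` with each row of ``b``."""
    a = a - a.mean()
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum() * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (b @ a) / denom


def mantel(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    flavor: str = "linear",
    alternative: str = "greater",
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive_cap: int = 10_000,
) -> MantelResult:
    """Mantel test of correlation between two distance matrices.

    The statistic is the Pearson correlation over the n(n-1)/2 distinct
    pairs, on raw distances (``flavor="linear"``, the conventional Mantel
    statistic) or on their mid-ranks (``flavor="rank"``, a Spearman-type
    variant).  Significance comes from simultaneous row/column
    permutation of the second matrix.
    """
    if dist_a.labels != dist_b.labels:
        raise StatisticalError("Mantel requires identical labels in the same order")
    n = len(dist_a)
    if n < 4:
        raise StatisticalError("Mantel needs at least 4 objects")
    if flavor not in ("linear", "rank"):
        raise StatisticalError(f"unknown Mantel flavor {flavor!r}")
    if alternative not in ("greater", "two-sided"):
        raise StatisticalError(f"unknown alternative {alternative!r}")
    a_sq = dist_a.values
    b_sq = dist_b.values
    if flavor == "rank":
        # mid-ranks commute with object permutation (same value multiset)
        a_sq = squareform(rankdata(squareform(a_sq, checks=False)), checks=False)
        b_sq = squareform(rankdata(squareform(b_sq, checks=False)), checks=False)
    iu, ju = _pair_indices(n)
    a_vec = a_sq[iu, ju]
    r_obs = float(_pearson_rows(a_vec, b_sq[iu, ju][None, :])[0])

    if math.factorial(n) <= exhaustive_cap:
        from itertools import permutations

        perms = np.array(list(permutations(range(n))), dtype=np.int64)
        method = "exhaustive"
        n_used = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = np.array(
            [rng.permutation(n) for _ in range(n_permutations)], dtype=np.int64
        )
        method = "monte-carlo"
        n_used = n_permutations
    b_perm = b_sq[perms[:, iu], perms[:, ju]]  # (P, M)
    r_perm = _pearson_rows(a_vec, b_perm)
    if alternative == "greater":
        hits = int(np.sum(r_perm >= r_obs - 1e-12))
    else:
        hits = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    p = hits / n_used if method == "exhaustive" else (1 + hits) / (1 + n_used)
    return MantelResult(
        r=r_obs,
        p_value=float(p),
        flavor=flavor,
        alternative=alternative,
        n_permutations=n_used,
        seed=seed,
        method=method,
    )


def mantel_between_regions(
    matrix: pd.DataFrame,
    regions,
    meta: pd.DataFrame,
    flavor: str = "linear",
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise Mantel correlations between the MP communities of regions.

    For each region, samples are ordered by (depth_layer, replicate) so
    that positions correspond across regions, a Bray-Curtis matrix is
    computed among that region's samples, and each pair of regions is
    compared with a standard two-matrix Mantel test.  This is one
    defensible reading of "similarity of MP communities among locations";
    the plain two-matrix :func:`mantel` is the other entry point.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    regions = pd.Series(list(regions), index=matrix.index)
    per_region: dict[str, DistanceMatrix] = {}
    for region in pd.unique(regions):
        ids = [s for s in matrix.index if regions[s] == region]
        order = meta.loc[ids].sort_values(["depth_layer", "replicate"]).index
        sub = matrix.loc[order]
        dm = bray_curtis(sub)
        # positional labels so matrices from different regions align
        per_region[str(region)] = DistanceMatrix(
            labels=[str(i) for i in range(len(order))],
            values=dm.values,
            method="bray-curtis",
        )
    names = list(per_region)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = mantel(
                per_region[a],
                per_region[b],
                flavor=flavor,
                n_permutations=n_permutations,
                seed=seed,
            )
            rows.append(
                {"region_a": a, "region_b": b, "r": res.r, "p_value": res.p_value,
                 "method": res.method}
            )
    return pd.DataFrame(rows)


def lda_ordination(
    matrix: pd.DataFrame,
    groups,
    ridge_scale: float = 1e-6,
    relative: bool = True,
) -> LdaOrdination:
    """Linear discriminant ordination of samples with per-axis explained
    variance.

    Solves the generalized symmetric eigenproblem S_b v = lambda (S_w +
    ridge I) v, where S_b/S_w are the between- and within-group scatter
    matrices; the ridge (``ridge_scale * trace(S_w)/d``) keeps the
    within-scatter invertible when features outnumber samples or are
    collinear.  At most min(groups - 1, features) axes are returned and
    per-axis explained fractions sum to 1.
    """
    groups = pd.Series(list(groups), index=matrix.index).astype(str)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise StatisticalError("LDA needs at least 2 groups")
    if (counts < 2).any():
        raise StatisticalError("LDA needs at least 2 samples per group")
    x = matrix.to_numpy(dtype=float)
    if relative:
        totals = x.sum(axis=1)
        if (totals == 0).any():
            raise DataError("all-zero rows cannot be normalised for LDA")
        x = x / totals[:, None]
    n, d = x.shape
    if n < len(counts) + 1:
        raise StatisticalError("fewer samples than needed for the group structure")
    grand = x.mean(axis=0)
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for g in counts.index:
        xg = x[(groups == g).to_numpy()]
        mu = xg.mean(axis=0)
        dev = xg - mu
        sw += dev.T @ dev
        diff = (mu - grand)[:, None]
        sb += len(xg) * (diff @ diff.T)
    trace = np.trace(sw)
    ridge = ridge_scale * (trace / d if trace > 0 else 1.0)
    from scipy.linalg import eigh

    vals, vecs = eigh(sb, sw + ridge * np.eye(d))
    order = np.argsort(vals)[::-1]
    n_axes = min(len(counts) - 1, d)
    vals = np.clip(vals[order][:n_axes], 0.0, None)
    vecs = vecs[:, order][:, :n_axes]
    total = vals.sum()
    explained = vals / total if total > 0 else np.full(n_axes, 1.0 / n_axes)
    scores = (x - grand) @ vecs
    axis_names = [f"LD{i + 1}" for i in range(n_axes)]
    score_df = pd.DataFrame(scores, index=matrix.index, columns=axis_names)
    score_df["group"] = groups
    centroids = score_df.groupby("group", sort=False)[axis_names].mean()
    return LdaOrdination(
        scores=score_df, explained=explained, centroids=centroids, ridge=float(ridge)
    )
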