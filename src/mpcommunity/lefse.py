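"""LEfSe-style discriminant-feature detection for MP communities.

Two stages, following the canonical linear-discriminant-effect-size
recipe: (1) a per-feature Kruskal-Wallis screen at ``alpha``; (2) for the
surviving features, a bootstrapped one-vs-all linear discriminant whose
per-feature effect size is reported on a log10 scale and thresholded.

Effect-size convention (fixed by regression tests, since the original
tool's scaling is under-documented): samples are row-normalised to
counts-per-million; for a feature's enriched group g (the argmax of
group means) the two-class discriminant w = (S_w + ridge I)^-1 (mu_g -
mu_rest) is rescaled to the abundance scale, w <- w * ||mu_g - mu_rest||
/ ||w||, and the feature's effect in one bootstrap is (|w_f| + |mu_g,f -
mu_rest,f|) / 2.  The LDA score is log10(max(mean over bootstraps, 1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from sympy.utilities.iterables import multiset_permutations

from .errors import StatisticalError
from .matrix import relative_abundance

CPM = 1_000_000.0


@dataclass(frozen=True)
class LefseFeature:
    feature: str
    kw_p: float
    lda_score: float  # NaN when the LDA stage was skipped/downgraded
    enriched_group: str
    passed: bool


def kruskal_wallis(
    values, groups, method: str = "auto", exact_max_n: int = 8
) -> tuple[float, float]:
    """Kruskal-Wallis H with mid-rank tie correction.

    H = [12/(n(n+1)) * sum R_i^2/n_i - 3(n+1)] / (1 - sum(t^3-t)/(n^3-n)).
    p comes from the chi-square approximation with k-1 degrees of
    freedom, or (``method="exact"``, automatic for n <= exact_max_n under
    ``"auto"``) from exhaustive enumeration of all distinct assignments
    of the observed values to the groups.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape or v.ndim != 1:
        raise StatisticalError("values and groups must be matching 1-D vectors")
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise StatisticalError("Kruskal-Wallis needs at least 2 groups")
    if (counts == 0).any() or v.size < 3:
        raise StatisticalError("every group needs observations and total n >= 3")
    n = v.size
    codes = np.searchsorted(labels, g)

    def h_stat(code_vec: np.ndarray) -> float:
        ranks = rankdata(v)
        sums = np.bincount(code_vec, weights=ranks, minlength=len(labels))
        h = 12.0 / (n * (n + 1)) * np.sum(sums**2 / counts) - 3.0 * (n + 1)
        _, tie_counts = np.unique(v, return_counts=True)
        correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
        if correction <= 0:  # all values identical
            return 0.0
        return h / correction

    h_obs = h_stat(codes)
    use_exact = method == "exact" or (method == "auto" and n <= exact_max_n)
    if method not in ("auto", "exact", "asymptotic"):
        raise StatisticalError(f"unknown Kruskal-Wallis method {method!r}")
    if use_exact:
        total = math.factorial(n)
        for c in counts:
            total //= math.factorial(int(c))
        hits = 0
        for perm in multiset_permutations(codes.tolist()):
            if h_stat(np.asarray(perm)) >= h_obs - 1e-12:
                hits += 1
        return float(h_obs), hits / total
    if h_obs == 0.0:
        return 0.0, 1.0
    return float(h_obs), float(chi2.sf(h_obs, len(labels) - 1))


def _two_class_weights(x: np.ndarray, mask: np.ndarray, ridge_scale: float = 1e-6):
    """Regularized Fisher discriminant weights for group-vs-rest, rescaled
    onto the abundance scale."""
    mu1 = x[mask].mean(axis=0)
    mu0 = x[~mask].mean(axis=0)
    dev1 = x[mask] - mu1
    dev0 = x[~mask] - mu0
    sw = dev1.T @ dev1 + dev0.T @ dev0
    d = x.shape[1]
    trace = np.trace(sw)
    ridge = ridge_scale * (trace / d if trace > 0 else 1.0)
    w = np.linalg.solve(sw + ridge * np.eye(d), mu1 - mu0)
    diff_norm = np.linalg.norm(mu1 - mu0)
    w_norm = np.linalg.norm(w)
    if w_norm > 0 and diff_norm > 0:
        w = w * (diff_norm / w_norm)
    return w, mu1 - mu0


def lefse(
    matrix: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> list[LefseFeature]:
    """Discriminant MP types per group, LEfSe-style.

    Returns one :class:`LefseFeature` per feature of the matrix (constant
    features get kw_p = 1), with ``passed`` marking the reported set:
    kw_p < alpha and lda_score >= lda_threshold.  With ``n_boot=0`` (or
    ``lda_threshold=-inf``) the result reduces to the Kruskal-Wallis
    screen alone, lda_score = NaN.  Groups with fewer than 3 samples make
    the bootstrap unreliable; the LDA stage is then skipped and the
    result downgraded to the screen (recorded in ``result[i].lda_score``
    being NaN).
    """
    groups = pd.Series(list(groups), index=matrix.index).astype(str)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise StatisticalError("LEfSe needs at least 2 groups")
    rel = relative_abundance(matrix, scale=CPM)
    x = rel.to_numpy(dtype=float)
    g = groups.to_numpy()
    group_means = rel.groupby(groups).mean()

    # constancy is judged on the raw counts: a feature that never varies
    # across samples is never discriminant, even though row-normalisation
    # would make its relative abundance vary
    raw_constant = matrix.nunique(axis=0) <= 1
    kw_ps: dict[str, float] = {}
    for j, feature in enumerate(rel.columns):
        col = x[:, j]
        if raw_constant[feature] or np.ptp(col) == 0:
            kw_ps[feature] = 1.0
            continue
        _, p = kruskal_wallis(col, g, method="asymptotic")
        kw_ps[feature] = p

    survivors = [f for f, p in kw_ps.items() if p < alpha]
    downgraded = (counts < 3).any() or n_boot == 0
    scores: dict[str, float] = {f: float("nan") for f in rel.columns}
    if survivors and not downgraded:
        rng = np.random.default_rng(seed)
        cols = [rel.columns.get_loc(f) for f in survivors]
        xs = x[:, cols]
        group_labels = list(counts.index)
        members = {lab: np.flatnonzero(g == lab) for lab in group_labels}
        enriched = {
            f: group_means[f].idxmax() for f in survivors
        }
        acc = np.zeros((len(survivors),))
        for _ in range(n_boot):
            idx = _stratified_resample(members, rng)
            xb = xs[idx]
            gb = g[idx]
            effects = np.zeros(len(survivors))
            for lab in group_labels:
                mask = gb == lab
                w, diff = _two_class_weights(xb, mask)
                e = 0.5 * (np.abs(w) + np.abs(diff))
                sel = [k for k, f in enumerate(survivors) if enriched[f] == lab]
                effects[sel] = e[sel]
            acc += effects
        mean_effect = acc / n_boot
        for k, f in enumerate(survivors):
            scores[f] = float(np.log10(max(mean_effect[k], 1.0)))

    out = []
    for feature in rel.columns:
        score = scores[feature]
        if downgraded:
            # screen-only result: the reported set is the KW screen itself
            passed = kw_ps[feature] < alpha
        else:
            passed = kw_ps[feature] < alpha and score >= lda_threshold
        out.append(
            LefseFeature(
                feature=feature,
                kw_p=kw_ps[feature],
                lda_score=score,
                enriched_group=str(group_means[feature].idxmax()),
                passed=bool(passed),
            )
        )
    return out


def _stratified_resample(members: dict[str, np.ndarray], rng) -> np.ndarray:
    """Bootstrap sample indices stratified within group, requiring at
    least 2 distinct samples per group (retried; guaranteed possible for
    group sizes >= 2)."""
    picks = []
    for lab, idx in members.items():
        for _ in range(1000):
            draw = rng.choice(idx, size=len(idx), replace=True)
            if len(np.unique(draw)) >= 2:
                break
        picks.append(draw)
    return np.concatenate(picks)


def lefse_table(features: list[LefseFeature]) -> pd.DataFrame:
    """Ranked feature table (reported features first, by score)."""
    df = pd.DataFrame([f.__dict__ for f in features])
    return df.sort_values(
        ["passed", "lda_score"], ascending=[False, False], na_position="last"
    ).reset_index(drop=True)
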