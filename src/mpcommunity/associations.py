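"""Univariate association screens.

Spearman correlation matrices between MP metrics and environmental
covariates (pairwise-complete, raw p and Benjamini-Hochberg q side by
side), simple OLS regression of abundance on population, one-way ANOVA
with Duncan's multiple range letters for among-region contrasts, and
independent two-sample t-tests for topsoil/subsoil contrasts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import StatisticalError


@dataclass(frozen=True)
class CorrelationScreen:
    rho: pd.DataFrame  # metrics x covariates
    p: pd.DataFrame
    q: pd.DataFrame  # BH-adjusted over all estimable cells
    n: pd.DataFrame  # pairwise-complete counts; cells with n < min_n are
    # flagged by rho/p/q being NaN while n records the available pairs


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class LetterAssignment:
    letters: dict[str, str]  # group -> letter string, e.g. "a", "ab"
    means: dict[str, float]
    alpha: float
    ms_error: float
    df_error: int


def spearman_rho(x, y) -> float:
    """Mid-rank Spearman correlation (Pearson on mid-ranks)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise StatisticalError("Spearman undefined for a constant variable")
    return float(np.corrcoef(rx, ry)[0, 1])


def _spearman_p(x: np.ndarray, y: np.ndarray, rho: float, exact_max_n: int) -> float:
    n = x.size
    if n <= exact_max_n:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        rx = rx - rx.mean()
        denom_x = math.sqrt(float(rx @ rx))
        hits = 0
        total = 0
        abs_obs = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            pv = np.asarray(perm) - ry.mean()
            r = float(rx @ pv) / (denom_x * math.sqrt(float(pv @ pv)))
            if abs(r) >= abs_obs:
                hits += 1
            total += 1
        return hits / total
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman_screen(
    metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    min_n: int = 4,
    exact_max_n: int = 9,
) -> CorrelationScreen:
    """Spearman rho/p/q matrix between every metric and every covariate.

    Pairs are matched on the index (sample_id); missing cells are handled
    pairwise-complete.  Cells with fewer than ``min_n`` complete pairs
    are flagged not-estimable (NaN rho/p/q) rather than NaN-propagated
    from the data.  p is exact (permutation) for n <= ``exact_max_n``,
    else the t-approximation; q is Benjamini-Hochberg over all estimable
    cells of the matrix.
    """
    common = metrics.index.intersection(covariates.index)
    m = metrics.loc[common]
    c = covariates.loc[common]
    shape = (len(m.columns), len(c.columns))
    rho = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    nmat = np.zeros(shape, dtype=int)
    for i, mc in enumerate(m.columns):
        for j, cc in enumerate(c.columns):
            x = m[mc].to_numpy(dtype=float)
            y = c[cc].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            nmat[i, j] = int(ok.sum())
            if nmat[i, j] < min_n:
                continue
            xs, ys = x[ok], y[ok]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                continue  # constant variable: not estimable
            r = spearman_rho(xs, ys)
            rho[i, j] = r
            p[i, j] = _spearman_p(xs, ys, r, exact_max_n)
    q = np.full(shape, np.nan)
    flat_ok = ~np.isnan(p)
    if flat_ok.any():
        q[flat_ok] = multipletests(p[flat_ok], method="fdr_bh")[1]
    idx, cols = m.columns, c.columns
    return CorrelationScreen(
        rho=pd.DataFrame(rho, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        q=pd.DataFrame(q, index=idx, columns=cols),
        n=pd.DataFrame(nmat, index=idx, columns=cols),
    )


def simple_regression(x, y) -> RegressionResult:
    """OLS of y on x with the Pearson r and the two-sided slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatisticalError("regression needs n >= 3 matched observations")
    if np.ptp(x) == 0:
        raise StatisticalError("regression undefined for constant x")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise StatisticalError("values and groups must match")
    return {str(lab): v[g == lab] for lab in pd.unique(g)}


def one_way_anova(values, groups) -> tuple[float, float]:
    """Standard one-way ANOVA F with (k-1, n-k) degrees of freedom."""
    arrays = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise StatisticalError("ANOVA needs at least 2 groups")
    small = [lab for lab, arr in arrays.items() if arr.size < 2]
    if small:
        raise StatisticalError(f"ANOVA groups with fewer than 2 observations: {small}")
    f, p = stats.f_oneway(*arrays.values())
    return float(f), float(p)


def anova_mse(values, groups) -> tuple[float, int]:
    """Within-group mean square and its degrees of freedom."""
    arrays = _group_arrays(values, groups)
    n = sum(arr.size for arr in arrays.values())
    k = len(arrays)
    ss_within = sum(((arr - arr.mean()) ** 2).sum() for arr in arrays.values())
    return float(ss_within / (n - k)), int(n - k)


def studentized_range_quantile(alpha: float, n_means: int, df: float) -> float:
    """Upper-alpha quantile of the studentized range distribution, the
    critical value tabulated in multiple-range-test tables."""
    return float(stats.studentized_range.ppf(1.0 - alpha, n_means, df))


def duncan_letters(values, groups, alpha: float = 0.05) -> LetterAssignment:
    """Duncan's multiple range test with compact letter display.

    Group means are sorted; a range spanning p means is declared
    significant when it exceeds the least significant range LSR_p =
    q(alpha_p; p, df) * sqrt(MSE / n_h), with Duncan's protection level
    alpha_p = 1 - (1 - alpha)^(p-1) and n_h the harmonic mean group size.
    The step-down rule never declares a subrange of a non-significant
    range significant; letters mark maximal non-separated runs.
    """
    arrays = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise StatisticalError("Duncan test needs at least 2 groups")
    small = [lab for lab, arr in arrays.items() if arr.size < 2]
    if small:
        raise StatisticalError(f"groups with fewer than 2 observations: {small}")
    mse, df_error = anova_mse(values, groups)
    sizes = np.array([arr.size for arr in arrays.values()], dtype=float)
    n_h = len(sizes) / np.sum(1.0 / sizes)
    means = {lab: float(arr.mean()) for lab, arr in arrays.items()}
    ordered = sorted(means, key=means.get, reverse=True)
    k = len(ordered)

    lsr = {}
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = studentized_range_quantile(alpha_p, p, df_error)
        lsr[p] = q * math.sqrt(mse / n_h) if mse > 0 else 0.0

    # step-down: test the full range first; a non-significant range
    # protects all its subranges from being declared significant
    separated = np.zeros((k, k), dtype=bool)
    visited = set()

    def test_range(i: int, j: int) -> None:
        if j <= i or (i, j) in visited:
            return
        visited.add((i, j))
        span = j - i + 1
        diff = means[ordered[i]] - means[ordered[j]]
        if mse > 0 and diff > lsr[span]:
            separated[i, j] = separated[j, i] = True
            test_range(i + 1, j)
            test_range(i, j - 1)
        # non-significant: leave the whole subtree unseparated

    test_range(0, k - 1)

    # maximal runs of mutually non-separated groups -> letters
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and not any(separated[a, j + 1] for a in range(i, j + 1)):
            j += 1
        intervals.append((i, j))
    maximal = [
        iv
        for iv in intervals
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)
    ]
    # deduplicate while preserving order
    seen: list[tuple[int, int]] = []
    for iv in maximal:
        if iv not in seen:
            seen.append(iv)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in ordered}
    for letter_idx, (i, j) in enumerate(seen):
        for pos in range(i, j + 1):
            letters[ordered[pos]] += alphabet[letter_idx % len(alphabet)]
    return LetterAssignment(
        letters=letters, means=means, alpha=alpha, ms_error=mse, df_error=df_error
    )


def independent_t_test(a, b, variance_policy: str = "welch") -> tuple[float, float]:
    """Two-sided independent two-sample t-test.

    ``variance_policy="welch"`` (default, robust to unequal variances) or
    ``"pooled"`` for the classic equal-variance test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatisticalError("each sample needs n >= 2")
    if variance_policy not in ("welch", "pooled"):
        raise StatisticalError(f"unknown variance policy {variance_policy!r}")
    res = stats.ttest_ind(a, b, equal_var=(variance_policy == "pooled"))
    if np.isnan(res.statistic):  # zero variance in both samples, equal means
        return 0.0, 1.0
    return float(res.statistic), float(res.pvalue)
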