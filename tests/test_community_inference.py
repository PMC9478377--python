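"""Bray-Curtis, ANOSIM, Mantel and LDA ordination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from mpcommunity import (
    DataError,
    DistanceMatrix,
    StatisticalError,
    anosim,
    bray_curtis,
    lda_ordination,
    mantel,
)


def _dm(values, labels=None):
    n = values.shape[0]
    labels = labels or [f"s{i}" for i in range(n)]
    return DistanceMatrix(labels=labels, values=values)


def _random_dm(rng, n):
    return _dm(squareform(rng.random(n * (n - 1) // 2)))


# ---------------------------------------------------------------- Bray-Curtis

def test_bray_curtis_closed_form_cases():
    m = pd.DataFrame(
        [[6, 2], [2, 2], [6, 2], [0, 7]],
        index=["a", "b", "c", "d"],
        columns=["f1", "f2"],
    )
    d = bray_curtis(m, relative=False)
    df = d.to_dataframe()
    assert df.loc["a", "b"] == pytest.approx(1 / 3)  # 1 - 8/12
    assert df.loc["a", "c"] == pytest.approx(0.0)  # identical rows
    # disjoint supports -> 1
    m2 = pd.DataFrame([[5, 0], [0, 3]], index=["x", "y"], columns=["f1", "f2"])
    assert bray_curtis(m2, relative=False).to_dataframe().loc["x", "y"] == 1.0


def test_bray_curtis_matches_scipy(rng):
    m = pd.DataFrame(rng.integers(0, 20, size=(8, 6)) + 1)
    ours = bray_curtis(m, relative=False).condensed()
    theirs = pdist(m.to_numpy(), metric="braycurtis")
    np.testing.assert_allclose(ours, theirs, atol=1e-12)


def test_bray_curtis_relative_mode_ignores_row_scaling(rng):
    m = pd.DataFrame(rng.integers(1, 20, size=(5, 6)))
    scaled = m * np.array([1, 2, 3, 4, 5])[:, None]  # scale rows
    np.testing.assert_allclose(
        bray_curtis(m).condensed(), bray_curtis(scaled).condensed(), atol=1e-12
    )


def test_bray_curtis_names_offending_zero_row():
    m = pd.DataFrame([[1, 2], [0, 0]], index=["good", "empty"])
    with pytest.raises(DataError, match="empty"):
        bray_curtis(m)


# ------------------------------------------------------------------- ANOSIM

def _anosim_oracle(values, codes):
    """Independent brute-force ANOSIM: exhaustive p over all distinct
    label assignments."""
    n = len(codes)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(values[iu, ju])
    m = ranks.size

    def r_of(assign):
        assign = np.asarray(assign)
        within = assign[iu] == assign[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = r_of(codes)
    perms = sorted(set(itertools.permutations(codes)))
    hits = sum(1 for p in perms if r_of(p) >= r_obs - 1e-12)
    return r_obs, hits / len(perms), len(perms)


def test_anosim_r_is_one_for_complete_separation():
    # within distances all 0.1, between all 0.9
    v = np.full((6, 6), 0.9)
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                v[i, j] = 0.1 if i != j else 0.0
    res = anosim(_dm(v), ["a"] * 3 + ["b"] * 3)
    assert res.r == pytest.approx(1.0)
    assert res.method == "exhaustive"


def test_anosim_exhaustive_p_matches_bruteforce(rng):
    v = squareform(rng.random(15))
    groups = ["a", "a", "a", "b", "b", "b"]
    res = anosim(_dm(v), groups)
    r_oracle, p_oracle, n_arr = _anosim_oracle(v, np.array([0, 0, 0, 1, 1, 1]))
    assert n_arr == 20
    assert res.n_permutations == 20
    assert res.r == pytest.approx(r_oracle)
    assert res.p_value == pytest.approx(p_oracle)


def test_anosim_permutation_distribution_centred_at_zero(rng):
    v = squareform(rng.random(45))  # n = 10
    groups = ["a"] * 5 + ["b"] * 5
    rs = []
    for _ in range(300):
        perm = rng.permutation(10)
        rs.append(anosim(_dm(v), np.array(groups)[perm], n_permutations=0,
                         seed=0, exhaustive_cap=300).r)
    assert abs(np.mean(rs)) < 0.05


def test_anosim_invariant_under_monotone_distance_transform(rng):
    v = squareform(rng.random(28))
    groups = ["a", "a", "b", "b", "c", "c", "c", "a"]
    base = anosim(_dm(v), groups, seed=0)
    warped = anosim(_dm(np.sqrt(v)), groups, seed=0)
    assert warped.r == pytest.approx(base.r)
    assert warped.p_value == pytest.approx(base.p_value)


def test_anosim_matches_skbio(rng):
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    v = squareform(rng.random(66))  # n = 12
    groups = ["a", "b", "c"] * 4
    ours = anosim(_dm(v), groups, seed=0)
    theirs = skbio_distance.anosim(
        skbio_distance.DistanceMatrix(v, [f"s{i}" for i in range(12)]),
        pd.Series(groups, index=[f"s{i}" for i in range(12)], name="group"),
        permutations=99,
    )
    assert ours.r == pytest.approx(float(theirs["test statistic"]), abs=1e-12)


def test_anosim_precondition_errors(rng):
    v = squareform(rng.random(10))
    with pytest.raises(StatisticalError, match="size 1"):
        anosim(_dm(v), ["a", "a", "a", "a", "b"])
    with pytest.raises(StatisticalError, match="2 groups"):
        anosim(_dm(v), ["a"] * 5)
    res = anosim(_dm(v), ["a", "a", "a", "b", "b"], n_permutations=9)
    assert res.warnings  # low-permutation warning recorded


# -------------------------------------------------------------------- Mantel

def _mantel_oracle(a, b, alternative="greater"):
    n = a.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    av = a[iu, ju]

    def corr(perm):
        bp = b[np.ix_(perm, perm)][iu, ju]
        return np.corrcoef(av, bp)[0, 1]

    r_obs = corr(list(range(n)))
    rs = [corr(list(p)) for p in itertools.permutations(range(n))]
    if alternative == "greater":
        hits = sum(1 for r in rs if r >= r_obs - 1e-12)
    else:
        hits = sum(1 for r in rs if abs(r) >= abs(r_obs) - 1e-12)
    return r_obs, hits / len(rs)


def test_mantel_identity_gives_r_one_and_minimum_p(rng):
    a = _random_dm(rng, 5)
    res = mantel(a, a)
    assert res.r == pytest.approx(1.0)
    assert res.method == "exhaustive"
    # identity is the unique maximiser up to symmetry of the matrix
    assert res.p_value <= 0.05


def test_mantel_affine_invariance(rng):
    a = _random_dm(rng, 6)
    b = _dm(2.5 * a.values + 0.3 * (1 - np.eye(6)))
    res = mantel(a, b)
    assert res.r == pytest.approx(1.0)


def test_mantel_exhaustive_p_matches_bruteforce(rng):
    a = squareform(rng.random(6))
    b = squareform(rng.random(6))
    for alternative in ("greater", "two-sided"):
        res = mantel(_dm(a), _dm(b), alternative=alternative)
        r_oracle, p_oracle = _mantel_oracle(a, b, alternative)
        assert res.n_permutations == 24
        assert res.r == pytest.approx(r_oracle)
        assert res.p_value == pytest.approx(p_oracle)


def test_mantel_rank_flavor_invariant_to_monotone_transform(rng):
    a = _random_dm(rng, 7)
    b = _random_dm(rng, 7)
    base = mantel(a, b, flavor="rank", seed=0)
    warped = mantel(_dm(a.values**3), b, flavor="rank", seed=0)
    assert warped.r == pytest.approx(base.r)
    assert warped.p_value == pytest.approx(base.p_value)


def test_mantel_matches_skbio(rng):
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    a = squareform(rng.random(45))
    b = squareform(rng.random(45))
    ours = mantel(_dm(a), _dm(b), seed=0)
    r_skbio, _, _ = skbio_distance.mantel(
        skbio_distance.DistanceMatrix(a),
        skbio_distance.DistanceMatrix(b),
        method="pearson",
        permutations=0,
    )
    assert ours.r == pytest.approx(float(r_skbio), abs=1e-12)


def test_mantel_label_mismatch_is_error(rng):
    a = _random_dm(rng, 5)
    b = DistanceMatrix(labels=list("vwxyz"), values=_random_dm(rng, 5).values)
    with pytest.raises(StatisticalError, match="labels"):
        mantel(a, b)


# ----------------------------------------------------------------------- LDA

def test_lda_two_groups_single_axis(rng):
    x = pd.DataFrame(rng.random((8, 4)))
    groups = ["a"] * 4 + ["b"] * 4
    res = lda_ordination(x, groups, relative=False)
    assert res.scores.shape[1] == 2  # LD1 + group column
    np.testing.assert_allclose(res.explained.sum(), 1.0, atol=1e-9)
    assert res.explained[0] == pytest.approx(1.0)


def test_lda_explained_fractions_sum_to_one(rng):
    x = pd.DataFrame(rng.random((18, 6)))
    groups = ["a", "b", "c"] * 6
    res = lda_ordination(x, groups, relative=False)
    assert len(res.explained) == 2  # min(groups-1, features)
    np.testing.assert_allclose(res.explained.sum(), 1.0, atol=1e-9)
    assert (res.explained >= 0).all()


def test_lda_axis_matches_fisher_closed_form(rng):
    # separable 2-class data; LD1 must align with W^-1 (mu1 - mu2)
    n = 20
    x1 = rng.normal([0, 0, 0], 0.5, size=(n, 3))
    x2 = rng.normal([3, 1, -2], 0.5, size=(n, 3))
    x = pd.DataFrame(np.vstack([x1, x2]))
    groups = ["a"] * n + ["b"] * n
    res = lda_ordination(x, groups, relative=False, ridge_scale=1e-12)
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    w = (x1 - mu1).T @ (x1 - mu1) + (x2 - mu2).T @ (x2 - mu2)
    fisher = np.linalg.solve(w, mu1 - mu2)
    axis = res.scores["LD1"].to_numpy()
    proj = x.to_numpy() @ (fisher / np.linalg.norm(fisher))
    cosine = abs(np.corrcoef(axis, proj)[0, 1])
    assert cosine >= 0.999


def test_lda_centroid_separation_grows_with_planted_shift():
    from mpcommunity import build_community_matrix, perturb_config, simulate_survey
    from mpcommunity.synthetic import default_config

    gaps = []
    for delta in (0.0, 0.5, 1.5):
        config = perturb_config(default_config(), "community_shift", delta)
        bundle = simulate_survey(config, seed=5)
        m = build_community_matrix(bundle.particles)
        groups = bundle.meta.set_index("sample_id")["region"].loc[m.index]
        res = lda_ordination(m, groups)
        centroids = res.centroids.to_numpy()
        gap = np.mean(pdist(centroids))
        gaps.append(gap)
    assert gaps[0] < gaps[1] < gaps[2]


def test_lda_requires_replicated_groups(rng):
    x = pd.DataFrame(rng.random((3, 2)))
    with pytest.raises(StatisticalError):
        lda_ordination(x, ["a", "a", "b"], relative=False)
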