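"""Family selection and silhouette-guided hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, fcluster
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from fragtx.clustering import (
    average_silhouette,
    cut_and_select,
    hcluster_profiles,
    impute_profiles,
    select_candidates,
)
from fragtx.core import FragtxError

from .conftest import make_record


@pytest.mark.parametrize(
    "defline,go_ids,expected",
    [
        ("triacylglycerol lipase", set(), True),
        ("Putative LIPASE-like protein", set(), True),  # case-insensitive
        ("beta-hydrolase fold protein", set(), True),
        ("beta-galactosidase", set(), False),  # "beta" without "hydrolase"
        ("hypothetical protein", {"GO:0016298"}, True),
        ("hypothetical protein", {"GO:0016787", "GO:0016042"}, True),
        ("hypothetical protein", {"GO:0016787"}, False),  # needs both terms
        ("hypothetical protein", {"GO:0016042"}, False),
        ("hypothetical protein", set(), False),
    ],
)
def test_select_candidates_rules(defline, go_ids, expected):
    records = {"x": make_record("x", defline=defline, go_ids=frozenset(go_ids))}
    assert (("x" in select_candidates(records))) is expected


def test_impute_replaces_na_with_zero():
    df = pd.DataFrame({"t1": [1.0, np.nan], "t2": [np.nan, 2.0]}, index=["a", "b"])
    mask = df.isna()
    out = impute_profiles(df, mask)
    assert out.loc["b", "t1"] == 0.0 and out.loc["a", "t2"] == 0.0
    assert out.loc["a", "t1"] == 1.0


def test_first_merge_joins_identical_profiles():
    profiles = pd.DataFrame(
        [[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]], index=["a", "b", "c"]
    )
    tree = hcluster_profiles(profiles)
    assert tree[0, 2] == 0.0  # first merge at height 0
    assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}


def test_cophenetic_dominates_pairwise_distances(rng):
    # complete linkage: cophenetic distance >= pairwise distance
    profiles = pd.DataFrame(rng.normal(size=(8, 5)))
    tree = hcluster_profiles(profiles)
    coph = cophenet(tree)
    direct = pdist(profiles.to_numpy())
    assert (coph >= direct - 1e-10).all()


def test_tree_invariant_to_row_permutation(rng):
    profiles = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"g{i}" for i in range(10)])
    perm = profiles.sample(frac=1.0, random_state=3)
    t1 = hcluster_profiles(profiles)
    t2 = hcluster_profiles(perm)
    for k in (2, 3, 4):
        l1 = dict(zip(profiles.index, fcluster(t1, t=k, criterion="maxclust")))
        l2 = dict(zip(perm.index, fcluster(t2, t=k, criterion="maxclust")))
        ids = list(profiles.index)
        assert adjusted_rand_score([l1[i] for i in ids], [l2[i] for i in ids]) == 1.0


def test_tree_invariant_to_common_translation(rng):
    profiles = pd.DataFrame(rng.normal(size=(9, 4)))
    shifted = profiles + 7.5  # same vector added to every row
    t1, t2 = hcluster_profiles(profiles), hcluster_profiles(shifted)
    np.testing.assert_allclose(t1, t2, atol=1e-9)


def brute_force_silhouette(labels, dist):
    """Per-point silhouette by direct enumeration."""
    n = len(labels)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = sum(dist[i][j] for j in same) / len(same)
        bs = []
        for other in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            bs.append(sum(dist[i][j] for j in members) / len(members))
        b = min(bs)
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return sum(scores) / n


def test_silhouette_matches_brute_force_oracle(rng):
    points = rng.normal(size=(30, 2))
    dist = squareform(pdist(points))
    labels = rng.integers(1, 4, size=30)
    while len(set(labels.tolist())) < 3:
        labels = rng.integers(1, 4, size=30)
    assert average_silhouette(labels, dist) == pytest.approx(
        brute_force_silhouette(labels.tolist(), dist), abs=1e-12
    )


def test_silhouette_bounds_and_degenerate_cases(rng):
    # two tight duplicate-point clusters: a(i) = 0 -> s = 1
    pts = np.array([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0], [9.0, 9.0]])
    dist = squareform(pdist(pts))
    assert average_silhouette(np.array([1, 1, 2, 2]), dist) == pytest.approx(1.0)
    # all points identical: 0/0 convention gives 0
    dist0 = np.zeros((4, 4))
    assert average_silhouette(np.array([1, 1, 2, 2]), dist0) == 0.0
    with pytest.raises(FragtxError):
        average_silhouette(np.array([1, 1, 1, 1]), dist0)
    # always within [-1, 1]
    labels = rng.integers(1, 4, size=20)
    labels[:3] = [1, 2, 3]
    d = squareform(pdist(rng.normal(size=(20, 3))))
    assert -1.0 <= average_silhouette(labels, d) <= 1.0


def _planted_profiles(rng, sizes=(10, 14, 17, 20), noise=0.2):
    centroids = np.array(
        [
            [2, 2, 2, 0, 0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 2, 2, 2, 2, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0, -2, -2, -2, -2],
            [-2, -2, -2, -2, -2, -2, -2, 2, 2, 2, 2],
        ],
        dtype=float,
    )
    rows, truth = [], []
    for c, size in enumerate(sizes):
        rows.append(centroids[c] + rng.normal(0, noise, size=(size, 11)))
        truth += [c] * size
    profiles = pd.DataFrame(np.vstack(rows), index=[f"g{i}" for i in range(len(truth))])
    return profiles, np.array(truth)


def test_planted_clusters_recovered_with_noise(rng):
    profiles, truth = _planted_profiles(rng, noise=0.2)
    tree = hcluster_profiles(profiles)
    result = cut_and_select(tree, profiles)
    assert result.chosen_k == 4
    labels = [result.assignment[i] for i in profiles.index]
    assert adjusted_rand_score(truth, labels) >= 0.9


def test_planted_clusters_exact_at_zero_noise(rng):
    profiles, truth = _planted_profiles(rng, noise=0.0)
    tree = hcluster_profiles(profiles)
    result = cut_and_select(tree, profiles)
    assert result.chosen_k == 4
    labels = [result.assignment[i] for i in profiles.index]
    assert adjusted_rand_score(truth, labels) == 1.0


def test_k_range_collapsed_to_single_value(rng):
    profiles, _ = _planted_profiles(rng)
    tree = hcluster_profiles(profiles)
    result = cut_and_select(tree, profiles, k_range=[3])
    assert result.chosen_k == 3


def test_explicit_k_override(rng):
    profiles, _ = _planted_profiles(rng)
    tree = hcluster_profiles(profiles)
    result = cut_and_select(tree, profiles, k=4)
    assert result.chosen_k == 4
    assert set(result.silhouettes) >= {3, 4, 5, 6, 7}


def test_silhouette_agrees_with_sklearn(rng):
    from sklearn.metrics import silhouette_score

    points = rng.normal(size=(25, 3))
    dist = squareform(pdist(points))
    labels = rng.integers(1, 4, size=25)
    labels[:3] = [1, 2, 3]
    assert average_silhouette(labels, dist) == pytest.approx(
        silhouette_score(dist, labels, metric="precomputed"), abs=1e-10
    )
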