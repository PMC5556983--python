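"""Gene-family selection and hierarchical clustering of fold-change profiles.

Lipase-like candidates are selected by annotation rules (keyword or GO
criteria) and their log2 fold-change profiles are clustered with
Euclidean distance and complete linkage. The number of clusters is
guided by the average silhouette width evaluated for k = 3..7; an
explicit k can be forced instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .core import FragtxError, LocusRecord

LIPASE_ACTIVITY_GO = "GO:0016298"
HYDROLASE_ACTIVITY_GO = "GO:0016787"
LIPID_CATABOLISM_GO = "GO:0016042"

DEFAULT_K_RANGE = range(3, 8)


@dataclass
class ClusterResult:
    member_ids: list[str]
    linkage_tree: np.ndarray
    assignment: dict[str, int]
    silhouettes: dict[int, float]
    chosen_k: int


def select_candidates(records: dict[str, LocusRecord]) -> set[str]:
    """Select lipase-like loci by defline keywords or GO annotation.

    A locus qualifies if its defline contains "lipase", or contains both
    "hydrolase" and "beta" (case-insensitive), or its GO terms include
    lipase activity (GO:0016298), or include both hydrolase activity
    (GO:0016787) and lipid catabolic process (GO:0016042).
    """
    selected: set[str] = set()
    for locus, rec in records.items():
        defline = rec.defline.lower()
        if "lipase" in defline:
            selected.add(locus)
        elif "hydrolase" in defline and "beta" in defline:
            selected.add(locus)
        elif LIPASE_ACTIVITY_GO in rec.go_ids:
            selected.add(locus)
        elif {HYDROLASE_ACTIVITY_GO, LIPID_CATABOLISM_GO} <= rec.go_ids:
            selected.add(locus)
    return selected


def impute_profiles(log2fc: pd.DataFrame, na_mask: pd.DataFrame | None = None) -> pd.DataFrame:
    """Replace NA fold-change cells by 0 for distance computation.

    The NA mask is preserved by callers for display; zero imputation
    treats an unreliable cell as "not responsive".
    """
    profiles = log2fc.copy()
    if na_mask is not None:
        profiles[na_mask] = 0.0
    return profiles.fillna(0.0)


def hcluster_profiles(profiles: pd.DataFrame, method: str = "complete") -> np.ndarray:
    """Agglomerative clustering of profile rows (Euclidean, complete linkage)."""
    if profiles.shape[0] < 2:
        raise FragtxError("clustering requires at least 2 profiles")
    values = profiles.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise FragtxError("profiles contain non-finite values; impute first")
    return linkage(values, method=method, metric="euclidean")


def average_silhouette(assignment: np.ndarray, distances: np.ndarray) -> float:
    """Average silhouette width of a clustering given a distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)), where a(i) is the mean
    distance to co-members and b(i) the smallest mean distance to another
    cluster. Singleton clusters contribute s = 0, and 0/0 is taken as 0.
    """
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    if labels.size < 2:
        raise FragtxError("silhouette requires at least 2 clusters")
    n = assignment.size
    scores = np.zeros(n)
    for i in range(n):
        own = assignment[i]
        same = (assignment == own) & (np.arange(n) != i)
        if not same.any():
            continue  # singleton: s = 0
        a = distances[i, same].mean()
        b = min(
            distances[i, assignment == other].mean()
            for other in labels
            if other != own
        )
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def cut_and_select(
    tree: np.ndarray,
    profiles: pd.DataFrame,
    k_range: range | list[int] = DEFAULT_K_RANGE,
    k: int | None = None,
) -> ClusterResult:
    """Cut the tree at each candidate k and keep the best-silhouette cut.

    Ties go to the smallest k. Pass ``k`` to force a specific cut (the
    silhouette profile over ``k_range`` is still reported).
    """
    member_ids = list(profiles.index)
    distances = squareform(pdist(profiles.to_numpy(dtype=float), metric="euclidean"))
    silhouettes: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    ks = sorted(set(k_range) | ({k} if k is not None else set()))
    for kk in ks:
        if kk < 2 or kk > len(member_ids):
            continue
        labels = fcluster(tree, t=kk, criterion="maxclust")
        if np.unique(labels).size < 2:
            continue  # degenerate cut (tied heights); silhouette undefined
        assignments[kk] = labels
        silhouettes[kk] = average_silhouette(labels, distances)
    if not silhouettes:
        raise FragtxError("no feasible k in range")
    if k is not None:
        if k not in assignments:
            raise FragtxError(f"requested k={k} infeasible for {len(member_ids)} members")
        chosen = k
    else:
        in_range = {kk: s for kk, s in silhouettes.items() if kk in set(k_range)}
        best = max(in_range.values())
        chosen = min(kk for kk, s in in_range.items() if s == best)
    return ClusterResult(
        member_ids=member_ids,
        linkage_tree=tree,
        assignment=dict(zip(member_ids, (int(x) for x in assignments[chosen]))),
        silhouettes=silhouettes,
        chosen_k=chosen,
    )
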