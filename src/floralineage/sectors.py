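"""Radial floral sector discovery from shared mutations.

Mutations present in two or more organ units of one flower mark radial
sectors: wedges of the floral cup descended from a shared primordial cell
population. Organs are clustered on their shared-mutation profiles two
ways — K-means from stated initials, and a neighbor-joining dendrogram
with column-bootstrap supports — and the asymmetry of petal sharing
(petal–stamen and petal–sepal events but no petal–petal events) is tested
against a uniform null by chi-square.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj
from sklearn.cluster import KMeans

__all__ = [
    "build_sharing_matrix",
    "kmeans_sectors",
    "nj_tree",
    "nj_bootstrap",
    "bipartitions",
    "petal_sharing_counts",
    "petal_sharing_chisq",
]


def build_sharing_matrix(
    presence: pd.DataFrame,
    metadata: pd.DataFrame,
    flower: str,
    min_organs: int = 2,
    drop_empty_organs: bool = True,
) -> pd.DataFrame:
    """Binary organs x mutations matrix for one flower's sector analysis.

    Split subsamples are collapsed to their organ unit (present if called
    in either subsample). Mutations carried by fewer than ``min_organs``
    organ units are dropped — private mutations carry no sectoring
    information. By default organs carrying none of the retained shared
    mutations are dropped too (they contribute only zero rows, which
    collapse the dendrogram); the carpel typically exits here, mirroring
    its early genetic isolation from the radial parts.

    Returns an empty frame when no mutation is shared — the explicit
    "no sectoring information" outcome.
    """
    meta = metadata[metadata["flower"] == flower]
    if meta.empty:
        raise ValueError(f"no samples for flower {flower!r}")
    cols = [s for s in meta.index if s in presence.columns]
    sub = presence[cols]
    units = meta.loc[cols, "organ_unit"].fillna(pd.Series(cols, index=cols))
    by_organ = (sub == 1.0).T.groupby(units).any()  # organ units x mutations
    keep = by_organ.sum(axis=0) >= min_organs       # carrier-organ count per mutation
    mat = by_organ.loc[:, keep].astype(int)
    mat.index.name = "organ_unit"
    if drop_empty_organs and not mat.empty:
        mat = mat.loc[mat.sum(axis=1) > 0]
    if mat.empty or mat.shape[1] == 0:
        return pd.DataFrame(index=pd.Index([], name="organ_unit"))
    return mat


def kmeans_sectors(
    matrix: pd.DataFrame,
    k: int,
    initials=None,
    seed: int = 0,
) -> pd.Series:
    """Euclidean K-means on binary organ rows.

    ``initials`` may be a list of organ-unit names used as starting
    centroids (the convention of reporting which rows seeded each
    cluster) or an explicit k x n_mutations array; given initials the
    Lloyd iteration is deterministic. Without initials, seeded k-means++
    is used. Ties in assignment go to the lowest cluster index.
    """
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the {len(matrix)} organs available")
    X = matrix.to_numpy(dtype=float)
    if initials is not None:
        if isinstance(initials, (list, tuple)) and all(
            isinstance(i, str) for i in initials
        ):
            init = matrix.loc[list(initials)].to_numpy(dtype=float)
        else:
            init = np.asarray(initials, dtype=float)
        if init.shape != (k, X.shape[1]):
            raise ValueError("initials must give one centroid per cluster")
        km = KMeans(n_clusters=k, init=init, n_init=1, random_state=0)
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return pd.Series(labels, index=matrix.index, name="sector")


def _distance_matrix(matrix: pd.DataFrame, metric: str = "hamming") -> DistanceMatrix:
    if matrix.shape[1] == 0:
        raise ValueError("sharing matrix has no mutations")
    dist = squareform(pdist(matrix.to_numpy(dtype=float), metric=metric))
    return DistanceMatrix(dist, ids=list(matrix.index))


def nj_tree(matrix: pd.DataFrame, metric: str = "hamming") -> TreeNode:
    """Neighbor-joining dendrogram of organs on shared-mutation profiles.

    The organ–organ distance is the Hamming distance between presence
    profiles (Euclidean available via ``metric``). An all-zero distance
    matrix cannot be resolved; callers should check before.
    """
    dm = _distance_matrix(matrix, metric)
    tree = nj(dm)
    tree.prune()  # drop zero-degree artifacts if any
    return tree


def bipartitions(tree: TreeNode, taxa) -> set[frozenset]:
    """Internal bipartitions of an (unrooted) tree, each canonicalised as
    the tip set on the side not containing the first taxon."""
    taxa = list(taxa)
    ref = taxa[0]
    full = frozenset(taxa)
    splits = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(clade) > len(taxa) - 2:
            continue
        side = full - clade if ref in clade else clade
        splits.add(side)
    return splits


def nj_bootstrap(
    matrix: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    metric: str = "hamming",
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ dendrogram with column-bootstrap supports.

    Mutations (columns) are resampled with replacement ``n_boot`` times;
    the support of each internal bipartition of the observed tree is the
    percent of replicate trees containing it. Supports are written into
    the internal node names of the returned tree. An all-zero distance
    matrix yields a star — flagged by raising ``ValueError``.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 organs for a dendrogram")
    dm = _distance_matrix(matrix, metric)
    if np.allclose(dm.data, 0):
        raise ValueError("all organs identical: star tree, supports undefined")
    tree = nj_tree(matrix, metric)
    taxa = list(matrix.index)
    observed = bipartitions(tree, taxa)
    counts = {bp: 0 for bp in observed}
    rng = np.random.default_rng(seed)
    n_mut = matrix.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_mut, size=n_mut)
        boot = matrix.iloc[:, cols]
        bt = nj_tree(boot, metric)
        found = bipartitions(bt, taxa)
        for bp in observed:
            if bp in found:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_boot for bp, c in counts.items()}
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        full = frozenset(taxa)
        side = clade if taxa[0] not in clade else full - clade
        if side in supports:
            node.name = f"{supports[side]:.0f}"
    return tree, supports


def petal_sharing_counts(sharing: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Count petal sharing events by partner category.

    For every (mutation, petal) pair where the petal carries the
    mutation, one event is counted per partner category present among the
    other carriers: shared with >=1 stamen, with >=1 sepal, with >=1
    other petal. Organ types come from the metadata ``organ`` column
    keyed by organ unit.
    """
    organ_of = {}
    for unit in sharing.index:
        rows = metadata[metadata["organ_unit"] == unit]
        organ_of[unit] = rows["organ"].iloc[0] if len(rows) else unit.rstrip("0123456789")
    counts = {"petal_stamen": 0, "petal_sepal": 0, "petal_petal": 0}
    for mut in sharing.columns:
        carriers = sharing.index[sharing[mut] == 1]
        petals = [u for u in carriers if organ_of[u] == "petal"]
        for p in petals:
            others = [u for u in carriers if u != p]
            kinds = {organ_of[u] for u in others}
            if "stamen" in kinds:
                counts["petal_stamen"] += 1
            if "sepal" in kinds:
                counts["petal_sepal"] += 1
            if "petal" in kinds:
                counts["petal_petal"] += 1
    return counts


def petal_sharing_chisq(counts) -> dict:
    """Chi-square of petal sharing events against a uniform expectation.

    ``counts`` is the (petal–stamen, petal–sepal, petal–petal) event
    triple (or the dict from :func:`petal_sharing_counts`). The null
    distributes the total evenly over the three categories; df = 2 and
    the p-value is the upper tail of the chi-square distribution.
    """
    if isinstance(counts, dict):
        counts = (counts["petal_stamen"], counts["petal_sepal"], counts["petal_petal"])
    obs = np.asarray(counts, dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if obs.sum() == 0:
        raise ValueError("all-zero counts: no sharing events to test")
    chi2, p = stats.chisquare(obs)
    return {"chi2": float(chi2), "df": len(obs) - 1, "p": float(p),
            "counts": tuple(int(c) for c in obs)}
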