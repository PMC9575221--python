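"""Spot annotation and near / far classification of cell-type pairs.

Spots are labeled with the cell type of largest deconvolution proportion.
The spatial distance between two cell types is the symmetrized mean of
minimum Euclidean distances between their spot sets,

    ct_distance(a, b) = ( mean_i min_j d(a_i, b_j) + mean_j min_i d(b_j, a_i) ) / 2,

and the resulting pair distances are partitioned into near / medium / far
with 1-D k-means (k=3), labeled in ascending order of cluster mean.  Because
distance scales differ between slides, no absolute thresholds are used.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "SpotAnnotation",
    "CellTypePair",
    "annotate_spots",
    "pair_distance",
    "all_pair_distances",
    "classify_pairs",
    "pairs_frame",
]

logger = logging.getLogger(__name__)


class UnassignedSpotError(ValueError):
    pass


class MissingCellTypeError(KeyError):
    pass


@dataclass
class SpotAnnotation:
    """Hard cell-type labels per spot, optionally with the proportions."""

    spot_ids: list[str]
    labels: list[str]
    proportions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.spot_ids):
            raise ValueError("one label per spot required")
        if self.proportions is not None and (self.proportions.values < 0).any():
            raise ValueError("proportions must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.labels))

    def spots_of(self, cell_type: str) -> np.ndarray:
        mask = np.asarray([lab == cell_type for lab in self.labels])
        if not mask.any():
            raise MissingCellTypeError(cell_type)
        return mask


def annotate_spots(proportions: pd.DataFrame) -> SpotAnnotation:
    """Label each spot with its argmax-proportion cell type.

    ``proportions`` is spot x cell-type (index = spot ids).  Ties break to
    the lexicographically first cell type; all-zero rows are an error.
    """
    if proportions.shape[1] < 1:
        raise ValueError("at least one cell-type column required")
    if (proportions.values < 0).any():
        raise ValueError("proportions must be non-negative")
    zero_rows = proportions.index[(proportions.values <= 0).all(axis=1)]
    if len(zero_rows):
        raise UnassignedSpotError(
            f"spots with all-zero proportions cannot be annotated: {list(zero_rows)}"
        )
    ordered = proportions[sorted(proportions.columns)]
    labels = ordered.idxmax(axis=1)  # first (lexicographic) column wins ties
    return SpotAnnotation(
        spot_ids=[str(s) for s in proportions.index],
        labels=[str(l) for l in labels],
        proportions=proportions,
    )


@dataclass
class CellTypePair:
    """Unordered cell-type pair with its slide distance and class."""

    type_a: str
    type_b: str
    distance: float
    pair_class: Literal["near", "medium", "far"] = "medium"

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.type_a, self.type_b)))


def pair_distance(
    ann: SpotAnnotation, coords: np.ndarray, type_a: str, type_b: str
) -> float:
    """Symmetrized mean-of-minimum Euclidean distance between two types."""
    coords = np.asarray(coords, dtype=float)
    xa = coords[ann.spots_of(type_a)]
    xb = coords[ann.spots_of(type_b)]
    D = cdist(xa, xb)
    return 0.5 * (D.min(axis=1).mean() + D.min(axis=0).mean())


def all_pair_distances(
    ann: SpotAnnotation, coords: np.ndarray, cell_types: Sequence[str] | None = None
) -> list[CellTypePair]:
    """Distances for every unordered pair of (distinct) cell types."""
    types = list(cell_types) if cell_types is not None else ann.cell_types
    return [
        CellTypePair(a, b, pair_distance(ann, coords, a, b))
        for a, b in itertools.combinations(sorted(types), 2)
    ]


def _kmeans_1d_exact(values: np.ndarray, k: int) -> np.ndarray:
    """Optimal 1-D k-means by dynamic programming over sorted values.

    In one dimension the optimal clustering is a partition of the sorted
    sequence into contiguous blocks, which dynamic programming finds exactly;
    this removes any dependence on initialization.
    """
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = len(x)
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def block_cost(i: int, j: int) -> float:
        # sum of squared deviations of x[i:j] from its mean
        s = pref[j] - pref[i]
        s2 = pref2[j] - pref2[i]
        return s2 - s * s / (j - i)

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + block_cost(i, j)
                if v < best - 1e-15:
                    best, arg = v, i
            cost[c, j] = best
            split[c, j] = arg
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for c in range(k, 0, -1):
        i = split[c, j]
        labels_sorted[i:j] = c - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def classify_pairs(
    pairs: Sequence[CellTypePair],
    seed: int = 0,
    exact_max_n: int = 50,
) -> list[CellTypePair]:
    """Partition pair distances into near / medium / far (k=3).

    Uses the exact dynamic-programming 1-D k-means when the pair count is at
    most ``exact_max_n`` (guaranteeing a deterministic optimum), otherwise
    sklearn's k-means with 10 seeded restarts.  Clusters are labeled near,
    medium, far in ascending order of their mean distance.  With fewer than
    3 pairs a tertile split over the sorted distances is used instead; if
    every distance is identical all pairs are labeled medium.
    """
    pairs = list(pairs)
    if not pairs:
        return []
    d = np.asarray([p.distance for p in pairs], dtype=float)

    if np.allclose(d, d[0]):
        if len(pairs) > 1:
            warnings.warn("all cell-type pairs equidistant; labeling all medium")
        return [replace(p, pair_class="medium") for p in pairs]

    class_names = ("near", "medium", "far")
    if len(pairs) < 3:
        logger.warning("fewer than 3 pairs; falling back to a tertile split")
        order = np.argsort(d, kind="stable")
        out = [None] * len(pairs)
        for rank, idx in enumerate(order):
            # 2 pairs -> near and far; 1 pair -> near
            cls = class_names[0] if rank == 0 else class_names[2]
            out[idx] = replace(pairs[idx], pair_class=cls)
        return out

    if len(pairs) <= exact_max_n:
        labels = _kmeans_1d_exact(d, 3)
    else:
        km = KMeans(n_clusters=3, n_init=10, random_state=seed)
        labels = km.fit_predict(d[:, None])

    cluster_means = {lab: d[labels == lab].mean() for lab in np.unique(labels)}
    ordered = sorted(cluster_means, key=cluster_means.get)
    name_of = {lab: class_names[i] for i, lab in enumerate(ordered)}
    return [replace(p, pair_class=name_of[lab]) for p, lab in zip(pairs, labels)]


def pairs_frame(pairs: Sequence[CellTypePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "type_a": [p.type_a for p in pairs],
            "type_b": [p.type_b for p in pairs],
            "distance": [p.distance for p in pairs],
            "pair_class": [p.pair_class for p in pairs],
        }
    )
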