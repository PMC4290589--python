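"""Performance-class assignment via 1-D K-means.

Each axis (running time, memory, quality) carries one score per assembler
— by default the mean rank across datasets — and a best-to-worst label
vocabulary. K-means partitions the scores; the cluster with the best
(lowest) center takes the first label, and so on.

Initialization is deterministic: a quantile seeding (centers at the
(2i-1)/(2k) quantiles) competes on inertia with a fixed-seed batch of
random restarts, so repeated runs agree and local optima of Lloyd's
algorithm — common on one-dimensional data — are escaped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

#: Default axis vocabularies, best class first.
DEFAULT_VOCAB = {
    "time": ("fastest", "medium-fast", "slow"),
    "memory": (
        "most memory-efficient",
        "memory-efficient",
        "less memory-efficient",
        "memory-inefficient",
    ),
    "quality": (
        "high-quality",
        "high medium-quality",
        "medium-quality",
        "low quality",
    ),
}


@dataclass(frozen=True)
class AxisProfile:
    """Per-assembler scores on one axis plus the class vocabulary."""

    axis: str
    scores: Mapping[str, float]
    label_vocab: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.label_vocab) > len(self.scores):
            raise ValueError(
                f"axis {self.axis!r}: k={len(self.label_vocab)} exceeds"
                f" the {len(self.scores)} assemblers"
            )

    @property
    def k(self) -> int:
        return len(self.label_vocab)


@dataclass(frozen=True)
class ClassAssignment:
    """Class label per assembler on one axis, with the cluster centers."""

    axis: str
    labels: Mapping[str, str]
    centers: tuple[float, ...]
    flagged: tuple[str, ...] = ()


def _quantile_centers(values: np.ndarray, k: int) -> np.ndarray:
    qs = (2 * np.arange(1, k + 1) - 1) / (2 * k)
    centers = np.quantile(values, qs)
    # collapse accidental duplicates onto distinct sorted values so KMeans
    # keeps k clusters
    if len(np.unique(centers)) < k:
        centers = np.unique(values)[
            np.linspace(0, len(np.unique(values)) - 1, k).round().astype(int)
        ]
    return centers.reshape(-1, 1)


def cluster_1d(
    values: Sequence[float],
    k: int,
    seed: int | None = None,
    n_restarts: int = 100,
) -> tuple[list[int], list[float]]:
    """K-means on 1-D data, quantile init plus seeded random restarts.

    The deterministic quantile initialization competes on inertia with
    ``n_restarts`` random-point restarts (seeded, so runs are reproducible;
    ``seed=None`` behaves as seed 0). Lloyd's algorithm can stall in local
    optima on 1-D data, so restarts matter even at small n. Returns
    cluster indices (re-indexed so centers ascend) and the sorted centers.

    Raises
    ------
    ValueError
        If k exceeds the number of distinct values.
    """
    arr = np.asarray(values, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(arr))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct values")
    X = arr.reshape(-1, 1)

    km = KMeans(n_clusters=k, init=_quantile_centers(arr, k), n_init=1)
    km.fit(X)
    if n_restarts > 0:
        # random data-point init: on tiny 1-D inputs the greedy k-means++
        # candidate selection can never propose some optimal center pairs
        alt = KMeans(
            n_clusters=k,
            init="random",
            n_init=n_restarts,
            random_state=0 if seed is None else seed,
        ).fit(X)
        if alt.inertia_ < km.inertia_:
            km = alt

    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers, kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    labels = [remap[int(l)] for l in km.labels_]
    return labels, [float(c) for c in centers[order]]


def assign_axis_classes(
    profile: AxisProfile, seed: int | None = None
) -> ClassAssignment:
    """Cluster an axis's scores and map clusters to vocabulary labels.

    The cluster whose center is lowest (best mean rank) takes the first
    vocabulary label; label order follows center order.
    """
    names = list(profile.scores)
    values = [profile.scores[n] for n in names]
    idx, centers = cluster_1d(values, profile.k, seed=seed)
    labels = {n: profile.label_vocab[i] for n, i in zip(names, idx)}
    return ClassAssignment(
        axis=profile.axis, labels=labels, centers=tuple(centers)
    )
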