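"""Mapper graph construction on symptom vectors.

The pipeline is the classical Mapper recipe: a metric on the 30-item
symptom vectors (normalized Pearson correlation distance), a
two-dimensional PCA lens, an overlapping rectangular cover of the lens
range, single-linkage clustering of each rectangle's preimage, and the
nerve graph of the resulting clusters (two clusters are joined by an edge
iff they share at least one patient).

Cover convention
----------------
``resolution`` is the number of intervals per lens dimension; the stride
per dimension is ``(max - min) / resolution`` with interval centers at
``min + (i + 0.5) * stride``.  ``gain`` scales the interval length to
``stride * gain``, so the overlap fraction between adjacent intervals is
``1 - 1/gain`` (gain 7 gives ~85.7% overlap).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class MapperConfig:
    resolution: int = 60
    gain: float = 7.0
    lens_dims: int = 2
    distance: str = "normalized_pearson"  # or "one_minus_r" / "euclidean" (point-cloud fixtures)
    cluster_histogram_bins: int = 10
    clusterer: str = "single_linkage_gap"  # "none" -> pure nerve of the cover
    scale_items: bool = False  # z-score columns before the PCA lens

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        if self.gain <= 1:
            raise ValueError("gain must be > 1 (gain = 1 leaves zero overlap)")
        if self.cluster_histogram_bins < 2:
            raise ValueError("cluster_histogram_bins must be >= 2")
        if self.distance not in ("normalized_pearson", "one_minus_r", "euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.clusterer not in ("single_linkage_gap", "none"):
            raise ValueError(f"unknown clusterer {self.clusterer!r}")


def normalized_pearson_distance(X: np.ndarray, form: str = "normalized_pearson") -> np.ndarray:
    """Pairwise distance matrix between row vectors.

    ``normalized_pearson``: d(x, y) = sqrt(2 (1 - r(x, y))) — the Euclidean
    metric on z-scored rows (up to a global scale), hence a true metric.
    ``one_minus_r``: d = 1 - r, kept for comparison; not a metric.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-d matrix with >= 2 columns")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(
            f"constant symptom vectors (zero variance) for row(s) {bad.tolist()}; "
            "correlation distance is undefined"
        )
    R = np.corrcoef(X)
    R = np.clip(R, -1.0, 1.0)
    if form == "normalized_pearson":
        D = np.sqrt(np.maximum(2.0 * (1.0 - R), 0.0))
    elif form == "one_minus_r":
        D = 1.0 - R
    else:
        raise ValueError(f"unknown distance form {form!r}")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def pca_lens(X: np.ndarray, dims: int = 2, scale: bool = False) -> np.ndarray:
    """Project rows onto the top principal components.

    Columns are centered (optionally z-scored); the sign of each component
    is fixed so its largest-magnitude loading is positive, making the lens
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} rows for a {dims}-dim lens")
    Xc = X - X.mean(axis=0)
    if scale:
        col_sd = Xc.std(axis=0)
        col_sd[col_sd == 0] = 1.0
        Xc = Xc / col_sd
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[dims - 1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError(f"data rank < {dims}: cannot build a {dims}-dim PCA lens")
    V = Vt[:dims]
    for j in range(dims):
        i = np.argmax(np.abs(V[j]))
        if V[j, i] < 0:
            V[j] = -V[j]
    return Xc @ V.T


@dataclass
class Cover:
    """Overlapping axis-aligned rectangular cover of the lens range."""

    centers: list[np.ndarray]  # per dimension, `resolution` interval centers
    lengths: np.ndarray  # per dimension, interval length
    rectangles: dict[int, np.ndarray] = field(default_factory=dict)  # rect id -> member indices
    shape: tuple[int, ...] = ()

    def n_rectangles(self) -> int:
        return int(np.prod(self.shape))


def build_cover(lens: np.ndarray, resolution: int, gain: float) -> Cover:
    """Cover the lens range with overlapping rectangles and assign points.

    Each point belongs to every rectangle whose closed interval product
    contains it; the closed intervals make points on the range maximum fall
    in the last interval.  A dimension with zero spread collapses to a
    single full-range interval (logged).
    """
    lens = np.atleast_2d(np.asarray(lens, dtype=float))
    if lens.ndim != 2:
        raise ValueError("lens must be an n x d matrix")
    if not np.all(np.isfinite(lens)):
        raise ValueError("lens contains non-finite values")
    n, d = lens.shape
    centers: list[np.ndarray] = []
    lengths = np.empty(d)
    dim_masks: list[np.ndarray] = []  # per dim: resolution x n boolean
    shape = []
    for j in range(d):
        lo, hi = lens[:, j].min(), lens[:, j].max()
        if hi == lo:
            logger.warning("lens dimension %d is constant; using a single interval", j)
            centers.append(np.array([lo]))
            lengths[j] = 1.0
            dim_masks.append(np.ones((1, n), dtype=bool))
            shape.append(1)
            continue
        stride = (hi - lo) / resolution
        cj = lo + (np.arange(resolution) + 0.5) * stride
        length = stride * gain
        centers.append(cj)
        lengths[j] = length
        low = cj[:, None] - length / 2.0
        high = cj[:, None] + length / 2.0
        dim_masks.append((lens[None, :, j] >= low) & (lens[None, :, j] <= high))
        shape.append(resolution)

    cover = Cover(centers=centers, lengths=lengths, shape=tuple(shape))
    for flat, idx in enumerate(itertools.product(*(range(s) for s in shape))):
        mask = dim_masks[0][idx[0]]
        for j in range(1, d):
            mask = mask & dim_masks[j][idx[j]]
        members = np.flatnonzero(mask)
        if members.size:
            cover.rectangles[flat] = members
    return cover


def cluster_preimage(members: np.ndarray, distances: np.ndarray, bins: int = 10) -> list[np.ndarray]:
    """Partition one rectangle's preimage by single linkage.

    The dendrogram is cut at the left edge of the first empty histogram
    bin following a nonempty one, in a `bins`-bin histogram of merge
    heights over [0, max height] — the gap heuristic of the classical
    Mapper formulation (a gap in the merge-height distribution separates
    the within-cluster scale from the between-cluster scale).  Leading
    empty bins are ignored: on discrete ordinal data the smallest merge
    heights are bounded away from zero, and cutting below them would
    shatter every preimage into singletons.  With no gap all members form
    one cluster.
    """
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("empty member set")
    if members.size == 1:
        return [members.copy()]
    sub = distances[np.ix_(members, members)]
    Z = linkage(squareform(sub, checks=False), method="single")
    heights = Z[:, 2]
    hmax = heights.max()
    if hmax <= 0:
        return [members.copy()]
    counts, edges = np.histogram(heights, bins=bins, range=(0.0, hmax))
    first_nonempty = np.flatnonzero(counts > 0)[0]
    empty_after = np.flatnonzero((counts == 0) & (np.arange(bins) > first_nonempty))
    if empty_after.size == 0:
        return [members.copy()]
    threshold = edges[empty_after[0]]
    labels = fcluster(Z, t=threshold * (1 - 1e-12), criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        clusters.append(members[labels == lab])
    # deterministic order: by smallest member index
    clusters.sort(key=lambda c: int(c.min()))
    return clusters


def build_mapper_graph(
    X: np.ndarray,
    config: MapperConfig | None = None,
    patient_ids: np.ndarray | None = None,
) -> nx.Graph:
    """Full Mapper pipeline: distance -> lens -> cover -> clustering -> nerve.

    Nodes are ``(rectangle_id, cluster_rank)`` tuples carrying the member
    index set; edges carry the shared-member count.  Empty rectangles
    produce no node.
    """
    config = config or MapperConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    graph = nx.Graph(n_patients=n)
    if n == 1:
        graph.add_node((0, 0), members=frozenset([0]), rectangle=0)
        if patient_ids is not None:
            graph.nodes[(0, 0)]["patient_ids"] = frozenset({str(patient_ids[0])})
        return graph

    if config.distance == "euclidean":
        from scipy.spatial.distance import cdist

        D = cdist(X, X)
    else:
        D = normalized_pearson_distance(X, form=config.distance)
    dims = min(config.lens_dims, n - 1)
    lens = pca_lens(X, dims=dims, scale=config.scale_items)
    cover = build_cover(lens, config.resolution, config.gain)

    containing: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for rect_id in sorted(cover.rectangles):
        members = cover.rectangles[rect_id]
        if config.clusterer == "none":
            clusters = [members]
        else:
            clusters = cluster_preimage(members, D, bins=config.cluster_histogram_bins)
        for rank, cluster in enumerate(clusters):
            node = (rect_id, rank)
            data = {"members": frozenset(int(i) for i in cluster), "rectangle": rect_id}
            if patient_ids is not None:
                data["patient_ids"] = frozenset(str(patient_ids[i]) for i in cluster)
            graph.add_node(node, **data)
            for i in cluster:
                containing[int(i)].append(node)

    shared: dict[tuple, int] = {}
    for nodes in containing:
        for a, b in itertools.combinations(nodes, 2):
            key = (a, b) if a <= b else (b, a)
            shared[key] = shared.get(key, 0) + 1
    for (a, b), count in shared.items():
        graph.add_edge(a, b, shared=count)
    return graph


def nerve_edges(graph: nx.Graph) -> set[frozenset]:
    """Recompute the nerve from node member sets (verification helper)."""
    nodes = list(graph.nodes(data="members"))
    edges = set()
    for (a, ma), (b, mb) in itertools.combinations(nodes, 2):
        if ma & mb:
            edges.add(frozenset((a, b)))
    return edges
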