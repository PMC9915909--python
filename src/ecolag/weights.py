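"""Spatial weights over regions: contiguity, knn, distance band, GAL I/O.

The default for every statistic in this package is queen contiguity
(polygons sharing at least one boundary point are neighbours),
row-standardized — the GeoDa convention.  Weights are kept as an ordered
adjacency structure so GAL files round-trip exactly; dense-matrix views
are produced on demand for the linear-algebra paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import Region


@dataclass
class SpatialWeights:
    ids: list[str]
    neighbors: dict[str, list[str]]
    weights: dict[str, list[float]]
    standardized: str = "binary"  # {"binary", "row"}

    def __post_init__(self) -> None:
        for i in self.ids:
            if i in self.neighbors.get(i, []):
                raise ValueError(f"self-neighbour at {i!r}")
        known = set(self.ids)
        for i, nbrs in self.neighbors.items():
            missing = [j for j in nbrs if j not in known]
            if missing:
                raise ValueError(f"dangling neighbour ids {missing} for {i!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def islands(self) -> list[str]:
        return [i for i in self.ids if not self.neighbors.get(i)]

    def to_dense(self, include_self: float | None = None) -> np.ndarray:
        """n x n weight matrix in id order; optionally add ``include_self``
        on the diagonal (used by Gi*, which counts the unit itself)."""
        idx = {r: k for k, r in enumerate(self.ids)}
        W = np.zeros((self.n, self.n))
        for i in self.ids:
            for j, w in zip(self.neighbors.get(i, []), self.weights.get(i, [])):
                W[idx[i], idx[j]] = w
        if include_self is not None:
            np.fill_diagonal(W, include_self)
        return W

    def s0(self) -> float:
        return float(sum(sum(ws) for ws in self.weights.values()))


def _from_adjacency(ids: list[str], adj: dict[str, list[str]]) -> SpatialWeights:
    w = SpatialWeights(
        ids=list(ids),
        neighbors={i: list(adj.get(i, [])) for i in ids},
        weights={i: [1.0] * len(adj.get(i, [])) for i in ids},
        standardized="binary",
    )
    if w.islands:
        warnings.warn(f"isolated units (no neighbours): {w.islands}", stacklevel=3)
    return w


def queen_contiguity(regions: list[Region]) -> SpatialWeights:
    """Queen contiguity: i, j neighbours iff their boundaries share >= 1
    point.  Binary and symmetric; isolates trigger a warning."""
    for r in regions:
        if r.geometry is None:
            raise ValueError(f"region {r.id!r} has no geometry")
    ids = [r.id for r in regions]
    adj: dict[str, list[str]] = {i: [] for i in ids}
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            if regions[a].geometry.intersects(regions[b].geometry):
                adj[ids[a]].append(ids[b])
                adj[ids[b]].append(ids[a])
    return _from_adjacency(ids, adj)


def rook_contiguity(regions: list[Region]) -> SpatialWeights:
    """Rook contiguity: neighbours must share a boundary of positive length
    (a shared corner point is not enough)."""
    for r in regions:
        if r.geometry is None:
            raise ValueError(f"region {r.id!r} has no geometry")
    ids = [r.id for r in regions]
    adj: dict[str, list[str]] = {i: [] for i in ids}
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            inter = regions[a].geometry.intersection(regions[b].geometry)
            if inter.length > 0:
                adj[ids[a]].append(ids[b])
                adj[ids[b]].append(ids[a])
    return _from_adjacency(ids, adj)


def knn_weights(regions: list[Region], k: int) -> SpatialWeights:
    """k-nearest-neighbour weights from polygon centroids (asymmetric in
    general; k = n-1 gives the complete graph)."""
    if not 1 <= k <= len(regions) - 1:
        raise ValueError(f"k must be in [1, n-1], got {k}")
    pts = np.array([[r.geometry.centroid.x, r.geometry.centroid.y] for r in regions])
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    ids = [r.id for r in regions]
    adj = {ids[i]: [ids[j] for j in np.argsort(d[i], kind="stable")[:k]]
           for i in range(len(ids))}
    return _from_adjacency(ids, adj)


def distance_band(regions: list[Region], threshold: float) -> SpatialWeights:
    """Neighbours are all units whose centroids lie within ``threshold``."""
    pts = np.array([[r.geometry.centroid.x, r.geometry.centroid.y] for r in regions])
    d = cdist(pts, pts)
    ids = [r.id for r in regions]
    adj = {ids[i]: [ids[j] for j in range(len(ids))
                    if j != i and d[i, j] <= threshold]
           for i in range(len(ids))}
    return _from_adjacency(ids, adj)


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Scale each non-isolated row to sum 1; isolates stay empty rows."""
    new_weights = {}
    for i in w.ids:
        ws = w.weights.get(i, [])
        s = sum(ws)
        new_weights[i] = [v / s for v in ws] if s > 0 else []
    return SpatialWeights(ids=list(w.ids),
                          neighbors={i: list(w.neighbors.get(i, [])) for i in w.ids},
                          weights=new_weights, standardized="row")


# ---------------------------------------------------------------------------
# GAL: header "<n>", then per unit "<id> <k>" followed by the k neighbour ids.

def write_gal(w: SpatialWeights, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{w.n}\n")
        for i in w.ids:
            nbrs = w.neighbors.get(i, [])
            fh.write(f"{i} {len(nbrs)}\n")
            fh.write(" ".join(nbrs) + "\n")


def read_gal(path) -> SpatialWeights:
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh]
    lines = [t for t in tokens_by_line if t]
    if not lines:
        raise ValueError(f"{path}: empty GAL file")
    # header may be "n" or the GeoDa 4-token variant; unit count is the
    # last purely-numeric token of the first line
    n = int(lines[0][-1]) if lines[0][-1].isdigit() else int(lines[0][0])
    ids: list[str] = []
    adj: dict[str, list[str]] = {}
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh][1:]
    k = 0
    while k < len(raw):
        head = raw[k].split()
        if not head:
            k += 1
            continue
        rid, deg = head[0], int(head[1])
        if deg == 0:
            ids.append(rid)
            adj[rid] = []
            # an isolate may or may not carry its (empty) neighbour line
            k += 2 if k + 1 < len(raw) and not raw[k + 1].split() else 1
            continue
        nbrs = raw[k + 1].split()
        if len(nbrs) != deg:
            raise ValueError(f"{path}: {rid!r} declares {deg} neighbours, "
                             f"line has {len(nbrs)}")
        ids.append(rid)
        adj[rid] = nbrs
        k += 2
    if len(ids) != n:
        raise ValueError(f"{path}: header count {n} != {len(ids)} unit records")
    return _from_adjacency(ids, adj)
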