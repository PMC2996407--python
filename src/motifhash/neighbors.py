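"""Fixed-radius neighbor queries from precomputed 2r neighbor lists.

Match augmentation repeatedly asks for all target residues within r of an
*arbitrary* point (an aligned motif position).  With per-residue neighbor
lists precomputed at radius 2r, one nearest-neighbor search suffices: if the
nearest residue to the query point q is x away (x ≤ r, else the answer is
empty), every residue within r of q lies within r + x ≤ 2r of that residue.
Members of its list closer than r - x are accepted outright; those in the
[r - x, r + x] band are distance-checked against q.  The result is exact for
any r up to half the precomputed radius.

The single nearest-neighbor search uses a uniform spatial grid with cell size
2r; any exact structure satisfies the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NeighborLists", "precompute_neighbor_lists", "range_query"]

DEFAULT_RADIUS = 7.0  # ε; lists are precomputed at 2ε = 14 Å


@dataclass
class NeighborLists:
    radius_2r: float
    # per residue: ascending-distance arrays of neighbor indices and distances
    indices: list  # list[np.ndarray[int]]
    distances: list  # list[np.ndarray[float]]
    _grid: dict = field(default_factory=dict, repr=False)
    _cell: float = 0.0

    def to_flat(self):
        """(offsets, indices, distances) flattening for serialization."""
        offsets = np.zeros(len(self.indices) + 1, dtype=np.int64)
        for i, idx in enumerate(self.indices):
            offsets[i + 1] = offsets[i] + len(idx)
        cat_i = (
            np.concatenate(self.indices) if self.indices else np.empty(0, np.int64)
        ).astype(np.int64)
        cat_d = (
            np.concatenate(self.distances) if self.distances else np.empty(0, float)
        )
        return offsets, cat_i, cat_d

    @classmethod
    def from_flat(cls, radius_2r, offsets, cat_i, cat_d):
        idx = [cat_i[offsets[i]:offsets[i + 1]] for i in range(len(offsets) - 1)]
        dst = [cat_d[offsets[i]:offsets[i + 1]] for i in range(len(offsets) - 1)]
        return cls(radius_2r=float(radius_2r), indices=idx, distances=dst)


def precompute_neighbor_lists(target, r: float = DEFAULT_RADIUS) -> NeighborLists:
    """Exact per-residue neighbor lists at radius 2r, ascending distance."""
    if r <= 0:
        raise ValueError("radius r must be > 0")
    ca = target.ca_coords
    n = len(ca)
    radius = 2.0 * r
    diff = ca[:, None, :] - ca[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    indices, distances = [], []
    for i in range(n):
        within = np.flatnonzero(dist[i] <= radius)
        order = np.argsort(dist[i][within], kind="stable")
        indices.append(within[order].astype(np.int64))
        distances.append(dist[i][within][order])
    return NeighborLists(radius_2r=radius, indices=indices, distances=distances)


def _build_grid(lists: NeighborLists, ca: np.ndarray):
    cell = lists.radius_2r
    grid: dict = {}
    keys = np.floor(ca / cell).astype(np.int64)
    for i, k in enumerate(map(tuple, keys)):
        grid.setdefault(k, []).append(i)
    lists._grid = grid
    lists._cell = cell


def _nearest_residue(lists: NeighborLists, ca: np.ndarray, q: np.ndarray):
    """Exact nearest residue to q via an expanding uniform-grid search."""
    if not lists._grid:
        _build_grid(lists, ca)
    cell = lists._cell
    grid = lists._grid
    cq = tuple(np.floor(q / cell).astype(np.int64))
    best_i, best_d = -1, np.inf
    ring = 0
    while True:
        for dx in range(-ring, ring + 1):
            for dy in range(-ring, ring + 1):
                for dz in range(-ring, ring + 1):
                    if max(abs(dx), abs(dy), abs(dz)) != ring:
                        continue
                    bucket = grid.get((cq[0] + dx, cq[1] + dy, cq[2] + dz))
                    if not bucket:
                        continue
                    pts = ca[bucket]
                    d = np.linalg.norm(pts - q, axis=1)
                    j = int(np.argmin(d))
                    if d[j] < best_d:
                        best_d = float(d[j])
                        best_i = bucket[j]
        # Unscanned cells (Chebyshev ring ≥ ring+1) hold no point closer than
        # ring*cell, so stop once the incumbent beats that bound.
        if best_i >= 0 and best_d <= ring * cell:
            return best_i, best_d
        ring += 1


def range_query(target, lists: NeighborLists, q, r: float) -> list:
    """Indices of residues with ||ca - q|| ≤ r, exactly, via the 2r lists."""
    if r > lists.radius_2r / 2.0 + 1e-9:
        raise ValueError(
            f"query radius {r} exceeds half the precomputed radius {lists.radius_2r}"
        )
    ca = target.ca_coords
    if len(ca) == 0:
        return []
    q = np.asarray(q, dtype=float)
    near, x = _nearest_residue(lists, ca, q)
    if x > r:
        return []  # no residue can be within r of q
    out = []
    if x <= r:
        out.append(near)
    idx = lists.indices[near]
    dst = lists.distances[near]
    # accept outright below r - x; distance-check the [r - x, r + x] band
    lo = r - x
    hi = r + x
    for j, d in zip(idx, dst):
        if d > hi:
            break  # ascending order: nothing further can qualify
        if d < lo:
            out.append(int(j))
        elif np.linalg.norm(ca[j] - q) <= r:
            out.append(int(j))
    return sorted(out)
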