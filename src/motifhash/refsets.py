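"""Enumeration of geometrically valid residue n-tuples ("reference sets").

A reference set is an n-tuple of residues (n = 3 by default) that is compact
and near the protein surface:

1. each Cα lies within ``d_maxmindist`` of its nearest other Cα in the tuple;
2. all pairwise Cα distances are strictly below ``d_diameter``;
3. every residue is within ``d_maxdepth`` of the molecular surface;
4. at least one residue is within ``d_maxmindepth`` of the surface.

Reference sets are stored as unordered combinations, keyed by the sorted
tuple of their one-letter residue labels; orderings are resolved at match
time.  Defaults follow the published parameterization (16 / 25 / 3.1 / 1.6 Å,
n = 3), chosen so that typical catalytic-site motifs contain at least one
valid reference set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "GeometricParams",
    "ReferenceSet",
    "label_key",
    "is_valid_reference_set",
    "enumerate_reference_sets",
]


@dataclass(frozen=True)
class GeometricParams:
    n: int = 3
    d_maxmindist: float = 16.0
    d_diameter: float = 25.0
    d_maxdepth: float = 3.1
    d_maxmindepth: float = 1.6
    check_depth: bool = True  # False disables constraints 3 & 4 (testing / no depth data)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("reference-set size n must be ≥ 2")
        for name in ("d_maxmindist", "d_diameter", "d_maxdepth", "d_maxmindepth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.d_maxmindepth > self.d_maxdepth:
            raise ValueError("d_maxmindepth must not exceed d_maxdepth")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "d_maxmindist": self.d_maxmindist,
            "d_diameter": self.d_diameter,
            "d_maxdepth": self.d_maxdepth,
            "d_maxmindepth": self.d_maxmindepth,
            "check_depth": self.check_depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeometricParams":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass(frozen=True)
class ReferenceSet:
    target_id: str
    residue_indices: tuple  # ascending internal indices, length n
    key: tuple  # sorted one-letter labels, length n


def label_key(labels, n: int | None = None) -> tuple:
    """Sorted copy of an n-tuple of one-letter labels (order-independent key)."""
    key = tuple(sorted(labels))
    if n is not None and len(key) != n:
        raise ValueError(f"label key must have arity {n}, got {len(key)}")
    return key


def _pairwise_ok(ca: np.ndarray, params: GeometricParams) -> bool:
    """Constraints 1 (nearest-neighbor ≤ d_maxmindist) and 2 (diameter <)."""
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    n = len(ca)
    if (d >= params.d_diameter)[np.triu_indices(n, 1)].any():
        return False
    np.fill_diagonal(d, np.inf)
    return bool((d.min(axis=1) <= params.d_maxmindist).all())


def _depth_ok(depths: np.ndarray, params: GeometricParams) -> bool:
    """Constraints 3 (all ≤ d_maxdepth) and 4 (min ≤ d_maxmindepth)."""
    if not params.check_depth:
        return True
    return bool((depths <= params.d_maxdepth).all() and depths.min() <= params.d_maxmindepth)


def is_valid_reference_set(residues, params: GeometricParams | None = None) -> bool:
    """Whether n residues of one target form a valid reference set."""
    params = params or GeometricParams()
    if len(residues) != params.n:
        raise ValueError(f"expected {params.n} residues, got {len(residues)}")
    ca = np.array([r.ca for r in residues], dtype=float)
    depths = np.array([r.depth for r in residues], dtype=float)
    return _pairwise_ok(ca, params) and _depth_ok(depths, params)


def enumerate_reference_sets(target, params: GeometricParams | None = None):
    """All valid n-combinations of a target's residues, in ascending index order.

    Candidate tuples are pruned with a distance matrix (only residues within
    d_diameter of each other can co-occur), which must remain set-equal to the
    brute-force scan over all combinations.
    """
    params = params or GeometricParams()
    n_res = len(target.residues)
    if n_res < params.n:
        return []
    ca = target.ca_coords
    depths = target.depths
    labels = [r.label for r in target.residues]

    dist = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    close = dist < params.d_diameter  # necessary condition for co-membership

    depth_pass = (depths <= params.d_maxdepth) if params.check_depth else np.ones(n_res, bool)
    shallow = (depths <= params.d_maxmindepth) if params.check_depth else np.ones(n_res, bool)

    out = []
    candidates = np.flatnonzero(depth_pass)
    cand_set = set(candidates.tolist())
    for combo in _pruned_combinations(candidates, close, params.n, cand_set):
        idx = np.array(combo)
        sub = dist[np.ix_(idx, idx)]
        if (sub.min(axis=1) > params.d_maxmindist).any():
            continue
        if params.check_depth and not shallow[idx].any():
            continue
        out.append(
            ReferenceSet(
                target_id=target.target_id,
                residue_indices=tuple(combo),
                key=label_key(labels[i] for i in idx),
            )
        )
    return out


def _pruned_combinations(candidates, close, n, cand_set):
    """Ascending index n-tuples whose members are pairwise within d_diameter."""
    if n == 3:
        # the common case, unrolled for speed
        for a in candidates:
            nb = [b for b in np.flatnonzero(close[a]) if b > a and b in cand_set]
            for i, b in enumerate(nb):
                close_b = close[b]
                for c in nb[i + 1:]:
                    if close_b[c]:
                        yield (int(a), int(b), int(c))
        return
    for combo in combinations([int(c) for c in candidates], n):
        ok = all(close[a, b] for a, b in combinations(combo, 2))
        if ok:
            yield combo
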