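"""Motif matching by seeded depth-first match augmentation.

A motif is an ordered set of residue points (Cα coordinates with allowed
residue labels).  Matching proceeds in two steps: seed reference sets of the
motif are looked up in the label table (rarest label keys first, capped at
``max_seed_refsets``), and each seed correspondence is grown one motif point
at a time.  Every augmentation re-optimizes the rigid superposition; partial
matches whose RMSD exceeds ε are rejected.  Candidate residues for the next
motif point are taken from a fixed-radius neighbor query around the aligned
motif position, so residues added during augmentation are *not* subject to
the reference-set geometric constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations, permutations, product

import numpy as np

from .neighbors import NeighborLists, range_query
from .refsets import GeometricParams, label_key
from .superposition import apply_alignment, optimal_superposition

__all__ = [
    "MotifPoint",
    "Motif",
    "MotifRefSet",
    "MatchOptions",
    "Match",
    "MatchResults",
    "UnmatchableMotifError",
    "motif_reference_sets",
    "rank_seed_reference_sets",
    "resolve_correspondences",
    "augment_match",
    "match_motif",
    "select_best_per_target",
]


class UnmatchableMotifError(ValueError):
    """Motif has no valid reference set, so no seed lookup is possible."""


@dataclass(frozen=True)
class MotifPoint:
    res_id: tuple  # (chain, seq_number, insertion_code) in the source structure
    ca: tuple  # 3-vector, Å
    allowed_labels: frozenset
    sidechain_centroid: tuple | None = None

    def __post_init__(self):
        if not self.allowed_labels:
            raise ValueError(f"motif point {self.res_id} has no allowed labels")


@dataclass(frozen=True)
class Motif:
    motif_id: str
    source_structure: str
    points: tuple  # tuple[MotifPoint]

    def __post_init__(self):
        ids = [p.res_id for p in self.points]
        if len(set(ids)) != len(ids):
            raise ValueError("motif point identities must be unique")

    @property
    def m(self) -> int:
        return len(self.points)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([p.ca for p in self.points], dtype=float).reshape(-1, 3)

    @property
    def has_centroids(self) -> bool:
        return all(p.sidechain_centroid is not None for p in self.points)


@dataclass(frozen=True)
class MotifRefSet:
    point_indices: tuple  # ascending motif point indices, length n
    keys: tuple  # sorted tuple of induced sorted label keys
    allowed: tuple = ()  # per point (same order): frozenset of allowed labels


@dataclass(frozen=True)
class MatchOptions:
    epsilon: float = 7.0
    candidate_radius: float | None = None  # None -> epsilon
    max_seed_refsets: int = 15
    keep_multiple_per_target: bool = False
    min_partial_size: int | None = None
    rmsd_weight: float = 1.0  # partial-match score = size - rmsd_weight * rmsd
    best_match_criterion: str = "ca_rmsd"  # or "sidechain_centroid_rmsd"
    augmentation_order: str = "seed_proximity"  # or "input"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.best_match_criterion not in ("ca_rmsd", "sidechain_centroid_rmsd"):
            raise ValueError(f"unknown best_match_criterion {self.best_match_criterion!r}")

    @property
    def radius(self) -> float:
        return self.epsilon if self.candidate_radius is None else self.candidate_radius


@dataclass(frozen=True)
class Match:
    target_id: str
    correspondence: tuple  # ((motif point index, target residue res_id), ...) by point index
    rmsd: float
    complete: bool
    size: int
    seed_key: tuple
    sidechain_centroid_rmsd: float | None = None

    @property
    def pair_set(self) -> frozenset:
        return frozenset(self.correspondence)

    def score(self, rmsd_weight: float = 1.0) -> float:
        """Partial-match ranking score: size - rmsd_weight * rmsd."""
        return self.size - rmsd_weight * self.rmsd


@dataclass
class MatchResults:
    motif: Motif
    options: MatchOptions
    params: GeometricParams
    per_target: dict  # target_id -> list[Match]
    targets_considered: list = field(default_factory=list)

    @property
    def matches(self) -> list:
        return [m for tid in sorted(self.per_target) for m in self.per_target[tid]]


# ---------------------------------------------------------------------------
# seeds


def motif_reference_sets(motif: Motif, params: GeometricParams | None = None):
    """All n-subsets of motif points passing the two distance constraints.

    Depth constraints do not apply to motif points (a motif carries no
    surface).  Each subset carries the deduplicated set of label keys induced
    by its points' allowed-label combinations.

    Raises UnmatchableMotifError when no subset qualifies.
    """
    params = params or GeometricParams()
    n = params.n
    if motif.m < n:
        raise UnmatchableMotifError(
            f"motif {motif.motif_id} has {motif.m} points; at least {n} required"
        )
    ca = motif.ca_coords
    out = []
    for combo in combinations(range(motif.m), n):
        sub = ca[list(combo)]
        d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
        iu = np.triu_indices(n, 1)
        if (d[iu] >= params.d_diameter).any():
            continue
        np.fill_diagonal(d, np.inf)
        if (d.min(axis=1) > params.d_maxmindist).any():
            continue
        label_sets = [sorted(motif.points[i].allowed_labels) for i in combo]
        keys = sorted({label_key(c) for c in product(*label_sets)})
        out.append(
            MotifRefSet(
                point_indices=combo,
                keys=tuple(keys),
                allowed=tuple(motif.points[i].allowed_labels for i in combo),
            )
        )
    if not out:
        raise UnmatchableMotifError(
            f"motif {motif.motif_id} contains no valid reference set under "
            f"d_maxmindist={params.d_maxmindist}, d_diameter={params.d_diameter}"
        )
    return out


def rank_seed_reference_sets(motif_refsets, table, target_filter=None):
    """Order motif reference sets by ascending total table frequency.

    Frequency is summed over each refset's induced keys; ties break on the
    key tuple, then on the motif point indices, making the order fully
    deterministic.
    """
    ranked = []
    for rs in motif_refsets:
        freq = sum(table.key_frequency(k, target_filter) for k in rs.keys)
        ranked.append((freq, rs.keys, rs.point_indices, rs))
    ranked.sort(key=lambda t: t[:3])
    return [t[3] for t in ranked]


def resolve_correspondences(motif_refset: MotifRefSet, target_index_tuple, target):
    """All bijections motif point -> target residue with compatible labels.

    Returns a list of dicts {motif point index: target residue index},
    distinct by construction (permutations of distinct indices).
    """
    pts = motif_refset.point_indices
    out = []
    for perm in permutations(target_index_tuple):
        ok = all(
            target.residues[perm[i]].label in motif_refset.allowed[i]
            for i in range(len(pts))
        )
        if ok:
            out.append(dict(zip(pts, perm)))
    return out


# ---------------------------------------------------------------------------
# augmentation


def _augment_order(motif: Motif, seed_points, options: MatchOptions):
    """Order of the remaining motif points during depth-first expansion."""
    remaining = [i for i in range(motif.m) if i not in seed_points]
    if options.augmentation_order == "input":
        return remaining
    centroid = motif.ca_coords[list(seed_points)].mean(axis=0)
    dist = np.linalg.norm(motif.ca_coords - centroid, axis=1)
    remaining.sort(key=lambda i: (dist[i], i))
    return remaining


def augment_match(
    seed_correspondence: dict,
    motif: Motif,
    target,
    lists: NeighborLists,
    options: MatchOptions | None = None,
    seed_key: tuple = (),
):
    """Depth-first expansion of a seed correspondence into full matches.

    ``seed_correspondence`` maps motif point indices to target residue
    indices.  Complete matches (size m, RMSD ≤ ε) are always returned; when
    ``min_partial_size`` is set, dead-end branches of at least that size are
    emitted as partial matches.
    """
    options = options or MatchOptions()
    eps = options.epsilon
    radius = options.radius
    if radius > lists.radius_2r / 2.0 + 1e-9:
        raise ValueError(
            "candidate radius exceeds half the precomputed neighbor radius; "
            "rebuild the table with a larger neighbor radius"
        )
    mca = motif.ca_coords
    tca = target.ca_coords

    seed_points = tuple(sorted(seed_correspondence))
    seed_targets = [seed_correspondence[i] for i in seed_points]
    align = optimal_superposition(mca[list(seed_points)], tca[seed_targets])
    if align.rmsd > eps:
        return []
    order = _augment_order(motif, seed_points, options)
    results: list[Match] = []

    def emit(corr: dict, rmsd: float, complete: bool):
        pairs = tuple(
            (i, target.residues[corr[i]].res_id) for i in sorted(corr)
        )
        results.append(
            Match(
                target_id=target.target_id,
                correspondence=pairs,
                rmsd=float(rmsd),
                complete=complete,
                size=len(corr),
                seed_key=tuple(seed_key),
            )
        )

    def dfs(corr: dict, align, depth: int):
        if depth == len(order):
            emit(corr, align.rmsd, complete=True)
            return True
        point = order[depth]
        pos = apply_alignment(align, mca[point])
        used = set(corr.values())
        survived = False
        for ri in range_query(target, lists, pos, radius):
            if ri in used:
                continue
            if target.residues[ri].label not in motif.points[point].allowed_labels:
                continue
            new_corr = {**corr, point: ri}
            idx = sorted(new_corr)
            new_align = optimal_superposition(
                mca[idx], tca[[new_corr[i] for i in idx]]
            )
            if new_align.rmsd > eps:
                continue
            if dfs(new_corr, new_align, depth + 1):
                survived = True
        if not survived and options.min_partial_size is not None:
            if len(corr) >= options.min_partial_size:
                emit(corr, align.rmsd, complete=False)
        return survived

    dfs(dict(seed_correspondence), align, 0)
    return results


# ---------------------------------------------------------------------------
# whole-table matching


def _centroid_rmsd(match: Match, motif: Motif, target) -> float | None:
    """Side-chain centroid RMSD under an optimal superposition of centroids."""
    if not motif.has_centroids:
        return None
    mpts, tpts = [], []
    for point_idx, res_id in match.correspondence:
        c = motif.points[point_idx].sidechain_centroid
        r = target.residue_by_id(res_id)
        mpts.append(c)
        tpts.append(r.sidechain_centroid)
    return optimal_superposition(np.array(mpts), np.array(tpts)).rmsd


def match_motif(
    motif: Motif,
    table,
    target_filter=None,
    options: MatchOptions | None = None,
    params: GeometricParams | None = None,
    override_params: bool = False,
    seed_rank_filter=None,
) -> MatchResults:
    """Match a motif against every (filtered) target of a label table.

    Seeds are drawn from the ``max_seed_refsets`` rarest motif reference
    sets; every correspondence of every matching table reference set is
    expanded by :func:`augment_match`.  Matches are deduplicated by their
    correspondence (the same match reached from several seeds is reported
    once, with the rarest seed's key); by default only the best match per
    target is kept under ``best_match_criterion``.
    """
    options = options or MatchOptions()
    table.check_params(params, override=override_params)
    params = table.params
    refsets = motif_reference_sets(motif, params)  # raises if unmatchable
    considered = (
        sorted(target_filter) if target_filter is not None else table.target_ids
    )
    results = MatchResults(
        motif=motif,
        options=options,
        params=params,
        per_target={},
        targets_considered=considered,
    )
    if not considered:
        return results
    filt = set(considered)
    # Seed ranking must not depend on how targets are partitioned over
    # workers, so a parallel driver passes the full target set here.
    rank_filt = set(seed_rank_filter) if seed_rank_filter is not None else filt
    ranked = rank_seed_reference_sets(refsets, table, rank_filt)[
        : options.max_seed_refsets
    ]

    cache: dict = {}

    def get_target(tid):
        if tid not in cache:
            cache[tid] = table.read_target(tid)
        return cache[tid]

    found: dict = {}  # target_id -> {pair_set: Match}
    for rs in ranked:
        for key in rs.keys:
            hits = table.lookup(key, filt)
            for tid in sorted(hits):
                target, lists = get_target(tid)
                bucket = found.setdefault(tid, {})
                for tup in hits[tid]:
                    for corr in resolve_correspondences(rs, tup, target):
                        for m in augment_match(
                            corr, motif, target, lists, options, seed_key=key
                        ):
                            bucket.setdefault(m.pair_set, m)

    for tid, bucket in found.items():
        if not bucket:
            continue
        target, _ = get_target(tid)
        matches = [
            replace(m, sidechain_centroid_rmsd=_centroid_rmsd(m, motif, target))
            for m in bucket.values()
        ]
        matches.sort(key=lambda m: (-m.size, m.rmsd, m.correspondence))
        if options.keep_multiple_per_target:
            results.per_target[tid] = matches
        else:
            complete = [m for m in matches if m.complete] or matches
            best = select_best_per_target(
                {tid: complete}, options.best_match_criterion
            )
            results.per_target[tid] = [best[tid]]
    return results


def select_best_per_target(per_target: dict, criterion: str = "ca_rmsd") -> dict:
    """Argmin match per target under the criterion.

    Ties break by smaller Cα RMSD, then lexicographic correspondence.  With
    ``criterion="sidechain_centroid_rmsd"`` every match must carry a centroid
    RMSD; missing ones raise, naming the offending residues.
    """
    out = {}
    for tid, matches in per_target.items():
        if not matches:
            continue
        if criterion == "sidechain_centroid_rmsd":
            missing = [m for m in matches if m.sidechain_centroid_rmsd is None]
            if missing:
                names = sorted(
                    {rid for m in missing for _, rid in m.correspondence}
                )
                raise ValueError(
                    f"centroid RMSD unavailable for matches in {tid}; "
                    f"residues involved: {names}"
                )
            keyf = lambda m: (m.sidechain_centroid_rmsd, m.rmsd, m.correspondence)
        else:
            keyf = lambda m: (m.rmsd, m.rmsd, m.correspondence)
        out[tid] = min(matches, key=keyf)
    return out
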