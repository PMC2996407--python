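"""Match augmentation: seeds, correspondences, DFS expansion, selection."""

from itertools import combinations, permutations

import numpy as np
import pytest

from motifhash.matcher import (
    Match,
    MatchOptions,
    Motif,
    MotifPoint,
    UnmatchableMotifError,
    augment_match,
    match_motif,
    motif_reference_sets,
    rank_seed_reference_sets,
    resolve_correspondences,
    select_best_per_target,
)
from motifhash.neighbors import precompute_neighbor_lists
from motifhash.refsets import GeometricParams
from motifhash.synth import (
    BenchmarkSpec,
    default_benchmark_motif,
    generate_structure,
    make_benchmark,
    plant_motif,
)
from motifhash.table import build_table

from conftest import kabsch_rmsd
from test_refsets import _target, brute_force_valid


def _motif(coords, labels, centroids=None):
    points = tuple(
        MotifPoint(
            res_id=("A", 100 + i, ""),
            ca=tuple(np.asarray(c, float)),
            allowed_labels=frozenset(l),
            sidechain_centroid=tuple(centroids[i]) if centroids else None,
        )
        for i, (c, l) in enumerate(zip(coords, labels))
    )
    return Motif(motif_id="m", source_structure="src", points=points)


# ---------------------------------------------------------------------------
# motif-side reference sets


def test_three_point_motif_has_one_refset():
    m = _motif([(0, 0, 0), (6, 0, 0), (0, 6, 0)], ["H", "D", "E"])
    (rs,) = motif_reference_sets(m)
    assert rs.point_indices == (0, 1, 2)
    assert rs.keys == (("D", "E", "H"),)


def test_five_point_motif_refsets_match_bruteforce_filter():
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, 14, size=(5, 3))
    m = _motif(coords, ["K", "D", "E", "N", "H"])
    params = GeometricParams()
    got = {rs.point_indices for rs in motif_reference_sets(m, params)}

    class _P:
        def __init__(self, ca):
            self.ca = ca
            self.depth = 0.0

    expected = {
        combo
        for combo in combinations(range(5), 3)
        if brute_force_valid(
            [_P(coords[i]) for i in combo],
            GeometricParams(check_depth=False),
        )
    }
    assert got == expected


def test_alternate_labels_induce_deduplicated_keys():
    m = _motif([(0, 0, 0), (5, 0, 0), (0, 5, 0)], [{"E", "D", "N"}, {"D"}, {"E"}])
    (rs,) = motif_reference_sets(m)
    assert rs.keys == (("D", "D", "E"), ("D", "E", "E"), ("D", "E", "N"))


def test_unmatchable_motif_raises():
    far = _motif([(0, 0, 0), (30, 0, 0), (60, 0, 0)], ["A", "A", "A"])
    with pytest.raises(UnmatchableMotifError):
        motif_reference_sets(far)
    small = _motif([(0, 0, 0), (5, 0, 0)], ["A", "A"])
    with pytest.raises(UnmatchableMotifError):
        motif_reference_sets(small)


# ---------------------------------------------------------------------------
# seed ranking and correspondences


def test_rarest_seed_first_and_absent_keys_rank_zero(tmp_path):
    targets = [generate_structure(30, seed=s, target_id=f"g{s}") for s in (1, 2, 3)]
    table = build_table(targets, GeometricParams(), tmp_path / "t.h5")
    m = _motif(
        [(0, 0, 0), (5, 0, 0), (0, 5, 0), (5, 5, 4)],
        ["A", "G", "L", {"W"}],
    )
    refsets = motif_reference_sets(m, table.params)
    ranked = rank_seed_reference_sets(refsets, table)
    freqs = [
        sum(table.key_frequency(k) for k in rs.keys) for rs in ranked
    ]
    assert freqs == sorted(freqs)  # recount oracle agrees with the ordering
    table.close()


def test_resolve_correspondences_counts():
    t = _target([(0, 0, 0), (5, 0, 0), (0, 5, 0)], labels=["D", "H", "E"])
    m = _motif([(0, 0, 0), (5, 0, 0), (0, 5, 0)], ["H", "D", "E"])
    (rs,) = motif_reference_sets(m)
    corr = resolve_correspondences(rs, (0, 1, 2), t)
    assert corr == [{0: 1, 1: 0, 2: 2}]

    t2 = _target([(0, 0, 0), (5, 0, 0), (0, 5, 0)], labels=["H", "K", "D"])
    m2 = _motif([(0, 0, 0), (5, 0, 0), (0, 5, 0)], [{"H", "K"}, {"H", "K"}, {"D"}])
    (rs2,) = motif_reference_sets(m2)
    assert len(resolve_correspondences(rs2, (0, 1, 2), t2)) == 2


def test_resolve_correspondences_equals_bruteforce_pairings():
    rng = np.random.default_rng(8)
    alphabet = "DEHKN"
    for _ in range(30):
        t_labels = [str(rng.choice(list(alphabet))) for _ in range(3)]
        m_labels = [
            set(rng.choice(list(alphabet), size=rng.integers(1, 4), replace=False))
            for _ in range(3)
        ]
        t = _target([(0, 0, 0), (5, 0, 0), (0, 5, 0)], labels=t_labels)
        m = _motif([(0, 0, 0), (5, 0, 0), (0, 5, 0)], m_labels)
        (rs,) = motif_reference_sets(m)
        got = resolve_correspondences(rs, (0, 1, 2), t)
        expected = [
            dict(zip((0, 1, 2), perm))
            for perm in permutations((0, 1, 2))
            if all(t_labels[perm[i]] in m_labels[i] for i in range(3))
        ]
        assert got == expected


# ---------------------------------------------------------------------------
# augmentation


def _self_match_setup():
    target = generate_structure(20, seed=99)
    sub = [2, 5, 9, 12]
    coords = [target.residues[i].ca for i in sub]
    labels = [target.residues[i].label for i in sub]
    motif = _motif(coords, labels)
    lists = precompute_neighbor_lists(target, 7.0)
    return target, motif, lists, sub


def test_self_substructure_reaches_complete_zero_rmsd_match():
    target, motif, lists, sub = _self_match_setup()
    seed = {0: sub[0], 1: sub[1], 2: sub[2]}
    matches = augment_match(seed, motif, target, lists, MatchOptions())
    complete = [m for m in matches if m.complete]
    assert complete
    assert min(m.rmsd for m in complete) <= 1e-8


def test_epsilon_rejection_emits_partial_when_requested():
    coords = [(0, 0, 0), (5, 0, 0), (0, 5, 0), (4, 4, 3)]
    target = _target(coords[:3] + [(60, 60, 60)], labels=["A", "A", "A", "A"])
    motif = _motif(coords, ["A", "A", "A", "A"])
    lists = precompute_neighbor_lists(target, 7.0)
    seed = {0: 0, 1: 1, 2: 2}
    assert augment_match(seed, motif, target, lists, MatchOptions()) == []
    partials = augment_match(
        seed, motif, target, lists, MatchOptions(min_partial_size=3)
    )
    assert len(partials) == 1
    assert partials[0].size == 3 and not partials[0].complete


def _compact_blob(rng, n, radius=7.5, labels="ADEHK"):
    pts = []
    while len(pts) < n:
        c = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(c) > radius:
            continue
        if all(np.linalg.norm(c - p) >= 4.0 for p in pts):
            pts.append(c)
    labs = [str(rng.choice(list(labels))) for _ in pts]
    return _target(pts, labels=labs)


def test_complete_matches_equal_exhaustive_injection_oracle(tmp_path):
    """DFS over seeds finds exactly the seed-reachable label-compatible
    injections (ε and candidate radius made non-binding so the comparison is
    a pure reachability/machinery check)."""
    rng = np.random.default_rng(123)
    params = GeometricParams(check_depth=False)
    eps = 50.0
    for trial in range(4):
        target = _compact_blob(rng, 10)
        motif_coords = rng.uniform(-6, 6, size=(4, 3))
        motif_labels = [
            set(rng.choice(list("ADEHK"), size=rng.integers(1, 3), replace=False))
            for _ in range(4)
        ]
        try:
            motif = _motif(motif_coords, motif_labels)
            refsets = motif_reference_sets(motif, params)
        except UnmatchableMotifError:
            continue
        table = build_table([target], params, tmp_path / f"o{trial}.h5",
                            neighbor_radius=eps)
        options = MatchOptions(
            epsilon=eps, candidate_radius=eps, max_seed_refsets=10_000,
            keep_multiple_per_target=True,
        )
        results = match_motif(motif, table, options=options)
        got = {
            frozenset(m.correspondence): m.rmsd
            for m in results.per_target.get(target.target_id, [])
            if m.complete
        }

        # oracle: all label-compatible injections reachable from some valid
        # seed pair (motif refset, valid target triple)
        valid_triples = {
            combo
            for combo in combinations(range(10), 3)
            if brute_force_valid([target.residues[i] for i in combo], params)
        }
        expected = {}
        for inj in permutations(range(10), 4):
            if not all(
                target.residues[inj[p]].label in motif_labels[p] for p in range(4)
            ):
                continue
            reachable = any(
                tuple(sorted(inj[p] for p in rs.point_indices)) in valid_triples
                for rs in refsets
            )
            if not reachable:
                continue
            pairs = frozenset(
                (p, target.residues[inj[p]].res_id) for p in range(4)
            )
            expected[pairs] = kabsch_rmsd(
                motif_coords, [target.residues[inj[p]].ca for p in range(4)]
            )
        assert set(got) == set(expected)
        for pairs, rmsd in expected.items():
            assert got[pairs] == pytest.approx(rmsd, abs=1e-8)
        table.close()


# ---------------------------------------------------------------------------
# whole-table matching


def test_self_match_from_stored_target(tmp_path):
    target = generate_structure(25, seed=77, target_id="self")
    sub = [3, 7, 11, 15, 19]
    motif = _motif(
        [target.residues[i].ca for i in sub],
        [target.residues[i].label for i in sub],
    )
    table = build_table([target], GeometricParams(check_depth=False), tmp_path / "s.h5")
    results = match_motif(motif, table)
    (best,) = results.per_target["self"]
    assert best.complete and best.rmsd <= 1e-6
    table.close()


def test_planted_targets_and_only_those_report_near_zero_matches(tmp_path):
    spec = BenchmarkSpec(n_targets=30, planted_fraction=1 / 3, noise_sigma=0.0,
                         seed=5, target_size=(25, 35))
    table, motif, truth = make_benchmark(spec, table_path=tmp_path / "p.h5")
    results = match_motif(motif, table)
    planted = {row["target_id"] for row in truth if row["is_positive"]}
    near_zero = {
        tid
        for tid, ms in results.per_target.items()
        if ms and ms[0].complete and ms[0].rmsd < 1e-3
    }
    assert near_zero == planted
    table.close()


def test_keep_multiple_reports_both_planted_copies(tmp_path):
    from motifhash.structure_io import TargetStructure

    motif = default_benchmark_motif()
    halves = []
    for seed, chain, shift in ((21, "A", 0.0), (22, "B", 60.0)):
        half = generate_structure(30, seed=seed, target_id=f"h{chain}")
        half, _ = plant_motif(half, motif, 0.0, seed=seed + 1)
        for r in half.residues:
            r.chain_id = chain
            r.ca = r.ca + np.array([shift, 0.0, 0.0])
            r.sidechain_centroid = r.sidechain_centroid + np.array([shift, 0.0, 0.0])
            r.atom_coords = [(n, xyz + np.array([shift, 0.0, 0.0]))
                             for n, xyz in r.atom_coords]
        halves.extend(half.residues)
    target = TargetStructure(target_id="twins", residues=halves)
    table = build_table([target], GeometricParams(check_depth=False),
                        tmp_path / "m.h5")
    results = match_motif(
        motif, table, options=MatchOptions(keep_multiple_per_target=True)
    )
    complete = [m for m in results.per_target["twins"] if m.complete]
    assert len({m.pair_set for m in complete}) >= 2
    table.close()


def test_matches_satisfy_soundness_invariants(benchmark):
    """Every emitted match is label-compatible and at most ε, re-verified
    with the independent SVD oracle."""
    motif = benchmark.motif
    for tid, matches in benchmark.results.per_target.items():
        target, _ = benchmark.table.read_target(tid)
        for m in matches:
            assert m.size == len(m.correspondence)
            assert m.complete == (m.size == motif.m)
            mpts, tpts = [], []
            for point_idx, res_id in m.correspondence:
                residue = target.residue_by_id(res_id)
                assert residue.label in motif.points[point_idx].allowed_labels
                mpts.append(motif.points[point_idx].ca)
                tpts.append(residue.ca)
            oracle = kabsch_rmsd(np.array(mpts), np.array(tpts))
            assert m.rmsd == pytest.approx(oracle, abs=1e-6)
            assert m.rmsd <= benchmark.results.options.epsilon + 1e-9


def test_more_seeds_never_worsen_best_rmsd(benchmark):
    subset = sorted(benchmark.results.per_target)[:25]
    few = match_motif(
        benchmark.motif, benchmark.table, target_filter=subset,
        options=MatchOptions(max_seed_refsets=2),
    )
    many = match_motif(
        benchmark.motif, benchmark.table, target_filter=subset,
        options=MatchOptions(max_seed_refsets=15),
    )
    for tid, ms in few.per_target.items():
        assert tid in many.per_target
        assert many.per_target[tid][0].rmsd <= ms[0].rmsd + 1e-12


def test_epsilon_monotonicity_of_complete_match_sets(benchmark):
    subset = sorted(benchmark.results.per_target)[:10]
    opts = dict(keep_multiple_per_target=True, max_seed_refsets=15)
    tight = match_motif(benchmark.motif, benchmark.table, target_filter=subset,
                        options=MatchOptions(epsilon=5.0, **opts))
    loose = match_motif(benchmark.motif, benchmark.table, target_filter=subset,
                        options=MatchOptions(epsilon=7.0, **opts))
    for tid in subset:
        tight_set = {
            m.pair_set for m in tight.per_target.get(tid, []) if m.complete
        }
        loose_set = {
            m.pair_set for m in loose.per_target.get(tid, []) if m.complete
        }
        assert tight_set <= loose_set


# ---------------------------------------------------------------------------
# best-match selection


def _mk_match(tid, rmsd, centroid_rmsd=None, tag=0):
    return Match(
        target_id=tid,
        correspondence=((0, ("A", tag, "")), (1, ("A", tag + 1, ""))),
        rmsd=rmsd,
        complete=True,
        size=2,
        seed_key=("A", "A", "A"),
        sidechain_centroid_rmsd=centroid_rmsd,
    )


def test_single_match_is_its_own_best():
    m = _mk_match("t", 1.0)
    assert select_best_per_target({"t": [m]}) == {"t": m}


def test_centroid_criterion_overrides_ca_rmsd():
    good_centroid = _mk_match("t", 2.0, centroid_rmsd=0.4, tag=0)
    good_ca = _mk_match("t", 0.9, centroid_rmsd=1.2, tag=2)
    best = select_best_per_target(
        {"t": [good_ca, good_centroid]}, "sidechain_centroid_rmsd"
    )
    assert best["t"] is good_centroid


def test_missing_centroid_rmsd_raises_with_residues():
    m = _mk_match("t", 1.0, centroid_rmsd=None)
    with pytest.raises(ValueError, match="centroid"):
        select_best_per_target({"t": [m]}, "sidechain_centroid_rmsd")


def test_argmin_equals_scan_on_random_match_sets():
    rng = np.random.default_rng(14)
    for _ in range(20):
        ms = [
            _mk_match("t", float(rng.uniform(0, 7)),
                      centroid_rmsd=float(rng.uniform(0, 7)), tag=2 * i)
            for i in range(6)
        ]
        best_ca = select_best_per_target({"t": ms})["t"]
        assert best_ca.rmsd == min(m.rmsd for m in ms)
        best_cen = select_best_per_target({"t": ms}, "sidechain_centroid_rmsd")["t"]
        assert best_cen.sidechain_centroid_rmsd == min(
            m.sidechain_centroid_rmsd for m in ms
        )
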