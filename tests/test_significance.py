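"""Bandwidth selection, missed-match feasibility, corrected p-values."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad

from motifhash.matcher import MatchOptions, MatchResults
from motifhash.significance import (
    MotifProfile,
    SignificanceUnavailable,
    build_profile,
    can_possibly_match,
    corrected_pvalue,
    exactness_bound,
    profile_density,
    sheather_jones_bandwidth,
)


# ---------------------------------------------------------------------------
# Sheather-Jones bandwidth


def test_constant_sample_falls_back_to_silverman():
    with pytest.warns(UserWarning, match="Silverman"):
        h, method = sheather_jones_bandwidth([1.0, 1.0, 1.0], return_method=True)
    assert method == "silverman"
    assert h > 0


def test_bandwidth_is_scale_equivariant():
    rng = np.random.default_rng(4)
    x = rng.normal(2.0, 0.7, 300)
    h = sheather_jones_bandwidth(x)
    assert sheather_jones_bandwidth(3.7 * x) == pytest.approx(3.7 * h, rel=1e-6)


def test_bandwidth_agrees_with_independent_reference_implementation():
    """Frozen oracle: R's bw.SJ(method='ste') at fine binning on this exact
    seeded sample gives 0.2761948792."""
    x = np.random.default_rng(12345).standard_normal(1000)
    h = sheather_jones_bandwidth(x)
    assert h == pytest.approx(0.2761948792, rel=0.01)


# ---------------------------------------------------------------------------
# missed-match feasibility


def test_feasibility_trivial_cases():
    assert can_possibly_match({"K": 1, "D": 1}, [{"K"}, {"D"}])
    assert not can_possibly_match({"K": 2}, [{"K"}, {"D"}])
    assert can_possibly_match({"H": 1, "K": 1}, [{"H", "K"}, {"H", "K"}])
    assert not can_possibly_match({"H": 1}, [{"H", "K"}, {"H", "K"}])
    assert can_possibly_match({"H": 2}, [{"H", "K"}, {"H", "K"}])


def _bruteforce_feasible(counts, allowed):
    pool = [lab for lab, c in counts.items() for _ in range(c)]
    if len(pool) < len(allowed):
        return False
    for combo in itertools.permutations(range(len(pool)), len(allowed)):
        if all(pool[combo[i]] in allowed[i] for i in range(len(allowed))):
            return True
    return False


def test_feasibility_equals_exhaustive_assignment_search():
    rng = np.random.default_rng(30)
    alphabet = list("DEHKN")
    for _ in range(60):
        counts = {
            lab: int(rng.integers(0, 3))
            for lab in rng.choice(alphabet, size=rng.integers(1, 5), replace=False)
        }
        counts = {k: v for k, v in counts.items() if v > 0}
        allowed = [
            set(rng.choice(alphabet, size=rng.integers(1, 3), replace=False))
            for _ in range(int(rng.integers(1, 5)))
        ]
        assert can_possibly_match(counts, allowed) == _bruteforce_feasible(
            counts, allowed
        )


# ---------------------------------------------------------------------------
# profile construction


class _StubTable:
    """Minimal stand-in (synthetic) providing only label_counts lookups."""

    def __init__(self, counts):
        self._counts = counts

    def label_counts(self, tid):
        return self._counts[tid]


def _results(per_target_rmsds, considered, motif=None, options=None):
    from motifhash.refsets import GeometricParams
    from motifhash.synth import default_benchmark_motif
    from motifhash.matcher import Match

    motif = motif or default_benchmark_motif()
    per_target = {}
    for tid, rmsd in per_target_rmsds.items():
        per_target[tid] = [
            Match(
                target_id=tid,
                correspondence=tuple(
                    (i, ("A", i, "")) for i in range(motif.m)
                ),
                rmsd=rmsd,
                complete=True,
                size=motif.m,
                seed_key=("D", "E", "K"),
            )
        ]
    return MatchResults(
        motif=motif,
        options=options or MatchOptions(),
        params=GeometricParams(),
        per_target=per_target,
        targets_considered=considered,
    )


_FEASIBLE = {"K": 2, "H": 1, "D": 2, "E": 2, "N": 1}
_INFEASIBLE = {"A": 5, "G": 3}


def test_profile_counts_matched_missed_and_infeasible():
    rng = np.random.default_rng(6)
    matched = {f"m{i}": float(rng.uniform(0.2, 4)) for i in range(10)}
    considered = list(matched) + [f"x{i}" for i in range(5)] + [f"z{i}" for i in range(3)]
    counts = {tid: _FEASIBLE for tid in considered}
    for i in range(3):
        counts[f"z{i}"] = _INFEASIBLE
    prof = build_profile(_results(matched, considered), _StubTable(counts))
    assert prof.n_matched == 10
    assert prof.n_missed == 5
    assert prof.bandwidth > 0


def test_all_matched_means_no_missed():
    matched = {f"m{i}": 0.5 + 0.1 * i for i in range(6)}
    prof = build_profile(
        _results(matched, list(matched)), _StubTable({})
    )
    assert prof.n_missed == 0 and prof.w_match == 1.0


def test_profile_refuses_multi_or_partial_runs():
    matched = {"a": 1.0, "b": 2.0}
    res = _results(matched, list(matched),
                   options=MatchOptions(keep_multiple_per_target=True))
    with pytest.raises(SignificanceUnavailable):
        build_profile(res, _StubTable({}))
    res2 = _results(matched, list(matched), options=MatchOptions(min_partial_size=3))
    with pytest.raises(SignificanceUnavailable):
        build_profile(res2, _StubTable({}))


# ---------------------------------------------------------------------------
# corrected p-values


def _profile(rmsds, n_missed, bandwidth=0.5, epsilon=7.0, m=5):
    return MotifProfile(
        rmsds=np.asarray(sorted(rmsds), float),
        n_missed=n_missed,
        bandwidth=bandwidth,
        bandwidth_method="sheather-jones",
        epsilon=epsilon,
        m=m,
    )


def _quadrature_pvalue(profile, rmsd):
    """Independent oracle: numerically integrate the renormalized kernel sum."""
    h = profile.bandwidth

    def density(t):
        total = 0.0
        for xi in profile.rmsds:
            mass = quad(
                lambda u: np.exp(-0.5 * ((u - xi) / h) ** 2) / (h * np.sqrt(2 * np.pi)),
                0, np.inf,
            )[0]
            total += (
                np.exp(-0.5 * ((t - xi) / h) ** 2) / (h * np.sqrt(2 * np.pi)) / mass
            )
        return total / profile.n_matched

    F = quad(density, 0.0, rmsd, limit=200)[0]
    return profile.w_match * F


def test_pvalue_matches_quadrature_oracle():
    rng = np.random.default_rng(9)
    for _ in range(5):
        prof = _profile(rng.uniform(0.1, 6, size=8), n_missed=int(rng.integers(0, 10)),
                        bandwidth=float(rng.uniform(0.2, 1.0)))
        for r in (0.5, 2.0, 5.0):
            assert corrected_pvalue(prof, r) == pytest.approx(
                _quadrature_pvalue(prof, r), abs=1e-6
            )


def test_no_missed_reduces_to_uncorrected():
    prof = _profile([1.0, 2.0, 3.0], n_missed=0)
    assert prof.w_match == 1.0
    assert corrected_pvalue(prof, 100.0) == pytest.approx(1.0, abs=1e-9)
    assert corrected_pvalue(prof, 2.0) == pytest.approx(
        _quadrature_pvalue(prof, 2.0), abs=1e-6
    )


def test_half_mass_at_infinity_when_missed_equals_matched():
    prof = _profile([1.0, 2.0, 3.0], n_missed=3)
    assert corrected_pvalue(prof, 1e6) == pytest.approx(0.5, abs=1e-9)


def test_pvalue_bounds_and_monotonicity():
    prof = _profile([0.5, 1.5, 2.5, 4.0], n_missed=2)
    grid = np.linspace(0, 10, 200)
    ps = [corrected_pvalue(prof, r) for r in grid]
    assert all(0.0 <= p <= 1.0 for p in ps)
    assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))
    # half-line renormalization pins p(0) to exactly 0; any positive RMSD
    # already accumulates kernel mass
    assert ps[0] == 0.0
    assert 0.0 < ps[1] <= prof.w_match
    assert corrected_pvalue(prof, 1e9) <= prof.w_match + 1e-12


def test_adding_missed_targets_strictly_lowers_p():
    base = _profile([0.5, 1.5, 2.5], n_missed=1)
    more = _profile([0.5, 1.5, 2.5], n_missed=4)
    for r in (0.3, 1.0, 3.0):
        assert corrected_pvalue(more, r) < corrected_pvalue(base, r)


def test_density_export_integrates_to_w_match():
    prof = _profile([0.5, 1.0, 2.0], n_missed=3, bandwidth=0.4)
    grid, dens = profile_density(prof, np.linspace(0, 30, 20001))
    assert np.trapezoid(dens, grid) == pytest.approx(prof.w_match, abs=1e-4)


def test_empty_profile_errors():
    prof = _profile([1.0], 0)
    object.__setattr__(prof, "rmsds", np.empty(0))
    with pytest.raises(SignificanceUnavailable):
        corrected_pvalue(prof, 1.0)
    with pytest.raises(ValueError):
        corrected_pvalue(_profile([1.0], 0), -0.5)


# ---------------------------------------------------------------------------
# exactness bound


def test_exactness_bound_values():
    assert exactness_bound(6, 7.0) == pytest.approx(7.0 / np.sqrt(6))
    assert round(exactness_bound(6, 7.0), 1) == 2.9
    assert exactness_bound(1, 7.0) == pytest.approx(7.0)
    assert exactness_bound(4, 7.0) == pytest.approx(3.5)
    with pytest.raises(ValueError):
        exactness_bound(0, 7.0)
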