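"""Nonparametric match significance with a point weight for missed matches.

The per-target best-match RMSDs of a motif against a background collection
form its *motif profile*.  Smoothing this sample with a Gaussian kernel at
the Sheather–Jones plug-in bandwidth gives a density over RMSD; the p-value
of a match is the probability mass to the left of its RMSD.  Because the
matcher rejects matches above the cutoff ε, targets that found no match but
contain enough residues of the right labels could have matched at a larger
cutoff; they are modelled as a point weight at infinity.  Writing A and B
for the density mass left and right of the match RMSD and C for the missed
mass, the corrected p-value is A / (A + B + C):

    p(r) = W_match * F(r),       W_match = n_matched / (n_matched + n_missed)

with F the kernel CDF renormalized to the nonnegative half-line.  Below
ε / sqrt(m) (m the motif size) p-values are provably unaffected by ε.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_flow
from scipy.special import ndtr  # standard normal CDF

__all__ = [
    "MotifProfile",
    "SignificanceUnavailable",
    "sheather_jones_bandwidth",
    "silverman_bandwidth",
    "can_possibly_match",
    "build_profile",
    "corrected_pvalue",
    "profile_density",
    "exactness_bound",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


class SignificanceUnavailable(RuntimeError):
    """p-values are defined only for single complete matches per target."""


# ---------------------------------------------------------------------------
# bandwidth selection


def silverman_bandwidth(samples) -> float:
    x = np.asarray(samples, dtype=float)
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(x).max(), 1.0) * 1e-3  # constant sample: token width
    return 0.9 * spread * n ** (-0.2)


def _phi4(u):
    return (u**4 - 6.0 * u**2 + 3.0) * np.exp(-0.5 * u**2) / _SQRT2PI


def _phi6(u):
    return (u**6 - 15.0 * u**4 + 45.0 * u**2 - 15.0) * np.exp(-0.5 * u**2) / _SQRT2PI


def sheather_jones_bandwidth(samples, return_method: bool = False):
    """Solve-the-equation Sheather–Jones plug-in bandwidth.

    Falls back to Silverman's rule (with a warning) when the sample has
    fewer than 2 distinct values or the plug-in equation cannot be solved.
    Scale-equivariant: h(c*X) = c*h(X).
    """
    from scipy.optimize import brentq

    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 2 or np.unique(x).size < 2:
        warnings.warn("Sheather-Jones needs >= 2 distinct samples; using Silverman")
        h = silverman_bandwidth(x) if n else 1.0
        return (h, "silverman") if return_method else h

    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    lam = min(sd, iqr / 1.349) if iqr > 0 else sd

    diff = x[:, None] - x[None, :]

    def SD(a):  # plug-in estimate of R(f''); positive near the root
        return _phi4(diff / a).sum() / (n * (n - 1) * a**5)

    def TD(b):  # plug-in estimate of R(f''')
        return -_phi6(diff / b).sum() / (n * (n - 1) * b**7)

    # stage-one bandwidths of the solve-the-equation recipe; the constants are
    # 0.920 and 0.912 on the raw-IQR scale, i.e. 1.24 and 1.23 on lam
    a = 1.24 * lam * n ** (-1.0 / 7.0)
    b = 1.23 * lam * n ** (-1.0 / 9.0)
    sda = SD(a)
    tdb = TD(b)
    if not (np.isfinite(sda) and np.isfinite(tdb)) or sda <= 0 or tdb <= 0:
        warnings.warn("Sheather-Jones functional estimates degenerate; using Silverman")
        h = silverman_bandwidth(x)
        return (h, "silverman") if return_method else h

    def objective(h):
        alpha2 = 1.357 * (sda / tdb) ** (1.0 / 7.0) * h ** (5.0 / 7.0)
        sd_a2 = SD(alpha2)
        if sd_a2 <= 0:
            return np.inf
        return (1.0 / (2.0 * np.sqrt(np.pi) * n * sd_a2)) ** 0.2 - h

    h0 = silverman_bandwidth(x)
    lo, hi = h0 / 1000.0, h0 * 10.0
    try:
        flo, fhi = objective(lo), objective(hi)
        tries = 0
        while np.isfinite(flo) and np.isfinite(fhi) and flo * fhi > 0 and tries < 6:
            hi *= 4.0
            fhi = objective(hi)
            tries += 1
        if not (np.isfinite(flo) and np.isfinite(fhi)) or flo * fhi > 0:
            raise ValueError("no sign change for the plug-in equation")
        h = brentq(objective, lo, hi, xtol=1e-12 * h0, rtol=1e-10)
        method = "sheather-jones"
    except ValueError:
        warnings.warn("Sheather-Jones solver failed; using Silverman")
        h, method = h0, "silverman"
    return (h, method) if return_method else h


# ---------------------------------------------------------------------------
# missed-match feasibility


def can_possibly_match(label_counts: dict, allowed_labels) -> bool:
    """Exact feasibility of assigning each motif point a distinct residue.

    ``allowed_labels`` is one set of allowed one-letter labels per motif
    point; ``label_counts`` the target's residue-label multiset.  Solved as a
    bipartite flow problem (points -> labels with capacities = counts), not a
    greedy count: motif {H,K},{H,K} is infeasible against {H:1} but feasible
    against {H:1, K:1}.
    """
    allowed = [set(a) for a in allowed_labels]
    m = len(allowed)
    if m == 0:
        return True
    labels = sorted({lab for a in allowed for lab in a if label_counts.get(lab, 0) > 0})
    if not labels:
        return False
    lab_index = {lab: i for i, lab in enumerate(labels)}
    # nodes: 0 source; 1..m points; m+1..m+L labels; m+L+1 sink
    L = len(labels)
    sink = m + L + 1
    rows, cols, caps = [], [], []
    for p in range(m):
        rows.append(0), cols.append(1 + p), caps.append(1)
        for lab in allowed[p]:
            if lab in lab_index:
                rows.append(1 + p)
                cols.append(1 + m + lab_index[lab])
                caps.append(1)
    for lab, i in lab_index.items():
        rows.append(1 + m + i), cols.append(sink), caps.append(int(label_counts[lab]))
    graph = csr_matrix((caps, (rows, cols)), shape=(sink + 1, sink + 1))
    return int(maximum_flow(graph, 0, sink).flow_value) == m


# ---------------------------------------------------------------------------
# profile and p-values


@dataclass(frozen=True)
class MotifProfile:
    rmsds: np.ndarray  # per-target best complete-match RMSDs, Å
    n_missed: int  # unmatched targets that could have matched
    bandwidth: float  # Å
    bandwidth_method: str  # "sheather-jones" or "silverman"
    epsilon: float  # Å, matcher cutoff in force when the profile was built
    m: int  # motif size

    @property
    def n_matched(self) -> int:
        return len(self.rmsds)

    @property
    def w_match(self) -> float:
        total = self.n_matched + self.n_missed
        return self.n_matched / total if total else 0.0


def build_profile(results, table, epsilon: float | None = None) -> MotifProfile:
    """Motif profile from per-target best matches plus missed-match count.

    ``results`` is a :class:`~motifhash.matcher.MatchResults` holding at most
    one complete match per target; runs made with multiple or partial
    matches enabled are refused, since the significance model assumes the
    single lowest-RMSD complete match per target.
    """
    opts = results.options
    if opts.keep_multiple_per_target or opts.min_partial_size is not None:
        raise SignificanceUnavailable(
            "significance is unavailable for multiple-match or partial-match "
            "runs; rerun with default match options"
        )
    eps = float(epsilon if epsilon is not None else opts.epsilon)
    motif = results.motif
    allowed = [p.allowed_labels for p in motif.points]
    rmsds = []
    n_missed = 0
    for tid in results.targets_considered:
        matches = results.per_target.get(tid, [])
        if matches:
            (match,) = matches
            if not match.complete:
                raise SignificanceUnavailable("profile requires complete matches")
            rmsds.append(match.rmsd)
        else:
            counts = table.label_counts(tid)
            if can_possibly_match(counts, allowed):
                n_missed += 1
    arr = np.asarray(sorted(rmsds), dtype=float)
    if len(arr) == 0:
        raise SignificanceUnavailable("no matches: profile is empty")
    if (arr < 0).any() or (arr > eps + 1e-9).any():
        raise ValueError("match RMSDs outside [0, epsilon]; wrong epsilon?")
    h, method = sheather_jones_bandwidth(arr, return_method=True)
    return MotifProfile(
        rmsds=arr,
        n_missed=n_missed,
        bandwidth=float(h),
        bandwidth_method=method,
        epsilon=eps,
        m=motif.m,
    )


def _halfline_mass(profile: MotifProfile) -> np.ndarray:
    """Per-sample kernel mass on [0, inf) — the renormalization denominators."""
    return 1.0 - ndtr(-profile.rmsds / profile.bandwidth)


def corrected_pvalue(profile: MotifProfile, rmsd: float) -> float:
    """Corrected p-value A/(A+B+C) of a match at the given RMSD.

    Monotone nondecreasing in RMSD, bounded by W_match as RMSD -> inf; with
    no missed matches it reduces to the uncorrected A/(A+B).
    """
    if rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    if profile.n_matched == 0:
        raise SignificanceUnavailable("empty profile")
    h = profile.bandwidth
    num = ndtr((rmsd - profile.rmsds) / h) - ndtr(-profile.rmsds / h)
    denom = _halfline_mass(profile)
    F = float((num / denom).sum() / profile.n_matched)
    return float(np.clip(profile.w_match * F, 0.0, 1.0))


def profile_density(profile: MotifProfile, grid=None):
    """(rmsd, density) table of the renormalized kernel density, for plots.

    The density integrates to W_match over [0, inf); the missed-match point
    weight at infinity carries the remaining 1 - W_match.
    """
    if grid is None:
        hi = float(profile.rmsds.max() + 4 * profile.bandwidth)
        grid = np.linspace(0.0, hi, 512)
    grid = np.asarray(grid, dtype=float)
    h = profile.bandwidth
    denom = _halfline_mass(profile)
    u = (grid[:, None] - profile.rmsds[None, :]) / h
    dens = (np.exp(-0.5 * u**2) / (_SQRT2PI * h) / denom[None, :]).sum(axis=1)
    dens *= profile.w_match / profile.n_matched
    return grid, dens


def exactness_bound(m: int, epsilon: float) -> float:
    """RMSD below which corrected p-values are unaffected by the ε cutoff.

    Equals ε / sqrt(m) for an m-residue motif: a complete match at RMSD r
    implies every point deviation is at most r * sqrt(m), so matches below
    ε / sqrt(m) cannot be displaced by competitors excluded at cutoff ε.
    """
    if m < 1:
        raise ValueError("motif size m must be >= 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return epsilon / np.sqrt(m)
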