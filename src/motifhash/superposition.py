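"""Optimal rigid-body superposition via the quaternion characteristic polynomial.

The minimum RMSD between two corresponded point sets is obtained from the
largest eigenvalue of the symmetric 4x4 quaternion key matrix.  Instead of a
full eigen decomposition, the largest root of the quartic characteristic
polynomial is found by Newton iteration started from its analytic upper bound
— the standard fast formulation for the small point sets that dominate match
augmentation.  An SVD (Kabsch) fallback guarantees correctness on degenerate
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Alignment", "optimal_superposition", "apply_alignment"]

_NEWTON_TOL = 1e-11
_NEWTON_MAXITER = 50


@dataclass(frozen=True)
class Alignment:
    """A proper rigid motion x -> rotation @ x + translation, with its RMSD."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float


def apply_alignment(alignment: Alignment, points: np.ndarray) -> np.ndarray:
    """Apply the rigid motion to a (k, 3) array (or a single 3-vector)."""
    pts = np.asarray(points, dtype=float)
    return pts @ alignment.rotation.T + alignment.translation


def invert_alignment(alignment: Alignment) -> Alignment:
    """The inverse rigid motion (same RMSD by symmetry)."""
    Rinv = alignment.rotation.T
    return Alignment(
        rotation=Rinv, translation=-(Rinv @ alignment.translation), rmsd=alignment.rmsd
    )


def _kabsch(Pc: np.ndarray, Qc: np.ndarray) -> tuple[np.ndarray, float]:
    """SVD-based optimal proper rotation of centered Pc onto centered Qc."""
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt(max((diff * diff).sum() / len(Pc), 0.0)))
    return R, rmsd


def _key_matrix(M: np.ndarray) -> np.ndarray:
    """Symmetric traceless 4x4 key matrix of the covariance M = Pc^T Qc."""
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    return np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )


def _largest_key_eigenvalue(K: np.ndarray, M: np.ndarray, upper: float) -> float | None:
    """Largest root of det(K - λI) = λ⁴ + C2 λ² + C1 λ + C0 by Newton iteration.

    The cubic term vanishes (K is traceless); C2 = -2 tr(M M^T), C1 = -8 det(M)
    and C0 = det(K).  Newton starts at ``upper`` = (GA+GB)/2, a bound on the
    largest eigenvalue, and descends monotonically onto it.  None on
    non-convergence.
    """
    C2 = -2.0 * float((M * M).sum())
    C1 = -8.0 * float(np.linalg.det(M))
    C0 = float(np.linalg.det(K))

    lam = upper
    if lam <= 0.0:  # both point sets degenerate to single points
        return 0.0
    for _ in range(_NEWTON_MAXITER):
        lam2 = lam * lam
        f = lam2 * lam2 + C2 * lam2 + C1 * lam + C0
        df = 4.0 * lam2 * lam + 2.0 * C2 * lam + C1
        if df == 0.0:
            break
        step = f / df
        lam_new = lam - step
        if abs(step) < _NEWTON_TOL * max(abs(lam_new), 1.0):
            return lam_new
        lam = lam_new
    return None


def _rotation_from_key_matrix(K: np.ndarray, lam: float) -> np.ndarray | None:
    """Rotation matrix from the key-matrix eigenvector (a unit quaternion).

    The eigenvector at λ_max is read off the adjugate of K - λI (any nonzero
    column spans the null space); None if all columns are numerically null.
    """
    A = K - lam * np.eye(4)
    adj = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            minor = np.delete(np.delete(A, j, axis=0), i, axis=1)
            adj[i, j] = ((-1) ** (i + j)) * np.linalg.det(minor)
    norms = np.linalg.norm(adj, axis=0)
    best = int(np.argmax(norms))
    scale = float(np.abs(A).max()) or 1.0
    if norms[best] < 1e-9 * scale**3:
        return None
    w, x, y, z = adj[:, best] / norms[best]
    return np.array(
        [
            [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
        ]
    )


def optimal_superposition(P, Q) -> Alignment:
    """Best proper rigid motion mapping points P onto corresponded points Q.

    Parameters
    ----------
    P, Q : (k, 3) arrays of coordinates in Å, equal length.

    Returns
    -------
    Alignment whose ``rmsd`` is the global minimum of the root-mean-square
    deviation over proper rigid motions, with a rotation/translation achieving
    it.  Reflections are never returned: for a chirally mirrored Q the
    reported RMSD is the (positive) proper-rotation optimum.  For fewer than
    3 points or collinear sets the RMSD is still the true minimum; the
    rotation is one of the (non-unique) minimizers.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must both be (k, 3); got {P.shape} and {Q.shape}")
    k = P.shape[0]
    if k == 0:
        raise ValueError("cannot superpose empty point sets")

    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq

    GA = float((Pc * Pc).sum())
    GB = float((Qc * Qc).sum())
    M = Pc.T @ Qc
    K = _key_matrix(M)

    R = None
    lam = _largest_key_eigenvalue(K, M, 0.5 * (GA + GB))
    if lam is not None:
        R = _rotation_from_key_matrix(K, lam)
    if R is None:
        R, _ = _kabsch(Pc, Qc)

    # Read the RMSD off the achieved deviation instead of GA+GB-2λ: the
    # subtraction cancels catastrophically near zero, while the direct form
    # is exact to machine precision at O(k) cost.
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt((diff * diff).sum() / k))
    t = cq - R @ cp
    return Alignment(rotation=R, translation=t, rmsd=rmsd)
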