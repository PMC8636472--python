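"""Rigid-body and plane-fitting primitives shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch", "apply_rigid", "fit_plane", "angle_between_normals"]


class DegenerateSelectionError(ValueError):
    """Too few / collinear points for a well-defined superposition or plane."""


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           allow_degenerate: bool = False) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t mapping mobile onto reference.

    Minimizes ||R @ (mobile - <mobile>) + <reference> - reference|| in the
    least-squares sense (classic SVD solution, reflection corrected).

    Returns
    -------
    R : (3, 3) rotation matrix
    t : (3,) translation, such that transformed = mobile @ R.T + t
    rmsd : root-mean-square deviation after superposition
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if P.shape[0] < 3 and not allow_degenerate:
        raise DegenerateSelectionError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if not allow_degenerate and P.shape[0] >= 3:
        # collinearity check: second singular value of the centred cloud
        if np.linalg.svd(P - pc, compute_uv=False)[1] < 1e-8:
            raise DegenerateSelectionError("selected points are collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R.T + t


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through ``points``.

    Returns (centroid, unit normal); the normal is the singular vector of the
    centred cloud with the smallest singular value, sign fixed to +z hemisphere
    (or +x if perpendicular to z) for reproducibility.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3:
        raise DegenerateSelectionError("plane fit needs at least 3 points")
    c = P.mean(axis=0)
    _, _, Vt = np.linalg.svd(P - c)
    n = Vt[-1]
    if abs(n[2]) > 1e-12:
        n = n * np.sign(n[2])
    elif abs(n[0]) > 1e-12:
        n = n * np.sign(n[0])
    return c, n / np.linalg.norm(n)


def angle_between_normals(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two plane normals folded into [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
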