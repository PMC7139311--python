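"""Superposition (Kabsch) and RMSD utilities shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_rotation", "superpose", "rmsd", "superposed_rmsd"]


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal rotation R (least squares) mapping centered ``q`` onto centered ``p``.

    Both inputs are (n, 3); centering is the caller's business.
    """
    h = q.T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Plain (unfitted) RMSD between coordinate sets of equal cardinality."""
    if p.shape != q.shape:
        raise ValueError(f"coordinate sets differ in shape: {p.shape} vs {q.shape}")
    diff = p - q
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff))))


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares fit of ``reference`` onto ``mobile``.

    Returns ``(fitted_reference, rotation, translation)`` such that
    ``fitted_reference = reference @ R.T + t`` minimizes the RMSD to
    ``mobile``.
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    r = kabsch_rotation(mobile - mob_c, reference - ref_c)
    t = mob_c - ref_c @ r.T
    return reference @ r.T + t, r, t


def superposed_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between the two coordinate sets over rigid motions."""
    if p.shape != q.shape:
        raise ValueError(f"coordinate sets differ in shape: {p.shape} vs {q.shape}")
    fitted, _, _ = superpose(p, q)
    return rmsd(p, fitted)
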