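"""Distances, rigid-body superposition and ensemble RMSD."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .ensemble import Ensemble, StateModel

__all__ = ["DistanceTable", "Superposition", "residue_distance_matrix", "superpose", "ensemble_rmsd"]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceTable:
    """Symmetric L x L matrix of interresidual distances (Angstrom)."""

    values: np.ndarray
    atom_mode: str


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid map ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def residue_distance_matrix(entity: StateModel, atom_mode: str = "CA") -> DistanceTable:
    """Pairwise distances between residue reference points of one entity.

    ``atom_mode`` selects the reference point: the Calpha atom (default),
    the Cbeta atom (Calpha for glycine), or the heavy-atom centroid.
    """
    pts = entity.reference_coords(atom_mode)
    if pts.shape[0] == 1:
        return DistanceTable(np.zeros((1, 1)), atom_mode)
    return DistanceTable(squareform(pdist(pts)), atom_mode)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Optimal rigid superposition of ``mobile`` onto ``reference`` (Kabsch).

    Returns a proper rotation (determinant +1), translation and the
    post-fit RMSD.  Requires at least 3 non-collinear points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("coordinate sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise GeometryError("degenerate (collinear) point set; superposition is not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return Superposition(R, t, rmsd)


def _mean_structure(coord_sets: np.ndarray, tol: float = 1e-10, max_iter: int = 50) -> np.ndarray:
    """Iterative mean structure: superpose every set onto the running mean
    and recompute until the mean stabilizes."""
    aligned = coord_sets.copy()
    mean = aligned[0].copy()
    for _ in range(max_iter):
        for i in range(aligned.shape[0]):
            sp = superpose(coord_sets[i], mean)
            aligned[i] = coord_sets[i] @ sp.rotation.T + sp.translation
        new_mean = aligned.mean(axis=0)
        shift = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if shift < tol:
            break
    return mean


def ensemble_rmsd(
    ensemble: Ensemble,
    atom_selection: str = "CA",
    method: str = "mean",
) -> float:
    """Spread of a bundle over all M x N entities.

    ``method="mean"`` (default): mean over entities of the RMSD to the
    iteratively refined mean structure.  ``method="pairwise"``: mean
    pairwise RMSD over all entity pairs after optimal superposition.
    """
    coords = np.array([e.selection_coords(atom_selection) for e in ensemble.entities()])
    m = coords.shape[0]
    if m < 2:
        raise GeometryError("ensemble RMSD requires at least two entities")
    if method == "pairwise":
        vals = [superpose(coords[i], coords[j]).rmsd for i in range(m) for j in range(i + 1, m)]
        return float(np.mean(vals))
    if method != "mean":
        raise ValueError(f"unknown method {method!r}")
    mean = _mean_structure(coords)
    rmsds = [superpose(coords[i], mean).rmsd for i in range(m)]
    return float(np.mean(rmsds))
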