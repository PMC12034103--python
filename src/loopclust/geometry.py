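"""Backbone geometry: nucleotide centers, Kabsch superposition, distances."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .core import BACKBONE_ATOMS, Loop, Nucleotide


def nucleotide_center(nt: Nucleotide) -> np.ndarray:
    """Geometric center (arithmetic mean) of the available backbone atoms."""
    if not nt.backbone_coords:
        raise ValueError(
            f"nucleotide {nt.residue_number} has no backbone atoms; "
            "attach coordinates first"
        )
    return np.mean([nt.backbone_coords[a] for a in sorted(nt.backbone_coords)], axis=0)


def loop_centers(loop: Loop) -> np.ndarray:
    """N x 3 matrix of nucleotide centers in loop order."""
    return np.array([nucleotide_center(nt) for nt in loop.nucleotides])


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD between corresponded point sets after optimal rigid superposition.

    Both point sets are centered, the optimal proper rotation (no
    reflection) is found by SVD of the covariance matrix, and the RMSD of
    the superposed sets is returned.

    Parameters
    ----------
    P, Q : (k, 3) arrays
        Corresponding points (row i of P matches row i of Q), k >= 1.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape != Q.shape:
        raise ValueError(f"point sets must both be (k,3); got {P.shape} and {Q.shape}")
    if P.shape[0] == 0:
        raise ValueError("point sets must contain at least one point")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Pc @ R.T - Qc
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _common_backbone(a: Nucleotide, b: Nucleotide) -> tuple[np.ndarray, np.ndarray]:
    common = [n for n in BACKBONE_ATOMS if n in a.backbone_coords and n in b.backbone_coords]
    if not common:
        raise ValueError(
            f"residues {a.residue_number} and {b.residue_number} share no backbone atoms"
        )
    return (
        np.array([a.backbone_coords[n] for n in common]),
        np.array([b.backbone_coords[n] for n in common]),
    )


def pairwise_distances(loop: Loop, mode: str = "center_euclidean") -> np.ndarray:
    """N x N inter-nucleotide distance matrix for the graph edge weights.

    ``center_euclidean`` (default) is the Euclidean distance between the
    backbone geometric centers; ``kabsch_backbone`` is the Kabsch RMSD over
    the two nucleotides' common backbone-atom sets.  Both are symmetric
    with a zero diagonal.
    """
    n = loop.n_nucleotides
    if mode == "center_euclidean":
        centers = loop_centers(loop)
        return cdist(centers, centers)
    if mode == "kabsch_backbone":
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                P, Q = _common_backbone(loop.nucleotides[i], loop.nucleotides[j])
                D[i, j] = D[j, i] = kabsch_rmsd(P, Q)
        return D
    raise ValueError(f"unknown distance mode {mode!r}")
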