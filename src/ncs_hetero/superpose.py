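"""Least-squares rigid superposition and Calpha displacement profiles.

The fit is the classic Kabsch SVD solution with unit weights over *all*
paired Calpha atoms and no outlier-rejection cycles, so results are fully
deterministic.  Interactive alignment tools typically iterate with outlier
rejection; qualitative displacement profiles (which regions move most) are
insensitive to that choice, but absolute Angstrom values can differ slightly.

Residue pairing is by author numbering (res_seq, insertion code): all chains
compared here are the same construct, so no sequence alignment is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Residue

__all__ = [
    "SuperpositionResult",
    "CaDistanceProfile",
    "kabsch",
    "pair_ca_atoms",
    "ca_distance_profile",
    "pairwise_rmsd_matrix",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int
    pairing: list[tuple[int, str]] = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid transform mapping P onto Q (x -> R x + t).

    Minimizes sum ||R p_i + t - q_i||^2 over proper rotations; a reflection
    in the SVD solution is corrected by flipping the smallest singular
    direction.  Degenerate (collinear) point sets trigger a warning because
    the rotation about the point axis is then unconstrained.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch: P and Q must be matching N x 3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"kabsch: need >= 3 points, got {n}")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise ValueError("kabsch: non-finite coordinates")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1.0):
        warnings.warn(
            "kabsch: near-collinear point set; rotation about the axis is unstable",
            stacklevel=2,
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def pair_ca_atoms(
    chain_a: list[Residue],
    chain_b: list[Residue],
    altloc_policy: str = "first",
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
    """Match Calpha atoms by identical (res_seq, i_code) in both chains.

    Returns (P, Q, pairing) with rows in ascending residue order.  The
    representative conformer is the lowest altloc letter.
    """
    def ca_map(chain):
        out = {}
        for res in chain:
            if not res.is_polymer:
                continue
            ca = res.first_conformer().atom("CA")
            if ca is not None:
                out[(res.res_seq, res.i_code)] = ca.pos
        return out

    ma, mb = ca_map(chain_a), ca_map(chain_b)
    common = sorted(set(ma) & set(mb))
    if len(common) < 3:
        raise ValueError(
            f"pair_ca_atoms: only {len(common)} common residues with Calpha (need >= 3)"
        )
    P = np.array([ma[k] for k in common])
    Q = np.array([mb[k] for k in common])
    return P, Q, list(common)


@dataclass
class CaDistanceProfile:
    entries: list[tuple[int, str, float]]  # (res_seq, i_code, distance A)
    rmsd: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["res_seq", "i_code", "ca_distance_A"])

    def distance(self, res_seq: int, i_code: str = "") -> float:
        for rs, ic, d in self.entries:
            if rs == res_seq and ic == i_code:
                return d
        raise KeyError((res_seq, i_code))


def ca_distance_profile(
    chain_a: list[Residue], chain_b: list[Residue]
) -> CaDistanceProfile:
    """Superpose on all common Calpha, then report per-residue displacement."""
    P, Q, pairing = pair_ca_atoms(chain_a, chain_b)
    fit = kabsch(P, Q)
    d = np.linalg.norm(fit.apply(P) - Q, axis=1)
    entries = [(rs, ic, float(di)) for (rs, ic), di in zip(pairing, d)]
    return CaDistanceProfile(entries=entries, rmsd=fit.rmsd)


def pairwise_rmsd_matrix(
    chains: list[tuple[str, list[Residue]]]
) -> pd.DataFrame:
    """Symmetric matrix of pairwise Calpha RMSDs over labelled chains.

    Pairs with fewer than 3 common residues are reported as NaN.
    """
    if len(chains) < 2:
        raise ValueError("pairwise_rmsd_matrix: need >= 2 chains")
    labels = [lab for lab, _ in chains]
    n = len(chains)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                P, Q, _ = pair_ca_atoms(chains[i][1], chains[j][1])
                M[i, j] = M[j, i] = kabsch(P, Q).rmsd
            except ValueError:
                M[i, j] = M[j, i] = np.nan
    return pd.DataFrame(M, index=labels, columns=labels)
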