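"""Allosteric-site openness metric and a grid-probe pocket-volume estimate.

The openness metric is the Calpha-Calpha distance between two marker
residues flanking the site mouth; for the PTP1B L16 allosteric site these
are Met235 and Lys239, so larger distances mean a more open site.

Pocket volume is a deterministic grid approximation: grid points inside a
bounding sphere around the site that are (i) outside every atom's
vdW+probe sphere and (ii) buried, where buried means at least ``k`` of 14
cast rays (6 axial + 8 diagonal) hit protein before leaving the bounding
region.  The grid is anchored to a local frame built from the site atoms,
so the volume is invariant under rigid motion of the structure.  This is a
simple stand-in for alpha-shape pocket software; no numeric agreement with
such tools is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import VDW_RADII, DEFAULT_PROBE
from .model import ModelError, StructureModel, select_atoms

__all__ = ["SiteDefinition", "PocketVolume", "l16_openness", "grid_pocket_volume", "L16_SITE"]


def l16_openness(
    model: StructureModel, chain_id: str, res_i: int = 235, res_j: int = 239
) -> float:
    """Calpha-Calpha distance (A) between the two site-mouth residues."""
    pts = []
    for res_seq in (res_i, res_j):
        res = model.residue(chain_id, res_seq)
        ca = res.first_conformer().atom("CA")
        if ca is None:
            raise ModelError(f"residue {chain_id}{res_seq} has no Calpha atom")
        pts.append(ca.pos)
    return float(np.linalg.norm(pts[0] - pts[1]))


@dataclass
class SiteDefinition:
    """Residue ranges defining a pocket site plus the grid parameters."""

    residue_ranges: list[tuple[int, int]]
    bounding_radius: float = 12.0
    spacing: float = 0.5
    probe: float = DEFAULT_PROBE
    k_rays: int = 9

    def residue_set(self) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.residue_ranges:
            out.update(range(lo, hi + 1))
        return out


#: L16 allosteric site: loop 16, the N-terminal region and the C-terminal
#: region that together form the pocket walls
L16_SITE = SiteDefinition(residue_ranges=[(35, 42), (235, 245), (282, 298)])

# 6 axial + 8 body-diagonal ray directions (unit vectors)
_RAY_DIRECTIONS = np.array(
    [
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
        [-1, 1, 1], [-1, 1, -1], [-1, -1, 1], [-1, -1, -1],
    ],
    dtype=float,
)
_RAY_DIRECTIONS /= np.linalg.norm(_RAY_DIRECTIONS, axis=1, keepdims=True)


@dataclass
class PocketVolume:
    volume: float  # A^3, multiple of spacing^3
    n_points: int
    site: SiteDefinition
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _site_frame(site_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic local frame (origin, rotation) from the site atoms.

    Origin is the centroid; axes are Gram-Schmidt over the first atoms that
    give a well-conditioned basis, so the frame co-moves under any rigid
    transform of the coordinates.
    """
    center = site_coords.mean(axis=0)
    rel = site_coords - center
    e1 = None
    for v in rel:
        if np.linalg.norm(v) > 1e-6:
            e1 = v / np.linalg.norm(v)
            break
    if e1 is None:
        raise ModelError("site atoms are coincident; cannot build a frame")
    e2 = None
    for v in rel:
        w = v - np.dot(v, e1) * e1
        if np.linalg.norm(w) > 1e-3 * max(np.linalg.norm(v), 1.0):
            e2 = w / np.linalg.norm(w)
            break
    if e2 is None:
        raise ModelError("site atoms are collinear; cannot build a frame")
    e3 = np.cross(e1, e2)
    return center, np.column_stack([e1, e2, e3])


def grid_pocket_volume(
    model: StructureModel,
    chain_id: str,
    site: SiteDefinition = L16_SITE,
) -> PocketVolume:
    """Grid-probe pocket volume of a site on one chain."""
    if not (0.2 < site.spacing <= 1.0):
        raise ValueError("grid spacing must lie in (0.2, 1.0] A")
    wanted = site.residue_set()
    site_atoms = [
        a
        for a in select_atoms(model, chain_id=chain_id, polymer_only=True, altloc_policy="first")
        if a.res_seq in wanted
    ]
    if len(site_atoms) < 3:
        raise ModelError(f"site resolves to {len(site_atoms)} atoms on chain {chain_id!r}")
    site_coords = np.array([a.pos for a in site_atoms])
    center, rot = _site_frame(site_coords)

    all_atoms = select_atoms(model, chain_id=chain_id, polymer_only=True, altloc_policy="first")
    margin = max(VDW_RADII.values()) + site.probe
    coords = np.array([a.pos for a in all_atoms])
    keep = np.linalg.norm(coords - center, axis=1) <= site.bounding_radius + margin + 2.0
    coords = coords[keep]
    radii = np.array(
        [
            VDW_RADII.get(a.element.upper(), 1.7) + site.probe
            for a, k in zip(all_atoms, keep)
            if k
        ]
    )

    # voxel grid in the site frame over the bounding cube
    R = site.bounding_radius
    h = site.spacing
    n_side = int(np.floor(2 * R / h)) + 1
    axis = (np.arange(n_side) - (n_side - 1) / 2.0) * h
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    local = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    world = local @ rot.T + center

    # occupancy: voxels inside any vdW+probe sphere (protein-filled)
    occ3 = np.zeros((n_side, n_side, n_side), dtype=bool)
    if len(coords):
        local_atoms = (coords - center) @ rot
        offset0 = (n_side - 1) / 2.0
        idx = np.rint(local_atoms / h + offset0).astype(int)
        rad_vox = np.ceil(radii / h).astype(int)
        for a_local, (ix, iy, iz), rv, rr in zip(local_atoms, idx, rad_vox, radii):
            lo = np.maximum([ix - rv, iy - rv, iz - rv], 0)
            hi = np.minimum([ix + rv + 1, iy + rv + 1, iz + rv + 1], n_side)
            if np.any(lo >= hi):
                continue
            sub = np.stack(
                np.meshgrid(
                    axis[lo[0]:hi[0]], axis[lo[1]:hi[1]], axis[lo[2]:hi[2]], indexing="ij"
                ),
                axis=-1,
            )
            occ3[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= (
                np.sum((sub - a_local) ** 2, axis=-1) <= rr**2
            )
    occupied = occ3.ravel()

    in_sphere = np.linalg.norm(local, axis=1) <= R
    candidates = in_sphere & ~occupied
    cand_idx = np.nonzero(candidates)[0]
    if not len(cand_idx):
        return PocketVolume(volume=0.0, n_points=0, site=site, center=center)

    cand_local = local[cand_idx]
    hits = np.zeros(len(cand_idx), dtype=int)
    n_steps = int(np.ceil(2 * R / h))
    offset = (n_side - 1) / 2.0
    for d in _RAY_DIRECTIONS:
        hit = np.zeros(len(cand_idx), dtype=bool)
        alive = ~hit
        for s in range(1, n_steps + 1):
            pts = cand_local + (s * h) * d
            inside = np.linalg.norm(pts, axis=1) <= R
            active = alive & inside
            if not active.any():
                break
            ijk = np.rint(pts[active] / h + offset).astype(int)
            ok = np.all((ijk >= 0) & (ijk < n_side), axis=1)
            sel = np.nonzero(active)[0][ok]
            ijk = ijk[ok]
            newly = occ3[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
            hit[sel[newly]] = True
            alive = ~hit
        hits += hit
    pocket = hits >= site.k_rays
    n_pocket = int(pocket.sum())
    return PocketVolume(volume=n_pocket * h**3, n_points=n_pocket, site=site, center=center)
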