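"""Crystal-lattice expansion, contact detection and buried surface area.

Symmetry mates are generated by applying every space-group operator plus
integer lattice translations (bounded search, default +/-2 cells per axis)
to each chain's fractionalized coordinates, keeping mates with at least one
atom within a cutoff of the asymmetric unit.  The identity operator with
zero translation is excluded for a chain onto itself, but *is* kept for
other chains, so the in-ASU partner chain counts as a lattice neighbor.

Buried area is measured with an internal Shrake-Rupley engine using a
deterministic golden-spiral point set and a small built-in van der Waals
radius table (C 1.70, N 1.55, O 1.52, S 1.80 A; probe 1.4 A), so results
reproduce bit-for-bit.  Contact counts and areas follow these definitions
and are self-consistent; they are not claimed to match any external
interface server's algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import ModelError, StructureModel, UnitCell, select_atoms

__all__ = [
    "VDW_RADII",
    "SymmetryMate",
    "ContactReport",
    "SasaResult",
    "frac_orth_matrices",
    "expand_neighbors",
    "find_contacts",
    "golden_spiral_points",
    "sasa",
    "buried_area",
    "attribute_altconf_contacts",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_PROBE = 1.4
DEFAULT_CONTACT_CUTOFF = 4.0


def frac_orth_matrices(cell: UnitCell) -> tuple[np.ndarray, np.ndarray]:
    """(orthogonalization, fractionalization) matrices for a unit cell.

    Standard PDB convention: a along x, b in the xy plane.  For orthogonal
    cells the orthogonalization matrix is diag(a, b, c).
    """
    al, be, ga = np.radians([cell.alpha, cell.beta, cell.gamma])
    ca, cb, cg = np.cos([al, be, ga])
    sg = np.sin(ga)
    v = np.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
    if v <= 0 or sg == 0:
        raise ModelError("degenerate unit cell")
    orth = np.array(
        [
            [cell.a, cell.b * cg, cell.c * cb],
            [0.0, cell.b * sg, cell.c * (ca - cb * cg) / sg],
            [0.0, 0.0, cell.c * v / sg],
        ]
    )
    # exact zeros for right angles keep diag(a, b, c) literal
    orth[np.abs(orth) < 1e-10] = 0.0
    frac = np.linalg.inv(orth)
    return orth, frac


@dataclass
class SymmetryMate:
    chain_id: str
    op_index: int
    translation: tuple[int, int, int]
    coords: np.ndarray  # (M, 3) Cartesian
    elements: list[str]
    res_seqs: np.ndarray  # (M,) author residue numbers of source atoms
    res_names: list[str] = field(default_factory=list)

    @property
    def is_identity_zero(self) -> bool:
        return self.op_index == 0 and self.translation == (0, 0, 0)


def _chain_atom_arrays(model: StructureModel, chain_id: str):
    atoms = select_atoms(model, chain_id=chain_id, polymer_only=True, altloc_policy="first")
    coords = np.array([a.pos for a in atoms]) if atoms else np.empty((0, 3))
    elements = [a.element for a in atoms]
    res_seqs = np.array([a.res_seq for a in atoms], dtype=int)
    res_names = [a.res_name for a in atoms]
    return atoms, coords, elements, res_seqs, res_names


def expand_neighbors(
    model: StructureModel, cutoff: float = 5.0, search: int = 2
) -> list[SymmetryMate]:
    """All symmetry mates with >= 1 atom within ``cutoff`` of the ASU.

    The ASU reference set is every polymer chain (first-conformer atoms).
    Requires cell and space-group operators on the model.
    """
    if model.cell is None or not model.symops:
        raise ModelError("expand_neighbors: model has no cell/space-group operators")
    orth, frac = frac_orth_matrices(model.cell)

    per_chain = {
        cid: _chain_atom_arrays(model, cid)
        for cid in model.chains
        if any(r.is_polymer for r in model.chains[cid])
    }
    asu_coords = np.vstack([arr[1] for arr in per_chain.values() if len(arr[1])])
    tree = cKDTree(asu_coords)
    asu_center = asu_coords.mean(axis=0)
    asu_radius = np.max(np.linalg.norm(asu_coords - asu_center, axis=1))

    mates: list[SymmetryMate] = []
    shifts = range(-search, search + 1)
    for cid, (_atoms, coords, elements, res_seqs, res_names) in per_chain.items():
        if not len(coords):
            continue
        fcoords = coords @ frac.T
        for k, (rot, tran) in enumerate(model.symops):
            base = fcoords @ rot.T + tran
            for u in shifts:
                for v in shifts:
                    for w in shifts:
                        if k == 0 and (u, v, w) == (0, 0, 0):
                            continue  # identity copy of the chain onto itself
                        cart = (base + np.array([u, v, w], dtype=float)) @ orth.T
                        center = cart.mean(axis=0)
                        rad = np.max(np.linalg.norm(cart - center, axis=1))
                        if np.linalg.norm(center - asu_center) > asu_radius + rad + cutoff:
                            continue
                        if not tree.query_ball_point(cart, r=cutoff, return_length=True).any():
                            continue
                        mates.append(
                            SymmetryMate(
                                chain_id=cid,
                                op_index=k,
                                translation=(u, v, w),
                                coords=cart,
                                elements=list(elements),
                                res_seqs=res_seqs.copy(),
                                res_names=list(res_names),
                            )
                        )
    # identity-zero copies are legitimate partners for the *other* chains in
    # the ASU; include them when they lie within cutoff of another chain
    for cid, (_atoms, coords, elements, res_seqs, res_names) in per_chain.items():
        if len(per_chain) <= 1 or not len(coords):
            continue
        others = np.vstack(
            [arr[1] for ocid, arr in per_chain.items() if ocid != cid and len(arr[1])]
        )
        if cKDTree(others).query_ball_point(coords, r=cutoff, return_length=True).any():
            mates.append(
                SymmetryMate(
                    chain_id=cid,
                    op_index=0,
                    translation=(0, 0, 0),
                    coords=coords.copy(),
                    elements=list(elements),
                    res_seqs=res_seqs.copy(),
                    res_names=list(res_names),
                )
            )
    mates.sort(key=lambda m: (m.chain_id, m.op_index, m.translation))
    return mates


@dataclass
class ContactReport:
    chain_id: str
    cutoff: float
    n_contact_interfaces: int
    contacting_residues: list[int]  # res_seq of the target chain
    interfaces: list[dict]  # partner chain/op/translation + n_atom_pairs
    buried_area: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "chain_id": self.chain_id,
            "cutoff_A": self.cutoff,
            "n_contact_interfaces": self.n_contact_interfaces,
            "contacting_residues": self.contacting_residues,
            "buried_area_A2": self.buried_area,
            "interfaces": self.interfaces,
        }


def find_contacts(
    model: StructureModel,
    chain_id: str,
    mates: list[SymmetryMate],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactReport:
    """Lattice-contact interfaces of one chain against symmetry mates.

    An interface is a (mate) partner with >= 1 heavy-atom pair within
    ``cutoff``; residues of the target chain with any such atom are the
    contacting set.  A mate that is the chain's own identity-zero copy is
    ignored.
    """
    _atoms, coords, _el, res_seqs, _rn = _chain_atom_arrays(model, chain_id)
    if not len(coords):
        raise ModelError(f"chain {chain_id!r} has no polymer atoms")
    tree = cKDTree(coords)
    interfaces = []
    contacting: set[int] = set()
    for mate in mates:
        if mate.chain_id == chain_id and mate.is_identity_zero:
            continue
        if cutoff <= 0:
            continue
        pairs = tree.query_ball_point(mate.coords, r=cutoff)
        hit_atoms = sorted({i for lst in pairs for i in lst})
        if not hit_atoms:
            continue
        interfaces.append(
            {
                "partner_chain": mate.chain_id,
                "op_index": mate.op_index,
                "translation": list(mate.translation),
                "n_atom_pairs": int(sum(len(lst) for lst in pairs)),
            }
        )
        contacting.update(int(res_seqs[i]) for i in hit_atoms)
    return ContactReport(
        chain_id=chain_id,
        cutoff=cutoff,
        n_contact_interfaces=len(interfaces),
        contacting_residues=sorted(contacting),
        interfaces=interfaces,
    )


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    per_atom: np.ndarray  # (N,) A^2
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def _radii_for(elements: list[str]) -> np.ndarray:
    radii = []
    for el in elements:
        key = el.upper()
        if key not in VDW_RADII:
            raise ModelError(f"no van der Waals radius for element {el!r}")
        radii.append(VDW_RADII[key])
    return np.array(radii)


def sasa(
    coords: np.ndarray,
    elements: list[str],
    probe: float = DEFAULT_PROBE,
    n_points: int = 960,
    env_coords: np.ndarray | None = None,
    env_elements: list[str] | None = None,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Per-atom area = exposed-point fraction x 4 pi (r + probe)^2, with test
    points on a fixed golden-spiral set so output is deterministic.  Extra
    occluders (e.g. symmetry mates) can be supplied via ``env_coords``.
    """
    if n_points < 100:
        raise ValueError("sasa: n_points must be >= 100")
    coords = np.asarray(coords, dtype=float)
    radii = _radii_for(elements)
    if env_coords is not None and len(env_coords):
        occ_coords = np.vstack([coords, np.asarray(env_coords, dtype=float)])
        occ_radii = np.concatenate([radii, _radii_for(env_elements or [])])
    else:
        occ_coords = coords
        occ_radii = radii
    ext_occ = occ_radii + probe
    tree = cKDTree(occ_coords)
    unit = golden_spiral_points(n_points)
    max_ext = ext_occ.max()

    per_atom = np.zeros(len(coords))
    n = len(coords)
    for i in range(n):
        r_ext = radii[i] + probe
        pts = coords[i] + r_ext * unit
        neigh = tree.query_ball_point(coords[i], r=r_ext + max_ext)
        neigh = [j for j in neigh if not (j < n and j == i)]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - occ_coords[j]) ** 2, axis=1)
            exposed &= d2 > ext_occ[j] ** 2
        per_atom[i] = exposed.mean() * 4.0 * np.pi * r_ext**2
    return SasaResult(per_atom=per_atom, probe=probe, n_points=n_points)


def buried_area(
    model: StructureModel,
    chain_id: str,
    mates: list[SymmetryMate],
    probe: float = DEFAULT_PROBE,
    n_points: int = 960,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> float:
    """SASA lost by a chain when its contacting lattice mates are present.

    Only mates with >= 1 atom within ``contact_cutoff`` of the chain count
    as environment.  Clipped at zero (sampling noise on a no-contact input
    could otherwise produce a tiny negative).
    """
    _atoms, coords, elements, _rs, _rn = _chain_atom_arrays(model, chain_id)
    tree = cKDTree(coords)
    env_coords = []
    env_elements: list[str] = []
    for mate in mates:
        if mate.chain_id == chain_id and mate.is_identity_zero:
            continue
        if tree.query_ball_point(mate.coords, r=contact_cutoff, return_length=True).any():
            env_coords.append(mate.coords)
            env_elements.extend(mate.elements)
    alone = sasa(coords, elements, probe=probe, n_points=n_points).total
    if not env_coords:
        return 0.0
    packed = sasa(
        coords,
        elements,
        probe=probe,
        n_points=n_points,
        env_coords=np.vstack(env_coords),
        env_elements=env_elements,
    ).total
    return max(alone - packed, 0.0)


def attribute_altconf_contacts(
    model: StructureModel,
    chain_id: str,
    mates: list[SymmetryMate],
    shell: float = DEFAULT_CONTACT_CUTOFF,
) -> dict:
    """How many alternate-conformation residues sit at lattice contacts.

    Counts residues with >= 2 lettered altlocs having >= 1 atom (any
    conformer) within ``shell`` of any mate atom.
    """
    mate_coords = [
        m.coords
        for m in mates
        if not (m.chain_id == chain_id and m.is_identity_zero)
    ]
    tree = cKDTree(np.vstack(mate_coords)) if mate_coords else None
    altconf_ids: list[int] = []
    affected: list[int] = []
    for res in model.chain(chain_id):
        if not res.is_polymer or not res.has_altconf:
            continue
        altconf_ids.append(res.res_seq)
        if tree is None or not np.isfinite(shell):
            in_contact = tree is not None  # infinite shell: any mate counts
        else:
            pts = np.array([a.pos for a in res.atoms])
            in_contact = bool(
                tree.query_ball_point(pts, r=shell, return_length=True).any()
            )
        if in_contact:
            affected.append(res.res_seq)
    return {
        "n_altconf": len(altconf_ids),
        "n_contact_affected": len(affected),
        "altconf_residues": altconf_ids,
        "affected_residues": affected,
    }
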