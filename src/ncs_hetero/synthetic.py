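"""Synthetic multiconformer crystal structures with known ground truth.

Chains are built from ideal internal coordinates (fixed bond lengths and
angles: N-CA 1.458, CA-C 1.525, C-N 1.329 A, standard valence angles) at
chosen backbone phi/psi, with side chains placed at requested chi torsions
by natural-extension (NeRF) construction.  There is no physics: the
pipeline stages under test measure geometry and statistics, so ideal
geometry with controllable perturbations is exactly what is needed.

The two-chain builder emulates the situation of a crystal with two
non-identical copies of one protein in the asymmetric unit: chain B is a
rigid copy of chain A carrying designed perturbations (a localized Calpha
loop shift, a uniform B-factor scale, rotamer changes, extra alternate
conformations, a different ordered-water count), and the builder emits the
ground truth each pipeline stage should recover.  The loop-shift
displacement field is projected orthogonal to the six rigid-body modes of
the Calpha set so a subsequent least-squares superposition does not absorb
any of it, then rescaled so the apex residue moves by exactly the designed
amount.

Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import dihedral, nerf_place
from .model import AtomRecord, Residue, StructureModel, UnitCell
from .pdbio import space_group_operators

__all__ = [
    "BFactorBump",
    "AltconfPlan",
    "ChainSpec",
    "TwoChainSpec",
    "EnsemblePlan",
    "build_chain",
    "build_two_chain_asu",
    "build_pseudo_ensemble",
    "build_loop_templates",
    "build_spherical_cage",
    "build_contact_lattice",
    "default_two_chain_spec",
    "SUPPORTED_RESIDUES",
]

# ---------------------------------------------------------------------------
# ideal internal-coordinate templates
# ---------------------------------------------------------------------------

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
OMEGA = 180.0
#: improper torsion C-N-CA-CB setting L-amino-acid chirality
CB_IMPROPER = -122.5

# side-chain atom placements: (name, (ref1, ref2, ref3), bond, angle, torsion)
# torsion is ("chi", i) for chi_i, ("chi+", i, offset) for branches riding on
# chi_i, or ("abs", value) for a fixed torsion.
_T = {
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1))],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi+", 1, -120.0)),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1)),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.5, ("chi+", 1, 122.3)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1)),
        ("CD1", ("CA", "CB", "CG"), 1.524, 110.7, ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), 1.525, 110.4, ("chi+", 2, 122.6)),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi+", 1, -122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2)),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1)),
        ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, ("chi+", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.384, 121.1, ("abs", 180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.384, 121.1, ("abs", 180.0)),
        ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, ("abs", 0.0)),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.0, ("chi", 1)),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2)),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3)),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.0, ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2)),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 3)),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, ("chi", 4)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1)),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2)),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi+", 2, 180.0)),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1)),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2)),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi+", 2, 180.0)),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.0, ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2)),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3)),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi+", 3, 180.0)),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.0, ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2)),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3)),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi+", 3, 180.0)),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.0, ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2)),
        ("NE", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3)),
        ("CZ", ("CG", "CD", "NE"), 1.330, 124.2, ("chi", 4)),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, ("abs", 0.0)),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, ("abs", 180.0)),
    ],
}
_T["TYR"] = _T["PHE"] + [("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, ("abs", 180.0))]

SUPPORTED_RESIDUES = frozenset(_T) | {"GLY", "ALA"}

N_CHI = {
    "GLY": 0, "ALA": 0, "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "LEU": 2, "ILE": 2, "PHE": 2, "TYR": 2, "ASP": 2, "ASN": 2,
    "MET": 3, "GLU": 3, "GLN": 3, "LYS": 4, "ARG": 4,
}

#: modal chi values matching the rotamer library's bin centres
MODE_OF_LETTER = {"p": 60.0, "t": 180.0, "m": -60.0, "0": 0.0, "90": 90.0}

#: a sensible default rotamer per type (one modal letter per chi)
DEFAULT_CHI: dict[str, tuple[float, ...]] = {
    "SER": (-60.0,), "CYS": (-60.0,), "THR": (60.0,), "VAL": (180.0,),
    "LEU": (-60.0, 180.0), "ILE": (-60.0, 180.0), "PHE": (-60.0, 90.0),
    "TYR": (-60.0, 90.0), "ASP": (-60.0, 0.0), "ASN": (-60.0, -60.0),
    "MET": (-60.0, 180.0, 180.0), "GLU": (-60.0, 180.0, 0.0),
    "GLN": (-60.0, 180.0, 180.0), "LYS": (180.0, 180.0, 180.0, 180.0),
    "ARG": (-60.0, 180.0, 180.0, 180.0), "GLY": (), "ALA": (),
}

_ELEMENT_OF = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _element_for(name: str) -> str:
    return _ELEMENT_OF.get(name[0], name[0])


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class BFactorBump:
    center: int  # res_seq
    width: float  # residues (Gaussian sigma)
    amplitude: float  # A^2


@dataclass
class AltconfPlan:
    """Split one residue's side chain into two conformers."""

    res_seq: int
    chi_a: tuple[float, ...]
    chi_b: tuple[float, ...]
    occ_a: float = 0.6
    occ_b: float = 0.4

    def __post_init__(self) -> None:
        if self.occ_a + self.occ_b > 1.0 + 1e-9:
            raise ValueError("altconf occupancies sum above 1")


@dataclass
class ChainSpec:
    sequence: list[str]
    chain_id: str = "A"
    start_res_seq: int = 1
    phi: float = -140.0
    psi: float = 135.0
    b_baseline: float = 20.0
    b_bumps: list[BFactorBump] = field(default_factory=list)
    chi_targets: dict[int, tuple[float, ...]] = field(default_factory=dict)
    altconf: list[AltconfPlan] = field(default_factory=list)
    n_waters: int = 0

    def b_value(self, res_seq: int) -> float:
        b = self.b_baseline
        for bump in self.b_bumps:
            b += bump.amplitude * np.exp(
                -((res_seq - bump.center) ** 2) / (2.0 * bump.width**2)
            )
        return b


@dataclass
class TwoChainSpec:
    """Two-chain asymmetric unit: chain B = transformed, perturbed chain A."""

    chain_a: ChainSpec
    chain_b_id: str = "B"
    rotation_deg: tuple[float, float, float] = (30.0, 0.0, 0.0)  # about x, y, z
    translation: tuple[float, float, float] = (0.0, 25.0, 0.0)
    b_scale_b: float = 1.0
    b_bumps_b: list[BFactorBump] | None = None  # None: reuse chain A's bumps
    chi_overrides_b: dict[int, tuple[float, ...]] = field(default_factory=dict)
    altconf_b: list[AltconfPlan] | None = None
    n_waters_b: int = 0
    loop_shift_res: int | None = None
    loop_shift_magnitude: float = 0.0
    loop_shift_halfwidth: int = 3
    cell_padding: float = 20.0
    contact_gap: float | None = None  # along x; None: isolated cell
    space_group: str = "P 1"
    seed: int = 0


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------

def _build_backbone(spec: ChainSpec) -> list[dict[str, np.ndarray]]:
    n = len(spec.sequence)
    res: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n):
        prev = res[-1]
        Ni = nerf_place(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, spec.psi)
        CAi = nerf_place(prev["CA"], prev["C"], Ni, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        Ci = nerf_place(prev["C"], Ni, CAi, BOND_CA_C, ANGLE_N_CA_C, spec.phi)
        res.append({"N": Ni, "CA": CAi, "C": Ci})
    for i, r in enumerate(res):
        nxt_psi = spec.psi
        r["O"] = nerf_place(r["N"], r["CA"], r["C"], BOND_C_O, ANGLE_CA_C_O, nxt_psi + 180.0)
    return res


def _place_side_chain(
    res_name: str, backbone: dict[str, np.ndarray], chi: tuple[float, ...]
) -> dict[str, np.ndarray]:
    """CB plus template atoms at the requested chi torsions."""
    if res_name not in SUPPORTED_RESIDUES:
        raise ValueError(f"unsupported residue type {res_name!r}")
    out: dict[str, np.ndarray] = {}
    if res_name == "GLY":
        return out
    coords = dict(backbone)
    cb = nerf_place(coords["C"], coords["N"], coords["CA"], BOND_CA_CB, ANGLE_N_CA_CB, CB_IMPROPER)
    coords["CB"] = cb
    out["CB"] = cb
    if res_name == "ALA":
        return out
    n_chi = N_CHI[res_name]
    if len(chi) != n_chi:
        raise ValueError(f"{res_name}: need {n_chi} chi values, got {len(chi)}")
    for name, refs, bond, angle, torsion in _T[res_name]:
        kind = torsion[0]
        if kind == "chi":
            t = chi[torsion[1] - 1]
        elif kind == "chi+":
            t = chi[torsion[1] - 1] + torsion[2]
        else:
            t = torsion[1]
        pos = nerf_place(coords[refs[0]], coords[refs[1]], coords[refs[2]], bond, angle, t)
        coords[name] = pos
        out[name] = pos
    return out


#: atoms shared between alternate conformations (backbone + CB)
_SHARED_ATOMS = {"N", "CA", "C", "O", "CB"}


def build_chain(spec: ChainSpec, seed: int = 0) -> StructureModel:
    """One ideal-geometry chain (plus waters) as a StructureModel."""
    for rname in spec.sequence:
        if rname not in SUPPORTED_RESIDUES:
            raise ValueError(f"unsupported residue type {rname!r}")
    backbone = _build_backbone(spec)
    altconf_by_seq = {p.res_seq: p for p in spec.altconf}
    model = StructureModel(id=f"synthetic-{spec.chain_id}")
    residues: list[Residue] = []
    serial = 1
    for i, rname in enumerate(spec.sequence):
        res_seq = spec.start_res_seq + i
        b = spec.b_value(res_seq)
        bb = backbone[i]
        plan = altconf_by_seq.get(res_seq)
        atoms: list[AtomRecord] = []

        def add(name: str, pos: np.ndarray, altloc: str = "", occ: float = 1.0):
            nonlocal serial
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    altloc=altloc,
                    res_name=rname,
                    chain_id=spec.chain_id,
                    res_seq=res_seq,
                    i_code="",
                    pos=pos,
                    occupancy=occ,
                    b_iso=b,
                    element=_element_for(name),
                )
            )
            serial += 1

        for name in ("N", "CA", "C", "O"):
            add(name, bb[name])
        if plan is None:
            chi = spec.chi_targets.get(res_seq, DEFAULT_CHI[rname])
            for name, pos in _place_side_chain(rname, bb, tuple(chi)).items():
                add(name, pos)
        else:
            side_a = _place_side_chain(rname, bb, tuple(plan.chi_a))
            side_b = _place_side_chain(rname, bb, tuple(plan.chi_b))
            if "CB" in side_a:
                add("CB", side_a["CB"])  # shared: CB position identical for both
            for name, pos in side_a.items():
                if name in _SHARED_ATOMS:
                    continue
                add(name, pos, altloc="A", occ=plan.occ_a)
            for name, pos in side_b.items():
                if name in _SHARED_ATOMS:
                    continue
                add(name, pos, altloc="B", occ=plan.occ_b)
        residues.append(Residue(spec.chain_id, res_seq, "", rname, atoms))
    model.chains[spec.chain_id] = residues
    _add_waters(model, spec.chain_id, spec.n_waters, spec.b_baseline, seed)
    model.validate()
    return model


def _add_waters(
    model: StructureModel, chain_id: str, n: int, b: float, seed: int
) -> None:
    """Rejection-sample waters >= 3.0 A from protein, >= 2.4 A from each other."""
    if n <= 0:
        return
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    coords = np.array([a.pos for res in model.chains[chain_id] for a in res.atoms])
    tree = cKDTree(coords)
    lo = coords.min(axis=0) - 6.0
    hi = coords.max(axis=0) + 6.0
    placed: list[np.ndarray] = []
    serial = 10000 + sum(len(r.atoms) for r in model.chains[chain_id])
    tries = 0
    while len(placed) < n and tries < 200000:
        tries += 1
        p = rng.uniform(lo, hi)
        if tree.query(p)[0] < 3.0 or tree.query(p)[0] > 8.0:
            continue  # keep waters in a believable solvation shell
        if placed and np.min(np.linalg.norm(np.array(placed) - p, axis=1)) < 2.4:
            continue
        placed.append(p)
        model.waters.append(
            AtomRecord(
                serial=serial + len(placed),
                name="O",
                altloc="",
                res_name="HOH",
                chain_id=chain_id,
                res_seq=1000 + len(placed),
                i_code="",
                pos=p,
                occupancy=1.0,
                b_iso=b,
                element="O",
            )
        )
    if len(placed) < n:
        raise RuntimeError(f"could not place {n} waters (placed {len(placed)})")


# ---------------------------------------------------------------------------
# rigid transforms and torque-free displacement fields
# ---------------------------------------------------------------------------

def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(np.radians(rx)), np.sin(np.radians(rx))
    cy, sy = np.cos(np.radians(ry)), np.sin(np.radians(ry))
    cz, sz = np.cos(np.radians(rz)), np.sin(np.radians(rz))
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _project_out_rigid_modes(X: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Remove the components of displacement field D (on points X) that a
    rigid-body fit would absorb (3 translations + 3 infinitesimal rotations)."""
    n = len(X)
    c = X.mean(axis=0)
    modes = []
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        modes.append(np.tile(e, n))
    rel = X - c
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        modes.append(np.cross(np.tile(e, (n, 1)), rel).ravel())
    M = np.array(modes).T  # (3n, 6)
    Q, _ = np.linalg.qr(M)
    d = D.ravel()
    return (d - Q @ (Q.T @ d)).reshape(n, 3)


def build_two_chain_asu(spec: TwoChainSpec) -> tuple[StructureModel, dict]:
    """Two-chain asymmetric unit plus a ground-truth table.

    Chain B is chain A under a rigid transform with the designed
    perturbations applied first (in the chain A frame).  Returns
    (model, ground_truth).
    """
    a_spec = spec.chain_a
    model = build_chain(a_spec, seed=spec.seed)

    # chain B: same backbone, its own B profile / chi / altconf plan
    b_bumps = spec.b_bumps_b if spec.b_bumps_b is not None else list(a_spec.b_bumps)
    b_spec = replace(
        a_spec,
        chain_id=spec.chain_b_id,
        b_baseline=a_spec.b_baseline * spec.b_scale_b,
        b_bumps=[
            BFactorBump(b.center, b.width, b.amplitude * spec.b_scale_b) for b in b_bumps
        ],
        chi_targets={**a_spec.chi_targets, **spec.chi_overrides_b},
        altconf=spec.altconf_b if spec.altconf_b is not None else list(a_spec.altconf),
        n_waters=0,
    )
    model_b = build_chain(b_spec, seed=spec.seed + 1)
    chain_b = model_b.chains[spec.chain_b_id]

    # designed loop shift, made invisible to a rigid-body fit
    apex_actual = 0.0
    if spec.loop_shift_res is not None and spec.loop_shift_magnitude > 0:
        ca = np.array(
            [r.first_conformer().atom("CA").pos for r in chain_b]
        )
        seqs = np.array([r.res_seq for r in chain_b])
        apex = spec.loop_shift_res
        i_apex = int(np.nonzero(seqs == apex)[0][0])
        # direction that opens the 235-239 style marker pair if present,
        # otherwise a fixed transverse direction
        direction = np.array([0.0, 0.0, 1.0])
        w = np.where(
            np.abs(seqs - apex) <= spec.loop_shift_halfwidth,
            np.cos(np.pi * (seqs - apex) / (2.0 * (spec.loop_shift_halfwidth + 1))) ** 2,
            0.0,
        )
        D = np.outer(w, direction)
        D = _project_out_rigid_modes(ca, D)
        scale = spec.loop_shift_magnitude / np.linalg.norm(D[i_apex])
        D *= scale
        apex_actual = float(np.linalg.norm(D[i_apex]))
        for res, d in zip(chain_b, D):
            for atom in res.atoms:
                atom.pos = atom.pos + d

    # rigid placement of chain B next to chain A
    R = _rotation_matrix(*spec.rotation_deg)
    t = np.array(spec.translation, dtype=float)
    for res in chain_b:
        for atom in res.atoms:
            atom.pos = R @ atom.pos + t
    base_serial = max(a.serial for a in model.all_atoms()) + 100
    for res in chain_b:
        for atom in res.atoms:
            atom.serial += base_serial
    model.chains[spec.chain_b_id] = chain_b
    _add_waters(model, spec.chain_b_id, spec.n_waters_b, b_spec.b_baseline, spec.seed + 2)

    # unit cell: isolated by default, or sized to create +/-x lattice contacts
    coords = np.array([a.pos for a in model.all_atoms()])
    ext = coords.max(axis=0) - coords.min(axis=0)
    pad = spec.cell_padding
    if spec.contact_gap is not None:
        cell = UnitCell(ext[0] + spec.contact_gap, ext[1] + pad, ext[2] + pad)
    else:
        cell = UnitCell(ext[0] + pad, ext[1] + pad, ext[2] + pad)
    model.cell = cell
    model.space_group = spec.space_group
    model.symops = space_group_operators(spec.space_group)
    model.validate()

    n_wa, n_wb = a_spec.n_waters, spec.n_waters_b
    # zero-chi residues (GLY/ALA) are trivially assignable and always match,
    # so they sit in the denominator of the rotamer-difference fraction
    n_chi_positions = len(a_spec.sequence)
    truth = {
        "apex_res_seq": spec.loop_shift_res,
        "apex_shift_A": apex_actual if spec.loop_shift_res is not None else 0.0,
        "designed_shift_A": spec.loop_shift_magnitude,
        "water_pct_diff": round(100.0 * (n_wb - n_wa) / n_wa) if n_wa else None,
        "b_pct_diff": round(100.0 * (spec.b_scale_b - 1.0)),
        "b_bump_centers": [b.center for b in a_spec.b_bumps],
        "chi_overrides_b": sorted(spec.chi_overrides_b),
        "rotamer_diff_fraction": (
            len(spec.chi_overrides_b) / n_chi_positions if n_chi_positions else 0.0
        ),
        "altconf_a": sorted(p.res_seq for p in a_spec.altconf),
        "altconf_b": sorted(
            p.res_seq for p in (spec.altconf_b if spec.altconf_b is not None else a_spec.altconf)
        ),
    }
    return model, truth


# ---------------------------------------------------------------------------
# pseudo-ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsemblePlan:
    """Per-position rotamer-label distributions for an ensemble of chains."""

    sequence: list[str]
    start_res_seq: int = 1
    label_distributions: dict[int, dict[str, float]] = field(default_factory=dict)
    n_chains: int = 50
    seed: int = 0


def _chi_for_label(res_name: str, label: str) -> tuple[float, ...]:
    n = N_CHI[res_name]
    if n == 0:
        return ()
    # split the label into per-chi letters; "90"/"0" only occur terminally
    letters: list[str] = []
    i = 0
    while i < len(label):
        if label[i].isdigit():
            letters.append(label[i:])
            break
        letters.append(label[i])
        i += 1
    if len(letters) != n:
        raise ValueError(f"label {label!r} does not fit {res_name} ({n} chi)")
    return tuple(MODE_OF_LETTER[let] for let in letters)


def build_pseudo_ensemble(plan: EnsemblePlan) -> tuple[list[StructureModel], dict]:
    """n chains with per-position rotamers drawn from the plan's distributions.

    Returns (models, ground_truth) where ground_truth records the planned
    distributions and the actually sampled label counts per position.
    """
    rng = np.random.default_rng(plan.seed)
    models = []
    sampled: dict[int, dict[str, int]] = {
        pos: {lab: 0 for lab in dist} for pos, dist in plan.label_distributions.items()
    }
    for k in range(plan.n_chains):
        chi_targets: dict[int, tuple[float, ...]] = {}
        for pos, dist in plan.label_distributions.items():
            labels = sorted(dist)
            probs = np.array([dist[lab] for lab in labels], dtype=float)
            probs /= probs.sum()
            lab = labels[int(rng.choice(len(labels), p=probs))]
            sampled[pos][lab] += 1
            rname = plan.sequence[pos - plan.start_res_seq]
            chi_targets[pos] = _chi_for_label(rname, lab)
        spec = ChainSpec(
            sequence=list(plan.sequence),
            chain_id="A",
            start_res_seq=plan.start_res_seq,
            chi_targets=chi_targets,
        )
        models.append(build_chain(spec, seed=plan.seed * 100003 + k))
    truth = {
        "planned": plan.label_distributions,
        "sampled_counts": sampled,
        "n_chains": plan.n_chains,
    }
    return models, truth


# ---------------------------------------------------------------------------
# special-purpose fixtures
# ---------------------------------------------------------------------------

def build_loop_templates(
    states: dict[str, float] | None = None, seed: int = 0
) -> dict[str, StructureModel]:
    """Chains whose 235-239 Calpha distance is opened by a known margin.

    ``states`` maps a template name to the extra opening (A) applied by
    translating the chain tail from residue 238 onward along the 235->239
    Calpha direction; the default set is closed (0), open (+1.4) and
    extra-open (+2.8), echoing a loop that normally toggles between two
    states but can be caught beyond its usual open form.
    """
    states = states or {"closed": 0.0, "open": 1.4, "extra-open": 2.8}
    sequence = ["ALA", "SER", "LEU", "MET", "VAL", "THR", "LYS", "GLU", "PHE",
                "ALA", "LEU", "SER", "VAL", "MET", "ALA", "THR"]
    base = ChainSpec(sequence=sequence, chain_id="A", start_res_seq=230)
    out = {}
    for name, extra in states.items():
        model = build_chain(base, seed=seed)
        chain = model.chains["A"]
        ca235 = next(r for r in chain if r.res_seq == 235).first_conformer().atom("CA").pos
        ca239 = next(r for r in chain if r.res_seq == 239).first_conformer().atom("CA").pos
        direction = (ca239 - ca235) / np.linalg.norm(ca239 - ca235)
        for res in chain:
            if res.res_seq >= 238:
                for atom in res.atoms:
                    atom.pos = atom.pos + extra * direction
        model.id = f"loop-{name}"
        out[name] = model
    return out


def build_spherical_cage(
    shell_radius: float = 8.0,
    n_shell_atoms: int = 400,
    res_seq_start: int = 235,
) -> StructureModel:
    """A hollow cage of carbon atoms on a sphere (synthetic pocket fixture).

    The interior cavity accessible to grid points has radius
    ``shell_radius - (r_C + probe)``; useful as an analytic reference for
    the grid pocket-volume estimate.  Atoms are assigned to dummy ALA
    residues so site selections by residue range can address them.
    """
    from .lattice import golden_spiral_points

    pts = shell_radius * golden_spiral_points(n_shell_atoms)
    residues = []
    atoms_per_res = 8
    serial = 1
    for start in range(0, len(pts), atoms_per_res):
        res_seq = res_seq_start + start // atoms_per_res
        atoms = []
        for j, p in enumerate(pts[start:start + atoms_per_res]):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=f"C{j + 1}",
                    altloc="",
                    res_name="ALA",
                    chain_id="A",
                    res_seq=res_seq,
                    i_code="",
                    pos=p,
                    occupancy=1.0,
                    b_iso=20.0,
                    element="C",
                )
            )
            serial += 1
        residues.append(Residue("A", res_seq, "", "ALA", atoms))
    model = StructureModel(id="cage", chains={"A": residues})
    model.validate()
    return model


def _align_chain_axis_to_x(model: StructureModel, chain_id: str) -> None:
    """Rotate all atoms so the chain's principal Calpha axis runs along +x
    (first residue at x-min).  Needed before sizing a contact-gap cell."""
    chain = model.chains[chain_id]
    ca = np.array([r.first_conformer().atom("CA").pos for r in chain])
    center = ca.mean(axis=0)
    _u, _s, vt = np.linalg.svd(ca - center)
    R = vt  # rows: principal directions
    if np.linalg.det(R) < 0:
        R[2] *= -1.0
    if (R @ (ca[-1] - ca[0]))[0] < 0:
        # flip so the chain runs toward +x; keep handedness
        R = np.diag([-1.0, -1.0, 1.0]) @ R
    for res in chain:
        for atom in res.atoms:
            atom.pos = R @ (atom.pos - center)
    for w in model.waters:
        if w.chain_id == chain_id:
            w.pos = R @ (w.pos - center)


def build_contact_lattice(seed: int = 0) -> tuple[StructureModel, dict]:
    """Single chain in a P1 cell engineered for known lattice contacts.

    The chain is extended along x and the cell's a axis equals the chain's
    x extent plus a small gap, so the +/-x symmetry images touch the chain
    termini; b and c are padded so no other image comes close.  Five
    residues carry alternate conformations: the two terminal ones sit at
    the engineered interfaces, the three mid-chain ones do not.  The
    builder verifies its own construction (terminal heavy atoms within the
    contact cutoff of a mate, mid-chain altconf residues well outside it)
    and reports the designed attribution in the ground-truth table.
    """
    motif = ["LEU", "SER", "VAL", "THR", "GLU", "PHE", "GLY", "LYS", "MET", "ALA"]
    sequence = [motif[i % len(motif)] for i in range(60)]
    sequence[0], sequence[59] = "SER", "MET"  # terminal residues need side chains
    cutoff = 4.0
    altconf = [
        AltconfPlan(1, chi_a=(-60.0,), chi_b=(180.0,)),                  # SER, x-min end
        AltconfPlan(60, chi_a=(-60.0, 180.0, 180.0),
                    chi_b=(180.0, 180.0, 180.0)),                        # MET, x-max end
        AltconfPlan(21, chi_a=(-60.0, 180.0), chi_b=(180.0, 180.0)),     # LEU, interior
        AltconfPlan(32, chi_a=(-60.0,), chi_b=(180.0,)),                 # SER, interior
        AltconfPlan(45, chi_a=(-60.0, 180.0, 0.0), chi_b=(60.0, 180.0, 0.0)),  # GLU
    ]
    spec = ChainSpec(sequence=sequence, chain_id="A", start_res_seq=1, altconf=altconf)
    model = build_chain(spec, seed=seed)
    _align_chain_axis_to_x(model, "A")
    chain = model.chains["A"]
    coords = np.array([a.pos for res in chain for a in res.atoms])
    ext = coords.max(axis=0) - coords.min(axis=0)

    # choose the cell length a along x so that the +x lattice image neither
    # clashes with the chain anywhere (clearance >= 2.6 A) nor drifts out of
    # contact range of the terminal residues: for a pure x translation the
    # distance between atom i and image atom j is sqrt((a - (x_i - x_j))^2 +
    # transverse_ij^2), so scan a upward from the x extent
    pts60 = np.array([a.pos for a in next(r for r in chain if r.res_seq == 60).atoms])
    pts1 = np.array([a.pos for a in next(r for r in chain if r.res_seq == 1).atoms])

    def _min_dist(a_len: float, left: np.ndarray, right: np.ndarray) -> float:
        dx = a_len - (left[:, None, 0] - right[None, :, 0])
        t2 = (left[:, None, 1] - right[None, :, 1]) ** 2 + (
            left[:, None, 2] - right[None, :, 2]
        ) ** 2
        return float(np.sqrt((dx**2 + t2).min()))

    a_len = None
    for cand in np.arange(ext[0] - 2.0, ext[0] + 6.0, 0.05):
        if _min_dist(cand, pts60, coords) > 2.6 and _min_dist(cand, coords, pts1) > 2.6 \
                and _min_dist(cand, coords, coords) > 2.6:
            a_len = float(cand)
            break
    if a_len is None:
        raise RuntimeError("contact design failed: no clash-free cell length")
    model.cell = UnitCell(a_len, ext[1] + 30.0, ext[2] + 30.0)
    model.space_group = "P 1"
    model.symops = space_group_operators("P 1")

    # self-check: the terminal residues really touch their lattice images
    for res_seq, pts in ((60, pts60), (1, pts1)):
        dmin = (
            _min_dist(a_len, pts, coords)
            if res_seq == 60
            else _min_dist(a_len, coords, pts)
        )
        if dmin > cutoff:
            raise RuntimeError(
                f"contact design failed: terminal residue {res_seq} is {dmin:.2f} A from its mate"
            )
    truth = {
        "altconf_residues": [1, 21, 32, 45, 60],
        "contact_affected": [1, 60],
        "contact_cutoff": cutoff,
        "cell_a": a_len,
    }
    return model, truth


# ---------------------------------------------------------------------------
# the default study conditions
# ---------------------------------------------------------------------------

def default_two_chain_spec(seed: int = 0) -> TwoChainSpec:
    """The default synthetic study conditions.

    A 100-residue chain (numbered 180-279 so it spans the 235/239 openness
    markers), with chain B carrying the designed differentials: a 1.4 A
    Calpha loop shift at residue 239, 25% lower B factors, 49% more ordered
    waters (149 vs 100), rotamer changes at ten positions, and alternate
    conformations whose placement at the chain termini engineers two of the
    five chain-B altconf residues into lattice contacts under the
    contact-gap cell.
    """
    motif = ["LEU", "SER", "VAL", "THR", "GLU", "PHE", "GLY", "LYS", "MET", "ALA"]
    sequence = [motif[i % len(motif)] for i in range(100)]
    start = 180

    # residue type at res_seq: motif[res_seq % 10] (start 180 is motif[0])
    altconf_a = [
        AltconfPlan(201, chi_a=(-60.0,), chi_b=(180.0,)),                # SER
        AltconfPlan(212, chi_a=(180.0,), chi_b=(60.0,)),                 # VAL
        AltconfPlan(225, chi_a=(-60.0, 90.0), chi_b=(180.0, 90.0)),      # PHE
        AltconfPlan(247, chi_a=(180.0, 180.0, 180.0, 180.0),
                    chi_b=(-60.0, 180.0, 180.0, 180.0)),                 # LYS
        AltconfPlan(264, chi_a=(-60.0, 180.0, 0.0), chi_b=(60.0, 180.0, 0.0)),  # GLU
        AltconfPlan(270, chi_a=(-60.0, 180.0), chi_b=(180.0, 180.0)),    # LEU
    ]
    altconf_b = [
        AltconfPlan(180, chi_a=(-60.0, 180.0), chi_b=(180.0, 180.0)),    # LEU
        AltconfPlan(278, chi_a=(-60.0, 180.0, 180.0),
                    chi_b=(180.0, 180.0, 180.0)),                        # MET
        AltconfPlan(222, chi_a=(180.0,), chi_b=(60.0,)),                 # VAL
        AltconfPlan(235, chi_a=(-60.0, 90.0), chi_b=(180.0, 90.0)),      # PHE
        AltconfPlan(251, chi_a=(-60.0,), chi_b=(180.0,)),                # SER
    ]
    # rotamer overrides in chain B at ten single-conformer positions; each
    # flips chi1 away from the type's default bin
    chi_overrides_b = {
        184: (60.0, 180.0, 0.0),   # GLU
        191: (60.0,),              # SER
        204: (60.0, 180.0, 0.0),   # GLU
        214: (60.0, 180.0, 0.0),   # GLU
        231: (60.0,),              # SER
        241: (60.0,),              # SER
        252: (60.0,),              # VAL
        261: (60.0,),              # SER
        271: (60.0,),              # SER
        274: (60.0, 180.0, 0.0),   # GLU
    }

    chain_a = ChainSpec(
        sequence=sequence,
        chain_id="A",
        start_res_seq=start,
        b_baseline=32.0,
        b_bumps=[BFactorBump(center=186, width=3.0, amplitude=18.0)],
        altconf=altconf_a,
        n_waters=100,
    )
    return TwoChainSpec(
        chain_a=chain_a,
        b_scale_b=0.75,
        chi_overrides_b=chi_overrides_b,
        altconf_b=altconf_b,
        n_waters_b=149,
        loop_shift_res=239,
        loop_shift_magnitude=1.4,
        loop_shift_halfwidth=3,
        contact_gap=None,  # lattice-contact truths live in build_contact_lattice
        space_group="P 1",
        seed=seed,
    )
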