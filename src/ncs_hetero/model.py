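"""In-memory model for multiconformer crystal structures.

The model mirrors what a refined X-ray structure deposits: chains of residues
whose atoms may carry alternate-location (altloc) identifiers with partial
occupancies, ordered waters kept per author chain, and the crystallographic
frame (unit cell plus space-group operators) needed to rebuild the lattice.

Altloc convention: atoms with a blank altloc in a residue that also has
lettered atoms are *shared* by every conformer of that residue (the usual
convention for residues whose backbone is single but whose side chain is
split).  A residue "has alternate conformations" iff at least two distinct
lettered altloc identifiers appear on any of its atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueConformer",
    "Residue",
    "UnitCell",
    "StructureModel",
    "ModelError",
    "STANDARD_AMINO_ACIDS",
    "select_atoms",
    "count_waters",
    "count_altconf_residues",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: altloc sum may exceed 1 by this much before we flag it (deposited models
#: often carry 0.51/0.50 style rounding)
OCC_SUM_TOL = 0.01


class ModelError(ValueError):
    """Raised when a structure violates a model invariant."""


@dataclass
class AtomRecord:
    """One coordinate record (one ATOM/HETATM line)."""

    serial: int
    name: str
    altloc: str  # single letter or "" for blank
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str  # insertion code or ""
    pos: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_iso: float = 0.0
    element: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,):
            raise ModelError(f"atom {self.name}: pos must be a 3-vector")
        if not np.all(np.isfinite(self.pos)):
            raise ModelError(f"atom {self.name}: non-finite coordinates")
        if not (0.0 <= self.occupancy <= 1.0 + 1e-9):
            raise ModelError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_iso < 0:
            raise ModelError(f"atom {self.name}: negative B factor {self.b_iso}")
        if not self.element:
            # PDB guesses: first letter of a left-justified name
            self.element = self.name.strip()[:1]

    def key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.i_code, self.name, self.altloc)

    def copy(self) -> "AtomRecord":
        return replace(self, pos=self.pos.copy())


@dataclass
class ResidueConformer:
    """One alternate conformation of a residue (shared blank atoms included)."""

    altloc: str
    atoms: list[AtomRecord]

    @property
    def occupancy(self) -> float:
        return min(a.occupancy for a in self.atoms)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Residue:
    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)

    @property
    def lettered_altlocs(self) -> list[str]:
        return sorted({a.altloc for a in self.atoms if a.altloc})

    @property
    def has_altconf(self) -> bool:
        return len(self.lettered_altlocs) >= 2

    @property
    def is_polymer(self) -> bool:
        return self.res_name in STANDARD_AMINO_ACIDS

    def conformers(self) -> list[ResidueConformer]:
        """Split into conformers; blank-altloc atoms are shared by each."""
        letters = self.lettered_altlocs
        shared = [a for a in self.atoms if not a.altloc]
        if not letters:
            return [ResidueConformer("", list(self.atoms))]
        out = []
        for letter in letters:
            own = [a for a in self.atoms if a.altloc == letter]
            out.append(ResidueConformer(letter, shared + own))
        return out

    def first_conformer(self) -> ResidueConformer:
        """Lowest-lettered conformer (or the blank one)."""
        return self.conformers()[0]

    def atom(self, name: str, altloc_policy: str = "first") -> AtomRecord | None:
        return self.first_conformer().atom(name)


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ModelError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not (0.0 < ang < 180.0):
                raise ModelError(f"cell angle {ang} outside (0, 180)")


@dataclass
class StructureModel:
    """Chains of residues plus waters, cell and space-group operators.

    ``chains`` maps chain_id to the ordered residue list (polymer and any
    non-water heteroresidues); waters keep their author chain_id but live in
    ``waters`` so per-chain bookkeeping stays explicit.
    """

    id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    waters: list[AtomRecord] = field(default_factory=list)
    cell: UnitCell | None = None
    space_group: str | None = None
    symops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise ModelError(
                f"unknown chain {chain_id!r}; have {sorted(self.chains)}"
            )
        return self.chains[chain_id]

    def residue(self, chain_id: str, res_seq: int, i_code: str = "") -> Residue:
        for res in self.chain(chain_id):
            if res.res_seq == res_seq and res.i_code == i_code:
                return res
        raise ModelError(f"residue {chain_id}{res_seq}{i_code} not found")

    def all_atoms(self) -> Iterator[AtomRecord]:
        for residues in self.chains.values():
            for res in residues:
                yield from res.atoms
        yield from self.waters

    def validate(self) -> None:
        seen: set[tuple] = set()
        for atom in self.all_atoms():
            k = atom.key()
            if k in seen:
                raise ModelError(f"duplicate atom record {k}")
            seen.add(k)
        for residues in self.chains.values():
            for res in residues:
                for a in res.atoms:
                    if (a.chain_id, a.res_seq, a.i_code, a.res_name) != (
                        res.chain_id,
                        res.res_seq,
                        res.i_code,
                        res.res_name,
                    ):
                        raise ModelError(f"atom {a.key()} disagrees with residue {res.id}")
                letters = res.lettered_altlocs
                if letters:
                    occ = sum(
                        min(a.occupancy for a in res.atoms if a.altloc == letter)
                        for letter in letters
                    )
                    if occ > 1.0 + OCC_SUM_TOL:
                        raise ModelError(
                            f"residue {res.id}: altloc occupancies sum to {occ:.3f} > 1"
                        )
        if self.symops:
            rot0, tr0 = self.symops[0]
            if not (np.allclose(rot0, np.eye(3)) and np.allclose(tr0, 0.0)):
                raise ModelError("first symmetry operator must be the identity")

    def copy(self) -> "StructureModel":
        new = StructureModel(
            id=self.id,
            cell=self.cell,
            space_group=self.space_group,
            symops=[(r.copy(), t.copy()) for r, t in self.symops],
        )
        for cid, residues in self.chains.items():
            new.chains[cid] = [
                Residue(r.chain_id, r.res_seq, r.i_code, r.res_name, [a.copy() for a in r.atoms])
                for r in residues
            ]
        new.waters = [a.copy() for a in self.waters]
        return new


# ---------------------------------------------------------------------------
# selections and per-chain counts
# ---------------------------------------------------------------------------

def _atom_sort_key(a: AtomRecord) -> tuple:
    return (a.chain_id, a.res_seq, a.i_code, a.name, a.altloc)


def select_atoms(
    model: StructureModel,
    chain_id: str | None = None,
    atom_name: str | None = None,
    polymer_only: bool = True,
    altloc_policy: str = "all",
    include_hydrogens: bool = False,
) -> list[AtomRecord]:
    """Deterministically ordered atom selection.

    altloc_policy:
      * ``all`` — every atom record;
      * ``first`` — one conformer per residue (lowest altloc letter, shared
        blank atoms included);
      * ``blank-or-A`` — atoms whose altloc is blank or "A".
    """
    if altloc_policy not in ("all", "first", "blank-or-A"):
        raise ValueError(f"unknown altloc_policy {altloc_policy!r}")
    out: list[AtomRecord] = []
    for cid, residues in model.chains.items():
        if chain_id is not None and cid != chain_id:
            continue
        for res in residues:
            if polymer_only and not res.is_polymer:
                continue
            if altloc_policy == "first":
                atoms: Iterable[AtomRecord] = res.first_conformer().atoms
            elif altloc_policy == "blank-or-A":
                atoms = [a for a in res.atoms if a.altloc in ("", "A")]
            else:
                atoms = res.atoms
            for a in atoms:
                if atom_name is not None and a.name != atom_name:
                    continue
                if not include_hydrogens and a.element in ("H", "D"):
                    continue
                out.append(a)
    if not polymer_only:
        for a in model.waters:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if atom_name is not None and a.name != atom_name:
                continue
            out.append(a)
    out.sort(key=_atom_sort_key)
    return out


def count_waters(model: StructureModel, chain_id: str) -> int:
    """Number of distinct ordered water residues with the given author chain."""
    return len(
        {(a.res_seq, a.i_code) for a in model.waters if a.chain_id == chain_id}
    )


def count_altconf_residues(
    model: StructureModel, chain_id: str, polymer_only: bool = True
) -> int:
    """Residues carrying >= 2 distinct lettered altloc identifiers."""
    n = 0
    for res in model.chain(chain_id):
        if polymer_only and not res.is_polymer:
            continue
        if res.has_altconf:
            n += 1
    return n
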