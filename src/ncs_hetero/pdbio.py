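"""Reading and writing multiconformer coordinate files.

Parsing is delegated to gemmi (PDB v3.3 fixed columns, mmCIF ``atom_site``)
and mapped onto :class:`~ncs_hetero.model.StructureModel`.  Writing is a
small fixed-column formatter of our own so the parse/write round trip is
bit-stable at PDB precision (coordinates to 0.001 A, occupancy/B to 0.01).

Space-group symbols are resolved to rotation/translation operator lists via
gemmi's full Hermann-Mauguin table; an unrecognized symbol raises instead of
guessing a lattice.
"""

from __future__ import annotations

import numpy as np

try:
    import gemmi
except ImportError as _e:  # pragma: no cover
    raise ImportError("ncs_hetero.pdbio requires gemmi") from _e

from .model import (
    AtomRecord,
    ModelError,
    Residue,
    StructureModel,
    UnitCell,
)

__all__ = [
    "PdbParseError",
    "parse_pdb",
    "read_structure",
    "write_pdb",
    "space_group_operators",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}


class PdbParseError(ValueError):
    pass


def space_group_operators(symbol: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Hermann-Mauguin symbol -> list of (3x3 rotation, fractional translation).

    The identity operator comes first.  Unknown symbols raise ModelError.
    """
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise ModelError(
            f"unknown space-group symbol {symbol!r}; expected a standard "
            "Hermann-Mauguin symbol such as 'P 1', 'P 21 21 21' or 'P 43 21 2'"
        )
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append((rot, tran))
    # keep the identity first (gemmi emits it first, but be defensive)
    ops.sort(key=lambda rt: 0 if (np.allclose(rt[0], np.eye(3)) and np.allclose(rt[1], 0)) else 1)
    return ops


def _precheck_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PdbParseError(f"line {lineno}: truncated ATOM/HETATM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise PdbParseError(
                    f"line {lineno}: malformed coordinate fields in fixed columns 31-54"
                ) from None


def _from_gemmi(st: "gemmi.Structure", model_id: str) -> StructureModel:
    model = StructureModel(id=model_id)
    cell = st.cell
    if cell is not None and cell.a > 0:
        model.cell = UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    hm = st.spacegroup_hm
    if model.cell is not None and hm:
        model.space_group = hm
        model.symops = space_group_operators(hm)
    if len(st) == 0:
        raise PdbParseError("no models / no ATOM records found")
    gm = st[0]
    for gchain in gm:
        cid = gchain.name
        for gres in gchain:
            rname = gres.name.strip()
            is_water = rname in WATER_NAMES
            icode = gres.seqid.icode.strip()
            for gatom in gres:
                altloc = gatom.altloc if gatom.altloc != "\0" else ""
                rec = AtomRecord(
                    serial=gatom.serial,
                    name=gatom.name.strip(),
                    altloc=altloc.strip(),
                    res_name=rname,
                    chain_id=cid,
                    res_seq=gres.seqid.num,
                    i_code=icode,
                    pos=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=min(max(gatom.occ, 0.0), 1.0),
                    b_iso=max(gatom.b_iso, 0.0),
                    element=gatom.element.name,
                )
                if is_water:
                    model.waters.append(rec)
                else:
                    residues = model.chains.setdefault(cid, [])
                    if (
                        residues
                        and residues[-1].res_seq == gres.seqid.num
                        and residues[-1].i_code == icode
                        and residues[-1].res_name == rname
                    ):
                        residues[-1].atoms.append(rec)
                    else:
                        residues.append(
                            Residue(cid, gres.seqid.num, icode, rname, [rec])
                        )
    model.validate()
    return model


def parse_pdb(text: str, model_id: str = "model") -> StructureModel:
    """Parse PDB-format text into a validated StructureModel."""
    if "ATOM" not in text and "HETATM" not in text:
        raise PdbParseError("input contains no ATOM/HETATM records")
    _precheck_pdb_lines(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as e:
        raise PdbParseError(str(e)) from e
    st.setup_entities()
    return _from_gemmi(st, model_id)


def read_structure(path: str, model_id: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file (mmCIF detected by extension)."""
    mid = model_id or str(path)
    if str(path).endswith((".cif", ".cif.gz", ".mmcif")):
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        return _from_gemmi(st, mid)
    with open(path) as fh:
        return parse_pdb(fh.read(), model_id=mid)


def _format_atom_name(name: str, element: str) -> str:
    """PDB v3.3 name justification: cols 13-16, 1-2 letter elements start at 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def _atom_line(record_name: str, a: AtomRecord) -> str:
    if a.res_seq > 9999 or a.res_seq < -999:
        raise ModelError(f"res_seq {a.res_seq} overflows PDB fixed columns")
    if a.serial > 99999:
        raise ModelError(f"serial {a.serial} overflows PDB fixed columns")
    name = _format_atom_name(a.name, a.element)
    return (
        f"{record_name:<6s}{a.serial:5d} {name}{a.altloc or ' '}"
        f"{a.res_name:>3s} {a.chain_id:1s}{a.res_seq:4d}{a.i_code or ' '}   "
        f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.b_iso:6.2f}          {a.element:>2s}"
    )


def write_pdb(model: StructureModel) -> str:
    """Serialize to fixed-column PDB v3.3 text (round-trips through parse_pdb)."""
    model.validate()
    lines: list[str] = []
    if model.cell is not None:
        sg = model.space_group or "P 1"
        c = model.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {sg:<11s}{1:4d}"
        )
    for cid, residues in model.chains.items():
        last = None
        for res in residues:
            for a in res.atoms:
                lines.append(_atom_line("ATOM", a))
                last = a
        if last is not None:
            lines.append(
                f"TER   {last.serial + 1:5d}      {last.res_name:>3s} "
                f"{cid:1s}{last.res_seq:4d}{last.i_code or ' '}"
            )
    for a in model.waters:
        lines.append(_atom_line("HETATM", a))
    lines.append("END")
    return "\n".join(lines) + "\n"
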