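"""B-factor disorder metrics per chain and per residue, and their differentials.

Because the two chains compared here come from the *same* crystal and the
same refinement, no B-factor normalization is applied anywhere in this
module: raw isotropic B values are averaged as-is.  Averages are unweighted
means over atom records (an altloc pair contributes two records), matching a
plain spreadsheet mean over deposited lines; occupancy weighting is available
as an option but off by default.  Waters and non-polymer heteroatoms are
excluded from chain averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import StructureModel, count_altconf_residues, count_waters, select_atoms

__all__ = [
    "BFactorProfile",
    "BDifferenceProfile",
    "mean_bfactor",
    "per_residue_bfactor",
    "bfactor_difference",
    "chain_disorder_summary",
]

_SELECTIONS = ("calpha", "all_atoms")


def _selected(model: StructureModel, chain_id: str, selection: str):
    if selection not in _SELECTIONS:
        raise ValueError(f"selection must be one of {_SELECTIONS}, got {selection!r}")
    name = "CA" if selection == "calpha" else None
    return select_atoms(
        model, chain_id=chain_id, atom_name=name, polymer_only=True, altloc_policy="all"
    )


def mean_bfactor(
    model: StructureModel,
    chain_id: str,
    selection: str = "calpha",
    occupancy_weighted: bool = False,
) -> float:
    """Arithmetic mean isotropic B over the selected polymer atoms of a chain."""
    atoms = _selected(model, chain_id, selection)
    if not atoms:
        raise ValueError(f"chain {chain_id!r}: no atoms for selection {selection!r}")
    b = np.array([a.b_iso for a in atoms])
    if occupancy_weighted:
        w = np.array([a.occupancy for a in atoms])
        return float(np.sum(w * b) / np.sum(w))
    return float(b.mean())


@dataclass
class BFactorProfile:
    entries: list[tuple[int, str, float]]  # (res_seq, i_code, mean B A^2)
    selection: str
    chain_id: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["res_seq", "i_code", "mean_b"])

    def as_dict(self) -> dict[tuple[int, str], float]:
        return {(rs, ic): b for rs, ic, b in self.entries}


def per_residue_bfactor(
    model: StructureModel, chain_id: str, selection: str = "all_atoms"
) -> BFactorProfile:
    """Per-residue unweighted mean B over the selected atoms (all conformers)."""
    if selection not in _SELECTIONS:
        raise ValueError(f"selection must be one of {_SELECTIONS}, got {selection!r}")
    entries = []
    for res in model.chain(chain_id):
        if not res.is_polymer:
            continue
        atoms = [
            a
            for a in res.atoms
            if a.element not in ("H", "D")
            and (selection == "all_atoms" or a.name == "CA")
        ]
        if atoms:
            entries.append(
                (res.res_seq, res.i_code, float(np.mean([a.b_iso for a in atoms])))
            )
    return BFactorProfile(entries=entries, selection=selection, chain_id=chain_id)


@dataclass
class BDifferenceProfile:
    entries: list[tuple[int, str, float, float]]  # (res_seq, i_code, delta_b, relative_pct)
    selection: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["res_seq", "i_code", "delta_b", "relative_pct"]
        )


def bfactor_difference(
    profile_a: BFactorProfile, profile_b: BFactorProfile
) -> BDifferenceProfile:
    """Per-residue B difference (A minus B) over common residues.

    relative_pct uses the symmetric denominator (mean of the two chain
    values); residues where both means are zero report 0%.
    """
    if profile_a.selection != profile_b.selection:
        raise ValueError(
            f"selection mismatch: {profile_a.selection!r} vs {profile_b.selection!r}"
        )
    da, db = profile_a.as_dict(), profile_b.as_dict()
    entries = []
    for key in sorted(set(da) & set(db)):
        ba, bb = da[key], db[key]
        delta = ba - bb
        denom = 0.5 * (ba + bb)
        pct = 100.0 * delta / denom if denom > 0 else 0.0
        entries.append((key[0], key[1], float(delta), float(pct)))
    return BDifferenceProfile(entries=entries, selection=profile_a.selection)


def chain_disorder_summary(
    model: StructureModel, reference_chain: str | None = None
) -> pd.DataFrame:
    """Per-chain disorder metrics plus percent differences vs a reference chain.

    Rows: mean B (Calpha), mean B (all atoms), ordered-water count and
    altconf-residue count per chain; percent difference columns are
    100 x (other - reference) / reference, rounded to the nearest integer
    for reporting (raw per-chain values are kept at full precision).
    """
    chain_ids = [cid for cid, residues in model.chains.items() if any(r.is_polymer for r in residues)]
    if not chain_ids:
        raise ValueError("model has no polymer chains")
    ref = reference_chain or chain_ids[0]
    if ref not in chain_ids:
        raise ValueError(f"reference chain {ref!r} not among polymer chains {chain_ids}")

    metrics = {
        "mean_b_calpha": lambda cid: mean_bfactor(model, cid, "calpha"),
        "mean_b_all_atoms": lambda cid: mean_bfactor(model, cid, "all_atoms"),
        "n_waters": lambda cid: count_waters(model, cid),
        "n_altconf_residues": lambda cid: count_altconf_residues(model, cid),
    }
    rows = {}
    for name, fn in metrics.items():
        values = {cid: float(fn(cid)) for cid in chain_ids}
        row = dict(values)
        for cid in chain_ids:
            if cid == ref:
                continue
            base = values[ref]
            if base != 0:
                pct = 100.0 * (values[cid] - base) / base
            else:
                # 0 vs 0 is a 0% difference; 0 vs nonzero is undefined
                pct = 0.0 if values[cid] == 0 else np.nan
            row[f"pct_diff_{cid}_vs_{ref}"] = float(np.rint(pct)) if np.isfinite(pct) else np.nan
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
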