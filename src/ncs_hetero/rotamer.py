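"""Side-chain chi angles, rotamer binning and pseudo-ensemble rarity.

Rotamers are named with the compact p/t/m convention per chi: ``p`` near
+60 degrees, ``t`` near 180, ``m`` near -60 for sp3-sp3 torsions, letters
concatenated in chi order (e.g. leucine (-65, 175) -> "mt").  Terminal chi
angles with two-fold symmetric ends (PHE/TYR chi2, ASP chi2, GLU chi3) are
folded to [0, 180) before binning so 180-degree-equivalent orientations
never produce spurious rotamer differences; folded torsions use bins
centred at 0 and 90 degrees.

The library is a compact modal table built in here, not a dependency on
external validation software, so labels are deterministic but need not
coincide with any particular validation tool's tiers.  A chi vector whose
nearest mode lies outside that mode's half-width is labelled OUTLIER; a
conformer missing any chi-defining atom is INCOMPLETE and excluded from
statistics rather than imputed.

The pseudo-ensemble machinery treats a set of independently determined
chains of (near-)identical sequence as samples of one conformational
ensemble: per position it tabulates rotamer-label frequencies (one vote per
conformer) and flags observed labels whose ensemble frequency falls below a
rarity threshold (default 20%).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .geometry import dihedral, wrap_angle
from .model import Residue, ResidueConformer

__all__ = [
    "CHI_ATOMS",
    "SYMMETRIC_TERMINAL_CHI",
    "RotamerLibrary",
    "DEFAULT_LIBRARY",
    "RotamerAssignment",
    "EnsembleRotamerTable",
    "dihedral",
    "chi_angles",
    "assign_rotamer",
    "assign_residue",
    "interchain_rotamer_difference",
    "build_ensemble_table",
    "rarity_flags",
]

# chi-defining atom quadruples, in chi order
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "MET": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "SD"),
        ("CB", "CG", "SD", "CE"),
    ],
    "GLU": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ],
    "GLN": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
}

#: (res_name, chi index 1-based) whose terminal group is two-fold symmetric
SYMMETRIC_TERMINAL_CHI: frozenset[tuple[str, int]] = frozenset(
    {("PHE", 2), ("TYR", 2), ("ASP", 2), ("GLU", 3)}
)

ZERO_CHI_LABEL = "-"  # GLY/ALA: no chi, trivially comparable


@dataclass(frozen=True)
class ChiBin:
    letter: str
    mode: float  # degrees
    half_width: float  # degrees


# sp3-sp3 staggered wells; generous half-widths leave eclipsed gaps as outliers
_SP3_BINS = (ChiBin("p", 60.0, 55.0), ChiBin("t", 180.0, 55.0), ChiBin("m", -60.0, 55.0))
# folded symmetric torsions live on [0, 180) with period 180
_FOLDED_BINS = (ChiBin("0", 0.0, 45.0), ChiBin("90", 90.0, 45.0))


@dataclass
class RotamerLibrary:
    """Per-chi modal bins; symmetric terminal chis use folded bins."""

    sp3_bins: tuple[ChiBin, ...] = _SP3_BINS
    folded_bins: tuple[ChiBin, ...] = _FOLDED_BINS

    def bins_for(self, res_name: str, chi_index: int) -> tuple[tuple[ChiBin, ...], float]:
        """Return (bins, period) for 1-based chi index of a residue type."""
        if (res_name, chi_index) in SYMMETRIC_TERMINAL_CHI:
            return self.folded_bins, 180.0
        return self.sp3_bins, 360.0


DEFAULT_LIBRARY = RotamerLibrary()


def _circular_distance(a: float, b: float, period: float) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def chi_angles(conformer: ResidueConformer, res_name: str | None = None):
    """Chi angles chi1..chin for one residue conformer.

    Returns (angles, incomplete): ``angles`` holds the leading torsions whose
    atoms are all present; the first missing chi atom truncates the list and
    sets ``incomplete`` (deeper chis are undefined without their parents).
    """
    rname = res_name or conformer.atoms[0].res_name
    if rname not in CHI_ATOMS:
        raise ValueError(f"unknown residue type {rname!r}")
    quads = CHI_ATOMS[rname]
    angles: list[float] = []
    for quad in quads:
        atoms = [conformer.atom(n) for n in quad]
        if any(a is None for a in atoms):
            return angles, True
        angles.append(dihedral(*(a.pos for a in atoms)))
    return angles, False


def assign_rotamer(
    chi: list[float], res_name: str, library: RotamerLibrary = DEFAULT_LIBRARY
) -> str:
    """Rotamer-bin name for a complete chi vector ("mt", "OUTLIER", ...)."""
    if res_name not in CHI_ATOMS:
        raise ValueError(f"unknown residue type {res_name!r}")
    expected = len(CHI_ATOMS[res_name])
    if len(chi) != expected:
        raise ValueError(
            f"{res_name}: expected {expected} chi angles, got {len(chi)}"
        )
    if expected == 0:
        return ZERO_CHI_LABEL
    letters = []
    for i, angle in enumerate(chi, start=1):
        bins, period = library.bins_for(res_name, i)
        value = wrap_angle(angle) % period if period == 180.0 else wrap_angle(angle)
        best = min(bins, key=lambda b: _circular_distance(value, b.mode, period))
        if _circular_distance(value, best.mode, period) > best.half_width:
            return "OUTLIER"
        letters.append(best.letter)
    return "".join(letters)


@dataclass
class RotamerAssignment:
    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    altloc: str
    chi: list[float]
    label: str  # bin name, "OUTLIER", or "INCOMPLETE"

    @property
    def position(self) -> tuple[int, str]:
        return (self.res_seq, self.i_code)


def assign_residue(
    residue: Residue, library: RotamerLibrary = DEFAULT_LIBRARY
) -> list[RotamerAssignment]:
    """One assignment per conformer of a polymer residue."""
    out = []
    for conf in residue.conformers():
        chi, incomplete = chi_angles(conf, residue.res_name)
        label = "INCOMPLETE" if incomplete else assign_rotamer(chi, residue.res_name, library)
        out.append(
            RotamerAssignment(
                chain_id=residue.chain_id,
                res_seq=residue.res_seq,
                i_code=residue.i_code,
                res_name=residue.res_name,
                altloc=conf.altloc,
                chi=chi,
                label=label,
            )
        )
    return out


def _position_labels(chain: list[Residue], library: RotamerLibrary):
    """Position -> (res_name, set of conformer labels), INCOMPLETE dropped."""
    table: dict[tuple[int, str], tuple[str, set[str]]] = {}
    for res in chain:
        if not res.is_polymer or res.res_name not in CHI_ATOMS:
            continue
        labels = {
            a.label for a in assign_residue(res, library) if a.label != "INCOMPLETE"
        }
        if labels:
            table[(res.res_seq, res.i_code)] = (res.res_name, labels)
    return table


def interchain_rotamer_difference(
    chain_a: list[Residue],
    chain_b: list[Residue],
    library: RotamerLibrary = DEFAULT_LIBRARY,
) -> dict:
    """Fraction of common positions whose rotamers differ between two chains.

    A position counts as SAME when *any* pairwise combination of conformer
    labels matches between the chains (so {mt, tt} vs {tt} is SAME);
    positions not assignable in either chain are dropped from the
    denominator.
    """
    ta = _position_labels(chain_a, library)
    tb = _position_labels(chain_b, library)
    common = sorted(set(ta) & set(tb))
    different = []
    for pos in common:
        _, la = ta[pos]
        _, lb = tb[pos]
        if not (la & lb):
            different.append(pos)
    n_common = len(common)
    return {
        "n_common": n_common,
        "n_different": len(different),
        "fraction": len(different) / n_common if n_common else 0.0,
        "different_positions": different,
    }


@dataclass
class EnsembleRotamerTable:
    """Per-position rotamer-label frequencies over an ensemble of chains."""

    counts: dict[tuple[int, str], Counter] = field(default_factory=dict)
    n_conformers: dict[tuple[int, str], int] = field(default_factory=dict)
    n_chains: int = 0

    def frequency(self, position: tuple[int, str], label: str) -> float | None:
        if position not in self.counts:
            return None
        total = self.n_conformers[position]
        return self.counts[position][label] / total if total else None

    def frequencies(self, position: tuple[int, str]) -> dict[str, float]:
        total = self.n_conformers.get(position, 0)
        if not total:
            return {}
        return {lab: c / total for lab, c in self.counts[position].items()}

    def to_json_dict(self) -> dict:
        return {
            f"{rs}{ic}": self.frequencies((rs, ic)) for rs, ic in sorted(self.counts)
        }


def build_ensemble_table(
    chains: list[list[Residue]], library: RotamerLibrary = DEFAULT_LIBRARY
) -> EnsembleRotamerTable:
    """Tabulate label frequencies per position: one vote per conformer."""
    if not chains:
        raise ValueError("build_ensemble_table: need >= 1 chain")
    table = EnsembleRotamerTable(n_chains=len(chains))
    for chain in chains:
        for res in chain:
            if not res.is_polymer or res.res_name not in CHI_ATOMS:
                continue
            pos = (res.res_seq, res.i_code)
            for a in assign_residue(res, library):
                if a.label == "INCOMPLETE":
                    continue
                table.counts.setdefault(pos, Counter())[a.label] += 1
                table.n_conformers[pos] = table.n_conformers.get(pos, 0) + 1
    return table


def rarity_flags(
    assignments: list[RotamerAssignment],
    table: EnsembleRotamerTable,
    threshold: float = 0.20,
) -> pd.DataFrame:
    """Flag observed rotamers whose ensemble frequency is below ``threshold``.

    Returns one row per conformer assignment with columns including
    ``ensemble_freq`` and ``rare``; positions absent from the table get
    status "no-data" and are excluded from the structure-level fraction.
    The structure-level summary (``.attrs``) counts a residue as rare when
    any of its conformers carries a rare label.
    """
    rows = []
    for a in assignments:
        if a.label == "INCOMPLETE":
            continue
        freq = table.frequency(a.position, a.label)
        if freq is None:
            status, rare = "no-data", False
        else:
            status, rare = "ok", freq < threshold
        rows.append(
            {
                "chain": a.chain_id,
                "res_seq": a.res_seq,
                "i_code": a.i_code,
                "res_name": a.res_name,
                "altloc": a.altloc,
                "label": a.label,
                "ensemble_freq": freq,
                "status": status,
                "rare": rare,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        scored = df[df["status"] == "ok"]
        per_res = scored.groupby(["chain", "res_seq", "i_code"])["rare"].any()
        n_res = len(per_res)
        n_rare = int(per_res.sum())
    else:
        n_res = n_rare = 0
    df.attrs["n_residues"] = n_res
    df.attrs["n_rare_residues"] = n_rare
    df.attrs["rare_fraction"] = n_rare / n_res if n_res else 0.0
    df.attrs["threshold"] = threshold
    return df
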