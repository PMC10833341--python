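"""Report assembly: chain comparisons, rotamers, contacts and openness.

Each ``run_*`` function orchestrates one analysis over a parsed model and
returns plain pandas/dict outputs; ``write_outputs`` serializes them as
CSV/JSON.  Summary tables round the way structure papers print them (B
factors to 1 decimal, percent differences to integers) while the raw
per-residue outputs keep full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import disorder, lattice, pocket, rotamer, superpose
from .model import StructureModel

logger = logging.getLogger("ncs_hetero")

__all__ = [
    "RunConfig",
    "run_compare_chains",
    "run_rotamers",
    "run_contacts",
    "run_openness",
    "write_outputs",
]


@dataclass
class RunConfig:
    chains: tuple[str, str] = ("A", "B")
    contact_cutoff: float = lattice.DEFAULT_CONTACT_CUTOFF
    rarity_threshold: float = 0.20
    altloc_policy: str = "first"
    sasa_points: int = 960
    probe: float = lattice.DEFAULT_PROBE
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def log(self) -> None:
        for key, value in asdict(self).items():
            logger.info("config %s = %r", key, value)


def run_compare_chains(model: StructureModel, config: RunConfig | None = None) -> dict:
    """Inter-chain comparison: summary metrics, Calpha profile, B profiles."""
    config = config or RunConfig()
    config.log()
    polymer_chains = [
        cid for cid, res in model.chains.items() if any(r.is_polymer for r in res)
    ]
    if len(polymer_chains) < 2:
        raise ValueError(
            "model has a single polymer chain; inter-chain comparison needs two "
            "(use pairwise mode across structures instead)"
        )
    ca, cb = config.chains
    summary = disorder.chain_disorder_summary(model, reference_chain=ca)
    profile = superpose.ca_distance_profile(model.chain(ca), model.chain(cb))
    prof_a = disorder.per_residue_bfactor(model, ca, "all_atoms")
    prof_b = disorder.per_residue_bfactor(model, cb, "all_atoms")
    bdiff = disorder.bfactor_difference(prof_a, prof_b)
    rounded = summary.copy()
    for row in ("mean_b_calpha", "mean_b_all_atoms"):
        for col in (ca, cb):
            rounded.loc[row, col] = round(float(rounded.loc[row, col]), 1)
    return {
        "summary": rounded,
        "summary_raw": summary,
        "ca_profile": profile.to_dataframe(),
        "ca_rmsd": profile.rmsd,
        "b_profile_a": prof_a.to_dataframe(),
        "b_profile_b": prof_b.to_dataframe(),
        "b_difference": bdiff.to_dataframe(),
    }


def run_rotamers(
    model: StructureModel,
    config: RunConfig | None = None,
    ensemble: list[StructureModel] | None = None,
) -> dict:
    """Rotamer assignments, inter-chain differences, optional ensemble rarity."""
    config = config or RunConfig()
    config.log()
    ca, cb = config.chains
    assignments = []
    for cid in (ca, cb):
        for res in model.chain(cid):
            if res.is_polymer and res.res_name in rotamer.CHI_ATOMS:
                assignments.extend(rotamer.assign_residue(res))
    rows = [
        {
            "chain": a.chain_id,
            "res_seq": a.res_seq,
            "i_code": a.i_code,
            "res_name": a.res_name,
            "altloc": a.altloc,
            **{f"chi{i + 1}": (a.chi[i] if i < len(a.chi) else np.nan) for i in range(4)},
            "label": a.label,
        }
        for a in assignments
    ]
    diff = rotamer.interchain_rotamer_difference(model.chain(ca), model.chain(cb))
    out = {
        "assignments": pd.DataFrame(rows),
        "difference": {k: v for k, v in diff.items() if k != "different_positions"},
        "different_positions": diff["different_positions"],
    }
    if ensemble:
        chains = [chain for m in ensemble for chain in m.chains.values()]
        table = rotamer.build_ensemble_table(chains)
        per_chain = {}
        for cid in (ca, cb):
            target = [
                a
                for a in assignments
                if a.chain_id == cid
            ]
            per_chain[cid] = rotamer.rarity_flags(
                target, table, threshold=config.rarity_threshold
            )
        out["rarity"] = per_chain
        out["ensemble_table"] = table
    return out


def run_contacts(model: StructureModel, config: RunConfig | None = None) -> dict:
    """Lattice contacts, buried area and altconf attribution per chain."""
    config = config or RunConfig()
    config.log()
    mates = lattice.expand_neighbors(model, cutoff=max(config.contact_cutoff, 5.0))
    out = {}
    for cid, residues in model.chains.items():
        if not any(r.is_polymer for r in residues):
            continue
        report = lattice.find_contacts(model, cid, mates, cutoff=config.contact_cutoff)
        report.buried_area = lattice.buried_area(
            model,
            cid,
            mates,
            probe=config.probe,
            n_points=config.sasa_points,
            contact_cutoff=config.contact_cutoff,
        )
        attribution = lattice.attribute_altconf_contacts(
            model, cid, mates, shell=config.contact_cutoff
        )
        out[cid] = {"report": report, "attribution": attribution}
    return out


def run_openness(
    models: list[StructureModel],
    config: RunConfig | None = None,
    res_pair: tuple[int, int] = (235, 239),
    pocket_site: pocket.SiteDefinition | None = None,
) -> pd.DataFrame:
    """L16-style openness (and optional pocket volume) over many chains."""
    config = config or RunConfig()
    config.log()
    rows = []
    for model in models:
        for cid, residues in model.chains.items():
            if not any(r.is_polymer for r in residues):
                continue
            row = {"structure": model.id, "chain": cid}
            try:
                row["openness_A"] = pocket.l16_openness(
                    model, cid, res_pair[0], res_pair[1]
                )
            except Exception as e:  # missing marker residues: report, don't die
                row["openness_A"] = np.nan
                row["note"] = str(e)
            if pocket_site is not None:
                row["pocket_volume_A3"] = pocket.grid_pocket_volume(
                    model, cid, pocket_site
                ).volume
            rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(results: dict, out_dir: str | Path) -> list[Path]:
    """Serialize a result dictionary: DataFrames to CSV, the rest to JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_json_dict"):
            return o.to_json_dict()
        return str(o)

    json_blob = {}
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            path = out / f"{key}.csv"
            value.to_csv(path, index=isinstance(value.index, pd.Index) and value.index.name is None and not isinstance(value.index, pd.RangeIndex))
            written.append(path)
        elif isinstance(value, dict) and all(
            isinstance(v, pd.DataFrame) for v in value.values()
        ) and value:
            for sub, df in value.items():
                path = out / f"{key}_{sub}.csv"
                df.to_csv(path, index=False)
                written.append(path)
        else:
            json_blob[key] = value
    if json_blob:
        path = out / "results.json"
        with open(path, "w") as fh:
            json.dump(json_blob, fh, indent=2, default=_default)
        written.append(path)
    return written
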