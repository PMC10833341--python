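"""Chi angles, rotamer binning, inter-chain differences and rarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncs_hetero.geometry import dihedral
from ncs_hetero.rotamer import (
    CHI_ATOMS,
    DEFAULT_LIBRARY,
    assign_residue,
    assign_rotamer,
    build_ensemble_table,
    chi_angles,
    interchain_rotamer_difference,
    rarity_flags,
)
from ncs_hetero.synthetic import (
    AltconfPlan,
    ChainSpec,
    EnsemblePlan,
    build_chain,
    build_pseudo_ensemble,
)


# ---------------------------------------------------------------------------
# dihedral
# ---------------------------------------------------------------------------

def test_dihedral_cis_trans_conventions():
    a, b, c = [0.0, 1, 0], [0.0, 0, 0], [1.0, 0, 0]
    assert dihedral(a, b, c, [1.0, 1, 0]) == pytest.approx(0.0, abs=1e-12)  # cis
    trans = dihedral(a, b, c, [1.0, -1, 0])
    assert trans == -180.0  # half-open convention: +180 reported as -180


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_dihedral_matches_independent_formula(seed):
    """Random quadruples: agree with an independent atan2 construction and
    with biotite's implementation to 1e-9 degrees."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4, 3)) * 4
    b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
    if min(np.linalg.norm(np.cross(b1, b2)), np.linalg.norm(np.cross(b2, b3))) < 1e-3:
        return
    # independent construction: angle between plane normals, signed by b2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(b2 / np.linalg.norm(b2), n1)
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    oracle = np.degrees(np.arctan2(y, x))
    ours = dihedral(*pts)
    assert abs(((ours - oracle + 180) % 360) - 180) < 1e-9
    import biotite.structure as struc

    ref = np.degrees(float(struc.dihedral(*pts)))
    assert abs(((ours - ref + 180) % 360) - 180) < 1e-4


def test_dihedral_degenerate_geometry_raises():
    with pytest.raises(ValueError):
        dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
    with pytest.raises(ValueError):
        dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


# ---------------------------------------------------------------------------
# chi angles
# ---------------------------------------------------------------------------

def test_constructed_phe_chi_angles():
    model = build_chain(ChainSpec(sequence=["ALA", "PHE", "ALA"], chi_targets={2: (180.0, 90.0)}))
    conf = model.chains["A"][1].first_conformer()
    chi, incomplete = chi_angles(conf, "PHE")
    assert not incomplete
    assert chi[0] == pytest.approx(-180.0, abs=1e-6) or chi[0] == pytest.approx(180.0, abs=1e-6)
    assert chi[1] == pytest.approx(90.0, abs=1e-6)


def test_gly_has_no_chi_and_met_truncation_flags_incomplete():
    model = build_chain(ChainSpec(sequence=["GLY", "MET"]))
    gly = model.chains["A"][0].first_conformer()
    assert chi_angles(gly, "GLY") == ([], False)
    met = model.chains["A"][1]
    met.atoms = [a for a in met.atoms if a.name != "CE"]  # drop the chi3 atom
    chi, incomplete = chi_angles(met.first_conformer(), "MET")
    assert incomplete and len(chi) == 2


def test_chi_invariant_under_rigid_motion():
    from scipy.spatial.transform import Rotation

    model = build_chain(ChainSpec(sequence=["LYS"]))
    conf = model.chains["A"][0].first_conformer()
    before, _ = chi_angles(conf, "LYS")
    R0 = Rotation.from_euler("zyx", [17, -40, 95], degrees=True).as_matrix()
    for atom in model.chains["A"][0].atoms:
        atom.pos = R0 @ atom.pos + np.array([3.0, -8.0, 2.0])
    after, _ = chi_angles(model.chains["A"][0].first_conformer(), "LYS")
    assert np.allclose(before, after, atol=1e-9)


# ---------------------------------------------------------------------------
# rotamer assignment
# ---------------------------------------------------------------------------

def test_named_bins_and_outliers():
    assert assign_rotamer([178.0], "VAL") == "t"
    assert assign_rotamer([-65.0, 175.0], "LEU") == "mt"
    assert assign_rotamer([120.0], "VAL") == "OUTLIER"  # eclipsed gap
    with pytest.raises(ValueError, match="unknown residue"):
        assign_rotamer([60.0], "XXX")
    with pytest.raises(ValueError, match="expected"):
        assign_rotamer([60.0], "LEU")


def test_exhaustive_grid_matches_nearest_mode_oracle():
    """Assignment over a 1-degree chi1 grid is piecewise constant with
    boundaries at mode +/- half-width, per a brute-force nearest-mode scan."""
    modes = {"p": 60.0, "t": 180.0, "m": -60.0}
    half_width = 55.0
    for chi1 in np.arange(-180.0, 180.0, 1.0):
        ours = assign_rotamer([float(chi1)], "VAL")
        dists = {
            name: min(abs(chi1 - m) % 360, 360 - abs(chi1 - m) % 360)
            for name, m in modes.items()
        }
        best = min(dists, key=dists.get)
        expected = best if dists[best] <= half_width else "OUTLIER"
        assert ours == expected, chi1


def test_symmetric_terminal_chi_folding():
    # 180-degree-equivalent aromatic flips must land in the same bin
    assert assign_rotamer([-65.0, 90.0], "PHE") == assign_rotamer([-65.0, -90.0], "PHE")
    assert assign_rotamer([-65.0, 30.0], "ASP") == assign_rotamer([-65.0, -150.0], "ASP")
    assert assign_rotamer([-60.0, 180.0, 10.0], "GLU") == assign_rotamer(
        [-60.0, 180.0, -170.0], "GLU"
    )


# ---------------------------------------------------------------------------
# inter-chain differences
# ---------------------------------------------------------------------------

def test_identical_chains_have_zero_difference():
    chain = build_chain(ChainSpec(sequence=["LEU", "SER", "VAL"] * 5)).chains["A"]
    diff = interchain_rotamer_difference(chain, chain)
    assert diff["fraction"] == 0.0 and diff["n_common"] == 15


def test_counting_one_changed_position_in_ten():
    seq = ["VAL"] * 10
    a = build_chain(ChainSpec(sequence=seq)).chains["A"]
    b = build_chain(ChainSpec(sequence=seq, chi_targets={5: (60.0,)})).chains["A"]
    diff = interchain_rotamer_difference(a, b)
    assert diff["n_common"] == 10 and diff["n_different"] == 1
    assert diff["fraction"] == pytest.approx(0.10)
    assert diff["different_positions"] == [(5, "")]


def test_altconf_any_pair_match_counts_as_same():
    seq = ["LEU"] * 4
    a = build_chain(
        ChainSpec(
            sequence=seq,
            altconf=[AltconfPlan(2, chi_a=(-60.0, 180.0), chi_b=(180.0, 180.0))],
        )
    ).chains["A"]
    b = build_chain(ChainSpec(sequence=seq, chi_targets={2: (180.0, 180.0)})).chains["A"]
    # position 2: A has {mt, tt}, B has {tt} -> SAME
    diff = interchain_rotamer_difference(a, b)
    assert diff["n_different"] == 0


def test_difference_symmetric(two_chain_model):
    a, b = two_chain_model.chain("A"), two_chain_model.chain("B")
    ab = interchain_rotamer_difference(a, b)
    ba = interchain_rotamer_difference(b, a)
    assert ab["n_common"] == ba["n_common"]
    assert ab["n_different"] == ba["n_different"]


def test_designed_difference_fraction(two_chain_model, two_chain_truth):
    diff = interchain_rotamer_difference(
        two_chain_model.chain("A"), two_chain_model.chain("B")
    )
    assert diff["fraction"] == pytest.approx(two_chain_truth["rotamer_diff_fraction"])
    assert [rs for rs, _ in diff["different_positions"]] == two_chain_truth[
        "chi_overrides_b"
    ]


# ---------------------------------------------------------------------------
# ensembles and rarity
# ---------------------------------------------------------------------------

def test_uniform_ensemble_frequency_one():
    plan = EnsemblePlan(
        sequence=["ALA", "VAL", "ALA"],
        label_distributions={2: {"m": 1.0}},
        n_chains=10,
        seed=0,
    )
    models, _ = build_pseudo_ensemble(plan)
    table = build_ensemble_table([m.chains["A"] for m in models])
    assert table.frequencies((2, "")) == {"m": 1.0}


def test_ensemble_frequency_recovery_within_binomial_error():
    p = 0.30
    plan = EnsemblePlan(
        sequence=["ALA", "VAL", "ALA"],
        label_distributions={2: {"t": p, "m": 1 - p}},
        n_chains=200,
        seed=11,
    )
    models, truth = build_pseudo_ensemble(plan)
    table = build_ensemble_table([m.chains["A"] for m in models])
    freq = table.frequency((2, ""), "t")
    se = np.sqrt(p * (1 - p) / plan.n_chains)
    assert abs(freq - p) <= 3 * se
    # frequencies at every tabulated position sum to 1
    for pos in table.counts:
        assert sum(table.frequencies(pos).values()) == pytest.approx(1.0, abs=1e-9)


def test_rarity_thresholds_and_boundaries():
    plan = EnsemblePlan(
        sequence=["ALA", "VAL", "ALA"],
        label_distributions={2: {"t": 0.02, "m": 0.98}},
        n_chains=500,
        seed=4,
    )
    models, _ = build_pseudo_ensemble(plan)
    table = build_ensemble_table([m.chains["A"] for m in models])
    # a chain observed in the rare 't' state
    observed = build_chain(ChainSpec(sequence=["ALA", "VAL", "ALA"], chi_targets={2: (180.0,)}))
    assignments = [
        a for res in observed.chains["A"] if res.res_name in CHI_ATOMS
        for a in assign_residue(res)
    ]
    flags = rarity_flags(assignments, table, threshold=0.20)
    val_row = flags[flags.res_name == "VAL"].iloc[0]
    assert val_row["rare"] and val_row["ensemble_freq"] < 0.05
    # boundary behavior
    none_rare = rarity_flags(assignments, table, threshold=0.0)
    assert not none_rare["rare"].any()
    all_rare = rarity_flags(assignments, table, threshold=1.0)
    scored = all_rare[all_rare["status"] == "ok"]
    assert scored[scored["ensemble_freq"] < 1.0]["rare"].all()


def test_rarity_no_data_positions_excluded():
    plan = EnsemblePlan(
        sequence=["ALA", "VAL", "ALA"],
        label_distributions={2: {"m": 1.0}},
        n_chains=5,
        seed=0,
    )
    models, _ = build_pseudo_ensemble(plan)
    table = build_ensemble_table([m.chains["A"] for m in models])
    # observed structure has an extra residue the table has never seen
    observed = build_chain(ChainSpec(sequence=["ALA", "VAL", "ALA", "SER"]))
    assignments = [
        a for res in observed.chains["A"] if res.res_name in CHI_ATOMS
        for a in assign_residue(res)
    ]
    flags = rarity_flags(assignments, table, threshold=0.2)
    ser = flags[flags.res_name == "SER"].iloc[0]
    assert ser["status"] == "no-data" and not ser["rare"]
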