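"""Symmetry expansion, contacts, SASA and buried area."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ncs_hetero.lattice import (
    attribute_altconf_contacts,
    buried_area,
    expand_neighbors,
    find_contacts,
    frac_orth_matrices,
    golden_spiral_points,
    sasa,
)
from ncs_hetero.model import ModelError, UnitCell
from ncs_hetero.pdbio import space_group_operators
from ncs_hetero.synthetic import ChainSpec, build_chain


# ---------------------------------------------------------------------------
# cell matrices
# ---------------------------------------------------------------------------

def test_orthogonal_cell_matrices_are_diagonal():
    orth, frac = frac_orth_matrices(UnitCell(10.0, 10.0, 10.0))
    assert np.allclose(orth, np.diag([10.0, 10.0, 10.0]))
    orth2, _ = frac_orth_matrices(UnitCell(88.41, 88.41, 163.00))
    assert np.allclose(np.diag(orth2), [88.41, 88.41, 163.00])
    assert np.allclose(orth2 - np.diag(np.diag(orth2)), 0.0)


def test_triclinic_round_trip(rng):
    cell = UnitCell(23.3, 31.1, 27.9, 88.0, 101.5, 95.0)
    orth, frac = frac_orth_matrices(cell)
    assert np.abs(orth @ frac - np.eye(3)).max() < 1e-10
    pts = rng.uniform(-20, 40, size=(100, 3))
    assert np.abs((pts @ frac.T) @ orth.T - pts).max() < 1e-9


# ---------------------------------------------------------------------------
# symmetry expansion
# ---------------------------------------------------------------------------

def _toy_model(cell, space_group="P 1", n_res=8):
    model = build_chain(ChainSpec(sequence=["ALA"] * n_res))
    model.cell = cell
    model.space_group = space_group
    model.symops = space_group_operators(space_group)
    return model


def test_isolated_cell_yields_no_mates():
    model = _toy_model(UnitCell(200.0, 200.0, 200.0))
    assert expand_neighbors(model, cutoff=5.0) == []


def test_p1_translation_neighbors_found_by_hand_geometry():
    from ncs_hetero.synthetic import _align_chain_axis_to_x

    model = _toy_model(UnitCell(200.0, 200.0, 200.0))
    _align_chain_axis_to_x(model, "A")
    coords = np.array([a.pos for r in model.chains["A"] for a in r.atoms])
    ext = coords.max(axis=0) - coords.min(axis=0)
    # a = extent + 3: the +/-a images sit 3 A from the chain ends along x
    model.cell = UnitCell(ext[0] + 3.0, 200.0, 200.0)
    mates = expand_neighbors(model, cutoff=5.0)
    assert {(m.op_index, m.translation) for m in mates} == {
        (0, (-1, 0, 0)),
        (0, (1, 0, 0)),
    }


def test_mate_enumeration_matches_brute_force_p43212():
    model = _toy_model(UnitCell(22.0, 22.0, 30.0), "P 43 21 2")
    cutoff = 5.0
    mates = expand_neighbors(model, cutoff=cutoff, search=2)
    coords = np.array([a.pos for r in model.chains["A"] for a in r.atoms])
    orth, frac = frac_orth_matrices(model.cell)
    fc = coords @ frac.T
    tree = cKDTree(coords)
    expected = set()
    for k, (rot, tran) in enumerate(model.symops):
        for u in range(-2, 3):
            for v in range(-2, 3):
                for w in range(-2, 3):
                    if k == 0 and (u, v, w) == (0, 0, 0):
                        continue
                    cart = (fc @ rot.T + tran + [u, v, w]) @ orth.T
                    if (tree.query(cart)[0] < cutoff).any():
                        expected.add((k, u, v, w))
    assert {(m.op_index,) + m.translation for m in mates} == expected
    # mate coordinate invariant: refractionalizing reproduces op * frac + tran
    from ncs_hetero.model import select_atoms

    ordered = np.array(
        [a.pos for a in select_atoms(model, chain_id="A", altloc_policy="first")]
    )
    m0 = mates[0]
    rot, tran = model.symops[m0.op_index]
    rebuilt = ((ordered @ frac.T) @ rot.T + tran + np.array(m0.translation)) @ orth.T
    assert np.abs(rebuilt - m0.coords).max() < 1e-6


def test_expansion_invariant_under_whole_cell_shift():
    model = _toy_model(UnitCell(22.0, 22.0, 30.0), "P 21 21 21")
    base = {(m.op_index,) + m.translation for m in expand_neighbors(model, cutoff=5.0)}
    shifted = model.copy()
    shift = np.array([22.0, 0.0, 0.0])  # one whole cell along a
    for res in shifted.chain("A"):
        for atom in res.atoms:
            atom.pos = atom.pos + shift
    after = {m.op_index for m in expand_neighbors(shifted, cutoff=5.0)}
    assert {k for k, *_ in base} == after  # same operators, relabeled translations


def test_missing_cell_errors():
    model = build_chain(ChainSpec(sequence=["ALA"] * 4))
    with pytest.raises(ModelError, match="cell"):
        expand_neighbors(model, cutoff=5.0)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def test_engineered_interface_found(contact_fixture):
    model, truth = contact_fixture
    mates = expand_neighbors(model, cutoff=5.0)
    report = find_contacts(model, "A", mates, cutoff=truth["contact_cutoff"])
    assert report.n_contact_interfaces == 2  # +a and -a images
    assert set(report.contacting_residues) == set(truth["contact_affected"])


def test_zero_cutoff_yields_no_interfaces(contact_fixture):
    model, _ = contact_fixture
    mates = expand_neighbors(model, cutoff=5.0)
    report = find_contacts(model, "A", mates, cutoff=0.0)
    assert report.n_contact_interfaces == 0


def test_altconf_contact_attribution(contact_fixture):
    model, truth = contact_fixture
    mates = expand_neighbors(model, cutoff=5.0)
    att = attribute_altconf_contacts(model, "A", mates, shell=truth["contact_cutoff"])
    assert att["n_altconf"] == len(truth["altconf_residues"])
    assert att["affected_residues"] == truth["contact_affected"]
    # infinite shell: every altconf residue counts once any mate exists
    att_inf = attribute_altconf_contacts(model, "A", mates, shell=np.inf)
    assert att_inf["n_contact_affected"] == att_inf["n_altconf"]


def test_no_mates_attribution(two_chain_model):
    att = attribute_altconf_contacts(two_chain_model, "A", mates=[], shell=4.0)
    assert att["n_contact_affected"] == 0 and att["n_altconf"] > 0


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_single_sphere_analytic():
    res = sasa(np.zeros((1, 3)), ["C"], probe=1.4, n_points=960)
    assert res.total == pytest.approx(4 * np.pi * 3.1**2, rel=1e-9)


def test_separated_spheres_full_area():
    res = sasa(np.array([[0.0, 0, 0], [20.0, 0, 0]]), ["C", "C"])
    full = 4 * np.pi * 3.1**2
    assert np.allclose(res.per_atom, full, rtol=1e-9)


def test_overlapping_spheres_match_cap_formula():
    d, R = 3.0, 1.7 + 1.4
    cap_h = R - d / 2
    analytic = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * cap_h)
    res = sasa(np.array([[0.0, 0, 0], [d, 0, 0]]), ["C", "C"], n_points=960)
    assert abs(res.total - analytic) / analytic < 0.02


def test_environment_only_occludes():
    coords = np.array([[0.0, 0, 0]])
    alone = sasa(coords, ["C"]).total
    shadowed = sasa(coords, ["C"], env_coords=np.array([[3.0, 0, 0]]), env_elements=["C"]).total
    assert shadowed < alone
    far = sasa(coords, ["C"], env_coords=np.array([[30.0, 0, 0]]), env_elements=["C"]).total
    assert far == pytest.approx(alone)


def test_unknown_element_named_in_error():
    with pytest.raises(ModelError, match="XX"):
        sasa(np.zeros((1, 3)), ["XX"])
    with pytest.raises(ValueError, match="n_points"):
        sasa(np.zeros((1, 3)), ["C"], n_points=10)


def test_golden_spiral_points_on_unit_sphere():
    pts = golden_spiral_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.abs(pts.mean(axis=0)).max() < 0.01  # near-uniform coverage


# ---------------------------------------------------------------------------
# buried area
# ---------------------------------------------------------------------------

def test_buried_area_zero_without_mates(two_chain_model):
    assert buried_area(two_chain_model, "A", mates=[], n_points=120) == 0.0


def test_buried_area_positive_at_engineered_interface(contact_fixture):
    model, _ = contact_fixture
    mates = expand_neighbors(model, cutoff=5.0)
    ba = buried_area(model, "A", mates, n_points=240)
    assert ba > 10.0


def test_buried_area_grows_with_admitted_mates(contact_fixture):
    model, _ = contact_fixture
    mates = expand_neighbors(model, cutoff=5.0)
    tight = buried_area(model, "A", mates, n_points=240, contact_cutoff=0.5)
    loose = buried_area(model, "A", mates, n_points=240, contact_cutoff=4.0)
    assert loose >= tight
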