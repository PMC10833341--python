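"""Rigid superposition, displacement profiles and the RMSD matrix."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ncs_hetero.superpose import (
    ca_distance_profile,
    kabsch,
    pair_ca_atoms,
    pairwise_rmsd_matrix,
)
from ncs_hetero.synthetic import ChainSpec, build_chain


def _cloud(rng, n=20, scale=5.0):
    return rng.normal(size=(n, 3)) * scale


def test_identity_superposition(rng):
    P = _cloud(rng)
    res = kabsch(P, P)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
    assert np.allclose(res.translation, 0.0, atol=1e-10)


def test_exact_rigid_motion_recovered(rng):
    P = _cloud(rng)
    R0 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    Q = P @ R0.T + np.array([5.0, 0.0, 0.0])
    res = kabsch(P, Q)
    assert res.rmsd < 1e-10
    assert np.allclose(res.rotation, R0, atol=1e-8)
    assert np.allclose(res.translation, [5.0, 0.0, 0.0], atol=1e-8)


def test_agrees_with_independent_quaternion_solver(rng):
    """Noisy clouds: RMSD and rotation must match scipy's align_vectors."""
    for _ in range(10):
        P = _cloud(rng)
        R0 = Rotation.random(rng=np.random.RandomState(int(rng.integers(2**31))))
        Q = P @ R0.as_matrix().T + rng.normal(size=3) * 4
        Q += rng.normal(scale=0.1, size=Q.shape)
        res = kabsch(P, Q)
        oracle_rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-6)
        assert np.abs(res.rotation - oracle_rot.as_matrix()).max() < 1e-6


def test_rmsd_invariant_under_rigid_pretransform(rng):
    P = _cloud(rng)
    Q = P + rng.normal(scale=0.3, size=P.shape)
    base = kabsch(P, Q).rmsd
    R0 = Rotation.from_euler("xyz", [11, -72, 140], degrees=True).as_matrix()
    assert kabsch(P @ R0.T + 7.0, Q).rmsd == pytest.approx(base, abs=1e-8)
    assert kabsch(P, Q @ R0.T - 3.0).rmsd == pytest.approx(base, abs=1e-8)


def test_proper_rotation_enforced_on_reflected_input(rng):
    P = _cloud(rng)
    Q = P.copy()
    Q[:, 2] *= -1  # mirror image
    res = kabsch(P, Q)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)


def test_too_few_points_and_collinear_warn_or_raise():
    with pytest.raises(ValueError, match=">= 3"):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.warns(UserWarning, match="collinear"):
        kabsch(line, line)


def test_pairing_by_author_numbering():
    a = build_chain(ChainSpec(sequence=["ALA"] * 50)).chains["A"]
    b = build_chain(ChainSpec(sequence=["ALA"] * 50, chain_id="B")).chains["B"]
    P, Q, pairing = pair_ca_atoms(a, b)
    assert len(pairing) == 50
    # drop residues 20-24 from b: pairs exclude exactly those
    b_gap = [r for r in b if not (20 <= r.res_seq <= 24)]
    _, _, pairing2 = pair_ca_atoms(a, b_gap)
    assert len(pairing2) == 45
    assert all(not (20 <= rs <= 24) for rs, _ in pairing2)
    # mismatched numbering: no common residues
    b_off = build_chain(ChainSpec(sequence=["ALA"] * 50, start_res_seq=500)).chains["A"]
    with pytest.raises(ValueError, match="common residues"):
        pair_ca_atoms(a, b_off)


def test_profile_zero_for_rigid_copy():
    a = build_chain(ChainSpec(sequence=["ALA"] * 30)).chains["A"]
    import copy

    b = copy.deepcopy(a)
    R0 = Rotation.from_euler("y", 35, degrees=True).as_matrix()
    for res in b:
        for atom in res.atoms:
            atom.pos = R0 @ atom.pos + np.array([3.0, -4.0, 9.0])
    prof = ca_distance_profile(a, b)
    assert max(d for _, _, d in prof.entries) < 1e-8


def test_single_displaced_residue_vs_leave_one_out_oracle():
    """A 2 A displacement of one Calpha shows up at ~2 A minus the small
    global-fit absorption; the fit excluding that residue recovers 2 A
    exactly."""
    a = build_chain(ChainSpec(sequence=["ALA"] * 50)).chains["A"]
    import copy

    b = copy.deepcopy(a)
    k = 25
    for atom in next(r for r in b if r.res_seq == k).atoms:
        atom.pos = atom.pos + np.array([0.0, 0.0, 2.0])
    prof = ca_distance_profile(a, b)
    assert abs(prof.distance(k) - 2.0) < 0.2
    # leave-one-out oracle: superpose on all other residues -> exact 2.0
    P, Q, pairing = pair_ca_atoms(a, b)
    mask = np.array([rs != k for rs, _ in pairing])
    fit = kabsch(P[mask], Q[mask])
    d_k = np.linalg.norm(fit.apply(P[~mask]) - Q[~mask])
    assert d_k == pytest.approx(2.0, abs=1e-8)


def test_designed_loop_shift_apex(two_chain_model, two_chain_truth):
    prof = ca_distance_profile(two_chain_model.chain("A"), two_chain_model.chain("B"))
    apex = two_chain_truth["apex_res_seq"]
    assert abs(prof.distance(apex) - two_chain_truth["designed_shift_A"]) < 0.1
    df = prof.to_dataframe()
    assert int(df.loc[df.ca_distance_A.idxmax(), "res_seq"]) == apex


def test_profile_symmetry(two_chain_model):
    ab = ca_distance_profile(two_chain_model.chain("A"), two_chain_model.chain("B"))
    ba = ca_distance_profile(two_chain_model.chain("B"), two_chain_model.chain("A"))
    for (rs1, ic1, d1), (rs2, ic2, d2) in zip(ab.entries, ba.entries):
        assert (rs1, ic1) == (rs2, ic2)
        assert d1 == pytest.approx(d2, abs=1e-8)


def test_pairwise_rmsd_matrix_structure(rng):
    import copy

    x = build_chain(ChainSpec(sequence=["ALA"] * 40)).chains["A"]
    x_rigid = copy.deepcopy(x)
    R0 = Rotation.from_euler("x", 65, degrees=True).as_matrix()
    for res in x_rigid:
        for atom in res.atoms:
            atom.pos = R0 @ atom.pos + 11.0
    x_noisy = copy.deepcopy(x)
    sigma = 0.2
    for res in x_noisy:
        for atom in res.atoms:
            atom.pos = atom.pos + rng.normal(scale=sigma, size=3)
    M = pairwise_rmsd_matrix([("x", x), ("rigid", x_rigid), ("noisy", x_noisy)])
    assert np.allclose(M.values, M.values.T, atol=1e-10)
    assert np.allclose(np.diag(M.values), 0.0)
    assert M.loc["x", "rigid"] < 1e-8
    # noisy pair close to the rms of the applied noise (sqrt(3) sigma)
    expected = np.sqrt(3) * sigma
    assert M.loc["x", "noisy"] == pytest.approx(expected, rel=0.2)


def test_mean_profile_distance_grows_with_noise(rng):
    import copy

    base = build_chain(ChainSpec(sequence=["ALA"] * 30)).chains["A"]
    means = []
    for sigma in (0.05, 0.2, 0.6):
        noisy = copy.deepcopy(base)
        local_rng = np.random.default_rng(7)
        for res in noisy:
            for atom in res.atoms:
                atom.pos = atom.pos + local_rng.normal(scale=sigma, size=3)
        prof = ca_distance_profile(base, noisy)
        means.append(np.mean([d for _, _, d in prof.entries]))
    assert means[0] < means[1] < means[2]
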