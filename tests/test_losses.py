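"""Loss-term oracles and the community min/mean aggregation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from commloop import toy_config
from commloop.autodiff import Tensor
from commloop.geometry import (TorsionSet, build_chain_from_torsions,
                               loop_rmsd, measure_torsions)
from commloop.losses import (backbone_from_frames, combine_losses,
                             community_loss, distogram_loss, fape_loss,
                             loop_rmsd_loss, per_residue_lddt, plddt_loss,
                             torsion_loss, violation_loss,
                             violation_loss_struct)
from commloop.model import CommunityModel, FrameTensor


def frames_of(struct):
    rot = np.stack([r.frame().rotation for r in struct])
    trans = np.stack([r.frame().translation for r in struct])
    return rot, trans


@pytest.fixture(scope="module")
def chain(rng_mod=np.random.default_rng(3)):
    n = 8
    phi = rng_mod.uniform(-np.pi, -1.0, n)
    psi = rng_mod.uniform(0.5, np.pi, n)
    _, st = build_chain_from_torsions("ASLEDNMT", phi, psi)
    return st


# ---------------------------------------------------------------------------
# FAPE
# ---------------------------------------------------------------------------

def test_fape_zero_on_identity(chain):
    rot, trans = frames_of(chain)
    atoms = chain.coords(("N", "CA", "C"))
    pred = FrameTensor.from_numpy(rot[None], trans[None])
    val = fape_loss(pred, Tensor(atoms[None]), (rot, trans), atoms)
    assert float(val.data[0]) == pytest.approx(0.0, abs=1e-5)


def test_fape_invariant_under_consistent_global_motion(chain, rng):
    rot, trans = frames_of(chain)
    atoms = chain.coords(("N", "CA", "C"))
    g_rot = Rotation.random(random_state=rng).as_matrix()
    g_t = rng.normal(size=3) * 5
    pred_rot = np.einsum("ab,fbc->fac", g_rot, rot)
    pred_trans = trans @ g_rot.T + g_t
    pred_atoms = atoms @ g_rot.T + g_t
    val = fape_loss(FrameTensor.from_numpy(pred_rot[None], pred_trans[None]),
                    Tensor(pred_atoms[None]), (rot, trans), atoms)
    assert float(val.data[0]) == pytest.approx(0.0, abs=1e-6)


def test_fape_matches_double_loop_oracle(rng):
    """Tiny case: 2 frames x 3 atoms vs explicit loops with clamping."""
    rot = Rotation.random(2, random_state=rng).as_matrix()
    trans = rng.normal(size=(2, 3)) * 3
    true_atoms = rng.normal(size=(3, 3)) * 8
    pred_atoms = true_atoms + rng.normal(size=(3, 3)) * 4
    pred = FrameTensor.from_numpy(rot[None], trans[None])
    got = float(fape_loss(pred, Tensor(pred_atoms[None]), (rot, trans),
                          true_atoms, clamp=10.0, scale=10.0).data[0])
    acc = 0.0
    for f in range(2):
        for a in range(3):
            lp = rot[f].T @ (pred_atoms[a] - trans[f])
            lt = rot[f].T @ (true_atoms[a] - trans[f])
            acc += min(np.linalg.norm(lp - lt), 10.0)
    assert got == pytest.approx(acc / 6 / 10.0, rel=1e-6)


def test_fape_shape_mismatch_rejected(chain):
    rot, trans = frames_of(chain)
    atoms = chain.coords(("N", "CA", "C"))
    pred = FrameTensor.from_numpy(rot[None], trans[None])
    with pytest.raises(ValueError):
        fape_loss(pred, Tensor(atoms[None]), (rot, trans), atoms[:-3])


# ---------------------------------------------------------------------------
# distogram
# ---------------------------------------------------------------------------

def test_distogram_perfect_prediction_zero():
    edges = np.linspace(2, 22, 3)  # 4 bins
    true_d = np.array([[0.0, 5.0], [5.0, 0.0]])
    idx = np.searchsorted(edges, true_d)
    logits = np.full((1, 2, 2, 4), -1e9)
    for i in range(2):
        for j in range(2):
            logits[0, i, j, idx[i, j]] = 1e9 * 0 + 40.0
    val = distogram_loss(Tensor(logits), true_d, edges)
    assert float(val.data[0]) == pytest.approx(0.0, abs=1e-10)


def test_distogram_uniform_is_log_bins():
    edges = np.linspace(2, 22, 7)  # 8 bins
    logits = np.zeros((2, 3, 3, 8))
    val = distogram_loss(Tensor(logits), np.ones((3, 3)) * 5, edges)
    np.testing.assert_allclose(val.data, np.log(8), atol=1e-12)


def test_distogram_matches_softmax_oracle(rng):
    edges = np.linspace(2, 22, 5)  # 6 bins
    logits = rng.normal(size=(1, 4, 4, 6))
    true_d = rng.uniform(1, 25, size=(4, 4))
    got = float(distogram_loss(Tensor(logits), true_d, edges).data[0])
    acc = 0.0
    for i in range(4):
        for j in range(4):
            lp = logits[0, i, j] - logits[0, i, j].max()
            p = np.exp(lp) / np.exp(lp).sum()
            b = np.searchsorted(edges, true_d[i, j], side="right")
            acc += -np.log(p[b])
    assert got == pytest.approx(acc / 16, rel=1e-8)


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def _sincos_from(ts: TorsionSet) -> np.ndarray:
    ang = np.stack([ts.omega, ts.phi, ts.psi] +
                   [ts.chi[:, j] for j in range(4)], axis=-1)
    return np.stack([np.sin(ang), np.cos(ang)], axis=-1)[None]


def test_torsion_loss_zero_on_truth(chain):
    ts = measure_torsions(chain)
    val = torsion_loss(Tensor(_sincos_from(ts)), ts, chain.sequence())
    assert float(val.data[0]) == pytest.approx(0.0, abs=1e-10)


def test_torsion_loss_periodicity(chain):
    ts = measure_torsions(chain)
    shifted = _sincos_from(ts)  # angles + 2pi give identical sin/cos
    ts2 = measure_torsions(chain)
    ts2.phi = ts2.phi + 2 * np.pi
    val = torsion_loss(Tensor(shifted), ts2, chain.sequence())
    assert float(val.data[0]) == pytest.approx(0.0, abs=1e-10)


def test_torsion_loss_symmetric_chi_alternative():
    """ASP chi2 prediction off by pi is rescued by the flipped target."""
    _, st = build_chain_from_torsions(
        "ADA", np.full(3, -2.0), np.full(3, 2.5),
        chi=np.tile(np.deg2rad([-60.0, 30.0, 0, 0]), (3, 1)))
    ts = measure_torsions(st)
    pred = _sincos_from(ts).copy()
    # flip chi2 of the ASP by pi
    ang = ts.chi[1, 1] + np.pi
    pred[0, 1, 4] = [np.sin(ang), np.cos(ang)]
    val = torsion_loss(Tensor(pred), ts, "ADA")
    assert float(val.data[0]) == pytest.approx(0.0, abs=1e-10)
    # the same flip on chi1 (not symmetric) must cost
    pred2 = _sincos_from(ts).copy()
    ang1 = ts.chi[1, 0] + np.pi
    pred2[0, 1, 3] = [np.sin(ang1), np.cos(ang1)]
    val2 = torsion_loss(Tensor(pred2), ts, "ADA")
    assert float(val2.data[0]) > 0.01


def test_torsion_norm_regularizer():
    _, st = build_chain_from_torsions("AAA", np.full(3, -2.0),
                                      np.full(3, 2.5))
    ts = measure_torsions(st)
    unit = _sincos_from(ts)
    val_unit = float(torsion_loss(Tensor(unit), ts, "AAA").data[0])
    val_scaled = float(torsion_loss(Tensor(unit * 3.0), ts, "AAA").data[0])
    assert val_scaled > val_unit  # same angles, non-unit norm is penalized


# ---------------------------------------------------------------------------
# loop RMSD loss
# ---------------------------------------------------------------------------

def test_loop_rmsd_loss_zero_on_truth(chain):
    rot, trans = frames_of(chain)
    bb = chain.coords(("N", "CA", "C")).reshape(1, len(chain), 3, 3)
    loop = np.zeros(len(chain), bool)
    loop[3:5] = True
    val = loop_rmsd_loss(Tensor(bb), chain, loop, ~loop)
    assert float(val.data[0]) == pytest.approx(0.0, abs=1e-5)


def test_loop_rmsd_loss_equals_geometry_on_random_toys():
    """Module equivalence with the evaluation metric on 20 perturbed toys."""
    rng = np.random.default_rng(0)
    n = 8
    _, ref = build_chain_from_torsions("ASLEDNMT",
                                       rng.uniform(-np.pi, -1, n),
                                       rng.uniform(0.5, np.pi, n))
    loop = np.zeros(n, bool)
    loop[3:6] = True
    for trial in range(20):
        pert = ref.copy()
        for res in pert.residues:
            for a in res.atoms:
                res.atoms[a] = res.atoms[a] + rng.normal(scale=0.6, size=3)
        bb = pert.coords(("N", "CA", "C")).reshape(1, n, 3, 3)
        got = float(loop_rmsd_loss(Tensor(bb), ref, loop, ~loop).data[0])
        want = loop_rmsd(pert, ref, loop, ~loop)
        assert got == pytest.approx(want, abs=1e-5)


def test_loop_rmsd_loss_gradient_nonzero(chain):
    rot, trans = frames_of(chain)
    n = len(chain)
    bb = chain.coords(("N", "CA", "C")).reshape(1, n, 3, 3).copy()
    bb[0, 4] += 1.0  # displace a loop residue
    loop = np.zeros(n, bool)
    loop[3:6] = True
    t = Tensor(bb, requires_grad=True)
    val = loop_rmsd_loss(t, chain, loop, ~loop)
    val.sum().backward()
    g = t.grad[0, 4]
    assert np.all(np.isfinite(g)) and np.abs(g).max() > 0


# ---------------------------------------------------------------------------
# violation
# ---------------------------------------------------------------------------

def test_violation_zero_on_ideal_chain(chain):
    assert violation_loss_struct(chain) == pytest.approx(0.0, abs=1e-12)


def test_violation_positive_on_stretched_bond(chain):
    st = chain.copy()
    shift = st.residues[4].atoms["N"] - st.residues[3].atoms["C"]
    stretch = shift / np.linalg.norm(shift) * (2.0 - np.linalg.norm(shift))
    for i in range(4, len(st)):
        for a in st.residues[i].atoms:
            st.residues[i].atoms[a] = st.residues[i].atoms[a] + stretch
    assert violation_loss_struct(st) > 0


def test_violation_matches_hand_computed_dipeptide():
    """Two residues with a deliberately long C-N bond: the penalty is the
    flat-bottom excess averaged over the (single) bond, angles within
    tolerance, no eligible clash pairs."""
    _, st = build_chain_from_torsions("AA", np.full(2, -2.0),
                                      np.full(2, 2.5))
    stretch = 0.8
    vec = st.residues[1].atoms["N"] - st.residues[0].atoms["C"]
    vec /= np.linalg.norm(vec)
    for a in st.residues[1].atoms:
        st.residues[1].atoms[a] = st.residues[1].atoms[a] + vec * stretch
    got = violation_loss_struct(st)
    expected = (1.329 + stretch - 1.329) - 12 * 0.014
    assert got == pytest.approx(expected, abs=0.02)


# ---------------------------------------------------------------------------
# LDDT / pLDDT
# ---------------------------------------------------------------------------

def test_lddt_identical_structures_is_100(chain):
    ca = chain.coords(("CA",))
    np.testing.assert_allclose(per_residue_lddt(ca, ca), 100.0)


def test_lddt_matches_bruteforce_definition(rng):
    ref = rng.normal(size=(5, 3)) * 4
    pred = ref + rng.normal(size=(5, 3)) * 1.0
    got = per_residue_lddt(pred, ref)
    for i in range(5):
        fracs = []
        for t in (0.5, 1, 2, 4):
            hits = total = 0
            for j in range(5):
                if j == i:
                    continue
                dr = np.linalg.norm(ref[i] - ref[j])
                if dr >= 15.0:
                    continue
                total += 1
                dp = np.linalg.norm(pred[i] - pred[j])
                hits += abs(dp - dr) < t
            fracs.append(hits / total)
        assert got[i] == pytest.approx(100 * np.mean(fracs), abs=1e-9)


def test_plddt_loss_zero_iff_confident_and_correct(chain):
    ca = chain.coords(("CA",))[None]
    nb = 10
    logits = np.full((1, len(chain), nb), -1e9)
    logits[:, :, -1] = 50.0  # all mass on the top bin; true LDDT = 100
    val = plddt_loss(Tensor(logits), ca, ca[0])
    assert float(val.data[0]) == pytest.approx(0.0, abs=1e-10)
    mid = np.full((1, len(chain), nb), -1e9)
    mid[:, :, 0] = 50.0
    val2 = plddt_loss(Tensor(mid), ca, ca[0])
    assert float(val2.data[0]) > 1.0


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def _terms(structure_vals, aux_vals):
    n = len(structure_vals)
    t = {k: Tensor(np.zeros(n)) for k in
         ("rmsd", "fape", "disto", "tors", "plddt", "viol")}
    t["rmsd"] = Tensor(np.asarray(structure_vals, float))
    t["viol"] = Tensor(np.asarray(aux_vals, float))
    return t


WEIGHTS = {"rmsd": 1.0, "fape": 1.0, "disto": 0.3, "tors": 0.5,
           "plddt": 0.01, "viol": 1.0}


def test_combine_unit_terms_arithmetic():
    """All four structure terms at 1 for one member: 1+1+0.3+0.5 = 2.8."""
    t = {k: Tensor(np.ones(1)) for k in
         ("rmsd", "fape", "disto", "tors")}
    t["plddt"] = Tensor(np.zeros(1))
    t["viol"] = Tensor(np.zeros(1))
    lb = combine_losses(t, WEIGHTS)
    assert lb.structure[0] == pytest.approx(2.8)


def test_combine_min_plus_mean():
    lb = combine_losses(_terms([2.0, 1.0, 3.0], [0.3, 0.6, 0.9]), WEIGHTS)
    assert lb.total == pytest.approx(1.6)
    assert lb.argmin == 1


def test_combine_single_member_degenerate():
    lb = combine_losses(_terms([1.7], [0.2]), WEIGHTS)
    assert lb.total == pytest.approx(1.9)


def test_combine_min_property_and_member_addition():
    vals = [2.0, 1.0, 3.0]
    aux = [0.3, 0.6, 0.9]
    lb = combine_losses(_terms(vals, aux), WEIGHTS)
    for i in range(3):
        assert lb.total <= vals[i] + np.mean(aux) + 1e-12
    # adding a member can never increase the structural minimum
    lb4 = combine_losses(_terms(vals + [5.0], aux + [0.0]), WEIGHTS)
    assert lb4.structure.min() <= lb.structure.min()


def test_combine_permutation_invariant(rng):
    vals = rng.uniform(0.5, 3.0, 5)
    aux = rng.uniform(0.0, 1.0, 5)
    a = combine_losses(_terms(vals, aux), WEIGHTS).total
    perm = rng.permutation(5)
    b = combine_losses(_terms(vals[perm], aux[perm]), WEIGHTS).total
    assert a == pytest.approx(b, abs=1e-12)


def test_combine_rejects_nonfinite():
    with pytest.raises(ValueError):
        combine_losses(_terms([np.nan], [0.0]), WEIGHTS)


# ---------------------------------------------------------------------------
# full example loss: perfect prediction
# ---------------------------------------------------------------------------

def test_community_loss_structure_terms_vanish_on_truth(toy_model,
                                                        toy_example):
    """Feeding the ground-truth frames makes every coordinate-driven
    structural term (loop RMSD, FAPE) vanish."""
    task = toy_example.task
    truth = toy_example.ground_truth
    rot = np.stack([r.frame().rotation for r in truth])[None]
    trans = np.stack([r.frame().translation for r in truth])[None]
    from commloop.model import CommunityState
    state0 = toy_model.init_community(task, 1, seed=0)
    state = CommunityState(Tensor(state0.S.data[:1]),
                           Tensor(state0.Z.data[:1]),
                           FrameTensor.from_numpy(rot, trans))
    lb = community_loss(toy_model, task, state, truth)
    assert lb.terms["rmsd"][0] == pytest.approx(0.0, abs=1e-4)
    assert lb.terms["fape"][0] == pytest.approx(0.0, abs=1e-4)
    assert lb.terms["viol"][0] == pytest.approx(0.0, abs=1e-6)
    # perturbing the loop (not globally, which superposition would absorb)
    # makes the coordinate terms strictly positive
    trans_p = trans.copy()
    trans_p[0, task.loop_mask] += np.array([1.0, -0.5, 0.7])
    state_p = CommunityState(state.S, state.Z,
                             FrameTensor.from_numpy(rot, trans_p))
    lb_p = community_loss(toy_model, task, state_p, truth)
    assert lb_p.terms["rmsd"][0] > 0.1
    assert lb_p.terms["fape"][0] > 0.001
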