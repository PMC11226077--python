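"""Structure-module contracts: SE(3) behavior, cross-over attention,
triangular updates, recycling determinism and permutation equivariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from commloop import ModelConfig, toy_config
from commloop.autodiff import Tensor
from commloop.model import (CommunityModel, FrameTensor, fallback_encoding,
                            distance_bin_onehot, rotation_from_quaternion_vec)


def global_transform(t: FrameTensor, rot, trans) -> FrameTensor:
    new_rot = np.einsum("ab,nlbc->nlac", rot, t.rot.data)
    new_trans = np.einsum("ab,nlb->nla", rot, t.trans.data) + trans
    return FrameTensor.from_numpy(new_rot, new_trans)


@pytest.fixture(scope="module")
def setup(toy_task_truth):
    """Model with dithered output projections: zero-initialized output
    heads would make frame/pair dependence (and hence the invariance
    checks) vacuous."""
    task, _ = toy_task_truth
    model = CommunityModel(toy_config())
    model.dither_output_projections(np.random.default_rng(8))
    state = model.init_community(task, 3, seed=5)
    return model, task, state


# ---------------------------------------------------------------------------
# sequence embedding
# ---------------------------------------------------------------------------

def test_embedding_deterministic(toy_model):
    a = toy_model.embed_sequence("ASLEDKA")
    b = toy_model.embed_sequence("ASLEDKA")
    assert np.array_equal(a.data, b.data)


def test_embedding_shape(toy_model):
    assert toy_model.embed_sequence("ASLEDKA").shape == \
        (7, toy_model.config.c_s)


def test_embedding_row_locality():
    enc_a = fallback_encoding("ASLEDKA", 64)
    enc_b = fallback_encoding("ASLEDCA", 64)
    diff_rows = np.nonzero(np.any(enc_a != enc_b, axis=1))[0]
    assert diff_rows.tolist() == [5]


def test_embedding_plugin_error(toy_model):
    with pytest.raises(RuntimeError, match="fallback"):
        toy_model.embed_sequence("ASL", embedder_id="esm2-plugin")


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_init_frames_even_spacing(toy_model, toy_task_truth):
    task, _ = toy_task_truth
    model = CommunityModel(toy_model.config.replace(
        loop_trans_perturb=0.0, loop_rot_perturb_deg=0.0,
        framework_trans_perturb=0.0, framework_rot_perturb_deg=0.0))
    t = model.init_loop_frames(task, 3, seed=0)
    ca_pre, ca_post = task.stem_ca()
    loop_idx = np.nonzero(task.loop_mask)[0]
    L = len(loop_idx)
    for j, i in enumerate(loop_idx):
        expected = ca_pre + (ca_post - ca_pre) * (j + 1) / (L + 1)
        for m in range(3):
            np.testing.assert_allclose(t.trans.data[m, i], expected,
                                       atol=1e-12)
    # zero perturbation: all members identical
    assert np.array_equal(t.trans.data[0], t.trans.data[1])
    assert np.array_equal(t.rot.data[0], t.rot.data[2])


def test_init_frames_seeded_and_member_distinct(toy_model, toy_task_truth):
    task, _ = toy_task_truth
    a = toy_model.init_loop_frames(task, 4, seed=3)
    b = toy_model.init_loop_frames(task, 4, seed=3)
    assert np.array_equal(a.trans.data, b.trans.data)
    assert np.array_equal(a.rot.data, b.rot.data)
    assert not np.allclose(a.trans.data[0], a.trans.data[1])


def test_init_pair_distance_bin_zero():
    edges = np.linspace(2.0, 22.0, 15)
    oh = distance_bin_onehot(np.array([[0.0, 1.5], [1.5, 0.0]]), edges)
    assert oh[0, 1, 0] == 1.0 and oh[0, 1, 1:].sum() == 0


def test_init_pair_identical_members_identical(setup):
    model, task, _ = setup
    cfg0 = model.config
    model0 = CommunityModel(cfg0.replace(
        loop_trans_perturb=0.0, loop_rot_perturb_deg=0.0,
        framework_trans_perturb=0.0, framework_rot_perturb_deg=0.0))
    s0 = model0.embed_sequence(task.sequence)
    t0 = model0.init_loop_frames(task, 2, seed=0)
    z0 = model0.init_pair(s0, t0, task)
    assert np.array_equal(z0.data[0], z0.data[1])


def test_init_pair_not_symmetric(setup):
    model, task, state = setup
    z = state.Z.data
    assert not np.allclose(z[0], np.swapaxes(z[0], 0, 1))


# ---------------------------------------------------------------------------
# IPA
# ---------------------------------------------------------------------------

def test_ipa_invariant_under_global_rigid_motion(setup, rng):
    model, task, state = setup
    s, z, t = state.S, state.Z, state.T
    base = model.ipa_layer("s_update", s, z, t).data
    rot = Rotation.random(random_state=rng).as_matrix()
    moved = model.ipa_layer("s_update", s, z,
                            global_transform(t, rot, rng.normal(size=3) * 9))
    np.testing.assert_allclose(moved.data, base, atol=1e-4)


def test_ipa_no_cross_member_mixing(setup):
    model, task, state = setup
    s, z, t = state.S, state.Z, state.T
    joint = model.ipa_layer("s_update", s, z, t).data
    for m in range(state.community_size):
        single = model.ipa_layer(
            "s_update", Tensor(s.data[m:m + 1]), Tensor(z.data[m:m + 1]),
            FrameTensor.from_numpy(t.rot.data[m:m + 1],
                                   t.trans.data[m:m + 1])).data
        np.testing.assert_allclose(single[0], joint[m], atol=1e-6)


def test_ipa_zeroed_output_projection_is_residual_identity(toy_task_truth):
    task, _ = toy_task_truth
    model = CommunityModel(toy_config())
    p = model.ipa_layers["s_update"]
    p["out"].w.data[:] = 0.0
    p["out"].b.data[:] = 0.0
    # and neutralize the post layer norm to observe the raw residual
    state = model.init_community(task, 2, seed=1)
    out = model.ipa_layer("s_update", state.S, state.Z, state.T)
    expected = p["ln_post"](state.S).data
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


def test_ipa_rejects_nonfinite(setup):
    model, task, state = setup
    bad = state.S.data.copy()
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        model.ipa_layer("s_update", Tensor(bad), state.Z, state.T)


# ---------------------------------------------------------------------------
# cross-over
# ---------------------------------------------------------------------------

def test_crossover_single_member_is_identity_attention(setup):
    model, task, state = setup
    s1 = Tensor(state.S.data[:1])
    out, w = model.crossover(s1, return_weights=True)
    np.testing.assert_allclose(w, 1.0, atol=1e-12)
    # o = v exactly: output equals residual + Linear(v)
    sl = model.cross_ln(s1)
    qkv = model.cross_qkv(sl).data.reshape(1, s1.shape[1], 3,
                                           model.config.crossover_heads, -1)
    v = Tensor(qkv[:, :, 2].reshape(s1.shape))
    expected = (s1 + model.cross_out(v)).data
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


def test_crossover_weights_sum_to_one(setup):
    model, _, state = setup
    _, w = model.crossover(state.S, return_weights=True)
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)


def test_crossover_identical_members_uniform_weights(setup):
    model, _, state = setup
    n = 3
    s = Tensor(np.tile(state.S.data[:1], (n, 1, 1)))
    out, w = model.crossover(s, return_weights=True)
    np.testing.assert_allclose(w, 1.0 / n, atol=1e-12)
    for m in range(1, n):
        np.testing.assert_allclose(out.data[m], out.data[0], atol=1e-12)


def test_crossover_matches_bruteforce_attention():
    """N=2, one head, hand-set projections vs an explicit loop."""
    cfg = toy_config(c_s=4, crossover_heads=1, ipa_heads=4)
    model = CommunityModel(cfg)
    rng = np.random.default_rng(0)
    wq = rng.normal(size=(4, 4))
    wk = rng.normal(size=(4, 4))
    wv = rng.normal(size=(4, 4))
    model.cross_qkv.w.data = np.concatenate([wq, wk, wv], axis=1)
    model.cross_out.w.data = np.eye(4)
    model.cross_out.b.data[:] = 0.0
    s = rng.normal(size=(2, 3, 4))
    out = model.crossover(Tensor(s)).data

    sl = model.cross_ln(Tensor(s)).data
    expected = np.empty_like(s)
    for i in range(3):  # residues
        q = sl[:, i] @ wq
        k = sl[:, i] @ wk
        v = sl[:, i] @ wv
        for nmem in range(2):
            logits = np.array([q[nmem] @ k[m] for m in range(2)]) / 2.0
            a = np.exp(logits - logits.max())
            a /= a.sum()
            o = sum(a[m] * v[m] for m in range(2))
            expected[nmem, i] = s[nmem, i] + o
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_crossover_residue_locality(setup):
    """Zeroing residue j's features changes outputs only at residue j."""
    model, _, state = setup
    s = state.S.data.copy()
    base = model.crossover(Tensor(s)).data
    s2 = s.copy()
    s2[:, 4, :] = 0.0
    out = model.crossover(Tensor(s2)).data
    changed = np.any(np.abs(out - base) > 1e-12, axis=(0, 2))
    assert changed[4]
    assert not changed[np.arange(len(changed)) != 4].any()


# ---------------------------------------------------------------------------
# Z-update
# ---------------------------------------------------------------------------

def test_triangular_mult_matches_explicit_sum():
    """Outgoing-edge multiplicative update vs a brute-force sum over k."""
    cfg = toy_config(c_s=4, c_z=3, tri_mult_hidden=3, ipa_heads=4,
                     crossover_heads=4)
    model = CommunityModel(cfg)
    p = model.tri_blocks[0]["mult_out"]
    rng = np.random.default_rng(1)
    z = Tensor(rng.normal(size=(1, 3, 3, 3)))
    out = model._tri_mult(p, z, outgoing=True).data

    zl = p["ln"](z).data
    a = 1 / (1 + np.exp(-(zl @ p["ga"].w.data + p["ga"].b.data))) * \
        (zl @ p["a"].w.data + p["a"].b.data)
    b = 1 / (1 + np.exp(-(zl @ p["gb"].w.data + p["gb"].b.data))) * \
        (zl @ p["b"].w.data + p["b"].b.data)
    x = np.zeros_like(a)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                x[0, i, j] += a[0, i, k] * b[0, j, k]
    g = 1 / (1 + np.exp(-(zl @ p["g"].w.data + p["g"].b.data)))
    xn = p["ln_x"](Tensor(x)).data
    expected = g * (xn @ p["proj"].w.data + p["proj"].b.data)
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_z_update_zeroed_projections_identity(toy_task_truth):
    task, _ = toy_task_truth
    model = CommunityModel(toy_config())
    # zero every projection that writes into Z
    model.pairup_proj.w.data[:] = 0.0
    model.pairup_proj.b.data[:] = 0.0
    for block in model.tri_blocks:
        for kind in ("mult_out", "mult_in"):
            block[kind]["proj"].w.data[:] = 0.0
            block[kind]["proj"].b.data[:] = 0.0
        for kind in ("attn_start", "attn_end"):
            block[kind]["out"].w.data[:] = 0.0
            block[kind]["out"].b.data[:] = 0.0
        block["trans_l2"].w.data[:] = 0.0
        block["trans_l2"].b.data[:] = 0.0
    state = model.init_community(task, 2, seed=0)
    z_new = model.z_update(state.S, state.T, state.Z)
    np.testing.assert_allclose(z_new.data, state.Z.data, atol=1e-12)


def test_z_update_deterministic(setup):
    model, task, state = setup
    a = model.z_update(state.S, state.T, state.Z).data
    b = model.z_update(state.S, state.T, state.Z).data
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# structure update
# ---------------------------------------------------------------------------

def test_structure_update_zeroed_head_keeps_frames(toy_task_truth):
    task, _ = toy_task_truth
    model = CommunityModel(toy_config())
    for lin in model.bb_update:
        lin.w.data[:] = 0.0
        lin.b.data[:] = 0.0
    state = model.init_community(task, 2, seed=0)
    t_new, _ = model.structure_update(state.S, state.Z, state.T)
    np.testing.assert_allclose(t_new.rot.data, state.T.rot.data, atol=1e-12)
    np.testing.assert_allclose(t_new.trans.data, state.T.trans.data,
                               atol=1e-12)


def test_structure_update_equivariance(setup, rng):
    model, task, state = setup
    t_new, s_out = model.structure_update(state.S, state.Z, state.T)
    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.normal(size=3) * 7
    t_moved, s_moved = model.structure_update(
        state.S, state.Z, global_transform(state.T, rot, shift))
    np.testing.assert_allclose(s_moved.data, s_out.data, atol=1e-4)
    np.testing.assert_allclose(
        t_moved.trans.data,
        np.einsum("ab,nlb->nla", rot, t_new.trans.data) + shift, atol=1e-4)
    np.testing.assert_allclose(
        t_moved.rot.data, np.einsum("ab,nlbc->nlac", rot, t_new.rot.data),
        atol=1e-4)


def test_structure_update_is_four_chained_layers(setup):
    model, task, state = setup
    t_got, s_got = model.structure_update(state.S, state.Z, state.T)
    s, t = state.S, state.T
    for i in range(4):
        s = model.ipa_layer(f"struct{i}", s, state.Z, t)
        s = model.struct_transitions[i](s)
        upd = model.bb_update[i](s)
        rot = rotation_from_quaternion_vec(upd[..., :3])
        t = t.compose(FrameTensor(rot, upd[..., 3:]))
    np.testing.assert_allclose(s_got.data, s.data, atol=1e-12)
    np.testing.assert_allclose(t_got.trans.data, t.trans.data, atol=1e-12)


def test_quaternion_rotations_are_orthonormal(rng):
    bcd = Tensor(rng.normal(size=(4, 5, 3)))
    rot = rotation_from_quaternion_vec(bcd).data
    eye = np.einsum("nlab,nlcb->nlac", rot, rot)
    np.testing.assert_allclose(eye, np.broadcast_to(np.eye(3), eye.shape),
                               atol=1e-12)
    np.testing.assert_allclose(np.linalg.det(rot), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# run_cycles
# ---------------------------------------------------------------------------

def test_run_cycles_trajectory_length_matches_cycles(toy_state, toy_model):
    _, traj = toy_state
    assert len(traj) == toy_model.config.n_cycles


def test_run_cycles_deterministic(toy_model, toy_task_truth):
    task, _ = toy_task_truth
    s1, _ = toy_model.run_cycles(task, seed=42, n_members=2,
                                 record_trajectory=False)
    s2, _ = toy_model.run_cycles(task, seed=42, n_members=2,
                                 record_trajectory=False)
    assert np.array_equal(s1.T.trans.data, s2.T.trans.data)
    assert np.array_equal(s1.S.data, s2.S.data)


def test_run_cycles_member_permutation_equivariance(toy_model,
                                                    toy_task_truth):
    task, _ = toy_task_truth
    init = toy_model.init_community(task, 3, seed=9)
    final, _ = toy_model.run_cycles(task, seed=9, init_state=init,
                                    record_trajectory=False)
    perm = np.array([2, 0, 1])
    final_p, _ = toy_model.run_cycles(task, seed=9,
                                      init_state=init.permute_members(perm),
                                      record_trajectory=False)
    np.testing.assert_allclose(final_p.S.data, final.S.data[perm], atol=1e-8)
    np.testing.assert_allclose(final_p.T.trans.data,
                               final.T.trans.data[perm], atol=1e-8)


def test_parameters_shared_across_cycles(toy_model):
    """The cycle loop reuses the same layer objects (identity, not value)."""
    assert toy_model.ipa_layers["s_update"]["q"].w is \
        toy_model.ipa_layers["s_update"]["q"].w
    n_before = toy_model.n_parameters()
    # parameters do not grow with the number of cycles
    more_cycles = CommunityModel(toy_model.config.replace(n_cycles=8))
    assert more_cycles.n_parameters() == n_before


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------

def test_plddt_point_mass_and_uniform(toy_model):
    nb = toy_model.config.plddt_bins
    centers = (np.arange(nb) + 0.5) * 100.0 / nb
    logits = np.full((1, 2, nb), -1e9)
    logits[0, 0, -1] = 0.0    # all mass on top bin
    logits[0, 1, :] = 0.0     # uniform
    probs = Tensor(logits).softmax(axis=-1).data
    vals = probs @ centers
    assert vals[0, 0] == pytest.approx(centers[-1])
    assert vals[0, 1] == pytest.approx(centers.mean())


def test_plddt_expectation_matches_loop_oracle(toy_model, toy_state,
                                               toy_task_truth):
    task, _ = toy_task_truth
    state, _ = toy_state
    per_res, member = toy_model.predict_plddt(state.S, task.loop_mask)
    probs = toy_model.plddt_logits(state.S).softmax(axis=-1).data
    nb = toy_model.config.plddt_bins
    centers = (np.arange(nb) + 0.5) * 100.0 / nb
    oracle = np.zeros(per_res.shape)
    for m in range(probs.shape[0]):
        for i in range(probs.shape[1]):
            oracle[m, i] = sum(probs[m, i, b] * centers[b]
                               for b in range(nb))
    np.testing.assert_allclose(per_res, oracle, atol=1e-10)
    assert np.all(per_res >= 0) and np.all(per_res <= 100)
    np.testing.assert_allclose(
        member, per_res[:, task.loop_mask].mean(axis=1), atol=1e-12)


def test_torsion_atan2_conventions(toy_model, toy_task_truth):
    task, _ = toy_task_truth
    # (sin, cos) = (0, 1) -> 0 ; (1, 0) -> pi/2 ; (2, 0) -> pi/2
    sc = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 0.0]])
    angles = np.arctan2(sc[:, 0] / np.linalg.norm(sc, axis=1),
                        sc[:, 1] / np.linalg.norm(sc, axis=1))
    assert angles[0] == pytest.approx(0.0)
    assert angles[1] == pytest.approx(np.pi / 2)
    assert angles[2] == pytest.approx(np.pi / 2)


def test_predict_torsions_masks_follow_sequence(toy_model, toy_state,
                                                toy_task_truth):
    task, _ = toy_task_truth
    state, _ = toy_state
    torsions = toy_model.predict_torsions(state.S, task.sequence)
    assert len(torsions) == state.community_size
    from commloop.geometry import CHI_ATOMS, ONE_TO_THREE
    for i, aa in enumerate(task.sequence):
        nchi = len(CHI_ATOMS[ONE_TO_THREE[aa]])
        assert torsions[0].chi_mask[i, :nchi].all()
        assert not torsions[0].chi_mask[i, nchi:].any()


# ---------------------------------------------------------------------------
# architecture size
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(c_s=0)
    with pytest.raises(ValueError):
        ModelConfig(w_fape=-1.0)
    with pytest.raises(ValueError):
        ModelConfig(c_s=130, crossover_heads=8)
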