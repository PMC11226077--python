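"""Training losses and the community min/mean aggregation.

Per member i the structural loss is

    L_structure_i = 1.0 L_loopRMSD + 1.0 L_FAPE + 0.3 L_distogram
                    + 0.5 L_torsion

and the auxiliary loss  L_aux_i = 0.01 L_pLDDT + 1.0 L_violation.  The
community loss combines the best structural member with the mean auxiliary
term:  L = min_i L_structure_i + mean_i L_aux_i.

All losses operate on batched members (leading axis N) and return one value
per member; everything that needs gradients runs on autodiff tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concat, einsum
from .geometry import (AtomStructure, BACKBONE_LOCAL, CHI_ATOMS, ONE_TO_THREE,
                       SYMMETRIC_CHI, TorsionSet, kabsch_superpose)
from .model import FrameTensor

LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
LDDT_RADIUS = 15.0
ANGLE_NORM_WEIGHT = 0.02

# backbone ideal values for the violation terms (Engh-Huber style)
VIOL_BOND_C_N = (1.329, 0.014)         # mean, sigma (Angstrom)
VIOL_ANGLE_CA_C_N = (np.deg2rad(116.2), np.deg2rad(2.0))
VIOL_ANGLE_C_N_CA = (np.deg2rad(121.7), np.deg2rad(1.8))
VIOL_SIGMAS = 12.0
CLASH_TOL = 1.5                        # Angstrom below radius sum
BB_RADII = {"N": 1.55, "CA": 1.70, "C": 1.70}


@dataclass
class LossBreakdown:
    """Per-member loss terms plus the combined community loss."""

    terms: dict[str, np.ndarray]       # name -> (N,) values
    structure: np.ndarray              # (N,) weighted structural loss
    aux: np.ndarray                    # (N,) weighted auxiliary loss
    total: float
    argmin: int
    loss: Tensor | None = field(default=None, repr=False)  # for backward

    @property
    def n_members(self) -> int:
        return len(self.structure)

    def tsv_row(self, step: int) -> str:
        cells = [str(step)]
        for name in sorted(self.terms):
            cells.append(",".join(f"{v:.5f}" for v in self.terms[name]))
        cells += [f"{self.total:.6f}", str(self.argmin)]
        return "\t".join(cells)

    @staticmethod
    def tsv_header(term_names) -> str:
        return "\t".join(["step"] + sorted(term_names) + ["total", "argmin"])


# ---------------------------------------------------------------------------
# individual losses
# ---------------------------------------------------------------------------

def fape_loss(pred_frames: FrameTensor, pred_atoms: Tensor,
              true_frames: tuple[np.ndarray, np.ndarray],
              true_atoms: np.ndarray, clamp: float = 10.0,
              scale: float = 10.0) -> Tensor:
    """Frame-aligned point error, clamped and length-scaled.

    pred_frames: (N, F) frames; pred_atoms: (N, A, 3); true_frames: (rot
    (F, 3, 3), trans (F, 3)); true_atoms: (A, 3).  Returns (N,).
    """
    n, f = pred_frames.shape
    if pred_atoms.shape[0] != n:
        raise ValueError("member axis mismatch between frames and atoms")
    a = pred_atoms.shape[1]
    if true_atoms.shape != (a, 3):
        raise ValueError("true/pred atom count mismatch")
    # local coordinates of every atom in every frame: (N, F, A, 3)
    pl = _frames_invert_apply(pred_frames, pred_atoms)
    t_rot, t_trans = true_frames
    tl = np.einsum("fab,fja->fjb", t_rot,
                   true_atoms[None, :, :] - t_trans[:, None, :])
    diff = pl - Tensor(tl[None])
    d = ((diff * diff).sum(axis=-1) + 1e-10).sqrt()
    return d.clip_max(clamp).mean(axis=(1, 2)) * (1.0 / scale)


def _frames_invert_apply(frames: FrameTensor, atoms: Tensor) -> Tensor:
    """(N, F) frames applied inversely to (N, A, 3) atoms -> (N, F, A, 3)."""
    n, f = frames.shape
    a = atoms.shape[1]
    shifted = atoms.reshape(n, 1, a, 3) - frames.trans.reshape(n, f, 1, 3)
    return einsum("nfab,nfja->nfjb", frames.rot, shifted)


def distogram_loss(pair_logits: Tensor, true_distances: np.ndarray,
                   edges: np.ndarray) -> Tensor:
    """Mean cross-entropy between predicted distance-bin distributions and
    the one-hot bin of the true Cbeta (Calpha for GLY) distances.

    pair_logits: (N, L, L, B); true_distances: (L, L).  Returns (N,).
    """
    n, L, _, b = pair_logits.shape
    if len(edges) != b - 1:
        raise ValueError("edge count does not match bin count")
    idx = np.searchsorted(edges, true_distances, side="right")
    logp = pair_logits.log_softmax(axis=-1)
    onehot = np.zeros((L, L, b))
    np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
    return -(logp * Tensor(onehot[None])).sum(axis=-1).mean(axis=(1, 2))


def torsion_loss(pred_sincos: Tensor, true_torsions: TorsionSet,
                 sequence: str) -> Tensor:
    """Unit-circle L2 loss on (sin, cos) pairs with pi-rotated alternatives
    for symmetric side-chain ends, plus a small angle-norm regularizer.

    pred_sincos: (N, L, 7, 2) raw head output, angle order
    (omega, phi, psi, chi1..4).  Returns (N,).
    """
    n, L, k, _ = pred_sincos.shape
    angles = np.stack([true_torsions.omega, true_torsions.phi,
                       true_torsions.psi] +
                      [true_torsions.chi[:, j] for j in range(4)], axis=-1)
    masks = np.stack([true_torsions.omega_mask, true_torsions.phi_mask,
                      true_torsions.psi_mask] +
                     [true_torsions.chi_mask[:, j] for j in range(4)], axis=-1)
    alt = angles.copy()
    for i, aa in enumerate(sequence):
        res = ONE_TO_THREE[aa]
        for chi_idx in SYMMETRIC_CHI.get(res, ()):
            alt[i, 2 + chi_idx] = angles[i, 2 + chi_idx] + np.pi
    target = np.stack([np.sin(angles), np.cos(angles)], axis=-1)
    target_alt = np.stack([np.sin(alt), np.cos(alt)], axis=-1)

    norm = ((pred_sincos * pred_sincos).sum(axis=-1) + 1e-12).sqrt()
    unit = pred_sincos / norm.reshape(n, L, k, 1)
    d1 = ((unit - Tensor(target[None])) ** 2).sum(axis=-1)
    d2 = ((unit - Tensor(target_alt[None])) ** 2).sum(axis=-1)
    # elementwise min via mask (no gradient through the selector)
    take_alt = (d2.data < d1.data).astype(float)
    d = d1 * Tensor(1.0 - take_alt) + d2 * Tensor(take_alt)
    m = masks[None].astype(float)
    denom = max(m.sum(), 1.0)     # valid angles per member
    main = (d * Tensor(m)).sum(axis=(1, 2)) * (1.0 / denom)
    reg = (((norm - 1.0) ** 2) * Tensor(m)).sum(axis=(1, 2)) * (1.0 / denom)
    return main + ANGLE_NORM_WEIGHT * reg


def loop_rmsd_loss(pred_bb: Tensor, ref: AtomStructure, loop_mask,
                   framework_mask) -> Tensor:
    """Differentiable loop RMSD: framework-CA superposition (computed on
    detached coordinates) followed by RMS deviation over loop N, CA, C.

    pred_bb: (N, L, 3, 3) with atom axis ordered (N, CA, C).  Returns (N,).
    Numerically equals :func:`commloop.geometry.loop_rmsd` on the same
    coordinates; the gradient flows through the transformed loop atoms but
    not through the superposition operator itself.
    """
    loop_mask = np.asarray(loop_mask, bool)
    framework_mask = np.asarray(framework_mask, bool)
    if np.any(loop_mask & framework_mask):
        raise ValueError("loop and framework masks overlap")
    n = pred_bb.shape[0]
    ref_fw = ref.coords(("CA",), framework_mask)
    ref_loop = ref.coords(("N", "CA", "C"), loop_mask)
    out = []
    loop_idx = np.nonzero(loop_mask)[0]
    for m in range(n):
        fw_ca = pred_bb.data[m][framework_mask, 1]
        frame, _ = kabsch_superpose(fw_ca, ref_fw)
        pred_loop = pred_bb[m][loop_idx].reshape(-1, 3)
        moved = pred_loop @ Tensor(frame.rotation.T) + Tensor(frame.translation)
        diff = moved - Tensor(ref_loop)
        out.append((((diff * diff).sum() * (1.0 / len(ref_loop))) + 1e-12).sqrt())
    return concat([o.reshape(1) for o in out], axis=0)


def violation_loss(pred_bb: Tensor, chain_index: np.ndarray) -> Tensor:
    """Flat-bottom penalties on backbone bond lengths, bond angles and
    non-bonded clashes; zero on ideal geometry.

    pred_bb: (N, L, 3, 3) with atoms (N, CA, C); chain_index: (L,) ints;
    only consecutive residues in the same chain are treated as bonded.
    Returns (N,).
    """
    n, L, _, _ = pred_bb.shape
    bonded = np.nonzero(np.asarray(chain_index)[:-1] ==
                        np.asarray(chain_index)[1:])[0]
    total = Tensor(np.zeros(n))
    n_terms = 0
    if len(bonded):
        c_i = pred_bb[:, bonded, 2]
        n_j = pred_bb[:, bonded + 1, 0]
        ca_i = pred_bb[:, bonded, 1]
        ca_j = pred_bb[:, bonded + 1, 1]
        d = _dist(c_i, n_j)
        mean, sig = VIOL_BOND_C_N
        bond_pen = (_abs(d - mean) - VIOL_SIGMAS * sig).relu()
        # angle terms via cosines
        for (a, b, c, (ang0, sig_a)) in (
                (ca_i, c_i, n_j, VIOL_ANGLE_CA_C_N),
                (c_i, n_j, ca_j, VIOL_ANGLE_C_N_CA)):
            cosv = _cos_angle(a, b, c)
            tol = np.sin(ang0) * VIOL_SIGMAS * sig_a
            ang_pen = (_abs(cosv - np.cos(ang0)) - tol).relu()
            total = total + ang_pen.mean(axis=1)
            n_terms += 1
        total = total + bond_pen.mean(axis=1)
        n_terms += 1
    # clashes: backbone atoms of residues >= 2 apart in sequence (or on
    # different chains), linear penalty for overlap beyond CLASH_TOL
    flat = pred_bb.reshape(n, L * 3, 3)
    radii = np.tile([BB_RADII["N"], BB_RADII["CA"], BB_RADII["C"]], L)
    res_of = np.repeat(np.arange(L), 3)
    ch_of = np.repeat(np.asarray(chain_index), 3)
    sep_ok = (np.abs(res_of[:, None] - res_of[None, :]) >= 2) | \
             (ch_of[:, None] != ch_of[None, :])
    pair_mask = np.triu(sep_ok, k=1).astype(float)
    diff = flat.reshape(n, L * 3, 1, 3) - flat.reshape(n, 1, L * 3, 3)
    d = ((diff * diff).sum(axis=-1) + 1e-10).sqrt()
    lim = radii[:, None] + radii[None, :] - CLASH_TOL
    clash = ((Tensor(lim[None]) - d).relu() * Tensor(pair_mask[None]))
    total = total + clash.sum(axis=(1, 2)) * (1.0 / max(pair_mask.sum(), 1.0))
    return total


def violation_loss_struct(struct: AtomStructure) -> float:
    """Violation loss of a realized structure (backbone N/CA/C)."""
    bb = struct.coords(("N", "CA", "C")).reshape(1, len(struct), 3, 3)
    chains = struct.chains()
    chain_index = np.array([chains.index(r.chain) for r in struct])
    return float(violation_loss(Tensor(bb), chain_index).data[0])


def per_residue_lddt(pred_ca: np.ndarray, ref_ca: np.ndarray,
                     radius: float = LDDT_RADIUS) -> np.ndarray:
    """Calpha LDDT (0-100) of pred vs ref under the standard thresholds."""
    pred_ca = np.asarray(pred_ca, float)
    ref_ca = np.asarray(ref_ca, float)
    L = len(ref_ca)
    dr = np.linalg.norm(ref_ca[:, None] - ref_ca[None, :], axis=-1)
    dp = np.linalg.norm(pred_ca[:, None] - pred_ca[None, :], axis=-1)
    incl = (dr < radius) & ~np.eye(L, dtype=bool)
    out = np.zeros(L)
    for i in range(L):
        js = np.nonzero(incl[i])[0]
        if not len(js):
            out[i] = 100.0
            continue
        delta = np.abs(dp[i, js] - dr[i, js])
        out[i] = 100.0 * np.mean([(delta < t).mean() for t in LDDT_THRESHOLDS])
    return out


def plddt_loss(plddt_logits: Tensor, pred_ca: np.ndarray,
               ref_ca: np.ndarray, n_bins: int | None = None) -> Tensor:
    """Cross-entropy between the confidence head and the binned true LDDT.

    plddt_logits: (N, L, B); pred_ca: (N, L, 3); ref_ca: (L, 3).
    Returns (N,)."""
    n, L, b = plddt_logits.shape
    b = n_bins or b
    logp = plddt_logits.log_softmax(axis=-1)
    onehot = np.zeros((n, L, b))
    for m in range(n):
        lddt = per_residue_lddt(pred_ca[m], ref_ca)
        idx = np.clip((lddt / 100.0 * b).astype(int), 0, b - 1)
        onehot[m, np.arange(L), idx] = 1.0
    return -(logp * Tensor(onehot)).sum(axis=-1).mean(axis=1)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

STRUCTURE_TERMS = ("rmsd", "fape", "disto", "tors")
AUX_TERMS = ("plddt", "viol")


def combine_losses(terms: dict[str, Tensor], weights: dict[str, float]
                   ) -> LossBreakdown:
    """L = min_i L_structure_i + mean_i L_aux_i with the printed weights."""
    first = next(iter(terms.values()))
    n = first.shape[0]
    if n < 1:
        raise ValueError("empty community")
    for name, t in terms.items():
        if not np.all(np.isfinite(t.data)):
            raise ValueError(f"non-finite loss term {name!r}")
    zero = Tensor(np.zeros(n))
    structure = zero
    for name in STRUCTURE_TERMS:
        structure = structure + weights[name] * terms[name]
    aux = zero
    for name in AUX_TERMS:
        aux = aux + weights[name] * terms[name]
    argmin = int(np.argmin(structure.data))
    loss = structure[argmin] + aux.mean()
    return LossBreakdown(
        terms={k: v.data.copy() for k, v in terms.items()},
        structure=structure.data.copy(), aux=aux.data.copy(),
        total=float(loss.data), argmin=argmin, loss=loss)


def _dist(a: Tensor, b: Tensor) -> Tensor:
    diff = a - b
    return ((diff * diff).sum(axis=-1) + 1e-12).sqrt()


def _abs(x: Tensor) -> Tensor:
    return (x * x + 1e-12).sqrt()


def _cos_angle(a: Tensor, b: Tensor, c: Tensor) -> Tensor:
    u = a - b
    v = c - b
    num = (u * v).sum(axis=-1)
    den = (((u * u).sum(axis=-1) + 1e-12) *
           ((v * v).sum(axis=-1) + 1e-12)).sqrt()
    return num / den


# ---------------------------------------------------------------------------
# full community loss for a training example
# ---------------------------------------------------------------------------

def backbone_from_frames(t: FrameTensor) -> Tensor:
    """Ideal-geometry backbone N/CA/C from residue frames: (N, L, 3, 3)."""
    local = np.stack([BACKBONE_LOCAL["N"], BACKBONE_LOCAL["CA"],
                      BACKBONE_LOCAL["C"]])
    n, L = t.shape
    pts = Tensor(np.broadcast_to(local, (n, L, 3, 3)).copy())
    return t.apply(pts, extra_dims=1)


def community_loss(model, task, state, ground_truth: AtomStructure,
                   weights: dict[str, float] | None = None) -> LossBreakdown:
    """All six loss terms for one training example, per community member."""
    cfg = model.config
    weights = weights or cfg.loss_weights
    n = state.community_size
    L = len(task)

    pred_bb = backbone_from_frames(state.T)
    true_bb = ground_truth.coords(("N", "CA", "C")).reshape(L, 3, 3)
    true_rot = np.stack([r.frame().rotation for r in ground_truth])
    true_trans = np.stack([r.frame().translation for r in ground_truth])

    terms: dict[str, Tensor] = {}
    # The loop RMSD loss mirrors how final structures are realized: the
    # predicted loop is re-inserted into the *input* framework, so the
    # superposition uses the fixed input framework coordinates rather than
    # the (weakly drifting) predicted framework frames.
    const_bb = np.zeros((L, 3, 3))
    for i in np.nonzero(~task.loop_mask)[0]:
        res = task.structure[i]
        if res.has_backbone:
            const_bb[i] = np.stack([res.atoms["N"], res.atoms["CA"],
                                    res.atoms["C"]])
    mix = task.loop_mask.astype(float).reshape(1, L, 1, 1)
    bb_for_rmsd = pred_bb * Tensor(mix) + Tensor(const_bb[None] * (1 - mix))
    terms["rmsd"] = loop_rmsd_loss(bb_for_rmsd, ground_truth, task.loop_mask,
                                   task.framework_mask)
    terms["fape"] = fape_loss(state.T, pred_bb.reshape(n, 3 * L, 3),
                              (true_rot, true_trans),
                              true_bb.reshape(3 * L, 3),
                              clamp=cfg.fape_clamp, scale=cfg.fape_scale)
    cb = []
    for res in ground_truth:
        cb.append(res.atoms.get("CB", res.atoms["CA"]))
    cb = np.asarray(cb)
    true_d = np.linalg.norm(cb[:, None] - cb[None, :], axis=-1)
    terms["disto"] = distogram_loss(model.distogram_logits(state.Z), true_d,
                                    model.disto_edges)
    from .geometry import measure_torsions
    true_tors = measure_torsions(ground_truth)
    terms["tors"] = torsion_loss(model.torsion_sincos(state.S), true_tors,
                                 task.sequence)
    pred_ca = pred_bb.data[:, :, 1]
    ref_ca = ground_truth.coords(("CA",))
    terms["plddt"] = plddt_loss(model.plddt_logits(state.S), pred_ca, ref_ca)
    terms["viol"] = violation_loss(pred_bb, task.chain_index())
    return combine_losses(terms, weights)
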