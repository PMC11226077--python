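"""The community structure module.

A community of N candidate loop conformations is evolved jointly for
``n_cycles`` refinement cycles with shared parameters.  Each cycle runs

    single-feature IPA update -> cross-over attention across members ->
    pair-feature update with two triangular blocks -> four IPA layers
    updating the residue frames,

after which torsion and pLDDT heads read the final single features.  All
attention over 3-D points is expressed in per-residue local frames, making
single-feature updates invariant and frame updates equivariant under global
rigid motions of the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, einsum, stack
from .config import ModelConfig
from .geometry import RigidFrame, TorsionSet, CHI_ATOMS, ONE_TO_THREE, wrap_angle
from .nn import Adam, LayerNorm, Linear, ParamStore  # noqa: F401  (Adam re-export)
from .task import LoopTask

log = logging.getLogger("commloop.model")

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
N_TORSIONS = 7  # omega, phi, psi, chi1..chi4

# registry for pluggable sequence embedders (e.g. a protein language model)
EMBEDDERS: dict[str, callable] = {}


# ---------------------------------------------------------------------------
# differentiable rigid frames
# ---------------------------------------------------------------------------

class FrameTensor:
    """Batched rigid frames with autodiff: rot (..., 3, 3), trans (..., 3)."""

    def __init__(self, rot: Tensor, trans: Tensor):
        self.rot = rot
        self.trans = trans

    @property
    def shape(self):
        return self.trans.shape[:-1]

    @staticmethod
    def identity(shape) -> "FrameTensor":
        rot = np.broadcast_to(np.eye(3), (*shape, 3, 3)).copy()
        return FrameTensor(Tensor(rot), Tensor(np.zeros((*shape, 3))))

    @staticmethod
    def from_numpy(rot: np.ndarray, trans: np.ndarray) -> "FrameTensor":
        return FrameTensor(Tensor(np.asarray(rot, float)),
                           Tensor(np.asarray(trans, float)))

    def detach(self) -> "FrameTensor":
        return FrameTensor(self.rot.detach(), self.trans.detach())

    def detach_rot(self) -> "FrameTensor":
        return FrameTensor(self.rot.detach(), self.trans)

    def numpy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.rot.data.copy(), self.trans.data.copy()

    def apply(self, pts: Tensor, extra_dims: int = 1) -> Tensor:
        """R x + t for points with ``extra_dims`` trailing batch axes
        between the frame axes and the final 3-vector axis."""
        ex = "pqr"[:extra_dims]
        out = einsum(f"...ab,...{ex}b->...{ex}a", self.rot, pts)
        t = self.trans
        for _ in range(extra_dims):
            t = t.reshape(*t.shape[:-1], 1, 3)
        return out + t

    def apply_inverse(self, pts: Tensor, extra_dims: int = 1) -> Tensor:
        ex = "pqr"[:extra_dims]
        t = self.trans
        for _ in range(extra_dims):
            t = t.reshape(*t.shape[:-1], 1, 3)
        return einsum(f"...ab,...{ex}a->...{ex}b", self.rot, pts - t)

    def compose(self, other: "FrameTensor") -> "FrameTensor":
        rot = einsum("...ab,...bc->...ac", self.rot, other.rot)
        trans = einsum("...ab,...b->...a", self.rot, other.trans) + self.trans
        return FrameTensor(rot, trans)


def rotation_from_quaternion_vec(bcd: Tensor) -> Tensor:
    """Rotation matrices from the non-normalized quaternion (1, b, c, d)."""
    b = bcd[..., 0]
    c = bcd[..., 1]
    d = bcd[..., 2]
    one = Tensor(np.ones(b.shape))
    norm2 = one + b * b + c * c + d * d
    a = one
    rows = [
        (a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)),
        (2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)),
        (2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d),
    ]
    mat = stack([stack(r, axis=-1) for r in rows], axis=-2)
    return mat / norm2.reshape(*norm2.shape, 1, 1)


# ---------------------------------------------------------------------------
# community state
# ---------------------------------------------------------------------------

@dataclass
class CommunityState:
    S: Tensor            # (N, L, c_s) single features
    Z: Tensor            # (N, L, L, c_z) pair features
    T: FrameTensor       # (N, L) residue frames
    cycle: int = 0

    def __post_init__(self):
        n = self.S.shape[0]
        if self.Z.shape[0] != n or self.T.shape[0] != n:
            raise ValueError("community size differs across S, Z, T")
        for arr in (self.S.data, self.Z.data, self.T.rot.data,
                    self.T.trans.data):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite value in community state")

    @property
    def community_size(self) -> int:
        return self.S.shape[0]

    def permute_members(self, order) -> "CommunityState":
        order = np.asarray(order)
        return CommunityState(Tensor(self.S.data[order].copy()),
                              Tensor(self.Z.data[order].copy()),
                              FrameTensor.from_numpy(self.T.rot.data[order],
                                                     self.T.trans.data[order]),
                              self.cycle)


# ---------------------------------------------------------------------------
# deterministic fallback sequence encoding
# ---------------------------------------------------------------------------

def fallback_encoding(sequence: str, dim: int) -> np.ndarray:
    """One-hot identity plus sinusoidal position features, width ``dim``.

    Fully deterministic stand-in for a language-model embedding; rows differ
    between two sequences only at positions where the residues differ.
    """
    L = len(sequence)
    out = np.zeros((L, dim))
    for i, aa in enumerate(sequence):
        if aa not in AA_ORDER:
            raise ValueError(f"non-standard residue {aa!r}")
        out[i, AA_ORDER.index(aa)] = 1.0
    n_pos = dim - 20
    k = np.arange(n_pos)
    angles = np.arange(L)[:, None] / (10000.0 ** (2 * (k // 2) / max(n_pos, 1)))
    out[:, 20:] = np.where(k % 2 == 0, np.sin(angles), np.cos(angles))
    return out


def distance_bin_onehot(dist: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, dist, side="right")
    out = np.zeros((*dist.shape, len(edges) + 1))
    np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
    return out


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class CommunityModel:
    """Holds all parameters; every cycle reuses the same layer objects."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        self.store = ParamStore(rng)
        c_s, c_z = config.c_s, config.c_z
        st = self.store

        self.disto_edges = np.linspace(config.distogram_min, config.distogram_max,
                                       config.distogram_bins - 1)
        self.relpos_clip = 32

        # input embedding
        self.embed_ln = LayerNorm(st, "embed/ln", config.embed_dim)
        self.embed_lin = Linear(st, "embed/proj", config.embed_dim, c_s)

        # initial pair features
        pair_in = config.distogram_bins + 2 * c_s + 3
        self.pair_init = Linear(st, "pair_init/proj", pair_in, c_z)
        self.relpos = Linear(st, "pair_init/relpos", 2 * self.relpos_clip + 1, c_z)

        # IPA layers: one for the single-feature update, four for structure
        self.ipa_layers = {name: self._build_ipa(name)
                           for name in ["s_update"] +
                           [f"struct{i}" for i in range(4)]}
        self.s_transition = self._build_transition("s_update/transition", c_s)
        self.struct_transitions = [
            self._build_transition(f"struct{i}/transition", c_s) for i in range(4)]
        self.bb_update = [Linear(st, f"struct{i}/bb", c_s, 6, init="zeros")
                          for i in range(4)]

        # cross-over attention across community members
        self.cross_ln = LayerNorm(st, "crossover/ln", c_s)
        self.cross_qkv = Linear(st, "crossover/qkv", c_s, 3 * c_s, bias=False)
        self.cross_out = Linear(st, "crossover/out", c_s, c_s, init="zeros")

        # pair update stack
        self.pairup_proj = Linear(st, "z_update/proj",
                                  2 * c_s + config.distogram_bins, c_z,
                                  init="zeros")
        self.tri_blocks = [self._build_triangle_block(f"tri{b}")
                           for b in range(config.n_triangle_blocks)]

        # heads
        self.plddt_ln = LayerNorm(st, "plddt/ln", c_s)
        self.plddt_l1 = Linear(st, "plddt/l1", c_s, c_s)
        self.plddt_l2 = Linear(st, "plddt/l2", c_s, c_s)
        self.plddt_out = Linear(st, "plddt/out", c_s, config.plddt_bins,
                                init="zeros")
        self.disto_ln = LayerNorm(st, "disto/ln", c_z)
        self.disto_out = Linear(st, "disto/out", c_z, config.distogram_bins,
                                init="zeros")
        self.tors_in1 = Linear(st, "torsion/in1", c_s, c_s)
        self.tors_in2 = Linear(st, "torsion/in2", c_s, c_s)
        self.tors_blocks = [(Linear(st, f"torsion/b{i}/l1", c_s, c_s),
                             Linear(st, f"torsion/b{i}/l2", c_s, c_s))
                            for i in range(config.torsion_blocks)]
        self.tors_out = Linear(st, "torsion/out", c_s, 2 * N_TORSIONS)

    # -- layer builders --------------------------------------------------
    def _build_ipa(self, name: str) -> dict:
        cfg = self.config
        st = self.store
        c_s, c_z = cfg.c_s, cfg.c_z
        h, pq, pv = cfg.ipa_heads, cfg.ipa_qk_points, cfg.ipa_v_points
        ch = c_s // h
        out_dim = h * (c_z + ch + 3 * pv + pv)
        return {
            "ln_s": LayerNorm(st, f"{name}/ipa/ln_s", c_s),
            "ln_z": LayerNorm(st, f"{name}/ipa/ln_z", c_z),
            "q": Linear(st, f"{name}/ipa/q", c_s, h * ch),
            "k": Linear(st, f"{name}/ipa/k", c_s, h * ch),
            "v": Linear(st, f"{name}/ipa/v", c_s, h * ch),
            "qp": Linear(st, f"{name}/ipa/qp", c_s, h * pq * 3),
            "kp": Linear(st, f"{name}/ipa/kp", c_s, h * pq * 3),
            "vp": Linear(st, f"{name}/ipa/vp", c_s, h * pv * 3),
            "bias": Linear(st, f"{name}/ipa/bias", c_z, h, bias=False),
            "gamma": st.param(f"{name}/ipa/gamma", (h,), init="zeros"),
            "out": Linear(st, f"{name}/ipa/out", out_dim, c_s, init="zeros"),
            "ln_post": LayerNorm(st, f"{name}/ipa/ln_post", c_s),
        }

    def _build_transition(self, name: str, dim: int):
        st = self.store
        l1 = Linear(st, f"{name}/l1", dim, dim)
        l2 = Linear(st, f"{name}/l2", dim, dim)
        l3 = Linear(st, f"{name}/l3", dim, dim, init="zeros")
        ln = LayerNorm(st, f"{name}/ln", dim)

        def apply(x: Tensor) -> Tensor:
            return ln(x + l3(l2(l1(x).relu()).relu()))

        return apply

    def _build_triangle_block(self, name: str) -> dict:
        cfg = self.config
        st = self.store
        c_z = cfg.c_z
        block = {}
        for kind in ("out", "in"):
            nm = f"{name}/mult_{kind}"
            block[f"mult_{kind}"] = {
                "ln": LayerNorm(st, f"{nm}/ln", c_z),
                "a": Linear(st, f"{nm}/a", c_z, cfg.tri_mult_hidden),
                "ga": Linear(st, f"{nm}/ga", c_z, cfg.tri_mult_hidden),
                "b": Linear(st, f"{nm}/b", c_z, cfg.tri_mult_hidden),
                "gb": Linear(st, f"{nm}/gb", c_z, cfg.tri_mult_hidden),
                "g": Linear(st, f"{nm}/g", c_z, c_z),
                "ln_x": LayerNorm(st, f"{nm}/ln_x", cfg.tri_mult_hidden),
                "proj": Linear(st, f"{nm}/proj", cfg.tri_mult_hidden, c_z,
                               init="zeros"),
            }
        hc = cfg.tri_attn_heads * cfg.tri_attn_channels
        for kind in ("start", "end"):
            nm = f"{name}/attn_{kind}"
            block[f"attn_{kind}"] = {
                "ln": LayerNorm(st, f"{nm}/ln", c_z),
                "qkv": Linear(st, f"{nm}/qkv", c_z, 3 * hc, bias=False),
                "bias": Linear(st, f"{nm}/bias", c_z, cfg.tri_attn_heads,
                               bias=False),
                "gate": Linear(st, f"{nm}/gate", c_z, hc),
                "out": Linear(st, f"{nm}/out", hc, c_z, init="zeros"),
            }
        f = cfg.pair_transition_factor
        block["trans_ln"] = LayerNorm(st, f"{name}/trans/ln", c_z)
        block["trans_l1"] = Linear(st, f"{name}/trans/l1", c_z, f * c_z)
        block["trans_l2"] = Linear(st, f"{name}/trans/l2", f * c_z, c_z,
                                   init="zeros")
        return block

    # -- spec operations -------------------------------------------------
    def n_parameters(self) -> int:
        return self.store.n_parameters()

    def dither_output_projections(self, rng: np.random.Generator,
                                  scale: float = 0.05) -> None:
        """Fill zero-initialized output projection matrices with small
        random values.

        Freshly initialized models have residual-identity output
        projections, so forward passes do not yet depend on frames or pair
        features; invariance/equivariance checks on an untrained model are
        vacuous without this."""
        for name, p in self.store.params.items():
            if name.endswith("/w") and p.data.ndim == 2 and not np.any(p.data):
                p.data = rng.normal(0.0, scale, p.shape)

    def embed_sequence(self, sequence: str,
                       embedder_id: str = "deterministic-fallback") -> Tensor:
        """Initial single features (L, c_s); identical for all members."""
        if embedder_id == "deterministic-fallback":
            enc = fallback_encoding(sequence, self.config.embed_dim)
        elif embedder_id in EMBEDDERS:
            enc = np.asarray(EMBEDDERS[embedder_id](sequence), float)
            if enc.shape != (len(sequence), self.config.embed_dim):
                raise ValueError("registered embedder returned wrong shape")
        elif embedder_id == "esm2-plugin":
            raise RuntimeError(
                "esm2-plugin embedder is not registered in this installation; "
                "pass embedder_id='deterministic-fallback' or register a "
                "callable in commloop.model.EMBEDDERS['esm2-plugin']")
        else:
            raise ValueError(f"unknown embedder {embedder_id!r}")
        return self.embed_lin(self.embed_ln(Tensor(enc)))

    def init_loop_frames(self, task: LoopTask, n_members: int,
                         seed: int) -> FrameTensor:
        """Initial residue frames for every member.

        Loop residues are evenly spaced on the stem CA segment (identity
        rotations), then perturbed independently per member; framework
        residues keep their structural frames with weak perturbations.
        """
        cfg = self.config
        L = len(task)
        ca_pre, ca_post = task.stem_ca()
        seg = ca_post - ca_pre
        n_loop = int(task.loop_mask.sum())
        if (np.linalg.norm(seg) < 1e-6 and n_loop > 0
                and cfg.loop_trans_perturb == 0):
            raise ValueError("coincident stems with zero perturbation")
        base_rot = np.tile(np.eye(3), (L, 1, 1))
        base_trans = np.zeros((L, 3))
        loop_counter = 0
        for i in range(L):
            if task.loop_mask[i]:
                loop_counter += 1
                base_trans[i] = ca_pre + seg * loop_counter / (n_loop + 1)
            else:
                fr = task.structure[i].frame()
                base_rot[i] = fr.rotation
                base_trans[i] = fr.translation
        rot = np.tile(base_rot, (n_members, 1, 1, 1))
        trans = np.tile(base_trans, (n_members, 1, 1))
        for m in range(n_members):
            mrng = np.random.default_rng([seed, m])
            for i in range(L):
                if task.loop_mask[i]:
                    tmax = cfg.loop_trans_perturb
                    amax = np.deg2rad(cfg.loop_rot_perturb_deg)
                else:
                    tmax = cfg.framework_trans_perturb
                    amax = np.deg2rad(cfg.framework_rot_perturb_deg)
                # uniform in a ball of radius tmax
                vec = mrng.normal(size=3)
                vec *= (mrng.uniform() ** (1 / 3)) * tmax / np.linalg.norm(vec)
                axis = mrng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = mrng.uniform(0.0, amax)
                from .geometry import _rotation_about_axis
                rot[m, i] = rot[m, i] @ _rotation_about_axis(axis, angle)
                trans[m, i] = trans[m, i] + vec
        return FrameTensor.from_numpy(rot, trans)

    def init_pair(self, s0: Tensor, t0: FrameTensor, task: LoopTask) -> Tensor:
        """Initial pair features from distogram bins of the initial
        structures, row/column single features, and chain/loop flags."""
        n, L = t0.shape
        dists = np.linalg.norm(t0.trans.data[:, :, None] -
                               t0.trans.data[:, None, :], axis=-1)
        onehot = distance_bin_onehot(dists, self.disto_edges)
        chain_idx = task.chain_index()
        same_chain = (chain_idx[:, None] == chain_idx[None, :]).astype(float)
        loop = task.loop_mask.astype(float)
        flags = np.stack([np.broadcast_to(same_chain, (L, L)),
                          np.broadcast_to(loop[:, None], (L, L)),
                          np.broadcast_to(loop[None, :], (L, L))], axis=-1)
        flags = np.tile(flags, (n, 1, 1, 1))
        si = s0.reshape(1, L, 1, -1) * Tensor(np.ones((n, 1, L, 1)))
        sj = s0.reshape(1, 1, L, -1) * Tensor(np.ones((n, L, 1, 1)))
        z = self.pair_init(concat([Tensor(onehot), si, sj, Tensor(flags)],
                                  axis=-1))
        # relative sequence position, clipped, within-chain only
        offset = np.arange(L)[:, None] - np.arange(L)[None, :]
        offset = np.clip(offset, -self.relpos_clip, self.relpos_clip)
        rel = np.eye(2 * self.relpos_clip + 1)[offset + self.relpos_clip]
        rel *= same_chain[..., None]
        return z + self.relpos(Tensor(rel))

    def ipa_layer(self, name: str, s: Tensor, z: Tensor, t: FrameTensor
                  ) -> Tensor:
        """AlphaFold-style invariant point attention for one member batch.

        Returns the updated single features (residual + layer norm applied).
        Output is invariant to global rigid transforms of ``t``.
        """
        if not (np.all(np.isfinite(s.data)) and np.all(np.isfinite(z.data))):
            raise ValueError("non-finite input to IPA")
        cfg = self.config
        p = self.ipa_layers[name]
        n, L, _ = s.shape
        h, ch = cfg.ipa_heads, cfg.c_s // cfg.ipa_heads
        pq, pv = cfg.ipa_qk_points, cfg.ipa_v_points
        sl = p["ln_s"](s)
        zl = p["ln_z"](z)
        t = t.detach_rot()

        q = p["q"](sl).reshape(n, L, h, ch)
        k = p["k"](sl).reshape(n, L, h, ch)
        v = p["v"](sl).reshape(n, L, h, ch)
        qp = t.apply(p["qp"](sl).reshape(n, L, h * pq, 3), 1).reshape(n, L, h, pq, 3)
        kp = t.apply(p["kp"](sl).reshape(n, L, h * pq, 3), 1).reshape(n, L, h, pq, 3)
        vp = t.apply(p["vp"](sl).reshape(n, L, h * pv, 3), 1).reshape(n, L, h, pv, 3)

        wc = np.sqrt(2.0 / (9.0 * pq))
        wl = np.sqrt(1.0 / 3.0)
        logits = einsum("nihc,njhc->nhij", q, k) * (1.0 / np.sqrt(ch))
        bias = p["bias"](zl).transpose((0, 3, 1, 2))
        diff = qp.reshape(n, L, 1, h, pq, 3) - kp.reshape(n, 1, L, h, pq, 3)
        d2 = (diff * diff).sum(axis=(-1, -2)).transpose((0, 3, 1, 2))
        gamma = (p["gamma"].exp() + 1.0).log()  # softplus, positive
        gamma = gamma.reshape(1, h, 1, 1)
        logits = wl * (logits + bias) - (wl * wc / 2.0) * gamma * d2
        a = logits.softmax(axis=-1)

        o_s = einsum("nhij,njhc->nihc", a, v).reshape(n, L, h * ch)
        o_z = einsum("nhij,nijz->nihz", a, zl).reshape(n, L, h * cfg.c_z)
        o_p = einsum("nhij,njhpa->nihpa", a, vp)
        o_p_local = t.apply_inverse(o_p.reshape(n, L, h * pv, 3), 1)
        o_norm = ((o_p_local * o_p_local).sum(axis=-1) + 1e-8).sqrt()
        out = p["out"](concat([o_s, o_z,
                               o_p_local.reshape(n, L, h * pv * 3),
                               o_norm.reshape(n, L, h * pv)], axis=-1))
        return p["ln_post"](s + out)

    def crossover(self, s: Tensor, return_weights: bool = False):
        """Attention across the member axis, independently per residue."""
        cfg = self.config
        n, L, c_s = s.shape
        h = cfg.crossover_heads
        ch = c_s // h
        sl = self.cross_ln(s)
        qkv = self.cross_qkv(sl).reshape(n, L, 3, h, ch)
        q, k, v = qkv[:, :, 0], qkv[:, :, 1], qkv[:, :, 2]
        logits = einsum("nlhc,mlhc->lhnm", q, k) * (1.0 / np.sqrt(ch))
        a = logits.softmax(axis=-1)     # weights over members m sum to 1
        o = einsum("lhnm,mlhc->nlhc", a, v).reshape(n, L, c_s)
        out = s + self.cross_out(o)
        if return_weights:
            return out, a.data
        return out

    def z_update(self, s_plus: Tensor, t: FrameTensor, z: Tensor) -> Tensor:
        """Pair update from single/structure features + triangular blocks."""
        cfg = self.config
        n, L, c_s = s_plus.shape
        dists = np.linalg.norm(t.trans.data[:, :, None] -
                               t.trans.data[:, None, :], axis=-1)
        onehot = Tensor(distance_bin_onehot(dists, self.disto_edges))
        si = s_plus.reshape(n, L, 1, c_s) * Tensor(np.ones((n, 1, L, 1)))
        sj = s_plus.reshape(n, 1, L, c_s) * Tensor(np.ones((n, L, 1, 1)))
        z = z + self.pairup_proj(concat([si, sj, onehot], axis=-1))
        for block in self.tri_blocks:
            z = z + self._tri_mult(block["mult_out"], z, outgoing=True)
            z = z + self._tri_mult(block["mult_in"], z, outgoing=False)
            z = z + self._tri_attn(block["attn_start"], z, starting=True)
            z = z + self._tri_attn(block["attn_end"], z, starting=False)
            zt = block["trans_ln"](z)
            z = z + block["trans_l2"](block["trans_l1"](zt).relu())
        return z

    def _tri_mult(self, p: dict, z: Tensor, outgoing: bool) -> Tensor:
        zl = p["ln"](z)
        a = p["ga"](zl).sigmoid() * p["a"](zl)
        b = p["gb"](zl).sigmoid() * p["b"](zl)
        spec = "nikc,njkc->nijc" if outgoing else "nkic,nkjc->nijc"
        x = einsum(spec, a, b)
        return p["g"](zl).sigmoid() * p["proj"](p["ln_x"](x))

    def _tri_attn(self, p: dict, z: Tensor, starting: bool) -> Tensor:
        cfg = self.config
        n, L, _, _ = z.shape
        h, ch = cfg.tri_attn_heads, cfg.tri_attn_channels
        zl = p["ln"](z)
        qkv = p["qkv"](zl).reshape(n, L, L, 3, h, ch)
        q, k, v = qkv[:, :, :, 0], qkv[:, :, :, 1], qkv[:, :, :, 2]
        scale = 1.0 / np.sqrt(ch)
        bias = p["bias"](zl)                      # (n, L, L, h)
        if starting:
            logits = einsum("nijhc,nikhc->nhijk", q, k) * scale
            logits = logits + bias.transpose((0, 3, 1, 2)).reshape(n, h, 1, L, L)
            a = logits.softmax(axis=-1)
            o = einsum("nhijk,nikhc->nijhc", a, v)
        else:
            logits = einsum("nijhc,nkjhc->nhijk", q, k) * scale
            logits = logits + bias.transpose((0, 3, 2, 1)).reshape(n, h, L, 1, L)
            a = logits.softmax(axis=-1)
            o = einsum("nhijk,nkjhc->nijhc", a, v)
        gate = p["gate"](zl).sigmoid().reshape(n, L, L, h, ch)
        return p["out"]((gate * o).reshape(n, L, L, h * ch))

    def structure_update(self, s_plus: Tensor, z: Tensor, t: FrameTensor
                         ) -> tuple[FrameTensor, Tensor]:
        """Four {IPA -> transition -> frame update} layers."""
        s = s_plus
        for i in range(4):
            s = self.ipa_layer(f"struct{i}", s, z, t)
            s = self.struct_transitions[i](s)
            upd = self.bb_update[i](s)
            rot = rotation_from_quaternion_vec(upd[..., :3])
            trans = upd[..., 3:]
            t = t.compose(FrameTensor(rot, trans))
        return t, s

    def run_cycles(self, task: LoopTask, seed: int,
                   n_members: int | None = None,
                   init_state: CommunityState | None = None,
                   embedder_id: str = "deterministic-fallback",
                   record_trajectory: bool = True
                   ) -> tuple[CommunityState, list]:
        """Full community maturation; returns the final state and the
        per-cycle trajectory of frames (rot, trans) arrays."""
        from .autodiff import graph_context

        cfg = self.config
        n = n_members or cfg.community_size
        if init_state is None:
            state = self.init_community(task, n, seed, embedder_id)
        else:
            state = init_state
        s, z, t = state.S, state.Z, state.T
        trajectory = []
        with graph_context():
            for cycle in range(cfg.n_cycles):
                s1 = self.ipa_layer("s_update", s, z, t)
                s1 = self.s_transition(s1)
                s_plus = self.crossover(s1)
                z = self.z_update(s_plus, t, z)
                t, s = self.structure_update(s_plus, z, t)
                if record_trajectory:
                    trajectory.append(t.numpy())
        return CommunityState(s, z, t, cycle=cfg.n_cycles), trajectory

    def init_community(self, task: LoopTask, n_members: int, seed: int,
                       embedder_id: str = "deterministic-fallback"
                       ) -> CommunityState:
        s0 = self.embed_sequence(task.sequence, embedder_id)
        n, L = n_members, len(task)
        s = s0.reshape(1, L, -1) * Tensor(np.ones((n, 1, 1)))
        t0 = self.init_loop_frames(task, n, seed)
        z0 = self.init_pair(s0, t0, task)
        return CommunityState(s, z0, t0, cycle=0)

    # -- heads ------------------------------------------------------------
    def plddt_logits(self, s_final: Tensor) -> Tensor:
        x = self.plddt_ln(s_final)
        x = self.plddt_l2(self.plddt_l1(x).relu()).relu()
        return self.plddt_out(x)

    def predict_plddt(self, s_final: Tensor, loop_mask=None
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Per-residue pLDDT in [0, 100] (expectation over bin centers) and
        the per-member mean over loop residues."""
        probs = self.plddt_logits(s_final).softmax(axis=-1).data
        nb = self.config.plddt_bins
        centers = (np.arange(nb) + 0.5) * (100.0 / nb)
        per_res = probs @ centers
        if loop_mask is None:
            member = per_res.mean(axis=-1)
        else:
            member = per_res[:, np.asarray(loop_mask, bool)].mean(axis=-1)
        return per_res, member

    def torsion_sincos(self, s_final: Tensor) -> Tensor:
        """Raw (sin, cos) pairs, shape (N, L, 7, 2); order
        (omega, phi, psi, chi1..chi4)."""
        a = self.tors_in1(s_final.relu())
        a = a + self.tors_in2(s_final.relu())
        for l1, l2 in self.tors_blocks:
            a = a + l2(l1(a.relu()).relu())
        out = self.tors_out(a.relu())
        n, L, _ = out.shape
        return out.reshape(n, L, N_TORSIONS, 2)

    def predict_torsions(self, s_final: Tensor, sequence: str
                         ) -> list[TorsionSet]:
        """Angles via atan2 of the normalized (sin, cos) head output."""
        sc = self.torsion_sincos(s_final).data
        norm = np.linalg.norm(sc, axis=-1, keepdims=True)
        small = norm < 1e-6
        if np.any(small):
            log.warning("%d torsion sin/cos pairs near zero norm; guarded",
                        int(small.sum()))
        sc = sc / np.maximum(norm, 1e-6)
        angles = np.arctan2(sc[..., 0], sc[..., 1])
        out = []
        for m in range(angles.shape[0]):
            ts = TorsionSet.empty(len(sequence))
            ts.omega = wrap_angle(angles[m, :, 0])
            ts.phi = wrap_angle(angles[m, :, 1])
            ts.psi = wrap_angle(angles[m, :, 2])
            ts.omega_mask[:] = ts.phi_mask[:] = ts.psi_mask[:] = True
            for i, aa in enumerate(sequence):
                nchi = len(CHI_ATOMS[ONE_TO_THREE[aa]])
                ts.chi[i, :nchi] = wrap_angle(angles[m, i, 3:3 + nchi])
                ts.chi_mask[i, :nchi] = True
            out.append(ts)
        return out

    def distogram_logits(self, z_final: Tensor) -> Tensor:
        return self.disto_out(self.disto_ln(z_final))

    # -- structure realization -------------------------------------------
    def realize_structures(self, task: LoopTask, state: CommunityState,
                           ) -> list:
        """Final full-atom structures: predicted loop residues (from frames
        and predicted torsions) reinserted into the input framework."""
        from .geometry import torsions_to_atoms

        torsions = self.predict_torsions(state.S, task.sequence)
        rot, trans = state.T.numpy()
        results = []
        loop_idx = np.nonzero(task.loop_mask)[0]
        for m in range(state.community_size):
            frames = [RigidFrame(rot[m, i], trans[m, i]) for i in loop_idx]
            ts = TorsionSet.empty(len(loop_idx))
            ts.phi = torsions[m].phi[loop_idx]
            ts.psi = torsions[m].psi[loop_idx]
            ts.omega = torsions[m].omega[loop_idx]
            ts.chi = torsions[m].chi[loop_idx]
            ts.phi_mask = torsions[m].phi_mask[loop_idx]
            ts.psi_mask = torsions[m].psi_mask[loop_idx]
            ts.omega_mask = torsions[m].omega_mask[loop_idx]
            ts.chi_mask = torsions[m].chi_mask[loop_idx]
            loop_seq = task.loop_sequence
            loop_struct = torsions_to_atoms(frames, ts, loop_seq)
            full = task.structure.copy()
            for j, i in enumerate(loop_idx):
                full.residues[i].atoms = {
                    k: v.copy() for k, v in loop_struct.residues[j].atoms.items()}
            results.append(full)
        return results
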