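"""Rigid-frame algebra, superposition, torsion/atom conversion and QC counts.

Structures are represented by :class:`AtomStructure` (per-residue atom
dictionaries), residues by rigid frames built from their N/CA/C atoms the
way the AlphaFold structure module defines them (CA at the origin, CA->C
along +x, N in the xy plane).  Ideal residue geometry is taken from the
chemical component dictionary bundled with biotite, re-expressed in the
backbone frame once at import time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AAS = tuple(sorted(THREE_TO_ONE))

# Ideal backbone internal coordinates (Engh-Huber style means).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = np.deg2rad(111.2)
ANGLE_CA_C_N = np.deg2rad(116.2)
ANGLE_C_N_CA = np.deg2rad(121.7)

# Backbone atom positions in the residue's own frame.
BACKBONE_LOCAL = {
    "CA": np.zeros(3),
    "C": np.array([BOND_CA_C, 0.0, 0.0]),
    "N": BOND_N_CA * np.array([np.cos(ANGLE_N_CA_C), np.sin(ANGLE_N_CA_C), 0.0]),
}

# Side-chain torsion definitions (atom quadruples), standard nomenclature.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [], "GLY": [],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}
# chi angles that are pi-periodic because of side-chain symmetry
SYMMETRIC_CHI = {"ASP": (2,), "GLU": (3,), "PHE": (2,), "TYR": (2,)}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

CIS_NONPLANAR_CUTOFF_DEG = 30.0
CLASH_TOLERANCE = 0.4  # Angstrom below radius sum
BONDED_C_N_CUTOFF = 2.0


# ---------------------------------------------------------------------------
# rigid frames
# ---------------------------------------------------------------------------

@dataclass
class RigidFrame:
    """A proper rigid transform: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def validate(self, tol: float = 1e-6) -> None:
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > tol:
            raise ValueError(f"rotation is not orthonormal (max dev {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > tol:
            raise ValueError("rotation determinant is not +1")

    @staticmethod
    def identity() -> "RigidFrame":
        return RigidFrame(np.eye(3), np.zeros(3))

    @staticmethod
    def from_three_points(n: np.ndarray, ca: np.ndarray, c: np.ndarray
                          ) -> "RigidFrame":
        """Backbone frame by Gram-Schmidt: CA origin, CA->C = +x, N in xy."""
        v1 = np.asarray(c, float) - ca
        v2 = np.asarray(n, float) - ca
        e1 = v1 / np.linalg.norm(v1)
        u2 = v2 - e1 * (e1 @ v2)
        e2 = u2 / np.linalg.norm(u2)
        e3 = np.cross(e1, e2)
        return RigidFrame(np.stack([e1, e2, e3], axis=1), np.asarray(ca, float))

    def apply(self, points) -> np.ndarray:
        self.validate()
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_inverse(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.translation) @ self.rotation

    def compose(self, other: "RigidFrame") -> "RigidFrame":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidFrame(self.rotation @ other.rotation,
                          self.rotation @ other.translation + self.translation)

    def invert(self) -> "RigidFrame":
        return RigidFrame(self.rotation.T, -self.rotation.T @ self.translation)


def compose_apply(frame: RigidFrame, points) -> np.ndarray:
    """Apply a validated rigid frame to a set of points."""
    return frame.apply(points)


# ---------------------------------------------------------------------------
# atom container
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    name: str
    chain: str
    res_id: int
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    b_factor: float = 0.0
    occupancy: float = 1.0

    def copy(self) -> "Residue":
        return Residue(self.name, self.chain, self.res_id,
                       {k: v.copy() for k, v in self.atoms.items()},
                       self.b_factor, self.occupancy)

    @property
    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    def frame(self) -> RigidFrame:
        return RigidFrame.from_three_points(self.atoms["N"], self.atoms["CA"],
                                            self.atoms["C"])


class AtomStructure:
    """A list of residues with named heavy-atom coordinates."""

    def __init__(self, residues: list[Residue] | None = None):
        self.residues: list[Residue] = residues or []

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i) -> Residue:
        return self.residues[i]

    def copy(self) -> "AtomStructure":
        return AtomStructure([r.copy() for r in self.residues])

    def subset(self, mask) -> "AtomStructure":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return AtomStructure([self.residues[i].copy() for i in idx])

    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def coords(self, atom_names=("CA",), mask=None) -> np.ndarray:
        """Stacked coordinates; raises naming the residue on missing atoms."""
        idx = range(len(self)) if mask is None else np.nonzero(np.asarray(mask))[0]
        out = []
        for i in idx:
            res = self.residues[i]
            for a in atom_names:
                if a not in res.atoms:
                    raise KeyError(
                        f"residue {res.chain}{res.res_id} ({res.name}) is "
                        f"missing atom {a}")
                out.append(res.atoms[a])
        return np.array(out, dtype=float).reshape(-1, 3)

    def transform(self, frame: RigidFrame) -> "AtomStructure":
        out = self.copy()
        for res in out.residues:
            for a in res.atoms:
                res.atoms[a] = frame.apply(res.atoms[a])
        return out

    def validate_finite(self) -> None:
        for res in self.residues:
            for a, xyz in res.atoms.items():
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(
                        f"non-finite coordinate at {res.chain}{res.res_id}/{a}")


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

@dataclass
class TorsionSet:
    """Backbone (phi, psi, omega) and side-chain chi1..4 angles in radians."""

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    chi: np.ndarray          # (L, 4)
    phi_mask: np.ndarray
    psi_mask: np.ndarray
    omega_mask: np.ndarray
    chi_mask: np.ndarray     # (L, 4)

    @staticmethod
    def empty(n: int) -> "TorsionSet":
        return TorsionSet(np.zeros(n), np.zeros(n), np.full(n, np.pi),
                          np.zeros((n, 4)), np.zeros(n, bool), np.zeros(n, bool),
                          np.zeros(n, bool), np.zeros((n, 4), bool))

    def validate(self) -> None:
        for ang, m in ((self.phi, self.phi_mask), (self.psi, self.psi_mask),
                       (self.omega, self.omega_mask)):
            a = ang[m]
            if a.size and (a.min() <= -np.pi - 1e-9 or a.max() > np.pi + 1e-9):
                raise ValueError("torsion angle outside (-pi, pi]")


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (IUPAC convention) in radians."""
    b0 = np.asarray(p0, float) - p1
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return float(np.arctan2(np.cross(b1, v) @ w, v @ w))


def wrap_angle(a):
    """Wrap to (-pi, pi]."""
    a = np.asarray(a, float)
    out = -(np.mod(-a + np.pi, 2 * np.pi) - np.pi)
    return out if out.ndim else float(out)


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


# ---------------------------------------------------------------------------
# ideal residue templates (from the bundled chemical component dictionary)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def residue_template(res_name: str) -> dict:
    """Heavy-atom positions in the backbone frame plus bond graph.

    Returns dict with ``local`` (atom -> 3-vector in the residue frame, with
    N/CA/C snapped to the ideal backbone positions), ``bonds`` (adjacency
    dict), and ``chi_template`` (chi angles the raw template encodes).
    """
    if res_name not in THREE_TO_ONE:
        raise ValueError(f"unknown residue name {res_name!r}")
    from biotite.structure.info import residue as ccd_residue

    arr = ccd_residue(res_name)
    keep = [i for i, (el, nm) in enumerate(zip(arr.element, arr.atom_name))
            if el != "H" and nm != "OXT"]
    names = [arr.atom_name[i] for i in keep]
    coords = arr.coord[keep].astype(float)
    pos = dict(zip(names, coords))
    frame = RigidFrame.from_three_points(pos["N"], pos["CA"], pos["C"])
    local = {n: frame.apply_inverse(pos[n]) for n in names}
    for bb, xyz in BACKBONE_LOCAL.items():
        local[bb] = xyz.copy()

    index = {n: i for i, n in enumerate(names)}
    bonds: dict[str, set[str]] = {n: set() for n in names}
    bl, _ = arr.bonds.get_all_bonds()
    for i in keep:
        for j in bl[i]:
            if j >= 0 and j in keep:
                a, b = arr.atom_name[i], arr.atom_name[j]
                bonds[a].add(b)
                bonds[b].add(a)
    del index

    chi_template = []
    for quad in CHI_ATOMS[res_name]:
        chi_template.append(dihedral(*[local[a] for a in quad]))
    psi_o = dihedral(local["N"], local["CA"], local["C"], local["O"])
    elements = {n: ("S" if n.startswith("S") else n[0]) for n in names}
    return {"local": local, "bonds": bonds, "chi_template": np.array(chi_template),
            "psi_o_template": psi_o, "atom_order": names, "elements": elements}


@lru_cache(maxsize=None)
def _chi_downstream(res_name: str, chi_index: int) -> frozenset:
    """Atoms rotated by chi_{chi_index+1}: reachable from the 4th axis atom
    without crossing the 3rd (axis base)."""
    tpl = residue_template(res_name)
    _, _, base, tip = CHI_ATOMS[res_name][chi_index]
    seen = {base, tip}
    queue = [tip]
    while queue:
        cur = queue.pop()
        for nb in tpl["bonds"][cur]:
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    seen.discard(base)
    return frozenset(seen)


@lru_cache(maxsize=None)
def _l_chirality_sign() -> float:
    tpl = residue_template("ALA")["local"]
    v = np.dot(np.cross(tpl["N"] - tpl["CA"], tpl["C"] - tpl["CA"]),
               tpl["CB"] - tpl["CA"])
    return float(np.sign(v))


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile, target) -> tuple[RigidFrame, float]:
    """Least-squares rigid superposition of paired point sets (Kabsch/SVD).

    Returns the frame mapping ``mobile`` onto ``target`` and the residual
    RMSD.  Requires at least three non-collinear points.
    """
    mob = np.asarray(mobile, float).reshape(-1, 3)
    tgt = np.asarray(target, float).reshape(-1, 3)
    if mob.shape != tgt.shape:
        raise ValueError("point sets must have matching shapes")
    if len(mob) < 3:
        raise ValueError("need at least 3 paired points")
    mc, tc = mob.mean(0), tgt.mean(0)
    a, b = mob - mc, tgt - tc
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    frame = RigidFrame(rot, tc - rot @ mc)
    diff = frame.apply(mob) - tgt
    rmsd = float(np.sqrt((diff ** 2).sum() / len(mob)))
    return frame, rmsd


def loop_rmsd(pred: AtomStructure, ref: AtomStructure, loop_mask,
              framework_mask) -> float:
    """Backbone (N, CA, C) RMSD over loop residues after superposing the
    prediction on the reference using framework CA atoms only."""
    loop_mask = np.asarray(loop_mask, bool)
    framework_mask = np.asarray(framework_mask, bool)
    if np.any(loop_mask & framework_mask):
        raise ValueError("loop and framework masks overlap")
    if loop_mask.sum() < 1:
        raise ValueError("loop mask selects no residues")
    if framework_mask.sum() < 3:
        raise ValueError("framework mask must select at least 3 residues")
    frame, _ = kabsch_superpose(pred.coords(("CA",), framework_mask),
                                ref.coords(("CA",), framework_mask))
    p = frame.apply(pred.coords(("N", "CA", "C"), loop_mask))
    r = ref.coords(("N", "CA", "C"), loop_mask)
    return float(np.sqrt(((p - r) ** 2).sum() / len(p)))


# ---------------------------------------------------------------------------
# torsion -> atoms and back
# ---------------------------------------------------------------------------

def torsions_to_atoms(frames: list[RigidFrame], torsions: TorsionSet,
                      sequence: str, chain: str = "A",
                      start_res_id: int = 1) -> AtomStructure:
    """Build all heavy atoms from per-residue frames and torsion angles.

    Backbone N/CA/C come straight from the frames with ideal internal
    coordinates; O is set by psi; side chains by applying chi rotations to
    the canonical template.
    """
    if len(frames) != len(sequence):
        raise ValueError("one frame per residue required")
    torsions.validate()
    residues = []
    for i, aa in enumerate(sequence):
        res_name = ONE_TO_THREE.get(aa)
        if res_name is None:
            raise ValueError(f"unknown residue letter {aa!r} at position {i}")
        tpl = residue_template(res_name)
        local = {k: v.copy() for k, v in tpl["local"].items()}
        # psi-driven carbonyl oxygen: dihedral(N, CA, C, O) = psi + pi
        if torsions.psi_mask[i]:
            delta = wrap_angle(torsions.psi[i] + np.pi - tpl["psi_o_template"])
            rot = _rotation_about_axis(local["C"] - local["CA"], delta)
            local["O"] = local["C"] + rot @ (local["O"] - local["C"])
        # chi-driven side chain, applied proximal -> distal; the proline
        # ring is kept rigid (its chi angles are not free parameters)
        for k in range(0 if res_name != "PRO" else 99,
                       len(CHI_ATOMS[res_name])):
            if not torsions.chi_mask[i, k]:
                continue
            a1, a2, a3, _ = CHI_ATOMS[res_name][k]
            current = dihedral(local[a1], local[a2], local[a3],
                               local[CHI_ATOMS[res_name][k][3]])
            delta = wrap_angle(torsions.chi[i, k] - current)
            rot = _rotation_about_axis(local[a3] - local[a2], delta)
            pivot = local[a3]
            for atom in _chi_downstream(res_name, k):
                local[atom] = pivot + rot @ (local[atom] - pivot)
        frames[i].validate()
        atoms = {n: frames[i].apply(x) for n, x in local.items()}
        residues.append(Residue(res_name, chain, start_res_id + i, atoms))
    return AtomStructure(residues)


def measure_torsions(struct: AtomStructure) -> TorsionSet:
    """Measure phi/psi/omega/chi from coordinates (masks mark defined angles)."""
    n = len(struct)
    ts = TorsionSet.empty(n)
    for i, res in enumerate(struct.residues):
        prev_res = struct.residues[i - 1] if i > 0 else None
        next_res = struct.residues[i + 1] if i < n - 1 else None
        if prev_res is not None and prev_res.chain != res.chain:
            prev_res = None
        if next_res is not None and next_res.chain != res.chain:
            next_res = None
        a = res.atoms
        if prev_res is not None and "C" in prev_res.atoms and res.has_backbone:
            ts.phi[i] = dihedral(prev_res.atoms["C"], a["N"], a["CA"], a["C"])
            ts.phi_mask[i] = True
            if "CA" in prev_res.atoms:
                ts.omega[i] = dihedral(prev_res.atoms["CA"], prev_res.atoms["C"],
                                       a["N"], a["CA"])
                ts.omega_mask[i] = True
        if next_res is not None and "N" in next_res.atoms and res.has_backbone:
            ts.psi[i] = dihedral(a["N"], a["CA"], a["C"], next_res.atoms["N"])
            ts.psi_mask[i] = True
        elif res.has_backbone and "O" in a:
            # terminal residue: infer psi from the carbonyl oxygen
            ts.psi[i] = wrap_angle(dihedral(a["N"], a["CA"], a["C"], a["O"]) - np.pi)
            ts.psi_mask[i] = True
        for k, quad in enumerate(CHI_ATOMS.get(res.name, [])):
            if all(q in a for q in quad):
                ts.chi[i, k] = dihedral(*[a[q] for q in quad])
                ts.chi_mask[i, k] = True
    return ts


def _nerf_place(a, b, c, bond: float, angle: float, dih: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(dih),
                        bond * np.sin(angle) * np.sin(dih)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain_from_torsions(sequence: str, phi, psi, omega=None,
                              chi=None, chain: str = "A",
                              start_res_id: int = 1,
                              start_frame: RigidFrame | None = None
                              ) -> tuple[list[RigidFrame], AtomStructure]:
    """Grow an ideal-geometry backbone from torsions and build full atoms.

    phi[0] and psi[-1] still shape O placement/the returned torsion set but
    the chain is anchored at ``start_frame`` (identity by default).
    """
    L = len(sequence)
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    omega = np.full(L, np.pi) if omega is None else np.asarray(omega, float)
    if start_frame is None:
        start_frame = RigidFrame.identity()
    n_xyz = np.zeros((L, 3))
    ca_xyz = np.zeros((L, 3))
    c_xyz = np.zeros((L, 3))
    n_xyz[0] = start_frame.apply(BACKBONE_LOCAL["N"])
    ca_xyz[0] = start_frame.apply(BACKBONE_LOCAL["CA"])
    c_xyz[0] = start_frame.apply(BACKBONE_LOCAL["C"])
    for i in range(1, L):
        n_xyz[i] = _nerf_place(n_xyz[i - 1], ca_xyz[i - 1], c_xyz[i - 1],
                               BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_xyz[i] = _nerf_place(ca_xyz[i - 1], c_xyz[i - 1], n_xyz[i],
                                BOND_N_CA, ANGLE_C_N_CA, omega[i])
        c_xyz[i] = _nerf_place(c_xyz[i - 1], n_xyz[i], ca_xyz[i],
                               BOND_CA_C, ANGLE_N_CA_C, phi[i])
    frames = [RigidFrame.from_three_points(n_xyz[i], ca_xyz[i], c_xyz[i])
              for i in range(L)]
    ts = TorsionSet.empty(L)
    ts.phi, ts.psi, ts.omega = phi.copy(), psi.copy(), omega.copy()
    ts.phi_mask[:] = ts.psi_mask[:] = ts.omega_mask[:] = True
    if chi is not None:
        chi = np.asarray(chi, float)
        for i, aa in enumerate(sequence):
            nchi = len(CHI_ATOMS[ONE_TO_THREE[aa]])
            ts.chi[i, :nchi] = chi[i, :nchi]
            ts.chi_mask[i, :nchi] = True
    struct = torsions_to_atoms(frames, ts, sequence, chain=chain,
                               start_res_id=start_res_id)
    return frames, struct


# ---------------------------------------------------------------------------
# geometry quality
# ---------------------------------------------------------------------------

def _bonded_pairs(struct: AtomStructure):
    """Consecutive same-chain residue pairs with a peptide bond (C-N < 2 A)."""
    for i in range(len(struct) - 1):
        a, b = struct.residues[i], struct.residues[i + 1]
        if a.chain != b.chain or "C" not in a.atoms or "N" not in b.atoms:
            continue
        if np.linalg.norm(a.atoms["C"] - b.atoms["N"]) < BONDED_C_N_CUTOFF:
            yield i, i + 1


def _cross_link_bond_distance(res_a: Residue, res_b: Residue) -> dict:
    """Bond-path length between atoms of peptide-bonded residues a-b,
    counting through the C(a)-N(b) link; pairs further than 3 bonds are
    omitted."""
    try:
        ta = residue_template(res_a.name)
        tb = residue_template(res_b.name)
    except ValueError:
        return {}
    def bfs(bonds, src):
        dist = {src: 0}
        q = [src]
        while q:
            cur = q.pop(0)
            if dist[cur] >= 3:
                continue
            for nb in bonds[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + 1
                    q.append(nb)
        return dist
    da = bfs(ta["bonds"], "C")   # distance to the linking C within residue a
    db = bfs(tb["bonds"], "N")   # distance to the linking N within residue b
    out = {}
    for na, la in da.items():
        for nb, lb in db.items():
            path = la + 1 + lb
            if path <= 3:
                out[(na, nb)] = path
    return out


def geometry_quality(struct: AtomStructure) -> dict:
    """Count cis amides, non-planar amides, van der Waals clashes and
    D-amino-acid centers.

    Amide checks run only on peptide-bonded residue pairs; clashes are
    counted between heavy atoms of different residues that are not within
    three bonds of each other across a peptide link.
    """
    counts = {"cis_amides": 0, "nonplanar_amides": 0, "vdw_clashes": 0,
              "d_amino_acids": 0, "skipped_checks": 0}
    bonded = list(_bonded_pairs(struct))
    bonded_set = set(bonded)
    cut = CIS_NONPLANAR_CUTOFF_DEG
    for i, j in bonded:
        a, b = struct.residues[i], struct.residues[j]
        if "CA" not in a.atoms or "CA" not in b.atoms:
            counts["skipped_checks"] += 1
            continue
        omega = np.rad2deg(dihedral(a.atoms["CA"], a.atoms["C"],
                                    b.atoms["N"], b.atoms["CA"]))
        if abs(omega) < cut:
            counts["cis_amides"] += 1
        elif abs(abs(omega) - 180.0) > cut:
            counts["nonplanar_amides"] += 1
    # chirality
    sign_l = _l_chirality_sign()
    for res in struct.residues:
        a = res.atoms
        if res.name == "GLY" or not all(x in a for x in ("N", "CA", "C", "CB")):
            if res.name != "GLY":
                counts["skipped_checks"] += 1
            continue
        v = np.dot(np.cross(a["N"] - a["CA"], a["C"] - a["CA"]),
                   a["CB"] - a["CA"])
        if np.sign(v) != sign_l:
            counts["d_amino_acids"] += 1
    # clashes
    names, elems, coords, res_idx = [], [], [], []
    for ri, res in enumerate(struct.residues):
        try:
            el_map = residue_template(res.name)["elements"]
        except ValueError:
            el_map = {}
        for nm, xyz in res.atoms.items():
            el = el_map.get(nm, nm[:1])
            if el not in VDW_RADII:
                continue
            names.append(nm)
            elems.append(el)
            coords.append(xyz)
            res_idx.append(ri)
    coords = np.asarray(coords).reshape(-1, 3)
    radii = np.array([VDW_RADII[e] for e in elems])
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(2 * max(VDW_RADII.values()), output_type="ndarray")
    for p, q in pairs:
        ri, rj = res_idx[p], res_idx[q]
        if ri == rj:
            continue
        if ri > rj:
            ri, rj, p, q = rj, ri, q, p
        if (ri, rj) in bonded_set:
            link = _cross_link_bond_distance(struct.residues[ri],
                                             struct.residues[rj])
            if (names[p], names[q]) in link:
                continue
        d = np.linalg.norm(coords[p] - coords[q])
        if d < radii[p] + radii[q] - CLASH_TOLERANCE:
            counts["vdw_clashes"] += 1
    return counts
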