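"""Deterministic toy structures for tests and toy training.

Everything is generated from torsion chains with ideal internal geometry:
framework stretches use alpha-helical (phi, psi); loop stretches draw from
coil windows of the Ramachandran map that the dihedral-based secondary
structure assignment classifies as neither helix nor strand.  Regenerating
with the same parameters is bitwise reproducible, and every ground-truth
structure passes the geometry-quality checks with zero counts.

These fixtures exercise contracts, not antibody geometry statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry as G
from .curation import assign_secondary_structure
from .task import LoopTask

# Fixed 8-letter toy alphabet (no PRO or GLY: simple templates, defined CB;
# no beta-branched residues, whose rotamers crowd an ideal helix)
TOY_ALPHABET = "ASLDETMN"

HELIX_PHI_PSI = (np.deg2rad(-62.0), np.deg2rad(-41.0))
# coil torsion windows (degrees); all are classified neither helix nor strand
# by the dihedral-region secondary-structure assignment
CAP_WINDOW = ((-90.0, -70.0), (10.0, 50.0))      # helix exit, leads away
EXTENDED_WINDOW = ((-150.0, -105.0), (30.0, 85.0))
TURN_WINDOW = ((55.0, 80.0), (5.0, 60.0))
TURN_PROB = 0.15


@dataclass
class ToyComplex:
    structure: G.AtomStructure
    loop_chain: str
    loop_start: int            # residue index into structure
    loop_end: int              # inclusive
    regions: dict = field(default_factory=dict)
    is_antibody: bool = False
    has_antigen: bool = False
    params: dict = field(default_factory=dict)

    @property
    def loop_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.structure), bool)
        mask[self.loop_start:self.loop_end + 1] = True
        return mask


def _toy_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(TOY_ALPHABET[i] for i in
                   rng.integers(0, len(TOY_ALPHABET), n))


def _coil_torsions(n: int, rng: np.random.Generator):
    phi, psi = np.empty(n), np.empty(n)
    for i in range(n):
        if i == 0:
            win = CAP_WINDOW
        elif rng.uniform() < TURN_PROB:
            win = TURN_WINDOW
        else:
            win = EXTENDED_WINDOW
        (plo, phi_hi), (slo, shi) = win
        phi[i] = np.deg2rad(rng.uniform(plo, phi_hi))
        psi[i] = np.deg2rad(rng.uniform(slo, shi))
    return phi, psi


def _build_chain(sequence: str, loop_slice: slice | None,
                 rng: np.random.Generator, chain: str = "A",
                 start_res_id: int = 1):
    """Helical chain with an optional coil stretch; returns frames+structure."""
    n = len(sequence)
    phi = np.full(n, HELIX_PHI_PSI[0])
    psi = np.full(n, HELIX_PHI_PSI[1])
    if loop_slice is not None:
        lo, hi = loop_slice.start, loop_slice.stop
        phi[lo:hi], psi[lo:hi] = _coil_torsions(hi - lo, rng)
    # common rotamer for every side chain: chi1 gauche-, the rest trans
    chi = np.tile(np.deg2rad([-60.0, 180.0, 180.0, 180.0]), (n, 1))
    return G.build_chain_from_torsions(sequence, phi, psi, chi=chi,
                                       chain=chain, start_res_id=start_res_id)


def make_toy_framework(n_res: int, seed: int) -> G.AtomStructure:
    """Ideal-geometry helical scaffold with all backbone atoms present."""
    if n_res < 8:
        raise ValueError("toy framework needs at least 8 residues")
    rng = np.random.default_rng(seed)
    _, struct = _build_chain(_toy_sequence(n_res, rng), None, rng)
    return struct


def make_toy_loop_task(loop_len: int, seed: int, n_framework: int = 16,
                       max_tries: int = 25
                       ) -> tuple[LoopTask, G.AtomStructure]:
    """A loop-rebuilding task plus its hidden ground truth.

    The full chain is helix + coil loop + helix; the returned task carries
    no coordinates for the loop residues.
    """
    if not 1 <= loop_len <= 20:
        raise ValueError("loop_len must be in [1, 20]")
    n1 = n_framework // 2
    n2 = n_framework - n1
    n = n1 + loop_len + n2
    for attempt in range(max_tries):
        rng = np.random.default_rng([seed, attempt])
        seq = _toy_sequence(n, rng)
        _, truth = _build_chain(seq, slice(n1, n1 + loop_len), rng)
        quality = G.geometry_quality(truth)
        if quality["vdw_clashes"] == 0:
            break
    else:
        raise RuntimeError("could not generate a clash-free toy loop")
    loop_mask = np.zeros(n, bool)
    loop_mask[n1:n1 + loop_len] = True
    framework = truth.copy()
    for i in np.nonzero(loop_mask)[0]:
        framework.residues[i].atoms = {}
    task = LoopTask(framework, loop_mask, ~loop_mask & np.ones(n, bool),
                    n1 - 1, n1 + loop_len)
    # geometric feasibility: the stems must be bridgeable by loop_len residues
    ca_pre, ca_post = task.stem_ca()
    if np.linalg.norm(ca_post - ca_pre) > 3.9 * (loop_len + 1):
        raise RuntimeError("unbridgeable stem separation")
    return task, truth


def make_toy_dimer(seed: int, loop_len: int, n_contacts: int,
                   max_tries: int = 40) -> ToyComplex:
    """Two-chain complex in which exactly ``n_contacts`` loop residues of
    chain A contact chain B under the Cbeta/Calpha < 8 A rule.

    Chain A is helix + extended coil loop + helix; chain B is a set of rigid
    ALA residues, one placed 7 A outward along each contacting loop
    residue's CA->CB direction, plus a distant anchor.  Chain B is a
    synthetic residue gas (no peptide bonds): the fixture exercises the
    curation contracts, not dimer physics.
    """
    if not 4 <= loop_len <= 16:
        raise ValueError("loop_len must be in [4, 16]")
    if not 0 <= n_contacts <= loop_len:
        raise ValueError("n_contacts must be in [0, loop_len]")
    n1 = n2 = 6
    n = n1 + loop_len + n2
    contact_ids = list(range(n1, n1 + n_contacts))
    loop_ids = list(range(n1, n1 + loop_len))
    for attempt in range(max_tries):
        rng = np.random.default_rng([seed, 1000 + attempt])
        seq = _toy_sequence(n, rng)
        phi = np.full(n, HELIX_PHI_PSI[0])
        psi = np.full(n, HELIX_PHI_PSI[1])
        # deterministic extended loop with a cap residue and small jitter
        phi[n1] = np.deg2rad(-80.0 + rng.uniform(-5, 5))
        psi[n1] = np.deg2rad(30.0 + rng.uniform(-5, 5))
        phi[n1 + 1:n1 + loop_len] = np.deg2rad(
            -125.0 + rng.uniform(-8, 8, loop_len - 1))
        psi[n1 + 1:n1 + loop_len] = np.deg2rad(
            60.0 + rng.uniform(-8, 8, loop_len - 1))
        chi = np.tile(np.deg2rad([-60.0, 180.0, 180.0, 180.0]), (n, 1))
        _, chain_a = G.build_chain_from_torsions(seq, phi, psi, chi=chi,
                                                 chain="A")
        if G.geometry_quality(chain_a)["vdw_clashes"]:
            continue
        result = _place_partner(chain_a, loop_ids, contact_ids)
        if result is not None:
            break
    else:
        raise RuntimeError("could not construct the requested dimer contacts")
    structure, regions = result
    quality = G.geometry_quality(structure)
    if any(quality[k] for k in
           ("cis_amides", "nonplanar_amides", "vdw_clashes", "d_amino_acids")):
        raise RuntimeError("toy dimer failed geometry checks")
    return ToyComplex(structure, "A", n1, n1 + loop_len - 1, regions=regions,
                      params={"seed": seed, "loop_len": loop_len,
                              "n_contacts": n_contacts})


def _place_partner(chain_a: G.AtomStructure, loop_ids, contact_ids):
    """One chain-B ALA residue per contacting loop residue, placed along
    that residue's CA->CB direction; verified against the extraction rule."""
    tpl = G.residue_template("ALA")["local"]
    cb_dir = tpl["CB"] / np.linalg.norm(tpl["CB"])
    a_pts = np.vstack([list(r.atoms.values()) for r in chain_a.residues])
    centroid = chain_a.coords(("CA",)).mean(axis=0)
    loop_cb = {i: _cb(chain_a, [i])[0] for i in loop_ids}
    contact_dist, exclusion_dist = 7.0, 8.4

    def rot_to(u):
        # rotation mapping the template CA->CB direction onto u
        v = np.cross(cb_dir, u)
        c = float(cb_dir @ u)
        if np.linalg.norm(v) < 1e-9:
            return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(u, u)
        k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        return np.eye(3) + k + k @ k / (1 + c)

    depths = {i: contact_dist for i in contact_ids}
    for _ in range(20):
        b_residues = []
        for j, i in enumerate(contact_ids):
            ca = chain_a[i].atoms["CA"]
            u = loop_cb[i] - ca
            u /= np.linalg.norm(u)
            t = loop_cb[i] + depths[i] * u      # partner CA position
            rot = rot_to(u)
            atoms = {k: rot @ v + t for k, v in tpl.items()}
            b_residues.append(G.Residue("ALA", "B", j + 1, atoms))
        # distant anchor so chain B exists even with zero contacts
        far = centroid + 60.0 * np.array([0.0, 0.0, 1.0])
        b_residues.append(G.Residue("ALA", "B", len(contact_ids) + 1,
                                    {k: v + far for k, v in tpl.items()}))
        b_pts = np.vstack([[r.atoms["CB"], r.atoms["CA"]] for r in b_residues])
        dist = {i: float(np.linalg.norm(b_pts - loop_cb[i], axis=1).min())
                for i in loop_ids}
        bad = False
        for i in loop_ids:
            if i in depths and dist[i] >= 7.8:
                depths[i] -= 0.2
                bad = True
            elif i not in depths and dist[i] < exclusion_dist:
                # deepen whichever partners crowd this non-contact residue
                for j in depths:
                    if np.linalg.norm(b_pts[2 * list(depths).index(j) + 1] -
                                      loop_cb[i]) < exclusion_dist:
                        depths[j] += 0.2
                bad = True
        if any(not (4.0 < d < 7.8) for d in depths.values()):
            return None
        if not bad:
            all_b = np.vstack([list(r.atoms.values()) for r in b_residues])
            if np.min(np.linalg.norm(all_b[:, None, :] - a_pts[None, :, :],
                                     axis=-1)) < 4.0:
                return None
            struct = G.AtomStructure([r.copy() for r in chain_a.residues] +
                                     b_residues)
            regions = {i: lab for i, lab in
                       enumerate(assign_secondary_structure(struct))}
            return struct, regions
    return None


def _cb(struct: G.AtomStructure, idx) -> np.ndarray:
    out = []
    for i in idx:
        res = struct[i]
        out.append(res.atoms["CA" if res.name == "GLY" else "CB"])
    return np.asarray(out).reshape(-1, 3)


def make_toy_antibody_example(seed: int = 4):
    """Toy antibody-like training example: a loop task with a distant
    'antigen' chain G and two residues annotated as another CDR loop.

    Exercises the antibody-specific augmentation rules (antigen dropping,
    flexible other-CDR marking); the antigen is a synthetic residue gas.
    """
    from .curation import TrainingExample
    from .task import LoopTask

    task, truth = make_toy_loop_task(6, seed=seed)
    ag = []
    for i in range(4):
        r = truth[0].copy()
        r.chain = "G"
        r.res_id = i + 1
        for a in r.atoms:
            r.atoms[a] = r.atoms[a] + np.array([50.0, 0.0, 0.0])
        ag.append(r)
    struct = G.AtomStructure([r.copy() for r in task.structure] + ag)
    gt = G.AtomStructure([r.copy() for r in truth] + [r.copy() for r in ag])
    loop = np.concatenate([task.loop_mask, np.zeros(4, bool)])
    fw = np.concatenate([task.framework_mask, np.zeros(4, bool)])
    regions = {i: "CDR-L1" for i in range(2, 4)}
    t2 = LoopTask(struct, loop, fw, task.stem_pre, task.stem_post,
                  antigen_chains=("G",), regions=regions)
    return TrainingExample(task=t2, ground_truth=gt, is_antibody=True,
                           has_antigen=True)


def emit_fixture_directory(out_dir, seeds=(0, 1, 2), loop_len: int = 6) -> dict:
    """Write a directory of PDB fixtures + annotation TSVs + manifest."""
    from .structure_io import write_structure

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"loop_len": loop_len, "seeds": list(seeds), "entries": []}
    for seed in seeds:
        task, truth = make_toy_loop_task(loop_len, seed)
        name = f"toy_loop_s{seed}"
        write_structure(truth, out_dir / f"{name}.pdb")
        # framework with the loop removed: direct input for sampling
        write_structure(truth.subset(~task.loop_mask),
                        out_dir / f"{name}_framework.pdb")
        ann = out_dir / f"{name}.regions.tsv"
        with ann.open("w") as f:
            f.write("chain\tres_id\tlabel\n")
            for i, r in enumerate(truth.residues):
                label = "LOOP" if task.loop_mask[i] else "FR"
                f.write(f"{r.chain}\t{r.res_id}\t{label}\n")
        stems = (f"{task.structure[task.stem_pre].chain}:"
                 f"{task.structure[task.stem_pre].res_id},"
                 f"{task.structure[task.stem_post].chain}:"
                 f"{task.structure[task.stem_post].res_id}")
        manifest["entries"].append({
            "name": name, "seed": seed, "stems": stems,
            "loop_sequence": task.loop_sequence})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
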