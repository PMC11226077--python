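"""Loop modeling task definition.

A :class:`LoopTask` carries the framework structure, the loop sequence to be
rebuilt between two stem residues, and per-residue masks.  The task never
contains coordinates for the loop residues themselves: the loop is
reconstructed from sequence alone within the given framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AtomStructure, Residue, THREE_TO_ONE, ONE_TO_THREE


@dataclass
class LoopTask:
    structure: AtomStructure          # full-length; loop residues have no atoms
    loop_mask: np.ndarray             # bool per residue
    framework_mask: np.ndarray        # bool per residue (superposition region)
    stem_pre: int                     # index of the stem before the loop
    stem_post: int                    # index of the stem after the loop
    antigen_chains: tuple[str, ...] = ()
    regions: dict = field(default_factory=dict)   # residue index -> region label

    def __post_init__(self):
        self.loop_mask = np.asarray(self.loop_mask, bool)
        self.framework_mask = np.asarray(self.framework_mask, bool)
        self.validate()

    # -- derived views ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.structure)

    @property
    def sequence(self) -> str:
        return self.structure.sequence()

    @property
    def loop_sequence(self) -> str:
        return "".join(np.array(list(self.sequence))[self.loop_mask])

    @property
    def chain_ids(self) -> list[str]:
        return [r.chain for r in self.structure]

    def chain_index(self) -> np.ndarray:
        chains = self.structure.chains()
        return np.array([chains.index(r.chain) for r in self.structure])

    def validate(self) -> None:
        n = len(self.structure)
        if self.loop_mask.shape != (n,) or self.framework_mask.shape != (n,):
            raise ValueError("mask length does not match structure length")
        if self.loop_mask.sum() < 1:
            raise ValueError("loop must contain at least one residue")
        if np.any(self.loop_mask & self.framework_mask):
            raise ValueError("loop and framework masks overlap")
        for stem in (self.stem_pre, self.stem_post):
            res = self.structure[stem]
            if "CA" not in res.atoms:
                raise ValueError(
                    f"stem residue {res.chain}{res.res_id} has no CA atom")
            if self.loop_mask[stem]:
                raise ValueError("stem residues cannot be loop residues")
        for i in np.nonzero(self.loop_mask)[0]:
            if self.structure[i].atoms:
                raise ValueError(
                    "task structure must not contain loop coordinates")

    def stem_ca(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.structure[self.stem_pre].atoms["CA"].copy(),
                self.structure[self.stem_post].atoms["CA"].copy())

    def drop_chains(self, chains) -> "LoopTask":
        keep = np.array([r.chain not in chains for r in self.structure])
        idx = np.nonzero(keep)[0]
        remap = {int(old): new for new, old in enumerate(idx)}
        return LoopTask(self.structure.subset(keep),
                        self.loop_mask[keep], self.framework_mask[keep],
                        remap[self.stem_pre], remap[self.stem_post],
                        tuple(c for c in self.antigen_chains if c not in chains),
                        {remap[i]: v for i, v in self.regions.items()
                         if i in remap})


def make_loop_task(framework: AtomStructure, loop_sequence: str,
                   stem_pre: tuple[str, int], stem_post: tuple[str, int],
                   antigen_chains=(), regions=None,
                   framework_mask=None) -> LoopTask:
    """Insert a loop of ``loop_sequence`` between two stem residues of a
    framework structure (given as (chain, author residue number))."""
    if not loop_sequence:
        raise ValueError("loop sequence must be non-empty")
    for aa in loop_sequence:
        if aa not in ONE_TO_THREE:
            raise ValueError(f"non-standard loop residue {aa!r}")

    def find(chain, res_id):
        for i, r in enumerate(framework.residues):
            if r.chain == chain and r.res_id == res_id:
                return i
        raise ValueError(f"stem residue {chain}{res_id} not found in framework")

    i_pre = find(*stem_pre)
    i_post = find(*stem_post)
    if i_post != i_pre + 1:
        raise ValueError("stem residues must be adjacent in the framework")
    residues = [r.copy() for r in framework.residues[:i_pre + 1]]
    chain = framework.residues[i_pre].chain
    base_id = framework.residues[i_pre].res_id
    for j, aa in enumerate(loop_sequence):
        residues.append(Residue(ONE_TO_THREE[aa], chain, base_id + 1 + j))
    residues += [r.copy() for r in framework.residues[i_post:]]
    struct = AtomStructure(residues)
    n = len(struct)
    loop_mask = np.zeros(n, bool)
    loop_mask[i_pre + 1:i_pre + 1 + len(loop_sequence)] = True
    if framework_mask is None:
        framework_mask = np.array(
            [(not loop_mask[i]) and r.chain == chain and
             r.chain not in antigen_chains
             for i, r in enumerate(struct.residues)])
    return LoopTask(struct, loop_mask, np.asarray(framework_mask, bool),
                    i_pre, i_pre + 1 + len(loop_sequence),
                    tuple(antigen_chains), regions or {})
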