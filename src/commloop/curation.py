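"""Training-set curation: interface-loop extraction, redundancy filters,
cropping and augmentation.

Interface loops are contiguous non-helix, non-strand segments of 5-15
standard residues with at least five residues contacting the partner chain
at Cbeta (Calpha for GLY) distances below 8 A.  Antibody sets are clustered
at 70% loop sequence identity; general interface sets are deduplicated at
40% protein / 70% loop identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import AtomStructure, THREE_TO_ONE, measure_torsions
from .task import LoopTask

log = logging.getLogger("commloop.curation")

CONTACT_CUTOFF = 8.0        # Angstrom, Cbeta (Calpha for GLY)
MIN_LOOP_LEN, MAX_LOOP_LEN = 5, 15
MIN_CONTACTS = 5
RESOLUTION_CUTOFF = 3.0     # Angstrom, curation mode

# phi/psi windows (degrees) for the dihedral-region secondary structure
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-170.0, -60.0)
STRAND_PSI_MIN = 90.0


@dataclass
class InterfaceLoopRecord:
    source_id: str
    chain: str
    start: int                  # residue index within the chain (0-based)
    end: int                    # inclusive
    loop_sequence: str
    partner_chain: str
    n_contacts: int
    resolution: float | None = None
    full_sequence: str = ""

    def validate(self) -> None:
        n = self.end - self.start + 1
        if not (MIN_LOOP_LEN <= n <= MAX_LOOP_LEN):
            raise ValueError(f"loop length {n} outside [{MIN_LOOP_LEN}, "
                             f"{MAX_LOOP_LEN}]")
        if len(self.loop_sequence) != n:
            raise ValueError("loop sequence length mismatch")
        if self.n_contacts < MIN_CONTACTS:
            raise ValueError(f"contact count {self.n_contacts} below "
                             f"{MIN_CONTACTS}")
        if any(aa == "X" for aa in self.loop_sequence):
            raise ValueError("non-standard residue in loop")


@dataclass
class TrainingExample:
    task: LoopTask
    ground_truth: AtomStructure       # full-length, covers all loop residues
    cluster_id: int = -1
    is_antibody: bool = False
    has_antigen: bool = False
    flexible_mask: np.ndarray | None = None

    def __post_init__(self):
        if len(self.ground_truth) != len(self.task):
            raise ValueError("ground truth length differs from task")
        for i in np.nonzero(self.task.loop_mask)[0]:
            res = self.ground_truth[i]
            if not res.has_backbone:
                raise ValueError(
                    f"ground truth missing backbone at loop residue "
                    f"{res.chain}{res.res_id}")


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def assign_secondary_structure(struct: AtomStructure,
                               supplied: dict | None = None) -> list[str]:
    """Per-residue 'H'/'E'/'C' labels from backbone dihedral regions.

    A residue with an undefined phi or psi (chain terminus) matches a
    category if its defined angle lies in that category's window.  An
    external per-residue assignment can be supplied instead (residue index
    -> label)."""
    n = len(struct)
    if supplied is not None:
        return [supplied.get(i, "C") for i in range(n)]
    ts = measure_torsions(struct)
    labels = []
    for i in range(n):
        phi = np.rad2deg(ts.phi[i]) if ts.phi_mask[i] else None
        psi = np.rad2deg(ts.psi[i]) if ts.psi_mask[i] else None

        def in_win(val, lo, hi):
            return val is None or lo <= val <= hi

        if in_win(phi, *HELIX_PHI) and in_win(psi, *HELIX_PSI):
            labels.append("H")
        elif in_win(phi, *STRAND_PHI) and (psi is None or psi >= STRAND_PSI_MIN
                                           or psi <= -150.0):
            labels.append("E")
        else:
            labels.append("C")
    return labels


def _contact_coords(struct: AtomStructure, idx) -> np.ndarray:
    """Cbeta (Calpha for GLY) coordinates for the given residue indices."""
    out = []
    for i in idx:
        res = struct[i]
        atom = "CA" if res.name == "GLY" else "CB"
        if atom not in res.atoms:
            atom = "CA"
        if atom not in res.atoms:
            continue
        out.append(res.atoms[atom])
    return np.asarray(out).reshape(-1, 3)


def extract_interface_loops(complex_struct: AtomStructure,
                            ss_assign: dict | None = None,
                            source_id: str = "",
                            resolution: float | None = None
                            ) -> list[InterfaceLoopRecord]:
    """Find interface loops in a multi-chain complex.

    Returns maximal contiguous coil segments of 5-15 standard residues with
    at least 5 residues in Cbeta/Calpha contact (< 8 A) with another chain.
    """
    chains = complex_struct.chains()
    if len(chains) < 2:
        raise ValueError("interface extraction requires at least two chains")
    labels = assign_secondary_structure(complex_struct, ss_assign)
    chain_of = np.array([r.chain for r in complex_struct])
    records: list[InterfaceLoopRecord] = []
    for chain in chains:
        idx = np.nonzero(chain_of == chain)[0]
        partners = {c: np.nonzero(chain_of == c)[0] for c in chains if c != chain}
        # Cbeta plus Calpha points of each partner chain
        partner_pts = {}
        for c, p in partners.items():
            cb = _contact_coords(complex_struct, p)
            ca = [complex_struct[i].atoms["CA"] for i in p
                  if "CA" in complex_struct[i].atoms]
            partner_pts[c] = np.vstack([cb, np.asarray(ca).reshape(-1, 3)])
        # segment the chain at coil stretches and chain breaks
        segments: list[list[int]] = []
        cur: list[int] = []
        prev = None
        for i in idx:
            breaks = (prev is not None and
                      ("C" not in complex_struct[prev].atoms or
                       "N" not in complex_struct[i].atoms or
                       np.linalg.norm(complex_struct[prev].atoms["C"] -
                                      complex_struct[i].atoms["N"]) > 2.0))
            if labels[i] == "C" and not breaks and cur:
                cur.append(i)
            elif labels[i] == "C":
                if cur:
                    segments.append(cur)
                cur = [i]
            else:
                if cur:
                    segments.append(cur)
                cur = []
            prev = i
        if cur:
            segments.append(cur)
        for seg in segments:
            if not (MIN_LOOP_LEN <= len(seg) <= MAX_LOOP_LEN):
                continue
            seq = "".join(THREE_TO_ONE.get(complex_struct[i].name, "X")
                          for i in seg)
            if "X" in seq:
                continue
            best_partner, best_count = None, 0
            for c, pts in partner_pts.items():
                if not len(pts):
                    continue
                count = 0
                for i in seg:
                    own = _contact_coords(complex_struct, [i])
                    if not len(own):
                        continue
                    d = np.linalg.norm(pts - own[0], axis=1).min()
                    if d < CONTACT_CUTOFF:
                        count += 1
                if count > best_count:
                    best_partner, best_count = c, count
            if best_count >= MIN_CONTACTS:
                chain_start = int(np.nonzero(idx == seg[0])[0][0])
                rec = InterfaceLoopRecord(
                    source_id=source_id, chain=chain,
                    start=chain_start, end=chain_start + len(seg) - 1,
                    loop_sequence=seq, partner_chain=best_partner,
                    n_contacts=best_count, resolution=resolution,
                    full_sequence="".join(
                        THREE_TO_ONE.get(complex_struct[i].name, "X")
                        for i in idx))
                rec.validate()
                records.append(rec)
    return records


# ---------------------------------------------------------------------------
# sequence identity and clustering
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Alignment scoring: match +1, mismatch 0, gap -1 (alignment only; the
    identity itself is count-based)."""
    if not a or not b:
        return 0.0
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return matches / len(sa)


def cluster_by_identity(sequences: list[str], cutoff: float) -> np.ndarray:
    """Single-linkage clustering: any pair with identity >= cutoff shares a
    cluster.  Returns an integer cluster id per sequence."""
    if not sequences:
        raise ValueError("empty sequence list")
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    n = len(sequences)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sequence_identity(sequences[i], sequences[j]) >= cutoff:
                parent[find(i)] = find(j)
    roots = {}
    out = np.empty(n, int)
    for i in range(n):
        r = find(i)
        out[i] = roots.setdefault(r, len(roots))
    return out


def exclude_clusters_with(assignments: np.ndarray, flagged) -> np.ndarray:
    """Boolean keep-mask dropping every cluster containing a flagged member."""
    assignments = np.asarray(assignments)
    flagged = np.asarray(flagged, bool)
    bad = set(assignments[flagged].tolist())
    return np.array([a not in bad for a in assignments])


def filter_nonredundant(records: list[InterfaceLoopRecord],
                        prot_id_cutoff: float = 0.4,
                        loop_id_cutoff: float = 0.7
                        ) -> list[InterfaceLoopRecord]:
    """Greedy longest-first selection so that no retained pair exceeds the
    protein or the loop identity cutoff."""
    order = sorted(range(len(records)),
                   key=lambda i: (-len(records[i].full_sequence), i))
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            if (sequence_identity(records[i].full_sequence,
                                  records[j].full_sequence) > prot_id_cutoff or
                    sequence_identity(records[i].loop_sequence,
                                      records[j].loop_sequence) > loop_id_cutoff):
                ok = False
                break
        if ok:
            kept.append(i)
    return [records[i] for i in sorted(kept)]


# ---------------------------------------------------------------------------
# cropping and augmentation
# ---------------------------------------------------------------------------

def crop_residues(example: TrainingExample, n: int,
                  rng: np.random.Generator,
                  center_perturb: float = 2.0) -> TrainingExample:
    """Keep the ``n`` residues nearest (by CA) to the perturbed midpoint of
    the two stem residues; loop and stem residues are always retained."""
    task = example.task
    if n < int(task.loop_mask.sum()) + 2:
        raise ValueError("crop size must cover the loop plus both stems")
    total = len(task)
    ca_pre, ca_post = task.stem_ca()
    center = 0.5 * (ca_pre + ca_post)
    vec = rng.normal(size=3)
    vec *= (rng.uniform() ** (1 / 3)) * center_perturb / np.linalg.norm(vec)
    center = center + vec
    if total <= n:
        log.info("structure of %d residues not cropped (crop size %d)",
                 total, n)
        return example
    ca = example.ground_truth.coords(("CA",))
    d = np.linalg.norm(ca - center, axis=1)
    forced = task.loop_mask.copy()
    forced[task.stem_pre] = forced[task.stem_post] = True
    d[forced] = -1.0
    keep_idx = np.sort(np.argsort(d, kind="stable")[:n])
    keep = np.zeros(total, bool)
    keep[keep_idx] = True
    remap = {int(o): k for k, o in enumerate(keep_idx)}
    new_task = LoopTask(task.structure.subset(keep), task.loop_mask[keep],
                        task.framework_mask[keep], remap[task.stem_pre],
                        remap[task.stem_post], task.antigen_chains,
                        {remap[i]: v for i, v in task.regions.items()
                         if i in remap})
    flex = (example.flexible_mask[keep]
            if example.flexible_mask is not None else None)
    return replace(example, task=new_task,
                   ground_truth=example.ground_truth.subset(keep),
                   flexible_mask=flex)


@dataclass
class AugmentationInfo:
    antigen_removed: bool = False
    other_cdrs_included: bool = False


def augment(example: TrainingExample, rng: np.random.Generator,
            p_drop_antigen: float = 0.7,
            p_include_other_cdrs: float = 0.5
            ) -> tuple[TrainingExample, AugmentationInfo]:
    """Antibody augmentation: drop the antigen with probability 0.7 and mark
    non-H3 CDR loops flexible with probability 0.5.  Non-antibody examples
    pass through unchanged."""
    info = AugmentationInfo()
    if not example.is_antibody:
        return example, info
    out = example
    if example.has_antigen and example.task.antigen_chains:
        if rng.uniform() < p_drop_antigen:
            info.antigen_removed = True
            chains = example.task.antigen_chains
            keep = np.array([r.chain not in chains
                             for r in example.task.structure])
            new_task = example.task.drop_chains(chains)
            flex = (example.flexible_mask[keep]
                    if example.flexible_mask is not None else None)
            out = replace(example, task=new_task,
                          ground_truth=example.ground_truth.subset(keep),
                          has_antigen=False, flexible_mask=flex)
    if rng.uniform() < p_include_other_cdrs:
        info.other_cdrs_included = True
        flex = np.zeros(len(out.task), bool)
        for i, label in out.task.regions.items():
            if label.startswith("CDR") and not out.task.loop_mask[i]:
                flex[i] = True
        out = replace(out, flexible_mask=flex)
    return out, info
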