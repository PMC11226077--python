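# Methods

## Model

A community of N loop candidates is refined jointly.  Member n at cycle k
is described by single features S_n ∈ R^{L×c_s} (c_s = 128), pair features
Z_n ∈ R^{L×L×c_z} (c_z = 96), and structure features T_n — one rigid frame
(R, t) per residue, built from N/CA/C by Gram–Schmidt with CA at the
origin and CA→C along +x.  Eight cycles share one set of weights; each
cycle runs a single-feature IPA update, cross-over attention across the
member axis, a pair update with two triangular blocks, and four IPA layers
that compose small frame updates (quaternion + translation) onto T.

Key properties, enforced by construction and checked in the test suite:

* IPA consumes points only in local frames, so single-feature updates are
  invariant and frame updates equivariant under global rigid motions of
  the input (tolerance 1e-4 over a full forward pass in float64).
* Cross-over attends over members independently per residue; its weights
  sum to one over the member axis, it reduces exactly to `o = v` at N = 1,
  and the whole cycle stack is equivariant under permutations of the
  member axis.
* All parameters are shared across cycles (the four structure-update IPA
  layers are distinct from each other but reused every cycle), so the
  parameter count is independent of the cycle count.

### Architecture sizes

Where the architecture's description leaves per-layer sizes open they
follow AlphaFold-2 conventions scaled to these channel widths: IPA with
8 heads × 16 channels, 4 query/key points and 8 value points; cross-over
with 8 heads of c_s/8 channels, scaled by 1/√c_head (pre-layer-norm, with
a residual connection); triangular multiplicative updates with 128 hidden
channels; triangular attention with 4 heads × 32 channels; pair
transitions with expansion factor 2; a 64-bin distogram spanning
2–22 Å with open outer bins; a 50-bin pLDDT head; a torsion head with two
residual blocks emitting (sin, cos) pairs for (ω, φ, ψ, χ1–χ4).  The
input projection takes a 2560-wide sequence embedding (the width of the
largest public protein-language-model embeddings; the deterministic
fallback encoding pads one-hot identity + sinusoidal position features to
the same width).  With these choices the full model holds 2.72 M
trainable parameters.

### Initialization

Loop residue frames start with identity rotations, translations evenly
spaced on the stem-CA segment at fractions i/(L+1), then receive per-member
perturbations: translation uniform in a 1.0 Å ball and rotation about a
uniform axis with angle uniform in [0°, 15°].  Framework residues keep
their structural frames with weak perturbations (0.1 Å / 2°), so the model
learns to tolerate imperfect frameworks.  A single integer seed fans out to
per-member substreams, making initialization a deterministic function of
(seed, member index, N).  Initial pair features combine a one-hot distance
bin of the initial inter-frame distances, the row/column single features,
same-chain and loop-membership flags, and a clipped relative-position
encoding (±32, within-chain).

### Differentiation

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine over numpy arrays (`commloop.autodiff`).
Design notes: rotations are detached inside IPA point transforms (the
standard stop-gradient that stabilizes frame-based attention), gradients
flow through all cycles, and the cyclic garbage collector is suspended
while a graph is alive (the tape is acyclic; reference counting reclaims
it, and generation-2 GC scans would otherwise dominate runtime).

## Losses

Structural terms per member: clamped FAPE (clamp 10 Å, length scale 10 Å)
over backbone atoms in all residue frames; distogram cross-entropy against
the true Cβ (Cα for GLY) distance bin, read from each member's final pair
features; torsion loss as unit-circle L2 on normalized (sin, cos) with the
π-rotated alternative for the symmetric ends of ASP/GLU/PHE/TYR plus an
angle-norm regularizer (weight 0.02); and a differentiable loop RMSD.  The
loop RMSD loss mirrors evaluation exactly: the predicted loop is scored
inside the *input* framework (the superposition onto the reference uses the
fixed input framework CAs), because final structures are realized by
re-inserting the predicted loop into that framework.  The transform from
the Kabsch superposition is treated as a constant (gradients flow through
the transformed loop atoms, not the superposition operator).  Auxiliary
terms: pLDDT cross-entropy against the binned true Cα LDDT (radius 15 Å,
thresholds 0.5/1/2/4 Å, 50 bins; the LDDT target is computed without
gradients) and a violation loss with flat-bottom penalties (mean ± 12 σ)
on backbone C–N bonds and CA–C–N / C–N–CA angles (via cosines) plus a
linear clash penalty for non-bonded backbone atoms closer than the radius
sum minus 1.5 Å.  The community loss is
`min_i L_structure_i + mean_i L_aux_i` with weights
(1.0, 1.0, 0.3, 0.5) and (0.01, 1.0); the minimum is taken over the
weighted per-member sums.  The distogram loss reads the final cycle's pair
features (per-cycle supervision was the alternative; the final cycle is
the one whose features feed the heads).

## Geometry

Residue templates come from the chemical component dictionary bundled with
biotite, re-expressed once in the backbone frame with N/CA/C snapped to
ideal internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, N–CA–C 111.2°,
etc.).  Full atoms are built by placing the carbonyl O from ψ and rotating
template side chains to the requested χ angles; the proline ring is kept
rigid (its χ angles are not free parameters, so requested values are
ignored and the template ring geometry is preserved).  Chain construction
from (φ, ψ, ω) uses standard internal-coordinate placement, and torsion
measurement inverts it exactly (round-trip error < 1e-6 rad).

Quality counts: a peptide bond exists where C–N < 2.0 Å; ω within 30° of 0°
is a cis amide, more than 30° from both 0° and 180° is non-planar; a clash
is a heavy-atom pair from different residues, more than 3 bonds apart
across the peptide link, closer than the van-der-Waals radius sum minus
0.4 Å (radii C 1.70, N 1.55, O 1.52, S 1.80 Å); D-amino-acid centers are
flagged by the sign of the Cα improper (N–CA–C–CB) against the L
reference.  These thresholds are this package's choices — the quality
categories are standard but no canonical threshold set exists.

## Curation

Interface loops are maximal contiguous non-helix/non-strand segments of
5–15 standard residues with ≥ 5 residues whose Cβ (Cα for GLY) lies
within 8 Å of any partner-chain Cβ/Cα.  Secondary structure is assigned
from φ/ψ windows (helix: φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°]; strand:
φ ∈ [−170°, −60°] and ψ ≥ 90° or ≤ −150°; else coil), with terminal
residues matching a category if their one defined angle does; an external
per-residue assignment can be supplied instead.  Sequence identity is
matches / alignment columns under global alignment (match +1, mismatch 0,
gap −1); clustering is single-linkage at the identity cutoff, and the
nonredundancy filter greedily keeps longest-first records so that no
retained pair exceeds 40 % protein or 70 % loop identity.  Cropping keeps
the n residues nearest the (perturbed, ≤ 2 Å) stem midpoint, always
retaining loop and stems.  Antibody augmentation drops the antigen chains
with probability 0.7 and marks non-H3 CDR residues as flexible with
probability 0.5; "included" CDRs are re-initialized as flexible regions
rather than fixed context (the other reading of the rule), recorded in the
returned example.

## Synthetic fixtures

Toy systems are torsion chains with ideal geometry: α-helical frameworks
(φ, ψ = −62°, −41°) and coil loops drawn from Ramachandran windows that the
secondary-structure assignment classifies as coil — a helix-exit cap
window (φ ∈ [−90°, −70°], ψ ∈ [10°, 50°]) followed by extended
(φ ∈ [−150°, −105°], ψ ∈ [30°, 85°]) with occasional left-handed turns
(probability 0.15).  Chains are resampled until the geometry-quality
counts are all zero.  Sequences come from a fixed 8-letter alphabet
(A S L D E T M N — no GLY/PRO for template simplicity, no β-branched
residues, whose fixed rotamers crowd an ideal helix), side chains use one
canonical rotamer (χ1 −60°, others trans).  Building the ground-truth
chain directly from torsions (framework + loop in one pass) replaces a
loop-closure step: the "framework" is whatever flanks the coil stretch, so
the dihedral-based filters see exactly the constructed boundary.  The toy
dimer places one rigid ALA partner residue 7 Å outward along each
contacting loop residue's CA→CB direction and verifies the exact contact
set under the extraction rule; chain B is a residue gas (no peptide
bonds), which the quality checks and the extractor treat correctly.  These
fixtures exercise contracts — they do not imitate antibody geometry
statistics, so passing tests demonstrate correctness of the machinery, not
real-data accuracy.

## Toy training

The desk-scale configuration uses c_s = 32, c_z = 16, N = 4 members,
2 cycles, 16 distogram bins and 10 pLDDT bins on ~22-residue tasks; full
channel widths and 8 cycles are reserved for real training runs.  Each
step re-initializes the community with fresh random perturbations (the
model must fold from arbitrary starts), runs the full cycle stack, and
applies Adam (lr 3e-3, warmup 50 steps then cosine decay, gradient-norm
clip 10).  Training tracks the best-member loop RMSD on a held-fixed
evaluation seed every 25 steps, keeps the best parameters seen, and stops
early at the target RMSD.  A non-finite loss aborts and restores the last
good parameters.

## Evaluation

Loop RMSD: backbone N/CA/C over loop residues after superposing framework
CAs.  "Best sampled" minimizes RMSD over members; "top scored" maximizes
mean loop pLDDT; success at a cutoff is strict (`< 2.0 Å` by default; the
boundary convention is configurable).  Target summaries average trials per
target (5 independent seeds by default), then take cross-target medians.
The community-size scan spends an equal total structure budget per size
(budget//N runs of size N) and reports the per-task best over the budget,
optionally averaged over independent trials; N = 1 is the no-communication
baseline.  Following the original per-N training design, the scan accepts
one model per community size: a model trained with N = 1 never sees
cross-over, so the comparison probes the architecture, not just inference
batching.  The desk-scale trend harness trains N = 1 and N = 8 models on
six 8-residue-loop fixtures (450 steps each) and compares them on ten
unseen fixtures at a budget of eight structures, three trials per task.
Loop length 8 (on a 12-residue framework) was chosen because the
equal-budget baseline is already near its floor on shorter toy loops,
leaving no headroom for sampling strategy to matter; the reported effect
at this scale is small and should be read as a direction check, not an
effect-size estimate.  Trajectory maps embed the
pairwise loop-RMSD matrix (zero diagonal, symmetric) with t-SNE
(precomputed metric, perplexity min(30, n/4), seed recorded).

## Limitations

* No trained weights are distributed; the desk-scale training demonstrates
  that the architecture and losses optimize correctly, not real-world
  accuracy.
* The ESM-2 sequence-embedding hook is a plug-in interface; without it the
  deterministic fallback encoding carries far less information than a
  language model.
* Violation terms cover backbone geometry only; side-chain clashes are
  handled by the (non-differentiable) quality counts.
* The proline ring is rigid in atom building, and χ angles beyond a
  residue's degrees of freedom are ignored.
* The dihedral-window secondary-structure assignment is deliberately
  simple; real curation should supply an external assignment.
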