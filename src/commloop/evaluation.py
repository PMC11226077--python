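"""Sampling metrics, ranking, community-size scans and trajectory maps.

The headline quantities follow the loop-modeling conventions: loop RMSD is
the backbone (N, CA, C) RMSD over loop residues after framework-CA
superposition; the "best sampled" member minimizes RMSD, the "top scored"
member maximizes mean loop pLDDT; a sampling run succeeds at a cutoff when
its best RMSD is below it (strict <, 2 A by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AtomStructure, loop_rmsd
from .model import CommunityModel
from .task import LoopTask

log = logging.getLogger("commloop.eval")

DEFAULT_RMSD_CUTOFF = 2.0


@dataclass
class SampleResult:
    structures: list[AtomStructure]
    plddt_per_residue: np.ndarray          # (N, L)
    member_scores: np.ndarray              # (N,) mean loop pLDDT
    rmsds: np.ndarray | None = None        # (N,) when a reference was given
    trajectory: list = field(default_factory=list, repr=False)

    @property
    def top_scored(self) -> int:
        return int(np.argmax(self.member_scores))

    @property
    def best_sampled(self) -> int | None:
        if self.rmsds is None:
            return None
        return int(np.argmin(self.rmsds))


def sample_loops(model: CommunityModel, task: LoopTask, seed: int,
                 n_members: int | None = None,
                 reference: AtomStructure | None = None,
                 record_trajectory: bool = False) -> SampleResult:
    """One community inference: N final structures with pLDDT scores."""
    state, traj = model.run_cycles(task, seed=seed, n_members=n_members,
                                   record_trajectory=record_trajectory)
    structures = model.realize_structures(task, state)
    per_res, member = model.predict_plddt(state.S, task.loop_mask)
    rmsds = None
    if reference is not None:
        rmsds = np.array([loop_rmsd(s, reference, task.loop_mask,
                                    task.framework_mask)
                          for s in structures])
    return SampleResult(structures, per_res, member, rmsds, traj)


def rank_by_plddt(result: SampleResult) -> np.ndarray:
    """Member indices in descending mean-pLDDT order (stable ties)."""
    scores = np.asarray(result.member_scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite pLDDT scores")
    return np.argsort(-scores, kind="stable")


def success_rate(rmsds, cutoff: float = DEFAULT_RMSD_CUTOFF) -> float:
    """Fraction of values strictly below the cutoff."""
    rmsds = np.asarray(rmsds, float)
    if rmsds.size == 0:
        raise ValueError("empty RMSD list")
    return float((rmsds < cutoff).mean())


def summarize_targets(per_target: dict[str, list[dict]],
                      cutoff: float = DEFAULT_RMSD_CUTOFF) -> pd.DataFrame:
    """Cross-target summary of multi-trial sampling results.

    ``per_target`` maps a target name to a list of per-trial dicts with
    keys ``best_rmsd`` and ``top_rmsd``.  Per target, trials are averaged;
    the summary row reports cross-target medians and success rates.
    """
    if not per_target:
        raise ValueError("need at least one target")
    rows = []
    for name in sorted(per_target):
        trials = per_target[name]
        best = np.mean([t["best_rmsd"] for t in trials])
        top = np.mean([t["top_rmsd"] for t in trials])
        rows.append({"target": name, "n_trials": len(trials),
                     "best_rmsd": best, "top_rmsd": top})
    df = pd.DataFrame(rows)
    summary = {
        "median_best_rmsd": float(df["best_rmsd"].median()),
        "median_top_rmsd": float(df["top_rmsd"].median()),
        "success_best": success_rate(df["best_rmsd"].to_numpy(), cutoff),
        "success_top": success_rate(df["top_rmsd"].to_numpy(), cutoff),
    }
    df.attrs["summary"] = summary
    return df


def community_size_scan(model: CommunityModel | dict,
                        tasks: list[tuple[LoopTask, AtomStructure]],
                        sizes=(1, 2, 4, 8), budget: int = 8,
                        seed: int = 0, n_trials: int = 1,
                        cutoff: float = DEFAULT_RMSD_CUTOFF) -> pd.DataFrame:
    """Equal-budget comparison of community sizes.

    For each size N the budget of ``budget`` total structures is spent as
    ``budget // N`` independent runs of size N; per task the best RMSD over
    the whole budget is recorded (averaged over ``n_trials`` independent
    repeats).  N = 1 is the no-communication baseline.  ``model`` may be a
    single model or a dict mapping each size to the model trained with that
    community size, mirroring the per-N training design of the original
    comparison.
    """
    models = model if isinstance(model, dict) else {s: model for s in sizes}
    rows = []
    for size in sorted(sizes):
        runs = max(budget // size, 1)
        best_rmsds = []
        for t_idx, (task, truth) in enumerate(tasks):
            trial_bests = []
            for trial in range(n_trials):
                pool = []
                for r in range(runs):
                    run_seed = int(np.random.default_rng(
                        [seed, size, t_idx, trial, r]).integers(2 ** 31))
                    res = sample_loops(models[size], task, seed=run_seed,
                                       n_members=size, reference=truth)
                    pool.extend(res.rmsds.tolist())
                trial_bests.append(min(pool))
            best_rmsds.append(float(np.mean(trial_bests)))
        best_rmsds = np.asarray(best_rmsds)
        rows.append({"N": size, "runs": runs,
                     "total_structures": runs * size,
                     "median_best_rmsd": float(np.median(best_rmsds)),
                     "mean_best_rmsd": float(best_rmsds.mean()),
                     "success_rate": success_rate(best_rmsds, cutoff)})
    return pd.DataFrame(rows)


def pairwise_loop_rmsd_matrix(structures: list[AtomStructure],
                              loop_mask, framework_mask) -> np.ndarray:
    n = len(structures)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = loop_rmsd(structures[i], structures[j], loop_mask,
                          framework_mask)
            mat[i, j] = mat[j, i] = d
    return mat


def trajectory_embedding(structures: list[AtomStructure], loop_mask,
                         framework_mask, seed: int = 0,
                         perplexity: float | None = None) -> np.ndarray:
    """2-D t-SNE embedding of the pairwise loop-RMSD matrix."""
    if len(structures) < 3:
        raise ValueError("need at least 3 structures to embed")
    from sklearn.manifold import TSNE

    mat = pairwise_loop_rmsd_matrix(structures, loop_mask, framework_mask)
    if perplexity is None:
        perplexity = min(30.0, max(len(structures) / 4.0, 2.0))
    perplexity = min(perplexity, (len(structures) - 1) / 3.0)
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                random_state=seed, perplexity=perplexity)
    return tsne.fit_transform(mat)


def plot_trajectory(coords: np.ndarray, cycle_index: np.ndarray, path,
                    marked: dict[str, int] | None = None,
                    seed: int | None = None) -> None:
    """Scatter of embedded structures colored by cycle; special structures
    (reference / best / top) marked by name."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=cycle_index, cmap="viridis",
                    s=18, alpha=0.85)
    fig.colorbar(sc, ax=ax, label="cycle")
    for name, idx in (marked or {}).items():
        ax.scatter(*coords[idx], marker="*", s=240, edgecolors="k",
                   label=name)
    if marked:
        ax.legend()
    title = "loop sampling trajectory"
    if seed is not None:
        title += f" (t-SNE seed {seed})"
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
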