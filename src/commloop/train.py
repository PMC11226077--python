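"""Toy-scale training of the community structure module.

Each step re-initializes the community with fresh random loop placements
(the model must fold from arbitrary starts, not memorize one), runs the
full cycle stack, and optimizes the community loss
L = min_i L_structure_i + mean_i L_aux_i with Adam.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import graph_context
from .curation import TrainingExample
from .geometry import loop_rmsd
from .losses import LossBreakdown, community_loss
from .model import CommunityModel
from .nn import Adam

log = logging.getLogger("commloop.train")


@dataclass
class TrainResult:
    steps_run: int
    loss_history: list[float]
    best_rmsd_history: list[tuple[int, float]]
    final_best_rmsd: float | None
    aborted_nonfinite: bool = False
    checkpoint_path: str | None = None
    breakdowns: list[LossBreakdown] = field(default_factory=list, repr=False)


def evaluate_best_rmsd(model: CommunityModel, example: TrainingExample,
                       seed: int, n_members: int | None = None) -> float:
    """Best (minimum over members) loop RMSD of a fresh sampling run."""
    state, _ = model.run_cycles(example.task, seed=seed,
                                n_members=n_members, record_trajectory=False)
    structs = model.realize_structures(example.task, state)
    return min(loop_rmsd(s, example.ground_truth, example.task.loop_mask,
                         example.task.framework_mask) for s in structs)


def cosine_lr(step: int, n_steps: int, lr: float, warmup: int = 50,
              floor: float = 0.05) -> float:
    """Linear warmup followed by cosine decay to ``floor * lr``."""
    if step < warmup:
        return lr * (step + 1) / warmup
    frac = (step - warmup) / max(n_steps - warmup, 1)
    return lr * (floor + (1 - floor) * 0.5 * (1 + np.cos(np.pi * frac)))


def train_toy(model: CommunityModel, examples: list[TrainingExample],
              n_steps: int = 2000, lr: float = 3e-3, seed: int = 0,
              n_members: int | None = None,
              target_rmsd: float | None = None, eval_every: int = 25,
              log_path=None, checkpoint_path=None,
              checkpoint_every: int = 100,
              keep_best: bool = True) -> TrainResult:
    """Optimize all parameters on the given examples.

    The learning rate follows warmup + cosine decay.  Training stops early
    once the best-member loop RMSD on the first example drops below
    ``target_rmsd`` (checked every ``eval_every`` steps); with
    ``keep_best`` the parameters from the best evaluation point are
    restored at the end.  A non-finite loss aborts, restoring the last
    good checkpoint.
    """
    if not examples:
        raise ValueError("need at least one training example")
    opt = Adam(model.store, lr=lr)
    n = n_members or model.config.community_size
    history: list[float] = []
    rmsd_history: list[tuple[int, float]] = []
    breakdowns: list[LossBreakdown] = []
    last_good = model.store.state_dict()
    aborted = False
    eval_seed = int(np.random.default_rng([seed, 987]).integers(2 ** 31))
    log_file = open(log_path, "w") if log_path else None
    t_start = time.time()
    steps_done = 0
    best_eval = np.inf
    best_params = None
    try:
        for step in range(n_steps):
            ex = examples[step % len(examples)]
            step_seed = int(np.random.default_rng([seed, step]).integers(2 ** 31))
            opt.lr = cosine_lr(step, n_steps, lr)
            with graph_context():
                state, _ = model.run_cycles(ex.task, seed=step_seed,
                                            n_members=n,
                                            record_trajectory=False)
                lb = community_loss(model, ex.task, state, ex.ground_truth)
                if not np.isfinite(lb.total):
                    log.error("non-finite loss at step %d; restoring last "
                              "good parameters", step)
                    model.store.load_state_dict(last_good)
                    aborted = True
                    break
                opt.zero_grad()
                lb.loss.backward()
                opt.step()
                lb.loss = None     # drop the graph; keep only the numbers
            steps_done = step + 1
            history.append(lb.total)
            breakdowns.append(lb)
            if log_file:
                if step == 0:
                    log_file.write(LossBreakdown.tsv_header(lb.terms) + "\n")
                log_file.write(lb.tsv_row(step) + "\n")
            if checkpoint_every and (step + 1) % checkpoint_every == 0:
                last_good = model.store.state_dict()
            if target_rmsd is not None and (step + 1) % eval_every == 0:
                r = evaluate_best_rmsd(model, examples[0], eval_seed, n)
                rmsd_history.append((step + 1, r))
                if keep_best and r < best_eval:
                    best_eval = r
                    best_params = model.store.state_dict()
                if (step + 1) % (4 * eval_every) == 0:
                    log.info("step %d loss %.3f best-rmsd %.3f (%.0fs)",
                             step + 1, lb.total, r, time.time() - t_start)
                if r < target_rmsd:
                    break
    finally:
        if log_file:
            log_file.close()
    if keep_best and best_params is not None and not aborted:
        model.store.load_state_dict(best_params)
    final = evaluate_best_rmsd(model, examples[0], eval_seed, n) \
        if not aborted else None
    if final is not None:
        rmsd_history.append((steps_done, final))
    ckpt = None
    if checkpoint_path is not None:
        model.store.save(checkpoint_path,
                         meta={"config": model.config.to_dict(),
                               "steps": steps_done, "seed": seed})
        ckpt = str(checkpoint_path)
    return TrainResult(steps_done, history, rmsd_history, final,
                       aborted_nonfinite=aborted, checkpoint_path=ckpt,
                       breakdowns=breakdowns)


def load_checkpoint(path) -> CommunityModel:
    """Rebuild a model from a checkpoint archive (bit-exact parameters)."""
    from .config import ModelConfig
    from .nn import ParamStore

    state, meta = ParamStore.read(path)
    model = CommunityModel(ModelConfig.from_dict(meta["config"]))
    model.store.load_state_dict(state)
    return model
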