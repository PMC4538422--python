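"""Stochastic-gradient training: single-task, shared-weight multitask, consensus.

Training maximises the L2-regularised conditional log-likelihood by plain
stochastic gradient ascent.  The multitask variant follows the three-step
recipe: (a) pick a task at random, (b) pick a random training example of that
task, (c) take a gradient step — the shared feature-to-neuron weights W
receive updates from every task while each task's output head (U_t, T_t) is
touched only by its own examples.

A consensus (stacked) model retrains a fresh CNF whose inputs are the
windowed posterior distributions emitted by a set of first-level models,
mirroring ensembling over models trained on different feature-class
combinations.

Everything is deterministic given the config seed: initialisation, example
order, and task sampling all draw from one ``numpy`` Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cnf_core import (
    CNFModel,
    PredictionResult,
    TaskHead,
    gradient,
    log_partition_and_marginals,
    map_decode,
    node_scores,
    sequence_loglik,
)
from .features import FeatureMatrix, window_stack

__all__ = [
    "TrainConfig",
    "TaskDataset",
    "TrainingDivergedError",
    "init_model",
    "train_single",
    "train_multitask",
    "train_consensus",
    "predict",
]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for SGD training.

    ``learning_rate`` is multiplied by ``lr_decay`` after every epoch.
    ``patience`` is the number of epochs without validation-log-likelihood
    improvement tolerated before stopping (only active when ``val_fraction``
    yields a nonempty held-out split).  ``minibatch=1`` is pure SGD.
    """

    epochs: int = 30
    learning_rate: float = 0.01
    lr_decay: float = 0.9
    l2_lambda: float = 1e-4
    H: int = 100
    k: int = 5
    seed: int = 0
    task_sampling: str = "uniform"   # or "proportional"
    minibatch: int = 1
    patience: int = 5
    val_fraction: float = 0.1
    gate: str = "sigmoid"
    standardize: bool = True


@dataclass
class TaskDataset:
    """Labeled examples for one prediction task.

    ``examples`` holds ``(X, y)`` pairs where X is a FeatureMatrix (or a raw
    windowed array) and y a 0-based integer label sequence in [0, M-1].
    """

    task_id: str
    examples: list[tuple]
    M: int

    def __post_init__(self):
        for i, (X, y) in enumerate(self.examples):
            y = np.asarray(y)
            if len(y) and (y.min() < 0 or y.max() >= self.M):
                raise ValueError(f"example {i}: labels outside [0, {self.M - 1}]")

    def __len__(self) -> int:
        return len(self.examples)


def _xmat(X) -> np.ndarray:
    return X.windowed if isinstance(X, FeatureMatrix) or hasattr(X, "windowed") else np.asarray(X, float)


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    r = math.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-r, r, size=shape)


def init_model(D: int, tasks: dict[str, int], cfg: TrainConfig, rng: np.random.Generator,
               scaler=None) -> CNFModel:
    """Glorot-uniform W and U, zero transitions and biases."""
    W = _glorot(rng, (cfg.H, D))
    heads = {}
    for task_id in sorted(tasks):
        M = tasks[task_id]
        heads[task_id] = TaskHead(_glorot(rng, (M, cfg.H)), np.zeros(M), np.zeros((M, M)))
    return CNFModel(W, np.zeros(cfg.H), heads, gate=cfg.gate, scaler=scaler)


def _fit_scaler(datasets: list[TaskDataset]) -> tuple[np.ndarray, np.ndarray]:
    rows = np.vstack([_xmat(X) for ds in datasets for X, _ in ds.examples])
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0)
    sd[sd < 1e-8] = 1.0
    return mean, sd


def _split(ds: TaskDataset, val_fraction: float, rng: np.random.Generator):
    n = len(ds)
    n_val = int(math.floor(val_fraction * n))
    perm = rng.permutation(n)
    val_idx = set(perm[:n_val].tolist())
    train = [ds.examples[i] for i in range(n) if i not in val_idx]
    val = [ds.examples[i] for i in sorted(val_idx)]
    return replace_examples(ds, train), replace_examples(ds, val)


def replace_examples(ds: TaskDataset, examples: list) -> TaskDataset:
    return TaskDataset(ds.task_id, examples, ds.M)


def _mean_loglik(model: CNFModel, ds: TaskDataset) -> float:
    if not ds.examples:
        return 0.0
    return float(np.mean([sequence_loglik(model, ds.task_id, X, np.asarray(y, int))
                          for X, y in ds.examples]))


def _apply(model: CNFModel, task_id: str, grads: dict, lr: float) -> None:
    head = model.heads[task_id]
    model.W += lr * grads["W"]
    model.w_bias += lr * grads["w_bias"]
    head.U += lr * grads["U"]
    head.u_bias += lr * grads["u_bias"]
    head.T += lr * grads["T"]


def _check_finite(model: CNFModel, task_id: str, step: int) -> None:
    head = model.heads[task_id]
    for name, arr in (("W", model.W), ("U", head.U), ("T", head.T)):
        if not np.isfinite(arr).all():
            raise TrainingDivergedError(
                f"non-finite {name} after step {step} (task {task_id}); "
                "reduce the learning rate or increase l2_lambda")


def _train(datasets: list[TaskDataset], cfg: TrainConfig) -> CNFModel:
    if not datasets or any(len(ds) == 0 for ds in datasets):
        raise ValueError("every task needs at least one training example")
    dims = {(_xmat(X).shape[1]) for ds in datasets for X, _ in ds.examples}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions across tasks: {sorted(dims)}")
    D = dims.pop()

    rng = np.random.default_rng(cfg.seed)
    scaler = _fit_scaler(datasets) if cfg.standardize else None
    model = init_model(D, {ds.task_id: ds.M for ds in datasets}, cfg, rng, scaler)

    splits = [_split(ds, cfg.val_fraction, rng) for ds in datasets]
    trains = [tr for tr, _ in splits]
    vals = [va for _, va in splits]
    have_val = any(len(v) for v in vals)

    n_steps = sum(len(tr) for tr in trains)
    if cfg.task_sampling == "proportional":
        task_p = np.array([len(tr) for tr in trains], dtype=float)
    else:
        task_p = np.ones(len(trains))
    task_p /= task_p.sum()

    lr = cfg.learning_rate
    log: list[dict] = []
    best_val, best_model, stale = -np.inf, None, 0
    step = 0
    for epoch in range(cfg.epochs):
        for _ in range(n_steps):
            t = int(rng.choice(len(trains), p=task_p)) if len(trains) > 1 else 0
            tr = trains[t]
            acc = None
            for _ in range(cfg.minibatch):
                e = int(rng.integers(len(tr)))
                X, y = tr.examples[e]
                g = gradient(model, tr.task_id, X, np.asarray(y, int), cfg.l2_lambda)
                acc = g if acc is None else {k: acc[k] + g[k] for k in g}
            if cfg.minibatch > 1:
                acc = {k: v / cfg.minibatch for k, v in acc.items()}
            _apply(model, tr.task_id, acc, lr)
            step += 1
            _check_finite(model, tr.task_id, step)
        entry = {"epoch": epoch, "lr": lr,
                 "train_loglik": float(np.mean([_mean_loglik(model, tr) for tr in trains]))}
        if have_val:
            val_ll = float(np.mean([_mean_loglik(model, va) for va in vals if len(va)]))
            entry["val_loglik"] = val_ll
            if val_ll > best_val + 1e-12:
                best_val, best_model, stale = val_ll, model.copy(), 0
            else:
                stale += 1
        log.append(entry)
        lr *= cfg.lr_decay
        if have_val and stale >= cfg.patience:
            break
    if have_val and best_model is not None:
        model = best_model
    model.meta["train_log"] = log
    model.meta["config"] = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    return model


def train_single(task: TaskDataset, cfg: TrainConfig) -> CNFModel:
    """Train one CNF on a single task by SGD; deterministic given ``cfg.seed``."""
    return _train([task], cfg)


def train_multitask(tasks: list[TaskDataset], cfg: TrainConfig) -> dict[str, CNFModel]:
    """Shared-weight multitask training.

    Returns one model per task; all returned models hold the *same* W array
    object (the shared hidden layer) alongside their task-specific head.
    """
    if len(tasks) < 2:
        raise ValueError("multitask training needs at least two tasks")
    joint = _train(tasks, cfg)
    out = {}
    for ds in tasks:
        m = CNFModel(joint.W, joint.w_bias, {ds.task_id: joint.heads[ds.task_id]},
                     joint.gate, joint.scaler, dict(joint.meta))
        out[ds.task_id] = m
    return out


def predict(model: CNFModel, task_id: str, X) -> PredictionResult:
    """Posterior marginals, MAP (Viterbi) labels and log-partition for one input."""
    if task_id not in model.heads:
        raise ValueError(f"model has no head for task {task_id!r}")
    S = node_scores(model, task_id, X)
    head = model.heads[task_id]
    logZ, unary, _ = log_partition_and_marginals(S, head.T)
    return PredictionResult(task_id, unary, map_decode(S, head.T), logZ)


def consensus_features(first_level: list[CNFModel], task_id: str, X_per_model: list, k: int) -> FeatureMatrix:
    """Windowed concatenation of first-level posterior vectors for one chain."""
    posts = []
    for m, Xm in zip(first_level, X_per_model):
        if task_id not in m.heads:
            raise ValueError(f"first-level model lacks a head for task {task_id!r}")
        posts.append(predict(m, task_id, Xm).posteriors)
    per_residue = np.concatenate(posts, axis=1)
    return FeatureMatrix(per_residue, window_stack(per_residue, k), k,
                         {"consensus": per_residue.shape[1]})


def train_consensus(
    first_level: list[CNFModel],
    task: TaskDataset,
    cfg: TrainConfig,
    model_inputs: list[list] | None = None,
) -> CNFModel:
    """Stacked CNF over first-level posterior features.

    ``model_inputs[m][e]`` supplies model m's input for example e when the
    first-level models consume different feature subsets; by default every
    model reads the example's own feature matrix.  The consensus input per
    residue is the concatenation of all first-level posterior vectors,
    windowed with ``cfg.k``.
    """
    if not first_level:
        raise ValueError("need at least one first-level model")
    if model_inputs is None:
        model_inputs = [[X for X, _ in task.examples] for _ in first_level]
    stacked = []
    for e, (X, y) in enumerate(task.examples):
        Xc = consensus_features(first_level, task.task_id,
                                [model_inputs[m][e] for m in range(len(first_level))], cfg.k)
        stacked.append((Xc, y))
    model = train_single(TaskDataset(task.task_id, stacked, task.M), cfg)
    model.meta["consensus"] = {"n_first_level": len(first_level), "k": cfg.k}
    return model
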