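"""Conditional neural field: potentials, exact chain inference, gradients.

A conditional neural field (CNF) is a linear-chain conditional random field
whose node potentials are produced by a single hidden layer of nonlinear
neurons.  For a length-L chain with windowed input vectors f(1) .. f(L) and a
label sequence Y with Y_i in {1..M},

    P(Y | X)  propto  exp( sum_i phi(Y_i, f(i)) + sum_i psi(Y_i, Y_{i+1}) )

with node potential   phi(a, f(i)) = sum_j U[a, j] * g(W[j] . f(i) + b_j) + c_a
and edge potential    psi(a, b)    = T[a, b],

where g is the hidden gate (logistic sigmoid by default), W the shared
feature-to-neuron weights, U the task-specific neuron-to-label weights and T
the task-specific label-transition weights.  In the multitask setting several
tasks (here 3-state burial and 15-state contact number) hold their own U and
T but share one W, so the hidden layer learns an embedding common to both.

All inference is exact and runs in log space (log-sum-exp stabilised):
forward-backward for the partition function and unary/pairwise posteriors,
Viterbi for MAP decoding, and analytic gradients of the L2-regularised
log-likelihood via empirical-minus-expected sufficient statistics.

Labels are 1-based in documentation and file formats; internally they are
contiguous 0-based integers (contact-number class c maps to index c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "TASK_ACC",
    "TASK_CN",
    "TASK_LABELS",
    "TaskHead",
    "CNFModel",
    "PredictionResult",
    "node_scores",
    "log_partition_and_marginals",
    "sequence_loglik",
    "map_decode",
    "gradient",
]

TASK_ACC = "acc"   # 3-state solvent accessibility (B/I/E)
TASK_CN = "cn"     # 15-state contact number (0..14)
TASK_LABELS = {TASK_ACC: 3, TASK_CN: 15}

_GATES = {
    "sigmoid": (expit, lambda g: g * (1.0 - g)),
    "tanh": (np.tanh, lambda g: 1.0 - g * g),
}


@dataclass
class TaskHead:
    """Task-specific parameters: neuron-to-label and label-to-label weights."""

    U: np.ndarray        # (M, H)
    u_bias: np.ndarray   # (M,)
    T: np.ndarray        # (M, M) transition weights

    @property
    def M(self) -> int:
        return self.U.shape[0]

    def copy(self) -> "TaskHead":
        return TaskHead(self.U.copy(), self.u_bias.copy(), self.T.copy())


@dataclass
class CNFModel:
    """Shared hidden layer plus per-task output heads.

    ``scaler`` holds per-feature standardisation parameters (mean, sd) fitted
    on training data and applied to every input before the hidden layer.
    """

    W: np.ndarray                 # (H, D) shared feature-to-neuron weights
    w_bias: np.ndarray            # (H,)
    heads: dict[str, TaskHead]
    gate: str = "sigmoid"
    scaler: tuple[np.ndarray, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def H(self) -> int:
        return self.W.shape[0]

    @property
    def D(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "CNFModel":
        return CNFModel(
            self.W.copy(), self.w_bias.copy(),
            {t: h.copy() for t, h in self.heads.items()},
            self.gate,
            None if self.scaler is None else (self.scaler[0].copy(), self.scaler[1].copy()),
            dict(self.meta),
        )

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is None:
            return X
        mean, sd = self.scaler
        return (X - mean) / sd

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """(L, H) gated hidden activations for windowed input rows."""
        Xs = self.transform(X)
        if Xs.shape[1] != self.D:
            raise ValueError(f"input dimension {Xs.shape[1]} != model D {self.D}")
        act, _ = _GATES[self.gate]
        return act(Xs @ self.W.T + self.w_bias)


@dataclass
class PredictionResult:
    """Posterior label distributions plus the single most probable labeling."""

    task_id: str
    posteriors: np.ndarray   # (L, M), rows sum to 1
    map_labels: np.ndarray   # (L,), 0-based class indices
    log_partition: float

    @property
    def L(self) -> int:
        return self.posteriors.shape[0]


def _windowed(X) -> np.ndarray:
    return X.windowed if hasattr(X, "windowed") else np.asarray(X, dtype=float)


def node_scores(model: CNFModel, task_id: str, X) -> np.ndarray:
    """(L, M) node potentials phi(a, f(i)) for every position and label."""
    head = model.heads[task_id]
    h = model.hidden(_windowed(X))
    return h @ head.U.T + head.u_bias


def log_partition_and_marginals(
    scores: np.ndarray, T: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact forward-backward on a label chain.

    Returns ``(logZ, unary (L, M), pairwise (L-1, M, M))`` posteriors; pairwise
    posteriors marginalise consistently to the unaries on either axis.
    """
    S = np.asarray(scores, dtype=float)
    L, M = S.shape
    alpha = np.empty((L, M))
    alpha[0] = S[0]
    for i in range(1, L):
        alpha[i] = S[i] + logsumexp(alpha[i - 1][:, None] + T, axis=0)
    logZ = float(logsumexp(alpha[-1]))

    beta = np.empty((L, M))
    beta[-1] = 0.0
    for i in range(L - 2, -1, -1):
        beta[i] = logsumexp(T + S[i + 1] + beta[i + 1], axis=1)

    unary = np.exp(alpha + beta - logZ)
    pairwise = np.empty((max(L - 1, 0), M, M))
    for i in range(L - 1):
        pairwise[i] = np.exp(alpha[i][:, None] + T + S[i + 1] + beta[i + 1] - logZ)
    return logZ, unary, pairwise


def _path_score(S: np.ndarray, T: np.ndarray, y: np.ndarray) -> float:
    idx = np.arange(len(y))
    return float(S[idx, y].sum() + T[y[:-1], y[1:]].sum())


def sequence_loglik(model: CNFModel, task_id: str, X, y: np.ndarray) -> float:
    """log P(Y | X) for one labeled example; always <= 0."""
    head = model.heads[task_id]
    y = np.asarray(y, dtype=int)
    if y.min() < 0 or y.max() >= head.M:
        raise ValueError(f"labels out of range [0, {head.M - 1}]")
    S = node_scores(model, task_id, X)
    if len(y) != S.shape[0]:
        raise ValueError("label sequence length != input length")
    logZ, _, _ = log_partition_and_marginals(S, head.T)
    return _path_score(S, head.T, y) - logZ


def map_decode(scores: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Viterbi argmax label sequence; ties break toward the lower label index."""
    S = np.asarray(scores, dtype=float)
    L, M = S.shape
    delta = S[0].copy()
    back = np.zeros((L, M), dtype=int)
    for i in range(1, L):
        cand = delta[:, None] + T          # (from, to)
        back[i] = np.argmax(cand, axis=0)  # first max -> lowest index on ties
        delta = S[i] + cand[back[i], np.arange(M)]
    y = np.empty(L, dtype=int)
    y[-1] = int(np.argmax(delta))
    for i in range(L - 1, 0, -1):
        y[i - 1] = back[i, y[i]]
    return y


def gradient(
    model: CNFModel, task_id: str, X, y: np.ndarray, l2_lambda: float = 0.0
) -> dict[str, np.ndarray]:
    """Gradient of ``log P(Y|X) - l2_lambda * ||weights||^2`` for one example.

    U and T gradients are the empirical-minus-expected sufficient statistics
    from forward-backward; the W gradient backpropagates the label residual
    through the gate.  Biases are not regularised.
    """
    head = model.heads[task_id]
    y = np.asarray(y, dtype=int)
    Xw = _windowed(X)
    Xs = model.transform(Xw)
    act, dact = _GATES[model.gate]
    h = act(Xs @ model.W.T + model.w_bias)              # (L, H)
    S = h @ head.U.T + head.u_bias                      # (L, M)
    _, unary, pairwise = log_partition_and_marginals(S, head.T)

    L, M = S.shape
    resid = -unary                                      # empirical - expected
    resid[np.arange(L), y] += 1.0

    gU = resid.T @ h
    gu_bias = resid.sum(axis=0)
    gT = -pairwise.sum(axis=0) if L > 1 else np.zeros_like(head.T)
    np.add.at(gT, (y[:-1], y[1:]), 1.0)

    dh = resid @ head.U                                 # (L, H)
    dz = dh * dact(h)
    gW = dz.T @ Xs
    gw_bias = dz.sum(axis=0)

    if l2_lambda:
        gW -= 2.0 * l2_lambda * model.W
        gU -= 2.0 * l2_lambda * head.U
        gT -= 2.0 * l2_lambda * head.T
    return {"W": gW, "w_bias": gw_bias, "U": gU, "u_bias": gu_bias, "T": gT}
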