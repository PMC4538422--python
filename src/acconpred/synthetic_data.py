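"""Synthetic inputs: toy helical structures and planted-CNF datasets.

Two generators make every stage of the pipeline testable without external
structure or profile databases:

* :func:`make_helix_chain` builds an ideal alpha-helical backbone (2.3 A
  helix radius, 100 degree twist and 1.5 A rise per residue, giving the
  canonical ~3.8 A consecutive CA-CA distance) with C-beta atoms placed by
  ideal tetrahedral geometry — enough structure for the surface-area and
  contact-number label generators to chew on;

* :func:`make_two_task_dataset` plants a known conditional neural field and
  samples exactly from it.  Features follow a smooth AR(1) process along the
  chain (mimicking the local correlation that windowed sequence profiles
  show); a single shared hidden layer drives both a 3-class burial-like track
  and a 15-class contact-number-like track.  The 15-class head is ordinal —
  class scores are monotone in a latent burial depth — so tolerance-accuracy
  curves behave like real contact-number predictions.  The ``coupling`` knob
  interpolates between tasks driven by one common latent direction
  (coupling=1) and tasks driven by disjoint hidden units (coupling=0).

Sampling from the planted model is exact (forward filtering, backward
sampling), so empirical label frequencies converge to the model's true
conditional distribution.  Everything is reproducible bit-for-bit from the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .cnf_core import CNFModel, TASK_ACC, TASK_CN, TaskHead, node_scores
from .features import FeatureMatrix, window_stack
from .structure_labels import Atom, Chain, Residue, virtual_cbeta
from .training import TaskDataset

__all__ = [
    "PlantedDataset",
    "make_helix_chain",
    "sample_cnf",
    "make_planted_model",
    "make_two_task_dataset",
]

# Residue-name cycle for toy chains: all 20 types appear (affects max-ASA lookups).
_CYCLE = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
          "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"]


def make_helix_chain(
    n_residues: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    jitter: float = 0.0,
    seed: int = 0,
) -> Chain:
    """Ideal alpha-helical chain with N/CA/C/CB atoms.

    ``twist`` is in degrees per residue.  ``jitter`` (A) adds seeded Gaussian
    noise to every atom; at the default 0 the chain is exactly deterministic.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n_residues):
        th = math.radians(twist) * i
        ca = np.array([radius * math.cos(th), radius * math.sin(th), rise * i])
        # local frame: helix tangent and outward radial direction
        tang = np.array([-radius * math.radians(twist) * math.sin(th),
                         radius * math.radians(twist) * math.cos(th), rise])
        tang /= np.linalg.norm(tang)
        rad = np.array([math.cos(th), math.sin(th), 0.0])
        n_at = ca - 1.10 * tang + 0.96 * rad   # |offset| ~ 1.46 A (N-CA bond)
        c_at = ca + 1.10 * tang + 0.96 * rad   # |offset| ~ 1.46 A (CA-C bond)
        cb = virtual_cbeta(n_at, ca, c_at)
        coords = {"N": n_at, "CA": ca, "C": c_at, "CB": cb}
        if jitter:
            coords = {k: v + rng.normal(0.0, jitter, 3) for k, v in coords.items()}
        name = _CYCLE[i % len(_CYCLE)]
        atoms = [Atom(an, an[0], xyz) for an, xyz in coords.items()]
        if name == "GLY":
            atoms = [a for a in atoms if a.name != "CB"]
        residues.append(Residue(name, i + 1, atoms))
    return Chain("A", residues)


# ---------------------------------------------------------------------------
# Exact CNF sampling
# ---------------------------------------------------------------------------

def sample_cnf(model: CNFModel, task_id: str, X, rng: np.random.Generator) -> np.ndarray:
    """Exact draw from P(Y | X): forward filtering, backward sampling."""
    S = node_scores(model, task_id, X)
    T = model.heads[task_id].T
    L, M = S.shape
    alpha = np.empty((L, M))
    alpha[0] = S[0]
    for i in range(1, L):
        alpha[i] = S[i] + logsumexp(alpha[i - 1][:, None] + T, axis=0)
    y = np.empty(L, dtype=int)
    p = np.exp(alpha[-1] - logsumexp(alpha[-1]))
    y[-1] = rng.choice(M, p=p / p.sum())
    for i in range(L - 2, -1, -1):
        logp = alpha[i] + T[:, y[i + 1]]
        p = np.exp(logp - logsumexp(logp))
        y[i] = rng.choice(M, p=p / p.sum())
    return y


# ---------------------------------------------------------------------------
# Planted two-task model
# ---------------------------------------------------------------------------

@dataclass
class PlantedDataset:
    """A planted generating model plus data sampled exactly from it."""

    model: CNFModel
    datasets: dict[str, TaskDataset]
    seed: int
    params: dict


def _ordinal_head(centers: np.ndarray, direction: np.ndarray, gamma: float,
                  center_offset: float, transition: float) -> TaskHead:
    """Head whose class scores are -gamma*(s - mu_c)^2 in a latent s = dir.h.

    Expanding the square gives scores linear in the hidden vector, so the
    ordinal construction is representable exactly: U[c] = 2*gamma*mu_c*dir and
    bias_c = -gamma*mu_c^2 - 2*gamma*mu_c*offset (the s-only term is constant
    across classes and drops out of the normalisation).
    """
    M = len(centers)
    U = 2.0 * gamma * centers[:, None] * direction[None, :]
    bias = -gamma * centers ** 2 - 2.0 * gamma * centers * center_offset
    T = transition * np.eye(M)
    return TaskHead(U, bias, T)


def make_planted_model(
    D: int,
    H: int = 4,
    coupling: float = 1.0,
    k: int = 2,
    seed: int = 0,
    gamma3: float = 25.0,
    gamma15: float = 60.0,
    transition: float = 0.4,
    w_scale: float = 2.5,
) -> CNFModel:
    """Planted two-task CNF over (2k+1)*D windowed inputs.

    Half of the hidden units form the "shared" latent direction, the other
    half an independent one; the 15-class head mixes them with weight
    ``coupling`` versus ``1 - coupling``.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    Dw = (2 * k + 1) * D
    W = rng.normal(0.0, w_scale / math.sqrt(Dw), size=(H, Dw))
    w_bias = np.zeros(H)

    half = max(H // 2, 1)
    v_shared = np.zeros(H)
    v_shared[:half] = 1.0 / half
    v_indep = np.zeros(H)
    v_indep[half:] = 1.0 / max(H - half, 1)
    if H == 1:
        v_indep = v_shared.copy()

    # sigmoid activations hover around 0.5 -> center the latent coordinates
    off_s = 0.5 * v_shared.sum()
    v_cn = coupling * v_shared + (1.0 - coupling) * v_indep
    off_cn = 0.5 * v_cn.sum()

    # class centers live in the latent's reachable range (sigmoid outputs)
    heads = {
        TASK_ACC: _ordinal_head(np.array([-0.16, 0.0, 0.16]), v_shared, gamma3, off_s, transition),
        TASK_CN: _ordinal_head(np.linspace(-0.25, 0.25, 15), v_cn, gamma15, off_cn, transition),
    }
    model = CNFModel(W, w_bias, heads, gate="sigmoid", scaler=None)
    model.meta["planted"] = {"coupling": coupling, "k": k, "seed": seed}
    return model


def _ar1_features(L: int, D: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    x = np.empty((L, D))
    x[0] = rng.normal(0.0, 1.0, D)
    innov_sd = math.sqrt(1.0 - rho * rho)
    for i in range(1, L):
        x[i] = rho * x[i - 1] + rng.normal(0.0, innov_sd, D)
    return x


def make_two_task_dataset(
    n_seq: int,
    L: int,
    D: int = 6,
    H: int = 4,
    coupling: float = 1.0,
    seed: int = 0,
    k: int = 2,
    rho: float = 0.8,
    **model_kwargs,
) -> PlantedDataset:
    """Sample ``n_seq`` chains of length ``L`` from a planted two-task CNF.

    Features are AR(1) along the chain (correlation ``rho``); the burial-like
    3-class track and the ordinal 15-class track share hidden structure
    according to ``coupling``.  Bit-reproducible for a fixed seed.
    """
    model = make_planted_model(D, H, coupling, k, seed=seed, **model_kwargs)
    rng = np.random.default_rng(seed + 1)
    acc_examples, cn_examples = [], []
    for _ in range(n_seq):
        x = _ar1_features(L, D, rho, rng)
        X = FeatureMatrix(x, window_stack(x, k), k, {"synthetic": D})
        y_acc = sample_cnf(model, TASK_ACC, X, rng)
        y_cn = sample_cnf(model, TASK_CN, X, rng)
        acc_examples.append((X, y_acc))
        cn_examples.append((X, y_cn))
    datasets = {
        TASK_ACC: TaskDataset(TASK_ACC, acc_examples, 3),
        TASK_CN: TaskDataset(TASK_CN, cn_examples, 15),
    }
    return PlantedDataset(model, datasets, seed,
                          {"n_seq": n_seq, "L": L, "D": D, "H": H,
                           "coupling": coupling, "k": k, "rho": rho})
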