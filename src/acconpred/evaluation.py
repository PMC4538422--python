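"""Evaluation metrics: Qm accuracy, per-label P/R/F1 with probability-thresholded
subsets, contact-number tolerance accuracy, and Pearson correlation.

Conventions worth spelling out:

* precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN);
* probability-thresholded rows restrict the *predicted* set to positions whose
  predicted-label probability exceeds the cutoff, while the recall denominator
  stays the full set of true positives — so recall shrinks toward zero at high
  cutoffs even when the retained predictions are nearly always right;
* tolerance-τ accuracy for contact numbers counts |pred - true| <= τ, so τ=0
  reproduces plain Q15 accuracy and the curve is non-decreasing in τ;
* contact-number correlation can be computed against either the MAP label or
  the posterior-expected contact number Σ_c c·p(c); the expectation is the
  headline variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

__all__ = [
    "EvalReport",
    "q_accuracy",
    "prf_per_label",
    "tolerance_accuracy",
    "pearson_correlation",
    "expected_contact_number",
    "evaluate_classification",
]


@dataclass
class EvalReport:
    q_accuracy: float
    per_label: dict            # label -> {precision, recall, f1, support}
    thresholded: list[dict]    # {label, prob_cutoff, precision, recall, f1, n_subset, defined}
    tolerance_accuracy: dict[int, float] = field(default_factory=dict)
    pearson_r: float | None = None

    def to_dict(self) -> dict:
        return {
            "q_accuracy": self.q_accuracy,
            "per_label": self.per_label,
            "thresholded": self.thresholded,
            "tolerance_accuracy": {str(t): a for t, a in self.tolerance_accuracy.items()},
            "pearson_r": self.pearson_r,
        }


def q_accuracy(pred_labels, true_labels) -> float:
    """Fraction of positions with matching labels (Q3 / Q15)."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    if pred.size == 0:
        raise ValueError("empty label sequences")
    return float((pred == true).mean())


def prf_per_label(
    pred,
    true,
    posteriors: np.ndarray | None = None,
    prob_cutoffs: tuple[float, ...] = (),
    labels: list | None = None,
) -> tuple[dict, list[dict]]:
    """Per-label precision/recall/F1, plus probability-thresholded subsets.

    For cutoff c the predicted set is restricted to positions whose predicted
    label's posterior probability exceeds c; TP/FP come from that subset while
    the recall denominator remains all positions truly in the class.  An empty
    subset yields metrics 0 with ``defined=False``.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    if labels is None:
        labels = sorted(set(np.concatenate([np.unique(pred), np.unique(true)]).tolist()))
    if any(not 0.0 <= c <= 1.0 for c in prob_cutoffs):
        raise ValueError("probability cutoffs must lie in [0, 1]")

    def _prf(pred_mask, true_mask):
        tp = int((pred_mask & true_mask).sum())
        fp = int((pred_mask & ~true_mask).sum())
        fn = int((~pred_mask & true_mask).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        return prec, rec, f1, tp, fp, fn

    per_label = {}
    for lab in labels:
        p, r, f1, tp, fp, fn = _prf(pred == lab, true == lab)
        per_label[lab] = {"precision": p, "recall": r, "f1": f1, "support": int((true == lab).sum())}

    thresholded: list[dict] = []
    if prob_cutoffs:
        if posteriors is None:
            raise ValueError("posteriors required for probability-thresholded metrics")
        posteriors = np.asarray(posteriors, dtype=float)
        label_index = {lab: i for i, lab in enumerate(labels)}
        pred_idx = np.array([label_index[v] for v in pred.tolist()])
        conf = posteriors[np.arange(len(pred)), pred_idx]
        for lab in labels:
            for c in prob_cutoffs:
                keep = conf > c
                pred_mask = (pred == lab) & keep
                true_mask = true == lab
                tp = int((pred_mask & true_mask).sum())
                fp = int((pred_mask & ~true_mask).sum())
                n_true = int(true_mask.sum())
                defined = bool(pred_mask.sum())
                prec = tp / (tp + fp) if tp + fp else 0.0
                rec = tp / n_true if n_true else 0.0
                f1 = (2 * prec * rec / (prec + rec)) if prec + rec else 0.0
                thresholded.append({
                    "label": lab, "prob_cutoff": c, "precision": prec, "recall": rec,
                    "f1": f1, "n_subset": int(pred_mask.sum()), "defined": defined,
                })
    return per_label, thresholded


def tolerance_accuracy(pred_cn, true_cn, tolerances=(0, 1, 2, 3)) -> dict[int, float]:
    """accuracy(τ) = fraction of positions with |pred - true| <= τ."""
    pred = np.asarray(pred_cn, dtype=int)
    true = np.asarray(true_cn, dtype=int)
    diff = np.abs(pred - true)
    return {int(t): float((diff <= t).mean()) for t in tolerances}


def pearson_correlation(pred_values, true_values) -> float | None:
    """Product-moment correlation; ``None`` when either side has zero variance."""
    x = np.asarray(pred_values, dtype=float)
    y = np.asarray(true_values, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return None
    return float(pearsonr(x, y).statistic)


def expected_contact_number(posteriors: np.ndarray) -> np.ndarray:
    """Posterior mean contact number Σ_c c·p(c) per residue (classes c = 0..14)."""
    p = np.asarray(posteriors, dtype=float)
    classes = np.arange(p.shape[1], dtype=float)
    return p @ classes


def evaluate_classification(
    pred,
    true,
    posteriors: np.ndarray | None = None,
    prob_cutoffs: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    tolerances: tuple[int, ...] = (),
    continuous_pred: np.ndarray | None = None,
) -> EvalReport:
    """One-stop report assembling every metric for a prediction run."""
    per_label, thresh = prf_per_label(pred, true, posteriors,
                                      prob_cutoffs if posteriors is not None else ())
    tol = tolerance_accuracy(pred, true, tolerances) if tolerances else {}
    r = None
    if continuous_pred is not None:
        r = pearson_correlation(continuous_pred, np.asarray(true, dtype=float))
    return EvalReport(q_accuracy(pred, true), per_label, thresh, tol, r)
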