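"""Threshold-free and threshold-dependent skill metrics for binary scores.

AUC uses the rank (Mann–Whitney) formulation with tie correction: the
probability that a random presence outscores a random absence, counting
ties as half.  The true skill statistic TSS = sensitivity + specificity − 1
is threshold-dependent; its maximum over a complete candidate-threshold
scan is used both for model scoring and for binarizing continuous
suitability maps.  Candidate thresholds are the midpoints between
consecutive sorted unique scores plus 0 and 1, which makes the scan finite
and exhaustive; ties in the argmax resolve to the smallest threshold.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann–Whitney AUC with tie correction.

    ``labels`` are 0/1; presences must outrank absences for AUC > 0.5.
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive sorted unique scores, plus 0 and 1."""
    uniq = np.unique(np.asarray(scores, float))
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.array([])
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def sens_spec(labels: np.ndarray, scores: np.ndarray,
              threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity when ``score >= threshold`` means suitable."""
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(scores, float) >= threshold
    sens = float(pred[labels].mean())
    spec = float((~pred[~labels]).mean())
    return sens, spec


def tss_at(labels: np.ndarray, scores: np.ndarray, threshold: float) -> float:
    sens, spec = sens_spec(labels, scores, threshold)
    return sens + spec - 1


def max_tss(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """(max TSS, threshold attaining it); ties -> smallest threshold."""
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("TSS scan needs both classes")
    best_tss, best_thr = -np.inf, np.nan
    for thr in candidate_thresholds(scores):
        t = tss_at(labels, scores, thr)
        if t > best_tss + 1e-12:
            best_tss, best_thr = t, thr
    return float(best_tss), float(best_thr)


def max_sens_plus_spec(labels: np.ndarray,
                       scores: np.ndarray) -> tuple[float, float]:
    """(max sensitivity+specificity, threshold); the argmax coincides with
    the max-TSS threshold since the criteria differ by the constant 1."""
    tss, thr = max_tss(labels, scores)
    return tss + 1, thr
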