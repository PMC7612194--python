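"""Posterior decision layer: inclusion probabilities, Bayes FDR, networks.

mPIP (s×p) are posterior means of the inclusion indicators γ_kj; mEPIP (s×s)
are model-averaged edge inclusion probabilities of the residual graph — the
average is over sampled decomposable graphs, so the thresholded network may
itself be non-decomposable. Simulation scoring (TPR/FPR/ROC) lives here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PosteriorSummary", "bayes_fdr", "threshold_network", "roc_tpr_fpr", "roc_curve_points"]


@dataclass
class PosteriorSummary:
    mpip: np.ndarray                  # s×p in [0,1]
    mepip: np.ndarray                 # s×s symmetric, unit diagonal
    pi_mean: np.ndarray               # length p
    o_mean: np.ndarray                # length s
    beta_mean: np.ndarray             # s×p posterior-mean coefficients
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    response_names: list | None = None
    predictor_names: list | None = None

    def __post_init__(self):
        for arr in (self.mpip, self.mepip):
            if np.any((arr < -1e-9) | (arr > 1 + 1e-9)):
                raise ValueError("probabilities must lie in [0, 1]")


def bayes_fdr(mpip: np.ndarray, threshold: float = 0.5):
    """Selected set {cells: mPIP >= t} and its Bayesian FDR.

    bFDR = mean of (1 − mPIP) over the selected cells — the expected
    proportion of false selections. Empty selection returns bFDR = 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mpip = np.asarray(mpip, dtype=float)
    mask = mpip >= threshold
    selected = np.argwhere(mask)
    if selected.size == 0:
        return selected, 0.0
    return selected, float(np.mean(1.0 - mpip[mask]))


def threshold_network(summary: PosteriorSummary, t_edge: float = 0.5,
                      t_assoc: float = 0.5):
    """Thresholded association list and residual-graph edge list.

    Returns (associations, edges) DataFrames with 1-based labels (or input
    names when available) and the supporting probability for each row.
    """
    if not (0 < t_edge < 1 and 0 < t_assoc < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    s, p = summary.mpip.shape
    rnames = summary.response_names or [f"response_{k+1}" for k in range(s)]
    pnames = summary.predictor_names or [f"predictor_{j+1}" for j in range(p)]
    rows = [(rnames[k], pnames[j], summary.mpip[k, j])
            for k, j in np.argwhere(summary.mpip >= t_assoc)]
    assoc = pd.DataFrame(rows, columns=["response", "predictor", "mPIP"])
    erows = []
    for k in range(s):
        for l in range(k + 1, s):
            if summary.mepip[k, l] >= t_edge:
                erows.append((rnames[k], rnames[l], summary.mepip[k, l]))
    edges = pd.DataFrame(erows, columns=["node1", "node2", "mEPIP"])
    return assoc, edges


def _upper(a):
    a = np.asarray(a)
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def roc_tpr_fpr(scores: np.ndarray, truth: np.ndarray, threshold: float = 0.5,
                kind: str = "auto"):
    """(TPR, FPR) at a threshold, over edges or association cells.

    ``kind='edges'`` scores the strict upper triangle of square matrices;
    ``kind='cells'`` scores every entry; 'auto' picks edges for square
    symmetric inputs. Degenerate truth (no positives / no negatives) yields
    NaN for the undefined rate, with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must share a shape")
    if kind == "auto":
        square = scores.ndim == 2 and scores.shape[0] == scores.shape[1]
        kind = "edges" if square and np.allclose(scores, scores.T) else "cells"
    if kind == "edges":
        sc, tr = _upper(scores), _upper(truth).astype(bool)
    else:
        sc, tr = scores.ravel(), truth.ravel().astype(bool)
    pos = sc >= threshold
    n_pos, n_neg = int(tr.sum()), int((~tr).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("degenerate truth: one class is empty; reporting NaN")
    tpr = float(np.sum(pos & tr) / n_pos) if n_pos else float("nan")
    fpr = float(np.sum(pos & ~tr) / n_neg) if n_neg else float("nan")
    return tpr, fpr


def roc_curve_points(scores: np.ndarray, truth: np.ndarray, kind: str = "auto"):
    """Full ROC curve by sweeping the threshold over the unique scores.

    Returns a DataFrame with columns threshold, tpr, fpr (descending
    threshold, so the curve runs from (0,0) to (1,1)).
    """
    scores = np.asarray(scores, dtype=float)
    thresholds = np.unique(scores)[::-1]
    rows = []
    for t in thresholds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tpr, fpr = roc_tpr_fpr(scores, truth, threshold=t, kind=kind)
        rows.append((t, tpr, fpr))
    return pd.DataFrame(rows, columns=["threshold", "tpr", "fpr"])
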