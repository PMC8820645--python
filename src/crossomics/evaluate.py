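"""Scoring of feature recovery and embedding quality.

- ``pr_auc``: area under the precision-recall curve of a ranking against
  binary truth, the metric used to judge whether the truly contributing
  input features rank above the null ones (prevalence for a useless
  ranking, 1 for a perfect one).
- ``knn_purity``: for k = 1..k_max, the average fraction of each
  point's k nearest embedded neighbors sharing its class label — a
  clustering-quality surrogate for an embedding.
- ``linear_baseline_rank``: a deliberately simple linear reference
  ranking (sum of squared Pearson correlations of each input with all
  outputs), standing in for linear integration methods in benchmarks.
  It is a simplification, not a reimplementation of CCA/PLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import OmicsMatrix
from .importance import ImportanceScores
from .network import Embedding

__all__ = ["RecoveryResult", "pr_auc", "knn_purity", "linear_baseline_rank"]


@dataclass
class RecoveryResult:
    pr_auc: float
    prevalence: float
    method: str = ""
    per_replicate: list[float] | None = None


def pr_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the precision-recall step curve of a score ranking.

    Thresholds sweep the distinct score values from high to low; all
    items at a tied score enter together, and the area is accumulated
    average-precision style as sum over threshold groups of
    (recall gain) x (precision at that operating point).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    if n_pos == 0 or n_pos == truth.size:
        raise ValueError("truth must contain both positives and negatives")

    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], truth[order]
    # group boundaries: last index of each tied block
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, s.size - 1)
    tp = np.cumsum(t)[ends]
    n_at = ends + 1.0
    precision = tp / n_at
    recall = tp / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


def knn_purity(e: Embedding, labels: np.ndarray, k_max: int = 20) -> np.ndarray:
    """Same-class fraction among each point's k nearest neighbors.

    Euclidean distances in embedding space, self excluded; distance ties
    broken by sample index (stable sort).  Returns one value per
    k = 1..k_max, each averaged over all points.
    """
    E = np.asarray(e.values, dtype=float)
    labels = np.asarray(labels)
    n = E.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length does not match embedding rows")
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be < N={n}")
    sq = np.sum(E**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (E @ E.T)
    np.fill_diagonal(d2, np.inf)
    nbr = np.argsort(d2, axis=1, kind="stable")[:, :k_max]
    same = labels[nbr] == labels[:, None]
    return np.cumsum(same, axis=1).mean(axis=0) / np.arange(1, k_max + 1)


def linear_baseline_rank(x: OmicsMatrix, y: OmicsMatrix) -> ImportanceScores:
    """Rank input features by total squared linear correlation with Y.

    ``score_j = sum_l corr(x_j, y_l)^2``; constant columns contribute
    correlation 0.
    """
    if x.sample_ids != y.sample_ids:
        raise ValueError("x and y must be sample-aligned")
    X, Y = x.values, y.values
    n = X.shape[0]

    def zscore(M: np.ndarray) -> np.ndarray:
        sd = M.std(axis=0, ddof=1)
        out = np.zeros_like(M)
        ok = sd > 0
        out[:, ok] = (M[:, ok] - M[:, ok].mean(axis=0)) / sd[ok]
        return out

    corr = zscore(X).T @ zscore(Y) / (n - 1)
    return ImportanceScores(list(x.feature_ids), np.sum(corr**2, axis=1))
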