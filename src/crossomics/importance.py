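"""Permutation importance of input features under a fixed trained model.

With the trained network's parameters frozen, one input column at a time
is randomly permuted across samples and the embedding is recomputed.
The importance of the feature is the total squared displacement of the
embedded points,

    score_j = sum_i || E'(x with column j permuted)_i - E(x)_i ||^2,

averaged over permutations.  In the same permutation pass, the influence
of input feature j on each output variable l (a miRNA-gene pair score,
say) is the total squared change in the reconstructed value of l.  A
feature the model ignores moves the embedding not at all; a constant
column scores exactly zero because any permutation leaves it unchanged.

Because the network fit is stochastic, importance scores from several
independently trained models can be averaged (``aggregate_runs``), which
also reports the mean pairwise correlation of the runs as a stability
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ConfounderTable, OmicsMatrix
from .network import FittedModel, _design

__all__ = [
    "ImportanceScores",
    "PairScores",
    "draw_permutations",
    "permutation_importance",
    "pairwise_importance",
    "aggregate_runs",
]


@dataclass
class ImportanceScores:
    feature_ids: list[str]
    scores: np.ndarray
    n_permutations: int = 1
    n_runs_aggregated: int = 1
    stability_correlation: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.feature_ids) != self.scores.shape[0]:
            raise ValueError("scores length does not match feature_ids")

    def top(self, n: int) -> list[str]:
        order = np.argsort(-self.scores, kind="stable")
        return [self.feature_ids[i] for i in order[:n]]


@dataclass
class PairScores:
    input_ids: list[str]
    output_ids: list[str]
    scores: np.ndarray  # p x q
    n_permutations: int = 1
    n_runs_aggregated: int = 1
    stability_correlation: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.input_ids), len(self.output_ids)):
            raise ValueError("scores shape does not match id lists")

    def row(self, input_id: str) -> np.ndarray:
        return self.scores[self.input_ids.index(input_id)]


def draw_permutations(seed: int, p: int, n_perm: int, n: int) -> np.ndarray:
    """The seeded permutation schedule: one permutation of ``n`` sample
    indices per (feature, repetition), drawn feature-major.

    Both scoring functions consume exactly this schedule, which makes
    scores reproducible and lets closed-form checks replay the very
    permutations used.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((p, n_perm, n), dtype=np.intp)
    for j in range(p):
        for t in range(n_perm):
            out[j, t] = rng.permutation(n)
    return out


def _permutation_pass(
    model: FittedModel,
    x: OmicsMatrix,
    C: np.ndarray | None,
    n_perm: int,
    seed: int,
    pairwise: bool,
) -> tuple[np.ndarray, np.ndarray | None]:
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if x.n_features != model.p:
        raise ValueError(
            f"matrix has {x.n_features} features, model expects {model.p}"
        )
    X = x.values
    n, p = X.shape
    net = model.net
    E0 = net.encode(X)
    Y0 = net.decode(E0, C) if pairwise else None
    perms = draw_permutations(seed, p, n_perm, n)

    scores = np.zeros(p)
    pair = np.zeros((p, model.q)) if pairwise else None
    Xp = X.copy()
    for j in range(p):
        col = X[:, j].copy()
        for t in range(n_perm):
            Xp[:, j] = col[perms[j, t]]
            E1 = net.encode(Xp)
            scores[j] += float(np.sum((E1 - E0) ** 2))
            if pairwise:
                Y1 = net.decode(E1, C)
                pair[j] += np.sum((Y1 - Y0) ** 2, axis=0)
        Xp[:, j] = col
    scores /= n_perm
    if pairwise:
        pair /= n_perm
    return scores, pair


def permutation_importance(
    model: FittedModel, x: OmicsMatrix, n_perm: int = 1, seed: int = 0
) -> ImportanceScores:
    """Embedding-shift importance of every input feature."""
    scores, _ = _permutation_pass(model, x, None, n_perm, seed, pairwise=False)
    return ImportanceScores(list(x.feature_ids), scores, n_permutations=n_perm)


def pairwise_importance(
    model: FittedModel,
    x: OmicsMatrix,
    c: ConfounderTable | None = None,
    output_ids: list[str] | None = None,
    n_perm: int = 1,
    seed: int = 0,
) -> PairScores:
    """Reconstruction-shift influence of every (input, output) pair.

    Uses the same permutation schedule as :func:`permutation_importance`
    with the same seed, so the two score sets come from the same
    permutations.
    """
    C = _design(c) if c is not None else None
    if C is None and model.s > 0:
        raise ValueError("model uses confounders; pass the encoded table")
    _, pair = _permutation_pass(model, x, C, n_perm, seed, pairwise=True)
    out_ids = output_ids or [f"y{l}" for l in range(model.q)]
    if len(out_ids) != model.q:
        raise ValueError("output_ids length does not match model output dim")
    return PairScores(list(x.feature_ids), list(out_ids), pair, n_permutations=n_perm)


def _stability(mat: np.ndarray) -> float | None:
    # mean pairwise Pearson correlation among flattened score vectors
    if mat.shape[0] < 2:
        return None
    cc = np.corrcoef(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    return float(np.mean(cc[iu]))


def aggregate_runs(score_sets: list) -> "ImportanceScores | PairScores":
    """Elementwise mean of importance scores across repeated model fits.

    All runs must carry identical identifier lists.  The returned object
    records the number of runs and the mean pairwise Pearson correlation
    between the runs' score vectors (a run-to-run stability diagnostic).
    """
    if not score_sets:
        raise ValueError("no score sets to aggregate")
    first = score_sets[0]
    if isinstance(first, ImportanceScores):
        for s in score_sets[1:]:
            if s.feature_ids != first.feature_ids:
                raise ValueError("feature_ids differ across runs")
        mat = np.stack([s.scores for s in score_sets])
        return ImportanceScores(
            list(first.feature_ids),
            mat.mean(axis=0),
            n_permutations=first.n_permutations,
            n_runs_aggregated=len(score_sets),
            stability_correlation=_stability(mat),
        )
    if isinstance(first, PairScores):
        for s in score_sets[1:]:
            if s.input_ids != first.input_ids or s.output_ids != first.output_ids:
                raise ValueError("id lists differ across runs")
        mat = np.stack([s.scores.ravel() for s in score_sets])
        return PairScores(
            list(first.input_ids),
            list(first.output_ids),
            mat.mean(axis=0).reshape(first.scores.shape),
            n_permutations=first.n_permutations,
            n_runs_aggregated=len(score_sets),
            stability_correlation=_stability(mat),
        )
    raise TypeError(f"cannot aggregate {type(first).__name__}")
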