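"""Hyperparameter selection by embedding non-normality.

A random projection of high-dimensional data into a few dimensions
tends to look multivariate normal, so an embedding that is *far* from
normal has likely captured structure.  Candidate settings (layer
counts, dropout rates, ...) are therefore compared by, first, the
average absolute pairwise correlation of the embedding columns —
settings whose components duplicate information are discarded — and
then Mardia's multivariate skewness and kurtosis,

    b1 = (1/N^2) sum_ij [ (e_i - ebar)' S^-1 (e_j - ebar) ]^3
    b2 = (1/N)   sum_i  [ (e_i - ebar)' S^-1 (e_i - ebar) ]^2

with S the 1/N sample covariance.  Under multivariate normality b1 is
near 0 and b2 near r(r+2); survivors are ranked by b1 (larger is
further from normal) and by the distance of b2 from r(r+2), and the
setting with the best average rank wins.  The kurtosis direction is an
interpretation: what is rewarded is distance from the normal reference
in either direction, matching the projection-pursuit rationale.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_io import ConfounderTable, OmicsMatrix
from .network import ArchitectureSpec, Embedding, TrainConfig, embed, fit

__all__ = ["TuningResult", "avg_abs_corr", "mardia", "tune", "selection_report"]


@dataclass
class TuningResult:
    settings: list[tuple[ArchitectureSpec, TrainConfig]]
    avg_abs_corr: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    kurtosis_reference: np.ndarray   # r(r+2) per setting
    ranks: np.ndarray                # mean rank among survivors (nan if filtered)
    survivors: np.ndarray            # boolean mask
    selected_index: int

    @property
    def selected(self) -> tuple[ArchitectureSpec, TrainConfig]:
        return self.settings[self.selected_index]


def avg_abs_corr(e: Embedding) -> float:
    """Mean |Pearson correlation| over all pairs of embedding columns."""
    E = np.asarray(e.values, dtype=float)
    n, r = E.shape
    if r < 2:
        raise ValueError("need at least 2 embedding columns")
    sds = E.std(axis=0)
    if np.any(sds == 0):
        col = int(np.nonzero(sds == 0)[0][0])
        raise ValueError(f"embedding column {col} is constant")
    C = np.corrcoef(E, rowvar=False)
    iu = np.triu_indices(r, k=1)
    return float(np.mean(np.abs(C[iu])))


def mardia(e: Embedding | np.ndarray) -> tuple[float, float]:
    """Mardia's multivariate skewness b1 and kurtosis b2.

    Writing u_i for the whitened rows (u_i'u_j equals the Mahalanobis
    cross-product), b1 = || sum_i u_i (x) u_i (x) u_i ||^2 / N^2 over the
    r^3 third-moment tensor and b2 = mean ||u_i||^4 — identical to the
    literal double sum but in O(N r^2) memory.  The covariance uses the
    1/N convention.
    """
    E = np.asarray(e.values if isinstance(e, Embedding) else e, dtype=float)
    n, r = E.shape
    if n <= r:
        raise ValueError(f"need N > r, got N={n}, r={r}")
    Xc = E - E.mean(axis=0)
    S = (Xc.T @ Xc) / n
    try:
        L = np.linalg.cholesky(S)
        U = Xc @ np.linalg.inv(L).T
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular embedding covariance; drop duplicated dimensions or "
            "add a ridge before computing Mardia statistics"
        ) from exc
    T = np.einsum("ia,ib,ic->abc", U, U, U)
    b1 = float(np.sum(T**2) / n**2)
    sq = np.sum(U**2, axis=1)
    b2 = float(np.mean(sq**2))
    return b1, b2


def _candidate_seed(arch: ArchitectureSpec, cfg: TrainConfig) -> int:
    """A stable per-candidate seed from the settings themselves.

    Hashing the settings (rather than their position in the list) makes
    the selection invariant to candidate ordering.
    """
    key = repr((vars(arch), vars(cfg))).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _evaluate_candidates(
    candidates: list[tuple[ArchitectureSpec, TrainConfig]],
    x: OmicsMatrix,
    y: OmicsMatrix,
    c: ConfounderTable | None,
) -> tuple[list[Embedding], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    embeddings, corrs, b1s, b2s, refs = [], [], [], [], []
    for arch, cfg in candidates:
        seeded = TrainConfig(**{**vars(cfg), "seed": _candidate_seed(arch, cfg)})
        model = fit(x, y, c, arch, seeded)
        e = embed(model, x)
        embeddings.append(e)
        corrs.append(avg_abs_corr(e))
        b1, b2 = mardia(e)
        b1s.append(b1)
        b2s.append(b2)
        refs.append(arch.embed_dim * (arch.embed_dim + 2))
    return (embeddings, np.array(corrs), np.array(b1s), np.array(b2s),
            np.array(refs, dtype=float))


def _rank_and_select(
    corrs: np.ndarray, b1: np.ndarray, b2: np.ndarray, refs: np.ndarray,
    corr_threshold: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    survivors = corrs < corr_threshold
    if not survivors.any():
        raise ValueError(
            f"no candidate passes the correlation filter "
            f"(minimum observed avg |corr| = {corrs.min():.3f}, "
            f"threshold = {corr_threshold})"
        )
    ranks = np.full(corrs.size, np.nan)
    idx = np.nonzero(survivors)[0]
    r1 = rankdata(b1[idx])                      # larger skewness -> higher rank
    r2 = rankdata(np.abs(b2[idx] - refs[idx]))  # further from normal -> higher
    mean_rank = (r1 + r2) / 2.0
    ranks[idx] = mean_rank
    best_local = np.lexsort((b1[idx], mean_rank))[-1]  # ties -> larger b1
    return survivors, ranks, int(idx[best_local])


def tune(
    candidates: list[tuple[ArchitectureSpec, TrainConfig]],
    x: OmicsMatrix,
    y: OmicsMatrix,
    c: ConfounderTable | None = None,
    corr_threshold: float = 0.5,
) -> TuningResult:
    """Fit every candidate setting and pick the least-normal embedding.

    Candidates whose embedding columns correlate at or above
    ``corr_threshold`` on average are discarded; survivors are ranked by
    skewness and by kurtosis distance from the normal reference, and
    the best average rank is selected (ties broken by larger b1).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate settings")
    _, corrs, b1, b2, refs = _evaluate_candidates(candidates, x, y, c)
    survivors, ranks, sel = _rank_and_select(corrs, b1, b2, refs, corr_threshold)
    return TuningResult(
        settings=list(candidates), avg_abs_corr=corrs, b1=b1, b2=b2,
        kurtosis_reference=refs, ranks=ranks, survivors=survivors,
        selected_index=sel,
    )


def selection_report(
    candidates: list[tuple[ArchitectureSpec, TrainConfig]],
    x: OmicsMatrix,
    y: OmicsMatrix,
    c: ConfounderTable | None,
    out_path: str,
    corr_threshold: float = 0.5,
) -> TuningResult:
    """Write a PDF with per-setting embedding panels and the metric table.

    One scatter page per candidate (first two embedding components,
    annotated with avg |corr|, b1, b2) followed by a summary table page;
    intended for informed manual hyperparameter selection.  Returns the
    same :class:`TuningResult` that :func:`tune` would.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    embeddings, corrs, b1, b2, refs = _evaluate_candidates(candidates, x, y, c)
    survivors, ranks, sel = _rank_and_select(corrs, b1, b2, refs, corr_threshold)

    with PdfPages(out_path) as pdf:
        for i, ((arch, _), e) in enumerate(zip(candidates, embeddings)):
            fig, ax = plt.subplots(figsize=(5, 5))
            ax.scatter(e.values[:, 0], e.values[:, 1], s=8, alpha=0.6)
            ax.set_xlabel("component 1")
            ax.set_ylabel("component 2")
            ax.set_title(
                f"setting {i}: layers {arch.n_in_layers}/{arch.n_out_layers}, "
                f"dropout {arch.dropout_max}\n"
                f"avg|corr|={corrs[i]:.3f}  b1={b1[i]:.2f}  b2={b2[i]:.2f} "
                f"(normal ref {refs[i]:.0f})"
            )
            pdf.savefig(fig)
            plt.close(fig)
        fig, ax = plt.subplots(figsize=(8, 0.5 * len(candidates) + 1.5))
        ax.axis("off")
        rows = [
            [i, f"{corrs[i]:.3f}", f"{b1[i]:.3f}", f"{b2[i]:.3f}",
             f"{ranks[i]:.1f}" if np.isfinite(ranks[i]) else "filtered",
             "selected" if i == sel else ""]
            for i in range(len(candidates))
        ]
        ax.table(
            cellText=rows,
            colLabels=["setting", "avg |corr|", "b1", "b2", "mean rank", ""],
            loc="center",
        )
        pdf.savefig(fig)
        plt.close(fig)

    return TuningResult(
        settings=list(candidates), avg_abs_corr=corrs, b1=b1, b2=b2,
        kurtosis_reference=refs, ranks=ranks, survivors=survivors,
        selected_index=sel,
    )
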