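"""Gamma-null local false discovery rate for nonnegative importance scores.

The observed importance scores are modelled as a two-group mixture: a
null component of unimportant features, well described empirically by a
gamma distribution, and a non-null component of unknown form.  Writing
``f`` for the overall score density and ``f0`` for the gamma null with
null proportion ``pi0``, the local fdr at score z is

    fdr(z) = pi0 * f0(z) / f(z),  clipped to [0, 1].

The fit proceeds as follows: (1) estimate ``f`` by a Gaussian kernel
density (Silverman bandwidth, reflected at 0 so no mass leaks below
zero) and locate its mode; (2) for each candidate ``pi0`` on the grid
0.60, 0.61, ..., 0.99, fit gamma shape/scale by maximum likelihood to
the scores below the ``pi0`` quantile (low scores are predominantly
null); (3) measure, on the density grid below the mode, the sum of
squared differences between ``pi0``-scaled gamma density and the kernel
density; (4) keep the ``pi0`` minimizing that discrepancy; (5) evaluate
fdr(z) at every observed score; (6) the significance threshold is the
smallest score whose fdr falls below the chosen cutoff — every score
above it is called significant.

``select_pairs`` applies the same machinery per selected input feature
to its row of pair scores, with a top-``min_per_input`` fallback for
inputs whose influence is strong but diffuse (the fdr procedure only
selects outputs that stand out from that input's own background).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .importance import ImportanceScores, PairScores

logger = logging.getLogger("crossomics")

__all__ = ["LocalFdrFit", "fit_local_fdr", "select_significant", "select_pairs"]

_PI0_GRID = np.round(np.arange(0.60, 0.995, 0.01), 2)
_GRID_SIZE = 512


@dataclass
class LocalFdrFit:
    """Everything the six-step procedure estimated, for one score vector."""

    scores: np.ndarray
    grid: np.ndarray
    density: np.ndarray            # reflected-KDE estimate of f on `grid`
    mode_location: float
    pi0: float
    gamma_shape: float
    gamma_scale: float
    fdr_values: np.ndarray         # per observed score, in [0,1]
    threshold_score: float
    fdr_cutoff: float
    pi0_grid: np.ndarray = field(default_factory=lambda: _PI0_GRID.copy())
    discrepancies: np.ndarray | None = None
    gamma_fits: np.ndarray | None = None   # per-candidate (shape, scale)
    bandwidth: float = 0.0

    def f(self, z: np.ndarray) -> np.ndarray:
        """Mixture density (reflected KDE) at arbitrary points."""
        return _reflected_kde(self.scores, self.bandwidth, np.asarray(z, float))

    def f0(self, z: np.ndarray) -> np.ndarray:
        return stats.gamma.pdf(z, a=self.gamma_shape, scale=self.gamma_scale)


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * n ** (-1.0 / 5.0)


def _reflected_kde(x: np.ndarray, bw: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE with boundary reflection at 0 (scores are >= 0)."""
    # evaluate sum of kernels at grid points for data and its mirror image
    z1 = (grid[:, None] - x[None, :]) / bw
    z2 = (grid[:, None] + x[None, :]) / bw
    k = np.exp(-0.5 * z1**2) + np.exp(-0.5 * z2**2)
    return k.sum(axis=1) / (x.size * bw * np.sqrt(2.0 * np.pi))


def _smoothed_gamma(
    shape: float, scale: float, bw: float, eval_pts: np.ndarray, upper: float
) -> np.ndarray:
    """The gamma(shape, scale) density pushed through the same reflected
    Gaussian kernel as the KDE.

    The KDE is a biased estimate of the underlying density (flattened
    peak, inflated boundary), so the null candidates are compared with
    the kernel density on equal footing: each candidate is smoothed with
    the identical kernel before the squared differences are taken.
    Without this, the below-mode discrepancy rewards whichever raw gamma
    happens to mimic the KDE's boundary bias.
    """
    fine = np.linspace(0.0, upper + 6.0 * bw, 2048)
    pdf = stats.gamma.pdf(fine, a=shape, scale=scale)
    z1 = (eval_pts[:, None] - fine[None, :]) / bw
    z2 = (eval_pts[:, None] + fine[None, :]) / bw
    k = np.exp(-0.5 * z1**2) + np.exp(-0.5 * z2**2)
    w = k / (bw * np.sqrt(2.0 * np.pi))
    return np.trapezoid(w * pdf[None, :], fine, axis=1)


def fit_truncated_gamma(x: np.ndarray, cut: float) -> tuple[float, float]:
    """Maximum-likelihood gamma (shape, scale) for a sample observed only
    below ``cut``.

    The lower portion of the scores is a *truncated* gamma sample: the
    log-likelihood is sum(log g(x)) - n log G(cut), with G the gamma CDF.
    Ignoring the truncation would bias the shape upward and, in a
    null/non-null mixture, let the non-null tail leak into the null fit.
    Method-of-moments initialization, Nelder-Mead on log parameters.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10 or np.ptp(x) == 0:
        raise ValueError("degenerate sample for gamma fit")
    mean, var = x.mean(), x.var()
    if var <= 0:
        raise ValueError("zero variance sample for gamma fit")
    shape0 = max(mean**2 / var, 1e-3)
    scale0 = max(var / mean, 1e-12)

    def nll(theta: np.ndarray) -> float:
        a, s = np.exp(theta)
        ll = np.sum(stats.gamma.logpdf(x, a=a, scale=s))
        ll -= x.size * np.log(special.gammainc(a, cut / s))
        return -ll

    res = optimize.minimize(
        nll, np.log([shape0, scale0]), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500},
    )
    if not np.all(np.isfinite(res.x)):
        raise ValueError("truncated gamma fit diverged")
    a, s = np.exp(res.x)
    return float(a), float(s)


def fit_local_fdr(scores: np.ndarray, fdr_cutoff: float = 0.05) -> LocalFdrFit:
    """Run the six-step gamma-null local-fdr procedure on a score vector."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 50:
        raise ValueError(f"need >= 50 scores, got {scores.size}")
    if not np.all(np.isfinite(scores)) or np.any(scores < 0):
        raise ValueError("scores must be finite and nonnegative")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate scores: all values identical")
    if not 0.0 < fdr_cutoff < 1.0:
        raise ValueError("fdr_cutoff must be in (0, 1)")

    # step 1: kernel density and its mode
    bw = _silverman_bandwidth(scores)
    if bw <= 0:
        raise ValueError("zero kernel bandwidth (scores nearly degenerate)")
    grid = np.linspace(0.0, scores.max(), _GRID_SIZE)
    density = _reflected_kde(scores, bw, grid)
    mode = float(grid[np.argmax(density)])
    below = grid <= mode

    # steps 2-4: sweep pi0, fit gamma to the lower tail, score the fit
    discrepancies = np.empty(_PI0_GRID.size)
    fits: list[tuple[float, float]] = []
    for i, pi0 in enumerate(_PI0_GRID):
        cut = np.quantile(scores, pi0)
        tail = scores[scores <= cut]
        tail = tail[tail > 0]
        if tail.size < 10 or np.ptp(tail) == 0:
            raise ValueError(f"gamma fit failed at pi0={pi0}: degenerate lower tail")
        try:
            shape, scale = fit_truncated_gamma(tail, cut)
        except ValueError as exc:
            raise ValueError(f"gamma fit failed at pi0={pi0}: {exc}") from exc
        g = _smoothed_gamma(shape, scale, bw, grid[below], scores.max())
        discrepancies[i] = float(np.sum((pi0 * g - density[below]) ** 2))
        fits.append((shape, scale))

    best = int(np.argmin(discrepancies))
    pi0 = float(_PI0_GRID[best])
    shape, scale = fits[best]

    # step 5: local fdr at each observed score
    f_at = _reflected_kde(scores, bw, scores)
    f0_at = stats.gamma.pdf(scores, a=shape, scale=scale)
    fdr = np.clip(pi0 * f0_at / f_at, 0.0, 1.0)

    # enforce a nonincreasing tail above the null mode so that a single
    # threshold cleanly separates significant from null scores
    order = np.argsort(scores, kind="stable")
    fdr_sorted = fdr[order]
    above = scores[order] > mode
    if above.any():
        fdr_sorted[above] = np.minimum.accumulate(fdr_sorted[above])
    fdr_mono = np.empty_like(fdr)
    fdr_mono[order] = fdr_sorted

    # step 6: smallest score with fdr below the cutoff
    sig = scores[fdr_mono < fdr_cutoff]
    threshold = float(sig.min()) if sig.size else float("inf")

    return LocalFdrFit(
        scores=scores, grid=grid, density=density, mode_location=mode,
        pi0=pi0, gamma_shape=float(shape), gamma_scale=float(scale),
        fdr_values=fdr_mono, threshold_score=threshold, fdr_cutoff=fdr_cutoff,
        discrepancies=discrepancies, gamma_fits=np.array(fits), bandwidth=bw,
    )


def select_significant(fit: LocalFdrFit, scores: ImportanceScores) -> list[str]:
    """Feature ids at or above the fdr threshold, highest score first."""
    keep = [
        (s, fid) for fid, s in zip(scores.feature_ids, scores.scores)
        if s >= fit.threshold_score
    ]
    keep.sort(key=lambda t: -t[0])
    return [fid for _, fid in keep]


@dataclass
class PairEdge:
    input_id: str
    output_id: str
    score: float
    passed_fdr: bool


def select_pairs(
    pairs: PairScores,
    selected_inputs: list[str],
    pair_fdr_cutoff: float = 0.01,
    min_per_input: int = 10,
) -> list[PairEdge]:
    """Per-input local-fdr selection of output partners, with fallback.

    For each selected input feature, the fdr procedure runs on that
    feature's row of pair scores.  When fewer than ``min_per_input``
    outputs pass (or the row is too short to fit), the input's top
    ``min_per_input`` outputs by score enter the list with
    ``passed_fdr=False``.
    """
    missing = set(selected_inputs) - set(pairs.input_ids)
    if missing:
        raise ValueError(f"inputs not present in pair scores: {sorted(missing)}")
    out_ids = np.asarray(pairs.output_ids)
    edges: list[PairEdge] = []
    for inp in selected_inputs:
        row = pairs.row(inp)
        passed = np.zeros(row.size, dtype=bool)
        if row.size >= 50:
            fit = fit_local_fdr(row, pair_fdr_cutoff)
            passed = row >= fit.threshold_score
        else:
            logger.warning(
                "input %r has only %d outputs; falling back to top-%d",
                inp, row.size, min_per_input,
            )
        order = np.argsort(-row, kind="stable")
        n_pass = int(passed.sum())
        chosen = order[passed[order]] if n_pass >= min_per_input else order[:min_per_input]
        for l in chosen:
            edges.append(PairEdge(inp, str(out_ids[l]), float(row[l]), bool(passed[l])))
    return edges
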