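"""Generative model for paired omics matrices with known ground truth.

The generator produces an input matrix ``X`` (N x n_x) and an output
matrix ``Y`` (N x n_y) in which only the first ``k`` X-variables carry
signal, routed to the first ``m*k`` Y-variables through a small set of
latent factors and (optionally nonlinear) link functions:

1. ``X`` is multivariate normal with unit variances and compound-
   symmetry correlation ``rho`` (every pair of columns correlated
   ``rho``), mapped through the standard normal CDF and shifted by 0.5,
   so every value lies strictly in (-0.5, 0.5).
2. Three latent factors ``z_m = sum_j beta_mj x_j`` combine the first
   ``k`` columns with coefficients drawn uniformly from
   [-2,-1] U [1,2].
3. For each affected output j, ``r_j = alpha_j1 z_1 + alpha_j2 z_2 +
   alpha_j3 z_3`` (same coefficient law), rescaled by subtracting the
   mean and dividing by 3 standard deviations so most values fall in
   (-1, 1), then passed through a link: identity, |r|, sin(5(r+0.5)pi),
   (2r)^2, or the indicator of r lying between its own 25th and 75th
   percentiles.  A ``prop_linear`` fraction of affected outputs keep the
   identity link; the rest draw uniformly among the four nonlinear
   forms.  Gaussian noise with variance one tenth of the signal's is
   added (10:1 signal-to-noise).
4. The remaining ``n_y - m*k`` outputs are pure compound-symmetry
   noise.  Every Y column is finally standardized to mean 0, sd 1.

The dataset records which inputs and outputs carry signal, the drawn
coefficients and link assignments, and the realized signal and noise
components, so recovery of the truth can be scored exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
from scipy.special import ndtr

from .data_io import OmicsMatrix, write_matrix

__all__ = [
    "SimConfig",
    "SimDataset",
    "simulate_dataset",
    "simulate_confounded",
    "apply_link",
    "scenario_grid",
    "write_dataset",
]

LINK_NAMES = {1: "identity", 2: "abs", 3: "sine", 4: "square", 5: "step"}


@dataclass(frozen=True)
class SimConfig:
    n_x: int = 100
    n_y: int = 300
    k: int = 10
    m: float = 12.0
    N: int = 1000
    rho: float = 0.3
    prop_linear: float = 0.5
    seed: int = 0

    @property
    def mk(self) -> int:
        mk = self.m * self.k
        if abs(mk - round(mk)) > 1e-9:
            raise ValueError(f"m*k = {mk} is not an integer")
        return int(round(mk))

    def validate(self) -> None:
        if self.k > self.n_x:
            raise ValueError(f"k={self.k} exceeds n_x={self.n_x}")
        if self.mk > self.n_y:
            raise ValueError(f"m*k={self.mk} exceeds n_y={self.n_y}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho={self.rho} must be in [0, 1)")
        if not 0.0 <= self.prop_linear <= 1.0:
            raise ValueError("prop_linear must be in [0, 1]")
        if self.N < 4:
            raise ValueError("N must be >= 4")


@dataclass
class SimDataset:
    x: OmicsMatrix
    y: OmicsMatrix
    true_x_indices: np.ndarray
    affected_y_indices: np.ndarray
    betas: np.ndarray               # 3 x k
    alphas: np.ndarray              # mk x 3
    link_assignments: list[str]
    z: np.ndarray                   # N x 3 latent factors
    r_latent: np.ndarray            # N x mk rescaled combinations
    signal: np.ndarray              # N x mk pre-noise f_j(r_j)
    noise: np.ndarray               # N x mk added noise
    config: SimConfig | None = None

    @property
    def truth_mask(self) -> np.ndarray:
        """Boolean length-n_x vector marking the contributing inputs."""
        mask = np.zeros(self.x.n_features, dtype=bool)
        mask[self.true_x_indices] = True
        return mask


def _compound_symmetry_normal(
    rng: np.random.Generator, n: int, d: int, rho: float
) -> np.ndarray:
    # Sigma = (1-rho) I + rho 11' realized via a shared factor per sample
    g = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, d))
    return np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e


def _coef(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    # uniform magnitude in [1, 2], random sign: the [-2,-1] U [1,2] law
    mag = rng.uniform(1.0, 2.0, shape)
    sign = rng.choice([-1.0, 1.0], shape)
    return mag * sign


def apply_link(r: np.ndarray, which: int) -> np.ndarray:
    """One of the five link functions applied elementwise.

    Link 5 (step) is evaluated against the vector's own empirical 25th
    and 75th percentiles (linear interpolation), inclusive at both ends.
    """
    r = np.asarray(r, dtype=float)
    if which == 1:
        return r.copy()
    if which == 2:
        return np.abs(r)
    if which == 3:
        return np.sin(5.0 * (r + 0.5) * np.pi)
    if which == 4:
        return (2.0 * r) ** 2
    if which == 5:
        q25, q75 = np.quantile(r, [0.25, 0.75])
        return ((r >= q25) & (r <= q75)).astype(float)
    raise ValueError(f"unknown link function label {which!r}")


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Draw one paired dataset according to the generative model above."""
    cfg.validate()
    mk = cfg.mk
    rng = np.random.default_rng(cfg.seed)

    # step 1: bounded input matrix
    raw = _compound_symmetry_normal(rng, cfg.N, cfg.n_x, cfg.rho)
    X = ndtr(raw) - 0.5

    # step 2: three latent factors from the first k inputs
    betas = _coef(rng, (3, cfg.k))
    Z = X[:, : cfg.k] @ betas.T

    # step 3: affected outputs through links, 10:1 signal-to-noise
    alphas = _coef(rng, (mk, 3))
    R = Z @ alphas.T
    R = (R - R.mean(axis=0)) / (3.0 * R.std(axis=0))

    n_lin = int(round(cfg.prop_linear * mk))
    which = np.full(mk, 1, dtype=int)
    nonlin_idx = rng.choice(mk, size=mk - n_lin, replace=False)
    which[nonlin_idx] = rng.integers(2, 6, size=mk - n_lin)

    signal = np.column_stack([apply_link(R[:, j], int(which[j])) for j in range(mk)]) \
        if mk else np.empty((cfg.N, 0))
    sd_noise = signal.std(axis=0) / np.sqrt(10.0)
    noise = rng.standard_normal((cfg.N, mk)) * sd_noise
    Y_sig = signal + noise

    # step 4: null outputs, then global standardization
    Y_null = _compound_symmetry_normal(rng, cfg.N, cfg.n_y - mk, cfg.rho)
    Y = np.concatenate([Y_sig, Y_null], axis=1)
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0)

    sample_ids = [f"s{i}" for i in range(cfg.N)]
    return SimDataset(
        x=OmicsMatrix(X, sample_ids, [f"x{j}" for j in range(cfg.n_x)]),
        y=OmicsMatrix(Y, sample_ids, [f"y{l}" for l in range(cfg.n_y)]),
        true_x_indices=np.arange(cfg.k),
        affected_y_indices=np.arange(mk),
        betas=betas,
        alphas=alphas,
        link_assignments=[LINK_NAMES[int(w)] for w in which],
        z=Z,
        r_latent=R,
        signal=signal,
        noise=noise,
        config=cfg,
    )


def simulate_confounded(
    cfg: SimConfig,
    effect: float = 1.5,
    frac_x: float = 0.2,
    frac_y: float = 0.2,
) -> tuple[SimDataset, np.ndarray]:
    """A dataset plus a balanced binary confounder (batch-style effect).

    On top of :func:`simulate_dataset`, a binary label shifts ``frac_x``
    of the non-contributing X columns and ``frac_y`` of the null Y
    columns by ``effect`` times their within-group standard deviation —
    the signature of a batch or dominant clinical factor that drives
    both data types.  Because the confounded X columns predict the
    confounded Y block, an unadjusted embedding will encode the label;
    injecting the label at the bottleneck lets the decoder absorb the
    block instead.  Returns ``(dataset, labels)``; Y columns are
    re-standardized after the shift.
    """
    ds = simulate_dataset(cfg)
    rng = np.random.default_rng(cfg.seed + 101)
    n = cfg.N
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[: n // 2]] = 1

    X = ds.x.values
    null_x = np.arange(cfg.k, cfg.n_x)
    n_cx = max(1, int(round(frac_x * cfg.n_x)))
    conf_x = rng.choice(null_x, size=min(n_cx, null_x.size), replace=False)
    X[:, conf_x] += effect * X[:, conf_x].std(axis=0) * labels[:, None]

    Y = ds.y.values
    null_y = np.arange(cfg.mk, cfg.n_y)
    n_cy = max(1, int(round(frac_y * cfg.n_y)))
    conf_y = rng.choice(null_y, size=min(n_cy, null_y.size), replace=False)
    Y[:, conf_y] += effect * Y[:, conf_y].std(axis=0) * labels[:, None]
    Y -= Y.mean(axis=0)
    Y /= Y.std(axis=0)
    return ds, labels


def scenario_grid(base: SimConfig, axes: dict[str, list]) -> list[SimConfig]:
    """Cartesian product of axis values over a base config.

    Each resulting config gets a distinct derived seed, supporting the
    replicate-and-average benchmarking loop.
    """
    valid = {f.name for f in fields(SimConfig)}
    unknown = set(axes) - valid
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    names = list(axes)
    configs = []
    for i, combo in enumerate(itertools.product(*(axes[n] for n in names))):
        derived_seed = (base.seed * 100003 + 7919 * i + 1) % (2**31)
        configs.append(replace(base, **dict(zip(names, combo)), seed=derived_seed))
    return configs


def write_dataset(ds: SimDataset, out_dir: str | Path) -> None:
    """Write x.tsv, y.tsv and truth.json into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(ds.x, out / "x.tsv")
    write_matrix(ds.y, out / "y.tsv")
    truth = {
        "true_x_indices": ds.true_x_indices.tolist(),
        "affected_y_indices": ds.affected_y_indices.tolist(),
        "link_assignments": ds.link_assignments,
        "betas": ds.betas.tolist(),
        "alphas": ds.alphas.tolist(),
        "config": None if ds.config is None else vars(ds.config) | {"m": ds.config.m},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
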