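"""Asymmetric autoencoder mapping one omics matrix to another.

The model is an encoder/decoder network X -> E -> Y in which the input
and reconstruction layers hold *different* omics data types: the encoder
compresses the input matrix ``X`` (N x p) to a low-dimensional embedding
``E`` (N x r), and the decoder reconstructs the second matrix ``Y``
(N x q) from ``E``.  Clinical confounders ``C`` (N x s), encoded as a
numeric design matrix, are concatenated to the embedding at the
bottleneck, so the decoder can explain confounder-driven variation in
``Y`` without routing it through ``E``.  With a narrow bottleneck the
encoder is forced to keep only the directions of ``X`` most informative
about ``Y`` — a nonlinear analogue of canonical correlation with
built-in confounder adjustment.

The network is a plain multilayer perceptron (tanh hidden units, linear
output, per-layer dropout) trained by minibatch Adam on the mean squared
reconstruction error of ``Y``.  Forward, backward and the optimizer are
implemented directly on numpy arrays; everything is driven by explicit
seeds and runs identically on any CPU.

Training protocol: the data is split into training and holdout sets, the
holdout reconstruction error is recorded at every epoch, and the epoch
minimizing it is selected; the model is then refit from a fresh
initialization on the full data for exactly that many epochs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import ConfounderTable, OmicsMatrix

logger = logging.getLogger("crossomics")

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "FittedModel",
    "Embedding",
    "resolve_layer_sizes",
    "assign_dropout",
    "build_model",
    "select_epochs",
    "fit",
    "embed",
    "reconstruct",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """How to size and regularize the encoder/decoder stacks.

    Layer sizes can be given three ways (``size_mode``):

    - ``"explicit"``: ``encoder_sizes`` / ``decoder_sizes`` verbatim;
    - ``"shrinkage"``: each encoder layer is the previous size times
      ``shrinkage`` (rounded), descending from p until the bottleneck;
      decoder sizes ascend symmetrically toward q;
    - ``"n_layers"``: the shrinkage factor is solved from the requested
      layer counts, ``(r/p)^(1/L)`` for the encoder, so the L-th layer
      lands exactly on r.

    ``dropout_max`` is the dropout rate of the outermost layer; with
    ``flat_dropout`` every layer uses it, otherwise rates decrease
    linearly to 0 at the bottleneck.
    """

    embed_dim: int = 3
    size_mode: str = "n_layers"
    encoder_sizes: list[int] | None = None
    decoder_sizes: list[int] | None = None
    shrinkage: float | None = None
    n_in_layers: int = 3
    n_out_layers: int = 3
    dropout_max: float = 0.4
    flat_dropout: bool = False
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if not 0.0 <= self.dropout_max < 1.0:
            raise ValueError("dropout_max must be in [0, 1)")
        if self.size_mode not in ("explicit", "shrinkage", "n_layers"):
            raise ValueError(f"unknown size_mode {self.size_mode!r}")
        if self.activation not in ("tanh", "relu", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class TrainConfig:
    max_epochs: int = 300
    batch_size: int = 64
    holdout_frac: float = 0.2
    seed: int = 0
    learning_rate: float = 3e-3
    patience: int = 0  # 0 disables early stopping

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0.0 < self.holdout_frac < 1.0:
            raise ValueError("holdout_frac must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


# ---------------------------------------------------------------------------
# Layer-size and dropout resolution
# ---------------------------------------------------------------------------

def _geometric_sizes(top: int, bottom: int, n_layers: int) -> list[int]:
    # sizes descending from `top` (exclusive) to `bottom` (inclusive),
    # spaced by the solved shrinkage factor (bottom/top)^(1/L)
    if n_layers < 1:
        raise ValueError("layer count must be >= 1")
    shrink = (bottom / top) ** (1.0 / n_layers)
    sizes = [max(bottom, round(top * shrink**i)) for i in range(1, n_layers)]
    sizes.append(bottom)
    return sizes


def _shrinkage_sizes(top: int, bottom: int, shrinkage: float) -> list[int]:
    if not 0.0 < shrinkage < 1.0:
        raise ValueError(f"shrinkage must be in (0, 1), got {shrinkage}")
    sizes: list[int] = []
    cur = float(top)
    while True:
        cur = cur * shrinkage
        if round(cur) <= bottom:
            break
        sizes.append(int(round(cur)))
    sizes.append(bottom)
    return sizes


def resolve_layer_sizes(
    p: int,
    r: int,
    spec: ArchitectureSpec,
    q: int | None = None,
    s: int = 0,
) -> tuple[list[int], list[int] | None]:
    """Resolve encoder and decoder layer sizes.

    Returns ``(encoder_sizes, decoder_sizes)``: the encoder list descends
    from below p and ends with the bottleneck r; the decoder list ascends
    from above r+s and ends with the output width q (``None`` when q is
    not supplied).
    """
    if not p > r >= 1:
        raise ValueError(f"need p > r >= 1, got p={p}, r={r}")
    if spec.size_mode == "explicit":
        if not spec.encoder_sizes:
            raise ValueError("explicit mode requires encoder_sizes")
        enc = list(spec.encoder_sizes)
        if enc[-1] != r:
            raise ValueError(
                f"explicit encoder_sizes must end at the bottleneck r={r}"
            )
        if any(e < r for e in enc):
            raise ValueError("encoder sizes must stay >= r")
        dec = None
        if q is not None:
            dec = list(spec.decoder_sizes) if spec.decoder_sizes else []
            if not dec or dec[-1] != q:
                dec = dec + [q]
        return enc, dec

    if spec.size_mode == "shrinkage":
        if spec.shrinkage is None:
            raise ValueError("shrinkage mode requires a shrinkage factor")
        enc = _shrinkage_sizes(p, r, spec.shrinkage)
        dec = None
        if q is not None:
            dec = _shrinkage_sizes(q, r + s, spec.shrinkage)[:-1][::-1] + [q]
        return enc, dec

    # n_layers mode
    enc = _geometric_sizes(p, r, spec.n_in_layers)
    if len(set(enc)) != len(enc) and spec.n_in_layers > 1:
        raise ValueError(
            f"{spec.n_in_layers} encoder layers collapse between p={p} and r={r}"
        )
    dec = None
    if q is not None:
        if q <= r + s:
            raise ValueError(f"need q > r+s for decoder sizing, got q={q}, r+s={r + s}")
        dec = _geometric_sizes(q, r + s, spec.n_out_layers)[:-1][::-1] + [q]
    return enc, dec


def assign_dropout(spec: ArchitectureSpec, n_layers: int) -> list[float]:
    """Per-layer dropout rates, outermost layer first.

    Flat mode repeats ``dropout_max``; graded mode interpolates linearly
    from ``dropout_max`` at the outermost layer down to 0 at the
    bottleneck.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if spec.flat_dropout:
        return [spec.dropout_max] * n_layers
    if n_layers == 1:
        return [0.0]
    return [
        spec.dropout_max * (1.0 - i / (n_layers - 1)) for i in range(n_layers)
    ]


# ---------------------------------------------------------------------------
# The network itself
# ---------------------------------------------------------------------------

_ACTS = {
    "tanh": (np.tanh, lambda h: 1.0 - h * h),
    "relu": (lambda z: np.maximum(z, 0.0), lambda h: (h > 0).astype(float)),
    "linear": (lambda z: z, lambda h: np.ones_like(h)),
}


class AsymmetricAutoencoder:
    """Weights plus forward/backward passes for the X -> E -> Y network.

    ``enc_weights``/``dec_weights`` are lists of ``(W, b)`` pairs.  The
    decoder's first layer takes the concatenation of the embedding and
    the confounder design matrix; its final layer is linear.
    """

    def __init__(
        self,
        enc_weights: list[tuple[np.ndarray, np.ndarray]],
        dec_weights: list[tuple[np.ndarray, np.ndarray]],
        activation: str = "tanh",
        enc_dropout: list[float] | None = None,
        dec_dropout: list[float] | None = None,
    ):
        self.enc_weights = [(np.asarray(W, float), np.asarray(b, float)) for W, b in enc_weights]
        self.dec_weights = [(np.asarray(W, float), np.asarray(b, float)) for W, b in dec_weights]
        self.activation = activation
        self.enc_dropout = enc_dropout or [0.0] * len(self.enc_weights)
        self.dec_dropout = dec_dropout or [0.0] * len(self.dec_weights)

    # -- dimensions ---------------------------------------------------
    @property
    def p(self) -> int:
        return self.enc_weights[0][0].shape[0]

    @property
    def r(self) -> int:
        return self.enc_weights[-1][0].shape[1]

    @property
    def q(self) -> int:
        return self.dec_weights[-1][0].shape[1]

    @property
    def s(self) -> int:
        return self.dec_weights[0][0].shape[0] - self.r

    @classmethod
    def initialize(
        cls,
        p: int,
        q: int,
        s: int,
        enc_sizes: list[int],
        dec_sizes: list[int],
        spec: ArchitectureSpec,
        rng: np.random.Generator,
    ) -> "AsymmetricAutoencoder":
        """Glorot-uniform initialization of all layers."""

        def glorot(fan_in: int, fan_out: int) -> tuple[np.ndarray, np.ndarray]:
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, (fan_in, fan_out)), np.zeros(fan_out)

        enc_dims = [p] + enc_sizes
        dec_dims = [enc_sizes[-1] + s] + dec_sizes
        enc_w = [glorot(a, b) for a, b in zip(enc_dims[:-1], enc_dims[1:])]
        dec_w = [glorot(a, b) for a, b in zip(dec_dims[:-1], dec_dims[1:])]
        enc_do = assign_dropout(spec, len(enc_sizes))
        # decoder hidden layers mirror the schedule (higher dropout toward
        # the outer layer); the linear output layer is never dropped
        dec_do = assign_dropout(spec, max(len(dec_sizes) - 1, 1))[::-1][: len(dec_sizes) - 1] + [0.0]
        if len(dec_sizes) == 1:
            dec_do = [0.0]
        return cls(enc_w, dec_w, spec.activation, enc_do, dec_do)

    # -- passes -------------------------------------------------------
    def encode(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        cache: list | None = None,
    ) -> np.ndarray:
        act, _ = _ACTS[self.activation]
        H = X
        for l, (W, b) in enumerate(self.enc_weights):
            if cache is not None:
                cache.append(H)
            H = act(H @ W + b)
            rate = self.enc_dropout[l] if training else 0.0
            if rate > 0.0:
                mask = (rng.random(H.shape) >= rate) / (1.0 - rate)
                H = H * mask
            if cache is not None:
                cache.append(H)
        return H

    def decode(
        self,
        E: np.ndarray,
        C: np.ndarray | None,
        training: bool = False,
        rng: np.random.Generator | None = None,
        cache: list | None = None,
    ) -> np.ndarray:
        act, _ = _ACTS[self.activation]
        if self.s > 0:
            if C is None:
                raise ValueError(
                    f"model was trained with {self.s} confounder columns; "
                    "a confounder design matrix is required"
                )
            H = np.concatenate([E, C], axis=1)
        else:
            H = E
        last = len(self.dec_weights) - 1
        for l, (W, b) in enumerate(self.dec_weights):
            if cache is not None:
                cache.append(H)
            Z = H @ W + b
            H = Z if l == last else act(Z)
            rate = self.dec_dropout[l] if (training and l != last) else 0.0
            if rate > 0.0:
                mask = (rng.random(H.shape) >= rate) / (1.0 - rate)
                H = H * mask
            if cache is not None:
                cache.append(H)
        return H

    def forward(
        self,
        X: np.ndarray,
        C: np.ndarray | None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        return self.decode(self.encode(X, training, rng), C, training, rng)

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for W, b in self.enc_weights + self.dec_weights:
            out.extend([W, b])
        return out


def build_model(
    arch: ArchitectureSpec,
    p: int,
    q: int,
    s: int = 0,
    rng: np.random.Generator | None = None,
) -> AsymmetricAutoencoder:
    """Construct an untrained network for the given dimensions."""
    if p < 1 or q < 1 or s < 0:
        raise ValueError(f"invalid dimensions p={p}, q={q}, s={s}")
    enc_sizes, dec_sizes = resolve_layer_sizes(p, arch.embed_dim, arch, q=q, s=s)
    rng = rng or np.random.default_rng(0)
    return AsymmetricAutoencoder.initialize(p, q, s, enc_sizes, dec_sizes, arch, rng)


# ---------------------------------------------------------------------------
# Training: backprop + Adam
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _train_batch(
    model: AsymmetricAutoencoder,
    X: np.ndarray,
    Y: np.ndarray,
    C: np.ndarray | None,
    opt: _Adam,
    rng: np.random.Generator,
) -> float:
    """One forward/backward/update on a minibatch; returns the batch loss."""
    _, dact = _ACTS[model.activation]
    n, q = X.shape[0], model.q

    # forward with caches: [input, activated-output] per layer
    enc_cache: list[np.ndarray] = []
    E = model.encode(X, training=True, rng=rng, cache=enc_cache)
    dec_cache: list[np.ndarray] = []
    Yhat = model.decode(E, C, training=True, rng=rng, cache=dec_cache)

    loss = float(np.mean((Yhat - Y) ** 2))
    delta = 2.0 * (Yhat - Y) / (n * q)

    grads_dec: list[tuple[np.ndarray, np.ndarray]] = []
    last = len(model.dec_weights) - 1
    for l in range(last, -1, -1):
        H_in, H_out = dec_cache[2 * l], dec_cache[2 * l + 1]
        W, _ = model.dec_weights[l]
        if l != last:
            # dropout mask is H_out / act(Z); recover via stored ratio
            delta = delta * _dropout_deriv(H_out, model.dec_dropout[l]) * dact(_strip_dropout(H_out, model.dec_dropout[l]))
        gW = H_in.T @ delta
        gb = delta.sum(axis=0)
        grads_dec.append((gW, gb))
        delta = delta @ W.T
    grads_dec.reverse()

    if model.s > 0:
        delta = delta[:, : model.r]  # confounder block is an input, no grad path

    grads_enc: list[tuple[np.ndarray, np.ndarray]] = []
    for l in range(len(model.enc_weights) - 1, -1, -1):
        H_in, H_out = enc_cache[2 * l], enc_cache[2 * l + 1]
        W, _ = model.enc_weights[l]
        delta = delta * _dropout_deriv(H_out, model.enc_dropout[l]) * dact(_strip_dropout(H_out, model.enc_dropout[l]))
        gW = H_in.T @ delta
        gb = delta.sum(axis=0)
        grads_enc.append((gW, gb))
        delta = delta @ W.T
    grads_enc.reverse()

    flat: list[np.ndarray] = []
    for gW, gb in grads_enc + grads_dec:
        flat.extend([gW, gb])
    opt.step(model.parameters(), flat)
    return loss


# Dropout bookkeeping: during the forward pass the cached post-layer
# tensor already includes the (inverted) dropout mask.  For tanh, the
# derivative 1-h^2 must be evaluated on the *pre-dropout* activation; we
# cannot recover it exactly from the masked tensor when units were
# zeroed, but zeroed units carry no gradient anyway (mask factor 0), so
# evaluating the derivative on the masked tensor is exact wherever the
# gradient is nonzero — except for the 1/(1-rate) scaling, handled below.


def _dropout_deriv(H_masked: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0.0:
        return np.ones_like(H_masked)
    return (H_masked != 0.0).astype(float) / (1.0 - rate)


def _strip_dropout(H_masked: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0.0:
        return H_masked
    return H_masked * (1.0 - rate)


@dataclass
class FittedModel:
    architecture: ArchitectureSpec
    net: AsymmetricAutoencoder
    selected_epochs: int
    history: list[float]
    p: int
    q: int
    s: int
    train_config: TrainConfig | None = None


@dataclass
class Embedding:
    values: np.ndarray
    sample_ids: list[str]
    source: FittedModel | None = None

    @property
    def r(self) -> int:
        return self.values.shape[1]


def _design(c: ConfounderTable | None) -> np.ndarray | None:
    if c is None:
        return None
    if c.design is None:
        raise ValueError("confounder table has no design matrix; "
                         "call encode_confounders first")
    return c.design


def _run_epochs(
    model: AsymmetricAutoencoder,
    X: np.ndarray,
    Y: np.ndarray,
    C: np.ndarray | None,
    n_epochs: int,
    cfg: TrainConfig,
    rng: np.random.Generator,
    eval_fn=None,
) -> list[float]:
    opt = _Adam(model.parameters(), cfg.learning_rate)
    n = X.shape[0]
    history: list[float] = []
    for epoch in range(n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Cb = C[idx] if C is not None else None
            loss = _train_batch(model, X[idx], Y[idx], Cb, opt, rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}"
                )
        if eval_fn is not None:
            err = eval_fn(model)
            if not np.isfinite(err):
                raise FloatingPointError(
                    f"non-finite holdout error at epoch {epoch + 1}"
                )
            history.append(err)
            if cfg.patience > 0 and len(history) - (int(np.argmin(history)) + 1) >= cfg.patience:
                break
    return history


def select_epochs(
    x: OmicsMatrix,
    y: OmicsMatrix,
    c: ConfounderTable | None,
    arch: ArchitectureSpec,
    cfg: TrainConfig,
) -> tuple[int, list[float]]:
    """Choose the number of training epochs on a random holdout split.

    Trains on ``1 - holdout_frac`` of the samples for up to
    ``max_epochs``, records the holdout mean squared reconstruction
    error of Y after every epoch, and returns the (1-based) epoch
    minimizing it, earliest epoch on ties.
    """
    X, Y = x.values, y.values
    C = _design(c)
    n = X.shape[0]
    n_hold = int(round(cfg.holdout_frac * n))
    if n_hold < 2 or n - n_hold < 2:
        raise ValueError(
            f"holdout_frac={cfg.holdout_frac} leaves too few samples "
            f"(N={n}, holdout={n_hold})"
        )
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    hold, train = perm[:n_hold], perm[n_hold:]
    Ch = C[hold] if C is not None else None
    Ct = C[train] if C is not None else None

    model = build_model(arch, X.shape[1], Y.shape[1], 0 if C is None else C.shape[1],
                        rng=np.random.default_rng(cfg.seed))

    def holdout_err(m: AsymmetricAutoencoder) -> float:
        return float(np.mean((m.forward(X[hold], Ch) - Y[hold]) ** 2))

    history = _run_epochs(model, X[train], Y[train], Ct,
                          cfg.max_epochs, cfg, rng, eval_fn=holdout_err)
    best = int(np.argmin(history)) + 1
    logger.info("selected %d epochs (holdout MSE %.5f)", best, history[best - 1])
    return best, history


def fit(
    x: OmicsMatrix,
    y: OmicsMatrix,
    c: ConfounderTable | None,
    arch: ArchitectureSpec,
    cfg: TrainConfig,
) -> FittedModel:
    """Epoch selection on a holdout split, then a full-data refit.

    The refit starts from a fresh initialization (seed derived as
    ``cfg.seed + 1``) and runs for exactly the selected number of epochs
    on all N samples.
    """
    best, history = select_epochs(x, y, c, arch, cfg)
    X, Y = x.values, y.values
    C = _design(c)
    s = 0 if C is None else C.shape[1]
    rng = np.random.default_rng(cfg.seed + 1)
    model = build_model(arch, X.shape[1], Y.shape[1], s, rng=rng)
    _run_epochs(model, X, Y, C, best, cfg, rng)
    return FittedModel(
        architecture=arch, net=model, selected_epochs=best, history=history,
        p=X.shape[1], q=Y.shape[1], s=s, train_config=cfg,
    )


def embed(model: FittedModel, x: OmicsMatrix) -> Embedding:
    """Encoder output (dropout disabled); deterministic inference."""
    if x.n_features != model.p:
        raise ValueError(
            f"matrix has {x.n_features} features, model expects {model.p}"
        )
    return Embedding(model.net.encode(x.values), list(x.sample_ids), model)


def reconstruct(
    model: FittedModel, x: OmicsMatrix, c: ConfounderTable | None = None
) -> np.ndarray:
    """Decoder output N x q (dropout disabled)."""
    if x.n_features != model.p:
        raise ValueError(
            f"matrix has {x.n_features} features, model expects {model.p}"
        )
    return model.net.decode(model.net.encode(x.values), _design(c))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: FittedModel, path: str | Path) -> None:
    """Save weights (npz) plus a JSON sidecar describing the run."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (W, b) in enumerate(model.net.enc_weights):
        arrays[f"enc_W{i}"], arrays[f"enc_b{i}"] = W, b
    for i, (W, b) in enumerate(model.net.dec_weights):
        arrays[f"dec_W{i}"], arrays[f"dec_b{i}"] = W, b
    np.savez(path / "weights.npz", **arrays)
    meta = {
        "architecture": {
            k: getattr(model.architecture, k)
            for k in ("embed_dim", "size_mode", "encoder_sizes", "decoder_sizes",
                      "shrinkage", "n_in_layers", "n_out_layers", "dropout_max",
                      "flat_dropout", "activation")
        },
        "train_config": None if model.train_config is None else vars(model.train_config),
        "selected_epochs": model.selected_epochs,
        "history": model.history,
        "p": model.p, "q": model.q, "s": model.s,
        "enc_dropout": model.net.enc_dropout,
        "dec_dropout": model.net.dec_dropout,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> FittedModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    data = np.load(path / "weights.npz")
    enc, dec = [], []
    i = 0
    while f"enc_W{i}" in data:
        enc.append((data[f"enc_W{i}"], data[f"enc_b{i}"]))
        i += 1
    i = 0
    while f"dec_W{i}" in data:
        dec.append((data[f"dec_W{i}"], data[f"dec_b{i}"]))
        i += 1
    arch = ArchitectureSpec(**meta["architecture"])
    net = AsymmetricAutoencoder(
        enc, dec, arch.activation, meta["enc_dropout"], meta["dec_dropout"]
    )
    cfg = TrainConfig(**meta["train_config"]) if meta["train_config"] else None
    return FittedModel(
        architecture=arch, net=net, selected_epochs=meta["selected_epochs"],
        history=meta["history"], p=meta["p"], q=meta["q"], s=meta["s"],
        train_config=cfg,
    )
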