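"""Reading, aligning and preprocessing of paired omics matrices.

The package works on two sample-matched matrices: an input omics type
``X`` (N samples x p features, e.g. miRNA expression) and an output omics
type ``Y`` (N x q, e.g. gene expression), plus an optional table of
clinical confounders (age, sex, batch, receptor status, ...) on the same
samples.  This module provides the light containers for those objects and
the standard preprocessing steps: ``log10(x+1)`` transformation,
coefficient-of-variation / zero-fraction feature filtering, sample
alignment, and design-matrix encoding of the confounders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("crossomics")

__all__ = [
    "OmicsMatrix",
    "ConfounderTable",
    "read_matrix",
    "write_matrix",
    "read_confounders",
    "log_transform",
    "filter_features",
    "align_samples",
    "encode_confounders",
]


@dataclass
class OmicsMatrix:
    """A samples-by-features numeric matrix with string identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, d = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"values has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if d != len(self.feature_ids):
            raise ValueError(
                f"values has {d} columns but {len(self.feature_ids)} feature ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.feature_ids)) != d:
            raise ValueError("duplicate feature identifiers")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OmicsMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
        )


@dataclass
class ConfounderTable:
    """Per-sample covariates plus their numeric design encoding.

    ``columns`` holds the raw covariates (numeric or categorical pandas
    Series); ``design`` is populated by :func:`encode_confounders` with
    standardized numeric columns and reference-level indicator columns.
    """

    frame: pd.DataFrame
    design: np.ndarray | None = None
    design_names: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    @property
    def n_design(self) -> int:
        return 0 if self.design is None else self.design.shape[1]


def _detect_sep(path: Path) -> str:
    header = path.open("r").readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_matrix(path: str | Path, orientation: str = "samples-in-rows") -> OmicsMatrix:
    """Read a delimited numeric table into an :class:`OmicsMatrix`.

    The file must have one header row and one leading identifier column.
    TSV is the default; comma delimiting is auto-detected from the header
    line.  ``orientation`` says which axis the on-disk rows represent; the
    returned matrix is always samples x features.
    """
    path = Path(path)
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().to_numpy().any():
        r, c = np.argwhere(bad.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if df.index.duplicated().any():
        raise ValueError(f"duplicate row identifiers in {path}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate column identifiers in {path}")
    if orientation == "features-in-rows":
        bad = bad.T
    return OmicsMatrix.from_frame(bad)


def write_matrix(m: OmicsMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write samples-in-rows with full float precision (round-trip safe)."""
    m.to_frame().to_csv(Path(path), sep=sep, float_format="%.17g")


def read_confounders(path: str | Path) -> ConfounderTable:
    """Read a confounder table (first column = sample id).

    Column types are inferred: a column that parses fully as numeric is
    numeric, anything else is treated as categorical.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample identifiers in {path}")
    if df.isna().to_numpy().any():
        raise ValueError(f"missing values in confounder table {path}")
    out = {}
    for col in df.columns:
        num = pd.to_numeric(df[col], errors="coerce")
        out[col] = num if not num.isna().any() else df[col].astype(str)
    return ConfounderTable(frame=pd.DataFrame(out, index=df.index.astype(str)))


def log_transform(m: OmicsMatrix, offset: float = 1.0) -> OmicsMatrix:
    """Elementwise ``log10(v + offset)``; shape and identifiers unchanged."""
    if np.any(m.values < 0):
        i, j = np.argwhere(m.values < 0)[0]
        raise ValueError(
            f"negative value {m.values[i, j]} at sample {m.sample_ids[i]!r}, "
            f"feature {m.feature_ids[j]!r}; log transform requires values >= 0"
        )
    return OmicsMatrix(
        np.log10(m.values + offset), list(m.sample_ids), list(m.feature_ids)
    )


def filter_features(
    m: OmicsMatrix, cv_min: float = 0.0, max_zero_frac: float = 1.0
) -> OmicsMatrix:
    """Keep features with CV (= sd/mean) > ``cv_min`` and zero fraction
    < ``max_zero_frac``, evaluated on the matrix as given.

    Features with mean exactly 0 have an undefined CV and are excluded
    with a logged warning (on nonnegative expression data these are the
    all-zero features).  Feature order is preserved, so the filter is
    idempotent.
    """
    if cv_min < 0:
        raise ValueError("cv_min must be >= 0")
    if not 0.0 <= max_zero_frac <= 1.0:
        raise ValueError("max_zero_frac must be in [0, 1]")
    vals = m.values
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=1)
    zero_frac = (vals == 0).mean(axis=0)
    keep = np.zeros(m.n_features, dtype=bool)
    for j in range(m.n_features):
        if means[j] == 0:
            logger.warning(
                "feature %r has mean 0 (undefined CV); excluded", m.feature_ids[j]
            )
            continue
        keep[j] = (sds[j] / means[j] > cv_min) and (zero_frac[j] < max_zero_frac)
    ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return OmicsMatrix(vals[:, keep], list(m.sample_ids), ids)


def align_samples(
    x: OmicsMatrix,
    y: OmicsMatrix,
    c: ConfounderTable | None = None,
) -> tuple[OmicsMatrix, OmicsMatrix, ConfounderTable | None]:
    """Restrict all inputs to the common samples, in one shared order.

    The shared order is the order of appearance in ``x``.
    """
    common = set(x.sample_ids) & set(y.sample_ids)
    if c is not None:
        common &= set(c.sample_ids)
    if len(common) < 2:
        sizes = f"x has {x.n_samples}, y has {y.n_samples}"
        if c is not None:
            sizes += f", confounders have {len(c.sample_ids)}"
        raise ValueError(
            f"need >= 2 common sample ids, found {len(common)} ({sizes})"
        )
    order = [s for s in x.sample_ids if s in common]

    def take(m: OmicsMatrix) -> OmicsMatrix:
        idx = [m.sample_ids.index(s) for s in order]
        return OmicsMatrix(m.values[idx], order, list(m.feature_ids))

    cx = None
    if c is not None:
        cx = ConfounderTable(frame=c.frame.loc[order].copy())
        if c.design is not None:
            idx = [c.sample_ids.index(s) for s in order]
            cx.design = c.design[idx]
            cx.design_names = list(c.design_names)
    return take(x), take(y), cx


def encode_confounders(t: ConfounderTable) -> ConfounderTable:
    """Build the numeric design matrix used at the bottleneck.

    Numeric columns are centered and scaled to unit (sample) standard
    deviation.  Categorical columns become indicator columns with the
    first sorted level dropped as reference, so no constant column is fed
    to the decoder.
    """
    if t.frame.isna().to_numpy().any():
        raise ValueError("confounder table has missing values")
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in t.frame.columns:
        s = t.frame[name]
        if pd.api.types.is_numeric_dtype(s):
            v = s.to_numpy(dtype=float)
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"numeric confounder {name!r} is constant")
            cols.append((v - v.mean()) / sd)
            names.append(str(name))
        else:
            levels = sorted(s.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(
                    f"categorical confounder {name!r} has a single level"
                )
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{name}={lev}")
    out = ConfounderTable(frame=t.frame.copy())
    out.design = np.column_stack(cols)
    out.design_names = names
    return out
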