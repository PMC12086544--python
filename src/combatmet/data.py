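"""Core data containers and transforms for methylation batch correction.

Methylation levels are proportions ("beta-values") in [0, 1]: the fraction of
methylated alleles at a locus, estimated from a microarray or from bisulfite
sequencing counts.  The beta likelihood used throughout the package is
undefined at the boundaries, so matrices are *squeezed* into the open
interval at load time; two standard squeezes are provided.

Containers are thin wrappers around :class:`pandas.DataFrame` /
:class:`numpy.ndarray` that enforce the invariants downstream modules rely
on (open-interval values, consistent sample metadata, non-confounded
designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "BetaValueMatrix",
    "CountMatrixPair",
    "SampleDesign",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_design",
    "beta_to_m",
    "m_to_beta",
    "squeeze_proportions",
    "counts_to_beta",
]

DEFAULT_EPS = 1e-6


def squeeze_proportions(values, mode="clip", eps=DEFAULT_EPS, n=None):
    """Move proportions in [0, 1] into the open interval (0, 1).

    Parameters
    ----------
    values : array-like
        Proportions in [0, 1]; NaNs pass through.
    mode : {"clip", "smithson"}
        ``clip`` clips to [eps, 1 - eps] (idempotent, scale-free).
        ``smithson`` applies the Smithson-Verkuilen compression
        ``(y * (n - 1) + 0.5) / n`` with ``n`` the sample count.
    eps : float
        Clip margin for ``mode="clip"``.
    n : int, optional
        Sample count for ``mode="smithson"``; defaults to the size of the
        last axis.

    Returns
    -------
    numpy.ndarray
        Squeezed values, same shape as input.
    """
    values = np.asarray(values, dtype=float)
    if mode == "clip":
        return np.clip(values, eps, 1.0 - eps)
    if mode == "smithson":
        if n is None:
            n = values.shape[-1] if values.ndim else 1
        if n < 1:
            raise ValueError("smithson squeeze needs n >= 1")
        return (values * (n - 1) + 0.5) / n
    raise ValueError(f"unknown squeeze mode: {mode!r}")


def beta_to_m(values):
    """Logit-transform beta-values to M-values, ``log(y / (1 - y))``.

    Values must lie strictly in (0, 1); squeeze boundary cells first.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (np.any(finite <= 0.0) or np.any(finite >= 1.0)):
        raise ValueError("beta_to_m requires values strictly in (0, 1); squeeze first")
    return logit(arr)


def m_to_beta(values):
    """Inverse-logit M-values back to beta-values in (0, 1)."""
    return expit(np.asarray(values, dtype=float))


@dataclass
class BetaValueMatrix:
    """Features x samples matrix of methylation proportions.

    ``values`` is an F x S float array; after construction with
    ``squeeze=True`` every finite cell lies strictly in (0, 1).
    ``squeezed_mask`` records which cells were moved off a boundary.
    """

    feature_ids: list
    sample_ids: list
    values: np.ndarray
    squeezed_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if len(self.feature_ids) != len(set(self.feature_ids)):
            raise ValueError("duplicate feature IDs")
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample IDs")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )

    @property
    def shape(self):
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df, squeeze_mode="clip", eps=DEFAULT_EPS):
        """Build from a features-x-samples DataFrame, validating the domain."""
        values = df.to_numpy(dtype=float)
        finite = np.isfinite(values)
        bad = finite & ((values < 0.0) | (values > 1.0))
        if bad.any():
            f, s = np.argwhere(bad)[0]
            raise ValueError(
                f"beta-value out of [0, 1] at feature {df.index[f]!r}, "
                f"sample {df.columns[s]!r}: {values[f, s]}"
            )
        on_boundary = finite & ((values == 0.0) | (values == 1.0))
        squeezed = squeeze_proportions(
            values, mode=squeeze_mode, eps=eps, n=values.shape[1]
        )
        if squeeze_mode == "clip":
            # clipping only alters boundary-adjacent cells
            changed = on_boundary | (finite & (squeezed != values))
        else:
            changed = finite
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=squeezed,
            squeezed_mask=changed,
        )

    def to_dataframe(self):
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def m_values(self):
        """M-value (logit) view of the matrix as an F x S array."""
        return beta_to_m(self.values)


@dataclass
class CountMatrixPair:
    """Paired coverage / methylated-count matrices from bisulfite sequencing."""

    feature_ids: list
    sample_ids: list
    coverage: np.ndarray
    methylated: np.ndarray

    def __post_init__(self):
        self.coverage = np.asarray(self.coverage)
        self.methylated = np.asarray(self.methylated)
        if self.coverage.shape != self.methylated.shape:
            raise ValueError("coverage and methylated shapes differ")
        if self.coverage.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("count matrix shape inconsistent with IDs")
        if np.any(self.coverage < 0) or np.any(self.methylated < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.methylated > self.coverage):
            raise ValueError("methylated count exceeds coverage")

    @property
    def shape(self):
        return self.coverage.shape

    def beta_values(self, squeeze_mode="clip", eps=DEFAULT_EPS):
        """Beta-values methylated/coverage as a squeezed :class:`BetaValueMatrix`.

        Zero-coverage cells become NaN.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(
                self.coverage > 0, self.methylated / np.maximum(self.coverage, 1), np.nan
            )
        df = pd.DataFrame(raw, index=self.feature_ids, columns=self.sample_ids)
        return BetaValueMatrix.from_dataframe(df, squeeze_mode=squeeze_mode, eps=eps)


def counts_to_beta(counts, squeeze_mode="clip", eps=DEFAULT_EPS):
    """Convenience wrapper: :meth:`CountMatrixPair.beta_values`."""
    return counts.beta_values(squeeze_mode=squeeze_mode, eps=eps)


@dataclass
class SampleDesign:
    """Per-sample batch / condition labels plus optional numeric covariates.

    Batches are processing groups (runs, plates, platforms); the condition is
    the biological contrast of interest.  Validation enforces the rules the
    adjustment depends on: every batch used for precision estimation has at
    least two samples, and batch must not be perfectly confounded with
    condition (the joint design matrix must have full column rank).
    """

    sample_ids: list
    batch: np.ndarray
    condition: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.batch = np.asarray(self.batch)
        self.condition = np.asarray(self.condition)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs in design")
        if len(self.batch) != n or len(self.condition) != n:
            raise ValueError("batch/condition length mismatch with sample IDs")
        self.batch_levels = [str(b) for b in pd.unique(self.batch.astype(str))]
        self.condition_levels = [str(c) for c in pd.unique(self.condition.astype(str))]
        self.batch = self.batch.astype(str)
        self.condition = self.condition.astype(str)
        counts = pd.Series(self.batch).value_counts()
        self.batch_sizes = {b: int(counts[b]) for b in self.batch_levels}
        for b, c in self.batch_sizes.items():
            if c < 2:
                raise ValueError(
                    f"batch {b!r} has {c} sample(s); precision estimation requires "
                    "at least two samples per batch"
                )
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates)
            if len(self.covariates) != n:
                raise ValueError("covariate table length mismatch")
        self._check_rank()

    def _check_rank(self):
        x = self.full_design_matrix()
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(
                "design is rank-deficient: batch and condition/covariates are confounded"
            )

    @property
    def n_samples(self):
        return len(self.sample_ids)

    @property
    def n_batches(self):
        return len(self.batch_levels)

    def batch_sizes_array(self):
        """Batch sizes n_i ordered as ``batch_levels``."""
        return np.array([self.batch_sizes[b] for b in self.batch_levels], dtype=float)

    def batch_index(self):
        """Integer batch code per sample, ordered as ``batch_levels``."""
        lut = {b: i for i, b in enumerate(self.batch_levels)}
        return np.array([lut[b] for b in self.batch], dtype=int)

    def batch_onehot(self):
        """S x N_B one-hot batch indicator matrix."""
        idx = self.batch_index()
        z = np.zeros((self.n_samples, self.n_batches))
        z[np.arange(self.n_samples), idx] = 1.0
        return z

    def condition_matrix(self):
        """S x (L-1) treatment-coded condition indicators (first level baseline)."""
        cols = []
        for lev in self.condition_levels[1:]:
            cols.append((self.condition == lev).astype(float))
        if not cols:
            return np.zeros((self.n_samples, 0))
        return np.column_stack(cols)

    def covariate_matrix(self):
        """S x C numeric covariate matrix (empty if none)."""
        if self.covariates is None or self.covariates.shape[1] == 0:
            return np.zeros((self.n_samples, 0))
        return self.covariates.to_numpy(dtype=float)

    def biological_matrix(self):
        """Condition indicators plus covariates: the X_j block of the mean model."""
        return np.column_stack([self.condition_matrix(), self.covariate_matrix()])

    def full_design_matrix(self):
        """Intercept + condition + covariates + batch contrasts (rank check)."""
        batch_contrasts = self.batch_onehot()[:, 1:]
        return np.column_stack(
            [np.ones(self.n_samples), self.biological_matrix(), batch_contrasts]
        )

    @classmethod
    def from_dataframe(cls, df):
        """Build from a table with columns sample, batch, condition [, covars]."""
        required = {"sample", "batch", "condition"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        extra = [c for c in df.columns if c not in required]
        cov = df[extra].apply(pd.to_numeric) if extra else None
        return cls(
            sample_ids=df["sample"].tolist(),
            batch=df["batch"].to_numpy(),
            condition=df["condition"].to_numpy(),
            covariates=cov,
        )

    def to_dataframe(self):
        df = pd.DataFrame(
            {"sample": self.sample_ids, "batch": self.batch, "condition": self.condition}
        )
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df


def _read_table(path):
    # TSV default; fall back to comma when the header has no tabs
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_beta_matrix(path, squeeze_mode="clip", eps=DEFAULT_EPS):
    """Read a features x samples beta-value table (TSV, comma auto-detected)."""
    try:
        df = _read_table(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ValueError(f"could not parse beta-value table {path}: {exc}") from exc
    df = df.apply(pd.to_numeric)
    return BetaValueMatrix.from_dataframe(df, squeeze_mode=squeeze_mode, eps=eps)


def write_beta_matrix(matrix, path):
    """Write a beta-value matrix as TSV with full double precision."""
    if len(matrix.feature_ids) == 0:
        raise ValueError("refusing to write a matrix with no features")
    matrix.to_dataframe().to_csv(path, sep="\t", float_format="%.17g")


def read_design(path):
    """Read a sample-design table (columns sample, batch, condition, covariates)."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    return SampleDesign.from_dataframe(df)


def write_design(design, path):
    design.to_dataframe().to_csv(path, sep="\t", index=False)


def read_count_pair(cov_path, meth_path):
    """Read paired coverage / methylated matrices, checking ID agreement."""
    cov = _read_table(cov_path).apply(pd.to_numeric)
    meth = _read_table(meth_path).apply(pd.to_numeric)
    if list(cov.index) != list(meth.index) or list(cov.columns) != list(meth.columns):
        raise ValueError("coverage and methylated tables disagree on IDs")
    return CountMatrixPair(
        feature_ids=[str(i) for i in cov.index],
        sample_ids=[str(c) for c in cov.columns],
        coverage=cov.to_numpy(dtype=float).astype(np.int64),
        methylated=meth.to_numpy(dtype=float).astype(np.int64),
    )
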