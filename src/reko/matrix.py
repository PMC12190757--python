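"""Standardized feature matrices.

Everything downstream (reflection, knockoff sampling, filtering) assumes the
feature matrix is column-centered with unit sample variance. The sample
covariance convention is divisor ``n - 1`` on centered columns, applied
consistently across the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["FeatureMatrix", "standardize", "sample_cov"]

#: divisor convention used for every sample (co)variance in the package
COV_DDOF = 1


def sample_cov(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Sample covariance matrix between columns of ``a`` and ``b`` (divisor n-1).

    Returns the full cross-covariance matrix ``cov(a_j, b_k)`` of shape
    ``(a.shape[1], b.shape[1])``; with ``b=None`` the auto-covariance of ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = a if b is None else np.asarray(b, dtype=float)
    n = a.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    return ac.T @ bc / (n - COV_DDOF)


@dataclass
class FeatureMatrix:
    """A standardized n x p feature matrix with provenance of the transform.

    Attributes
    ----------
    values : (n, p) float array, columns centered and scaled to unit sample
        variance (ddof=1).
    feature_names : p column identifiers.
    col_means, col_scales : the transform applied to the raw input, so that
        ``raw = values * col_scales + col_means``.
    """

    values: np.ndarray
    feature_names: list[str]
    standardized: bool = True
    col_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_scales: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} names for {p} columns"
            )
        if self.col_means is None:
            self.col_means = np.zeros(p)
        if self.col_scales is None:
            self.col_scales = np.ones(p)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def standardize(raw: np.ndarray, names: Sequence[str] | None = None) -> FeatureMatrix:
    """Center and scale columns to mean 0, sample variance 1 (ddof=1).

    Parameters
    ----------
    raw : (n, p) numeric array, n >= 2, p >= 2.
    names : optional column identifiers; defaults to ``f1..fp``.

    Raises
    ------
    ValueError
        on non-finite entries, fewer than two samples or features, or any
        constant (zero-variance) column — the offending column is named.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-dimensional samples x features matrix")
    n, p = raw.shape
    if names is None:
        names = [f"f{j + 1}" for j in range(p)]
    names = [str(x) for x in names]
    if len(names) != p:
        raise ValueError(f"{len(names)} names for {p} columns")
    if n < 2:
        raise ValueError("need at least 2 samples to standardize")
    if p < 2:
        raise ValueError("need at least 2 features (reflection is undefined for p=1)")
    if not np.all(np.isfinite(raw)):
        bad = np.argwhere(~np.isfinite(raw))[0]
        raise ValueError(
            f"non-finite entry at row {bad[0] + 1}, column {names[bad[1]]!r}"
        )
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=COV_DDOF)
    # relative threshold: a column of identical values can leave an O(eps)
    # residual spread after the mean subtraction
    const = np.flatnonzero(sds <= 1e-12 * np.maximum(1.0, np.abs(means)))
    if const.size:
        raise ValueError(
            "constant column(s): " + ", ".join(names[j] for j in const)
        )
    values = (raw - means) / sds
    return FeatureMatrix(
        values=values,
        feature_names=list(names),
        standardized=True,
        col_means=means,
        col_scales=sds,
    )
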