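"""Microarray normalization protocols applied before association screening.

Two protocols are provided. ``three_step`` (single-colour Agilent style):
normexp background correction with offset 50 per array, quantile
normalization between arrays, then log2. ``quantile_only`` (summarized
BeadStudio style): quantile normalization, with log2 applied only when the
input looks unlogged.

The normexp model treats each observed intensity as X = B + S with Gaussian
background B ~ N(mu, sigma^2) and exponential signal S with mean alpha; the
corrected value is the posterior mean E[S | X = x] plus a small offset that
keeps corrected intensities away from zero before the log step. Parameters
are estimated per array by method of moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from agewire.errors import ConfigurationError, InputError

__all__ = [
    "NormexpParams",
    "estimate_normexp_params",
    "normexp_correct",
    "quantile_normalize",
    "log2_transform",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class NormexpParams:
    """Background mean/SD and exponential signal mean, in intensity units."""

    mu: float
    sigma: float
    alpha: float

    def validate(self) -> None:
        if not self.sigma > 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")
        if not self.alpha > 0:
            raise ConfigurationError(f"alpha must be > 0, got {self.alpha}")


def estimate_normexp_params(column: np.ndarray) -> NormexpParams:
    """Method-of-moments fit of the normal + exponential convolution.

    The exponential component carries all the skewness, so its mean is
    recovered from the third central moment, alpha = (m3 / 2)^(1/3); then
    mu = mean - alpha and sigma^2 = max(var - alpha^2, eps). When the third
    moment is non-positive the convolution fit is infeasible and a
    conservative fallback (mu = min, sigma = SD/10, alpha = mean - min) is
    used with a warning.
    """
    x = np.asarray(column, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise InputError(f"normexp fit needs >= 10 finite values, got {x.size}")
    if np.any(x < 0):
        raise InputError("normexp fit requires non-negative intensities")
    var = float(np.var(x))
    if var <= 0:
        raise InputError("normexp fit requires positive variance (constant column)")

    m3 = float(np.mean((x - x.mean()) ** 3))
    if m3 <= 0:
        warnings.warn(
            "non-positive third central moment; using fallback normexp parameters",
            stacklevel=2,
        )
        mu = float(x.min())
        sigma = float(np.sqrt(var)) / 10.0
        alpha = max(float(x.mean()) - mu, sigma)
        return NormexpParams(mu=mu, sigma=sigma, alpha=alpha)

    alpha = (m3 / 2.0) ** (1.0 / 3.0)
    mu = float(x.mean()) - alpha
    eps = max(var * 1e-6, 1e-12)
    sigma = float(np.sqrt(max(var - alpha**2, eps)))
    return NormexpParams(mu=mu, sigma=sigma, alpha=alpha)


def normexp_correct(
    column: np.ndarray, params: NormexpParams, offset: float = 50.0
) -> np.ndarray:
    """Posterior-mean background correction plus offset.

    For each x: with mu_sf = x - mu - sigma^2/alpha,

        E[S | X = x] = mu_sf + sigma * phi(mu_sf/sigma) / Phi(mu_sf/sigma)

    evaluated through log-pdf/log-cdf so the Mills-ratio term stays finite
    for arbitrarily negative mu_sf/sigma. Output is strictly positive for
    offset >= 0.
    """
    params.validate()
    x = np.asarray(column, dtype=float)
    mu_sf = x - params.mu - params.sigma**2 / params.alpha
    z = mu_sf / params.sigma
    # phi(z)/Phi(z) via logs: stable for z << 0 where both terms underflow.
    ratio = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    posterior_mean = mu_sf + params.sigma * ratio
    posterior_mean = np.maximum(posterior_mean, np.finfo(float).tiny)
    return posterior_mean + offset


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column (array) onto the common reference distribution.

    The reference is the row-wise mean of all columns' order statistics;
    each value is replaced by the reference value at its within-column rank.
    Ties receive the mean of the tied reference values (average-rank
    convention), which keeps the map deterministic.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise InputError("quantile normalization requires a complete, finite matrix")
    n_rows, n_cols = values.shape
    if n_cols < 2:
        warnings.warn("single-column matrix: quantile normalization is a no-op", stacklevel=2)
        return matrix.copy()

    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(n_rows, dtype=float)
    for j in range(n_cols):
        ranks = stats.rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; a non-positive entry is an error naming gene and sample."""
    values = matrix.to_numpy(dtype=float)
    bad = np.argwhere(values <= 0)
    if bad.size:
        i, j = bad[0]
        raise InputError(
            f"log2 transform requires positive values; "
            f"gene {matrix.index[i]!r}, sample {matrix.columns[j]!r} has {values[i, j]}"
        )
    return pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)


#: heuristic: summarized intensities above this look unlogged
_UNLOGGED_MAX = 100.0


def preprocess_cohort(raw: pd.DataFrame, protocol: str) -> pd.DataFrame:
    """Run one of the two cohort normalization protocols.

    ``three_step``: per-column normexp correction (offset 50), quantile
    normalization between arrays, log2. ``quantile_only``: quantile
    normalization of already-summarized intensities; log2 is applied only
    when the matrix maximum exceeds 100 (i.e. the input looks unlogged).
    """
    values = raw.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise InputError("raw intensities must be finite and non-negative")
    if raw.shape[1] < 2:
        raise InputError("preprocessing requires >= 2 samples")

    if protocol == "three_step":
        corrected = np.empty_like(values)
        for j in range(values.shape[1]):
            params = estimate_normexp_params(values[:, j])
            corrected[:, j] = normexp_correct(values[:, j], params, offset=50.0)
        frame = pd.DataFrame(corrected, index=raw.index, columns=raw.columns)
        return log2_transform(quantile_normalize(frame))
    if protocol == "quantile_only":
        normalized = quantile_normalize(raw)
        if normalized.to_numpy().max() > _UNLOGGED_MAX:
            return log2_transform(normalized)
        return normalized
    raise ConfigurationError(
        f"unknown protocol {protocol!r}; expected 'three_step' or 'quantile_only'"
    )
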