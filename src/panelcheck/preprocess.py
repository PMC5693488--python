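"""Median-of-ratios normalization and the closed-form NB variance-stabilizing transform.

This is the input contract of the classifier: raw counts are scaled by
per-sample size factors (the median-of-ratios estimator popularized by DESeq)
and then passed through the variance-stabilizing transform for the
negative-binomial mean-variance relation ``var = mu + alpha*mu**2``,

    vst(q) = (2/sqrt(alpha)) * asinh(sqrt(alpha * q)),        alpha > 0
    vst(q) = 2 * sqrt(q),                                     alpha = 0,

which is the exact stabilizing integral for that variance function and the
continuous alpha -> 0 limit, respectively. A single pooled dispersion is used
in place of a fitted per-gene trend: the transform is treated as a fixed
preprocessing contract, not as an inference step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EstimationError

__all__ = [
    "estimate_size_factors",
    "estimate_dispersion",
    "vst_transform",
    "vst_inverse",
]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each gene with strictly positive counts in every sample the ratio of
    the sample's count to the gene's geometric mean is formed; a sample's size
    factor is the median of these ratios. Genes with any zero are excluded
    (the standard convention — the geometric mean would vanish).

    Raises
    ------
    ValueError
        Fewer than two samples.
    EstimationError
        No gene has all-positive counts.
    """
    if counts.shape[1] < 2:
        raise ValueError("size-factor estimation needs at least 2 samples")
    x = counts.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    positive = np.all(x > 0, axis=1)
    if not positive.any():
        raise EstimationError("no gene has positive counts in all samples")
    logx = np.log(x[positive])
    log_ratio = logx - logx.mean(axis=1, keepdims=True)
    log_s = np.median(log_ratio, axis=0)
    log_s -= log_s.mean()  # geometric mean 1
    return pd.Series(np.exp(log_s), index=counts.columns, name="size_factor")


def estimate_dispersion(counts: pd.DataFrame, size_factors: pd.Series) -> float:
    """Pooled method-of-moments NB dispersion on normalized counts.

    alpha_hat = max(0, mean over expressed genes of (var - mean) / mean^2),
    with per-gene sample means and variances (ddof=1) taken across samples
    after size-factor normalization. Degenerate data yield 0.
    """
    if counts.shape[1] < 2:
        raise ValueError("dispersion estimation needs at least 2 samples")
    q = counts.to_numpy(dtype=float) / size_factors.to_numpy(dtype=float)
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    expressed = m > 0
    if not expressed.any():
        return 0.0
    ratio = (v[expressed] - m[expressed]) / m[expressed] ** 2
    return float(max(0.0, ratio.mean()))


def vst_transform(counts, size_factors=None, alpha: float = 0.0):
    """Apply the closed-form NB variance-stabilizing transform.

    Accepts a DataFrame (genes x samples, divided column-wise by
    ``size_factors``) or a bare array of counts (``size_factors`` ignored
    unless given as a matching array). Strictly increasing in the normalized
    count for every ``alpha >= 0``, with vst(0) = 0.
    """
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    if isinstance(counts, pd.DataFrame):
        q = counts.to_numpy(dtype=float)
        if size_factors is not None:
            q = q / np.asarray(size_factors, dtype=float)
        out = _vst(q, alpha)
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    q = np.asarray(counts, dtype=float)
    if size_factors is not None:
        q = q / np.asarray(size_factors, dtype=float)
    return _vst(q, alpha)


def _vst(q: np.ndarray, alpha: float) -> np.ndarray:
    if np.any(q < 0):
        raise ValueError("counts must be nonnegative")
    if alpha == 0.0:
        return 2.0 * np.sqrt(q)
    sa = np.sqrt(alpha)
    return (2.0 / sa) * np.arcsinh(sa * np.sqrt(q))


def vst_inverse(values, alpha: float = 0.0):
    """Invert :func:`vst_transform` back to the normalized-count scale."""
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    v = np.asarray(values, dtype=float)
    if alpha == 0.0:
        return (v / 2.0) ** 2
    sa = np.sqrt(alpha)
    return np.sinh(v * sa / 2.0) ** 2 / alpha
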