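"""Shared correlation helpers.

Partial Pearson correlation by residual regression: both variables are
regressed on a common covariate design (plus intercept) with ordinary least
squares, and the Pearson correlation of the residuals is tested on
``df = n - 2 - q`` degrees of freedom, where ``q`` is the number of covariate
columns.  With an empty design this reduces to the plain Pearson test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["batch_design", "partial_pearson"]


def batch_design(batches) -> np.ndarray:
    """Dummy-code a categorical covariate, dropping the first level.

    Returns an (n, q) float array with q = number of levels - 1; a single
    level yields an empty design (plain correlation).
    """
    batches = np.asarray(batches)
    levels = np.unique(batches)
    return np.column_stack([(batches == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(batches), 0))


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_pearson(x, y, covariates: np.ndarray | None = None):
    """Partial Pearson correlation of ``x`` and ``y`` given ``covariates``.

    Parameters
    ----------
    x, y : array-like, shape (n,)
    covariates : (n, q) array or None
        Covariate columns; an intercept is always included.

    Returns
    -------
    (r, p) : floats
        ``(nan, nan)`` when either residual vector has (numerically) zero
        variance, so degenerate inputs are flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    q = 0 if covariates is None or covariates.size == 0 else covariates.shape[1]
    design = np.column_stack([np.ones(n)] + ([covariates] if q else []))
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    scale = max(np.abs(x).max(), 1.0) * max(np.abs(y).max(), 1.0)
    if sx * sy <= 1e-12 * scale or n - 2 - q <= 0:
        return np.nan, np.nan
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - q
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)
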