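"""Pearson correlation panels between splice-variant expression and
clinical covariates.

Each panel reports the product-moment r, its square, a two-sided p-value
from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, and the ordinary
least-squares line. Pairs with a missing member are dropped listwise per
panel and the dropped count is carried in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "UndefinedCorrelationError",
    "pearson",
    "vectors_with_exact_r",
    "correlation_panel",
]


class UndefinedCorrelationError(ValueError):
    """Zero variance in one of the vectors."""


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n_dropped: int = 0


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with listwise deletion of incomplete pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must be the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance")
    r, p = stats.pearsonr(x, y)
    ols = stats.linregress(x, y)
    return CorrelationResult(n, float(r), float(r) ** 2, float(p),
                             float(ols.slope), float(ols.intercept), n_dropped)


def vectors_with_exact_r(r: float, n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Construct an (x, y) pair whose sample Pearson correlation equals
    ``r`` exactly (up to floating point), by orthogonalization."""
    if not -1 <= r <= 1:
        raise ValueError("r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x  # orthogonal to x
    z /= z.std()
    y = r * x + np.sqrt(1 - r**2) * z
    return x, y


def correlation_panel(
    expr: pd.DataFrame,
    covariates: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
) -> pd.DataFrame:
    """Run Pearson panels.

    ``pairs`` lists ``(group, expression_column, covariate_column)``; the
    two frames are joined on ``sample_id``. Output columns: group, x, y, n,
    n_dropped, r, r_squared, p_value, slope, intercept.
    """
    merged = expr.merge(covariates, on="sample_id", suffixes=("", "_cov"))
    rows = []
    for group, xcol, ycol in pairs:
        sub = merged[merged["group"] == group]
        res = pearson(sub[xcol], sub[ycol])
        rows.append(
            {
                "group": group, "x": xcol, "y": ycol,
                "n": res.n, "n_dropped": res.n_dropped,
                "r": res.r, "r_squared": res.r_squared, "p_value": res.p_value,
                "slope": res.slope, "intercept": res.intercept,
            }
        )
    return pd.DataFrame(rows)
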