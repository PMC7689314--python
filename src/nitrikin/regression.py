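"""Simple covariate regressions of maximum nitrification rate on
environmental predictors (soil pH, log10 amoA gene abundance)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["RegressionResult", "covariate_regression"]


@dataclass
class RegressionResult:
    """Ordinary least-squares fit of a response on one covariate."""

    response: str
    covariate: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def covariate_regression(
    points: Sequence[tuple[float, float]],
    *,
    response: str = "Vmax",
    covariate: str = "covariate",
) -> RegressionResult:
    """OLS of response on covariate with slope, R^2 and a two-sided slope p.

    ``points`` are (covariate value, response value) pairs; needs >= 3 points
    and a non-constant covariate.  A constant response yields slope 0 and
    R^2 = 0 (nothing to explain).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (covariate, response) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.all(x == x[0]):
        raise ValueError("covariate is constant; slope is undefined")
    if np.all(y == y[0]):
        return RegressionResult(
            response=response, covariate=covariate,
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0,
            n=len(x),
        )
    res = stats.linregress(x, y)
    return RegressionResult(
        response=response,
        covariate=covariate,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )
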