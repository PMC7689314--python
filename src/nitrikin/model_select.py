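"""Model selection between Michaelis-Menten and Haldane fits.

The decision procedure mirrors standard nonlinear-regression practice in R:
Gaussian AIC for each fit (profile likelihood, with the error variance counted
as a parameter, so AIC differences are comparable across the two laws), an
extra-sum-of-squares F-test for the nested pair, and a rule that adopts the
three-parameter Haldane model only when it both lowers AIC and improves the
fit significantly (p < alpha, default alpha = 0.1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .kinetics import KineticFit

__all__ = [
    "ModelComparison",
    "aic_from_rss",
    "gaussian_aic",
    "extra_ss_ftest",
    "select_model",
]


@dataclass
class ModelComparison:
    """Paired MM/Haldane AICs, nested F statistic and the selected model for
    one (ecosystem, taxon) population.  ``haldane_failed`` marks populations
    where the Haldane fit did not converge (blank comparison entries)."""

    ecosystem_id: str
    taxon: str
    aic_mm: float
    aic_haldane: float
    f_stat: float
    p_value: float
    selected: str
    haldane_failed: bool


def aic_from_rss(rss: float, n: int, n_params: int) -> float:
    """Gaussian AIC from a residual sum of squares.

    AIC = n ln(2 pi) + n ln(rss / n) + n + 2 (n_params + 1); the "+1" counts
    the estimated error variance.
    """
    if rss <= 0:
        raise ValueError("rss must be positive (degenerate likelihood at rss = 0)")
    if n <= 0:
        raise ValueError("n must be positive")
    return n * math.log(2 * math.pi) + n * math.log(rss / n) + n + 2 * (n_params + 1)


def gaussian_aic(fit: "KineticFit") -> float:
    """AIC of a converged kinetic fit."""
    if not fit.converged:
        raise ValueError("AIC requested for a non-converged fit")
    return aic_from_rss(fit.rss, fit.n_obs, fit.n_params)


def extra_ss_ftest(fit_mm: "KineticFit", fit_haldane: "KineticFit"):
    """Nested extra-sum-of-squares F-test of Haldane (3 params) against
    Michaelis-Menten (2 params) on the same observations.

    F = (rss_mm - rss_haldane) / (rss_haldane / (n - 3)), upper-tail p from
    F(1, n-3).  A tiny negative numerator (optimizer round-off) is clipped
    to zero.
    """
    if fit_mm.n_obs != fit_haldane.n_obs:
        raise ValueError(
            f"fits are on different data (n={fit_mm.n_obs} vs {fit_haldane.n_obs})"
        )
    n = fit_mm.n_obs
    if n <= 3:
        raise ValueError("F-test needs n > 3")
    num = fit_mm.rss - fit_haldane.rss
    if num < 0:
        if num < -1e-6 * max(fit_mm.rss, 1e-300):
            warnings.warn(
                "Haldane RSS exceeds MM RSS by more than round-off; "
                "treating as no improvement",
                UserWarning,
                stacklevel=2,
            )
        num = 0.0
    f_stat = num / (fit_haldane.rss / (n - 3))
    p_value = float(stats.f.sf(f_stat, 1, n - 3))
    return float(f_stat), p_value


def select_model(
    ecosystem_id: str,
    taxon: str,
    fit_mm: "KineticFit",
    fit_haldane: "KineticFit | None",
    alpha: float = 0.1,
) -> ModelComparison:
    """Apply the selection rule: Haldane iff it converged, has the smaller
    AIC, and the nested F-test rejects at ``alpha``; otherwise MM."""
    haldane_failed = fit_haldane is None or not fit_haldane.converged
    if haldane_failed:
        return ModelComparison(
            ecosystem_id=ecosystem_id,
            taxon=taxon,
            aic_mm=fit_mm.aic,
            aic_haldane=float("nan"),
            f_stat=float("nan"),
            p_value=float("nan"),
            selected="MM",
            haldane_failed=True,
        )
    f_stat, p_value = extra_ss_ftest(fit_mm, fit_haldane)
    haldane_wins = (fit_haldane.aic < fit_mm.aic) and (p_value < alpha)
    return ModelComparison(
        ecosystem_id=ecosystem_id,
        taxon=taxon,
        aic_mm=fit_mm.aic,
        aic_haldane=fit_haldane.aic,
        f_stat=f_stat,
        p_value=p_value,
        selected="Haldane" if haldane_wins else "MM",
        haldane_failed=False,
    )
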