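"""Michaelis-Menten and Haldane rate laws and their nonlinear least-squares
fits to partitioned nitrification rates.

Michaelis-Menten:  V = Vmax * S / (Km + S)
Haldane:           V = Vmax * S / (Km + S + S^2 / Ki)

Vmax (mg N kg-1 dry soil day-1) is the maximum rate under non-limiting
substrate; Km (mM) the half-saturation constant (1/Km is the substrate
affinity); Ki (mM) governs inhibition at high NH4+ -- it equals the upper of
the two substrate concentrations at which the Haldane curve crosses Vmax/2,
and the curve peaks at S = sqrt(Km * Ki).

Fitting protocol: pooled replicate points per (ecosystem, taxon) are fit by
trust-region least squares.  The first pass leaves Km unconstrained (the
analog of a plain ``nls`` call); if the optimum has Km < 0 the model is refit
with Km bounded below at 1e-9 mM and flagged ``km_constrained``.  Asymptotic
standard errors come from the Jacobian at the optimum; replicate-level
bootstrap supplies confidence bands for the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .model_select import aic_from_rss
from .rates import RateObservation

__all__ = [
    "KineticFit",
    "BootstrapBand",
    "mm_rate",
    "haldane_rate",
    "fit_kinetics",
    "bootstrap_band",
]

_KM_FLOOR = 1e-9  # mM, lower bound when Km is constrained positive
_KI_FLOOR = 1e-9
_KI_CEIL = 1e12
_FTOL = 1e-10
_MAX_NFEV = 10_000


def mm_rate(s, vmax, km):
    """Michaelis-Menten rate Vmax*S/(Km+S).  Requires Km + S > 0."""
    s = np.asarray(s, dtype=float)
    den = km + s
    if np.any(den <= 0):
        raise ValueError("Michaelis-Menten denominator Km + S must be positive")
    out = vmax * s / den
    return float(out) if out.ndim == 0 else out


def haldane_rate(s, vmax, km, ki):
    """Haldane substrate-inhibition rate Vmax*S/(Km+S+S^2/Ki).

    Reduces to :func:`mm_rate` as Ki -> infinity.  Requires Ki > 0 and a
    positive denominator.
    """
    if ki <= 0:
        raise ValueError("Ki must be positive")
    s = np.asarray(s, dtype=float)
    den = km + s + s * s / ki
    if np.any(den <= 0):
        raise ValueError("Haldane denominator must be positive")
    out = vmax * s / den
    return float(out) if out.ndim == 0 else out


def _safe_curve(s, params, model):
    """Model curve tolerant of sign-crossing denominators (for optimizer use)."""
    if model == "MM":
        vmax, km = params
        den = km + s
    else:
        vmax, km, ki = params
        den = km + s + s * s / ki
    with np.errstate(divide="ignore", invalid="ignore"):
        out = vmax * s / den
    return np.nan_to_num(out, nan=1e6, posinf=1e6, neginf=-1e6)


@dataclass
class KineticFit:
    """A fitted rate law with uncertainty and bookkeeping.

    Parameters and SEs are in fitting units (Vmax mg N kg-1 day-1, Km and Ki
    mM).  ``converged`` is False when the optimizer failed, the Haldane Ki
    estimate collapsed to non-positive values, or the parameter covariance was
    singular -- the analog of a blank ("NA") entry in a model-comparison table.
    """

    model: str
    vmax: float
    km: float
    ki: float | None
    se_vmax: float
    se_km: float
    se_ki: float | None
    rss: float
    n_obs: int
    n_params: int
    converged: bool
    km_constrained: bool
    aic: float

    def predict(self, s):
        if self.model == "MM":
            return mm_rate(s, self.vmax, self.km)
        return haldane_rate(s, self.vmax, self.km, self.ki)


@dataclass
class BootstrapBand:
    """Pointwise bootstrap confidence band for a fitted curve."""

    s_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int
    level: float


def _prepare_arrays(
    obs: Sequence[RateObservation], exclude_below_detection: bool
) -> tuple[np.ndarray, np.ndarray]:
    kept = [o for o in obs if not (exclude_below_detection and o.below_detection)]
    s = np.array([o.substrate_s for o in kept], dtype=float)
    v = np.array([o.rate_v for o in kept], dtype=float)
    return s, v


def _fit_arrays(s: np.ndarray, v: np.ndarray, model: str) -> KineticFit:
    n_params = 2 if model == "MM" else 3
    n = len(s)
    if n <= n_params:
        raise ValueError(f"need more than {n_params} observations, got {n}")
    min_levels = 3 if model == "MM" else 4
    if len(np.unique(np.round(s, 12))) < min_levels:
        raise ValueError(f"{model} fit needs >= {min_levels} distinct substrate levels")
    if np.all(v == 0):
        raise ValueError("degenerate input: all rates are zero")

    vmax0 = float(np.max(v))
    half = s[v >= 0.5 * vmax0]
    km0 = float(np.min(half)) if half.size else float(np.median(s))
    km0 = max(km0, 1e-6)
    x0 = [vmax0, km0] if model == "MM" else [vmax0, km0, float(np.max(s))]

    def resid(p):
        return _safe_curve(s, p, model) - v

    if model == "MM":
        free_bounds = ([-np.inf, -np.inf], [np.inf, np.inf])
        con_bounds = ([0.0, _KM_FLOOR], [np.inf, np.inf])
    else:
        free_bounds = ([-np.inf, -np.inf, _KI_FLOOR], [np.inf, np.inf, _KI_CEIL])
        con_bounds = ([0.0, _KM_FLOOR, _KI_FLOOR], [np.inf, np.inf, _KI_CEIL])

    res = least_squares(
        resid, x0, bounds=free_bounds, method="trf",
        ftol=_FTOL, xtol=_FTOL, gtol=_FTOL, max_nfev=_MAX_NFEV,
    )
    km_constrained = False
    if res.x[1] < 0:
        x0c = list(res.x)
        x0c[0] = max(x0c[0], 1e-6)
        x0c[1] = max(x0c[1], _KM_FLOOR)
        res = least_squares(
            resid, x0c, bounds=con_bounds, method="trf",
            ftol=_FTOL, xtol=_FTOL, gtol=_FTOL, max_nfev=_MAX_NFEV,
        )
        km_constrained = True

    rss = float(np.sum(res.fun**2))
    converged = bool(res.success)
    ki = float(res.x[2]) if model == "Haldane" else None
    if model == "Haldane" and (ki is None or ki <= 1e-6):
        converged = False

    # asymptotic SEs from the Jacobian at the optimum
    ses = np.full(n_params, np.nan)
    dof = n - n_params
    jtj = res.jac.T @ res.jac
    try:
        if np.linalg.cond(jtj) > 1e14:
            raise np.linalg.LinAlgError("ill-conditioned")
        cov = np.linalg.inv(jtj) * (rss / dof if dof > 0 else np.nan)
        diag = np.diag(cov)
        if np.any(diag < 0) or not np.all(np.isfinite(diag)):
            raise np.linalg.LinAlgError("invalid covariance")
        ses = np.sqrt(diag)
    except np.linalg.LinAlgError:
        converged = False

    aic = aic_from_rss(rss, n, n_params) if rss > 0 else float("nan")
    return KineticFit(
        model=model,
        vmax=float(res.x[0]),
        km=float(res.x[1]),
        ki=ki,
        se_vmax=float(ses[0]),
        se_km=float(ses[1]),
        se_ki=float(ses[2]) if model == "Haldane" else None,
        rss=rss,
        n_obs=n,
        n_params=n_params,
        converged=converged,
        km_constrained=km_constrained,
        aic=aic,
    )


def fit_kinetics(
    obs: Sequence[RateObservation],
    model: str,
    *,
    exclude_below_detection: bool = True,
) -> KineticFit:
    """Fit one rate law to pooled rate observations by least squares."""
    if model not in ("MM", "Haldane"):
        raise ValueError(f"model must be MM or Haldane, got {model!r}")
    s, v = _prepare_arrays(obs, exclude_below_detection)
    return _fit_arrays(s, v, model)


def bootstrap_band(
    obs: Sequence[RateObservation],
    model: str,
    n_boot: int = 1000,
    seed: int = 0,
    *,
    s_grid: np.ndarray | None = None,
    level: float = 0.95,
    exclude_below_detection: bool = True,
) -> BootstrapBand:
    """Replicate-level bootstrap confidence band for the fitted curve.

    Field replicates (not individual points) are resampled with replacement
    ``n_boot`` times, the model refit on each resample, and pointwise
    percentile bounds of the fitted curves returned on ``s_grid``.
    """
    kept = [o for o in obs if not (exclude_below_detection and o.below_detection)]
    rep_ids = sorted({o.replicate_id for o in kept})
    if len(rep_ids) < 2:
        raise ValueError("bootstrap requires >= 2 distinct field replicates")
    by_rep = {r: [o for o in kept if o.replicate_id == r] for r in rep_ids}

    if s_grid is None:
        s_all = np.array([o.substrate_s for o in kept])
        lo = max(float(np.min(s_all)), 1e-6)
        s_grid = np.geomspace(lo, float(np.max(s_all)), 50)
    s_grid = np.asarray(s_grid, dtype=float)

    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_boot):
        draw = rng.choice(rep_ids, size=len(rep_ids), replace=True)
        sample: list[RateObservation] = []
        for r in draw:
            sample.extend(by_rep[r])
        try:
            fit = fit_kinetics(sample, model, exclude_below_detection=False)
        except (ValueError, np.linalg.LinAlgError):
            continue
        curves.append(_safe_curve(s_grid, _fit_params(fit), fit.model))
    if len(curves) < max(2, n_boot // 2):
        raise ValueError(
            f"too few successful bootstrap refits ({len(curves)}/{n_boot})"
        )
    arr = np.vstack(curves)
    alpha = (1.0 - level) / 2.0
    lower = np.percentile(arr, 100 * alpha, axis=0)
    upper = np.percentile(arr, 100 * (1 - alpha), axis=0)
    return BootstrapBand(
        s_grid=s_grid, lower=lower, upper=upper, n_boot=n_boot, level=level
    )


def _fit_params(fit: KineticFit):
    if fit.model == "MM":
        return (fit.vmax, fit.km)
    return (fit.vmax, fit.km, fit.ki)
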