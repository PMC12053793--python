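"""Levins equilibrium occupancy and its comparison with observed occupancy.

For a patch network with colonisation probability ``c`` (vacant, suitable ->
occupied per census interval) and extinction probability ``e`` (occupied ->
vacant), the stationary fraction of occupied patches is

    n* = c / (c + e),

the fixed point of the per-interval update ``n' = n (1 - e) + (1 - n) c``.
Feeding the distance-varying predictions of fitted colonisation and
extinction models through this identity yields a predicted occupancy gradient
``n*(d)`` that can be compared with the occupancy gradient actually observed
in suitable plots; a nonparametric bootstrap over the two (disjoint) event
pools provides a pointwise confidence envelope for ``n*(d)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .inference import GLM, ModelSpec, fit_glm, predict_response

logger = logging.getLogger(__name__)


def levins_equilibrium(c, e):
    """Equilibrium occupancy ``c / (c + e)`` for colonisation and extinction
    probabilities in [0, 1].  Undefined (raises) when both are zero."""
    c = np.asarray(c, float)
    e = np.asarray(e, float)
    if np.any((c < 0) | (c > 1) | (e < 0) | (e > 1)):
        raise ValueError("c and e must lie in [0, 1]")
    tot = c + e
    if np.any(tot == 0):
        raise ValueError("equilibrium undefined where c = e = 0")
    out = c / tot
    return float(out) if out.ndim == 0 else out


@dataclass
class EquilibriumCurve:
    """Gridded colonisation, extinction and equilibrium-occupancy curves,
    optionally with a pointwise bootstrap envelope."""

    dist_km: np.ndarray
    c_hat: np.ndarray
    e_hat: np.ndarray
    n_star: np.ndarray
    envelope_lo: np.ndarray | None = None
    envelope_hi: np.ndarray | None = None
    B: int = 0
    n_failed: int = 0
    seed: int | None = None
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"dist_km": self.dist_km, "c_hat": self.c_hat,
                           "e_hat": self.e_hat, "n_star": self.n_star})
        if self.envelope_lo is not None:
            df["envelope_lo"] = self.envelope_lo
            df["envelope_hi"] = self.envelope_hi
        return df


def distance_grid(pairs: pd.DataFrame, num: int = 200) -> np.ndarray:
    """Evenly spaced distances from the range limit (0) to the farthest plot."""
    return np.linspace(0.0, float(pairs["dist_km"].max()), num)


def equilibrium_curve(c_fit, e_fit, grid) -> EquilibriumCurve:
    """Predicted c(d), e(d) and n*(d) over a distance grid from two fitted
    distance models (population-level predictions)."""
    grid = np.asarray(grid, float)
    newdata = pd.DataFrame({"dist_km": grid})
    c_hat = predict_response(c_fit, newdata)
    e_hat = predict_response(e_fit, newdata)
    return EquilibriumCurve(grid, c_hat, e_hat, levins_equilibrium(c_hat, e_hat))


class BootstrapFailure(RuntimeError):
    """Raised when too many bootstrap refits fail (separation etc.)."""


def _distance_glm(d: np.ndarray, y: np.ndarray) -> GLM:
    return GLM(family="binomial").fit(d[:, None], y, feature_names=["dist_km"])


def bootstrap_envelope(col_pool: pd.DataFrame, ext_pool: pd.DataFrame, grid,
                       B: int = 1000, level: float = 0.95,
                       seed=None, max_fail_frac: float = 0.05) -> EquilibriumCurve:
    """Pointwise percentile envelope for n*(d) from ``B`` plot-level
    resamples of the two event pools.

    The colonisation pool (vacant at the first survey, response
    ``colonised``) and the extinction pool (occupied at the first survey,
    response ``extinct``) are disjoint, so resampling them independently with
    replacement -- each at its own size -- is equivalent to a joint
    plot-level bootstrap.  Replicates whose refit separates or fails to
    converge are dropped and counted.  Deterministic given ``seed``.
    """
    grid = np.asarray(grid, float)
    d_c = col_pool["dist_km"].to_numpy(float)
    y_c = col_pool["colonised"].to_numpy(float)
    d_e = ext_pool["dist_km"].to_numpy(float)
    y_e = ext_pool["extinct"].to_numpy(float)

    c_fit = _distance_glm(d_c, y_c)
    e_fit = _distance_glm(d_e, y_e)
    Xg = np.column_stack([np.ones(len(grid)), grid])
    n_star = levins_equilibrium(expit(Xg @ c_fit.coef_), expit(Xg @ e_fit.coef_))

    rng = np.random.default_rng(seed)
    curves = np.empty((B, len(grid)))
    n_ok = 0
    n_failed = 0
    for _ in range(B):
        ic = rng.integers(0, len(d_c), len(d_c))
        ie = rng.integers(0, len(d_e), len(d_e))
        cb = _distance_glm(d_c[ic], y_c[ic])
        eb = _distance_glm(d_e[ie], y_e[ie])
        if cb.separation_ or eb.separation_:
            n_failed += 1
            continue
        curves[n_ok] = levins_equilibrium(expit(Xg @ cb.coef_), expit(Xg @ eb.coef_))
        n_ok += 1
    if n_failed > max_fail_frac * B:
        raise BootstrapFailure(
            f"{n_failed}/{B} bootstrap refits failed; pools are too small or separable"
        )
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(curves[:n_ok], 100 * alpha, axis=0)
    hi = np.percentile(curves[:n_ok], 100 * (1 - alpha), axis=0)
    return EquilibriumCurve(grid, expit(Xg @ c_fit.coef_), expit(Xg @ e_fit.coef_),
                            n_star, lo, hi, B=B, n_failed=n_failed,
                            seed=seed, level=level)


def event_pools(pairs: pd.DataFrame):
    """The two disjoint event tables used by the distance-only models."""
    col = pairs.loc[pairs["colonisation_candidate"]].copy()
    col["colonised"] = col["colonised"].astype(float)
    ext = pairs.loc[pairs["extinction_candidate"]].copy()
    ext["extinct"] = ext["extinct"].astype(float)
    return col, ext


def observed_occupancy_model(pairs: pd.DataFrame, survey: str = "t2"):
    """Binomial GLM of occupancy on distance over plots suitable at the
    chosen survey (and within the range, dist_km >= 0)."""
    if survey not in ("t1", "t2"):
        raise ValueError("survey must be 't1' or 't2'")
    sub = pairs.loc[pairs[f"suitable_{survey}"] & (pairs["dist_km"] >= 0)].copy()
    sub["occupied"] = sub[f"occupied_{survey}"].astype(float)
    spec = ModelSpec(response="occupied", terms=("dist_km",), family="binomial")
    return fit_glm(spec, sub)


def occupancy_band(fit, grid, level: float = 0.95):
    """Fitted occupancy and pointwise Wald band on the probability scale
    (delta band on the linear predictor, then inverse-logit)."""
    grid = np.asarray(grid, float)
    X = np.column_stack([np.ones(len(grid)), grid])
    eta = X @ fit.coef_
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_, X))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return expit(eta), expit(eta - z * se), expit(eta + z * se)


@dataclass
class OccupancyComparison:
    """Containment of the predicted equilibrium curve within the pointwise
    confidence band of the observed-occupancy model."""

    dist_km: np.ndarray
    n_star: np.ndarray
    n_obs: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    containment_fraction: float
    endpoints: dict = field(default_factory=dict)
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dist_km": self.dist_km, "n_star": self.n_star,
                             "n_obs": self.n_obs, "band_lo": self.band_lo,
                             "band_hi": self.band_hi})


def compare_curves(eq: EquilibriumCurve, obs_fit, level: float = 0.95) -> OccupancyComparison:
    """Fraction of grid points where n*(d) lies inside the observed-occupancy
    Wald band, plus both curves' values at the grid extremes (range core and
    range limit)."""
    p, lo, hi = occupancy_band(obs_fit, eq.dist_km, level)
    inside = (eq.n_star >= lo) & (eq.n_star <= hi)
    core, limit = int(np.argmax(eq.dist_km)), int(np.argmin(eq.dist_km))
    endpoints = {
        "n_obs_core": float(p[core]), "n_obs_limit": float(p[limit]),
        "n_star_core": float(eq.n_star[core]), "n_star_limit": float(eq.n_star[limit]),
    }
    return OccupancyComparison(eq.dist_km, eq.n_star, p, lo, hi,
                               float(inside.mean()), endpoints, level)
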