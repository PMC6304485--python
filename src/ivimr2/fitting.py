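"""Segmented IVIM fitting and log-linear R2* estimation.

The segmented approach exploits the scale separation between tissue diffusion
(D ~ 1e-3 mm^2/s) and capillary pseudo-diffusion (D* ~ 1e-2..1e-1 mm^2/s).
Above a b-value threshold (default 200 s/mm^2) the perfusion compartment has
decayed to a negligible level, so the high-b points follow a monoexponential
whose slope gives D and whose extrapolated intercept gives the tissue-only
signal at b = 0; the perfusion fraction follows in closed form as

    f = 1 - SI0_extrapolated / SI(b = 0)

and D* is then recovered from the low-b points by bounded one-dimensional
least squares with D and f held fixed.  The literal low-b-first ordering
(biexponential on b < split for D* and f with D profiled, then high-b mono
for D) is kept as ``order="low_b_first"`` for comparison; it is
ill-conditioned and not the default.

R2* is the negative slope of ln(signal) versus echo time, by ordinary least
squares, converted to Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import numpy as np
from scipy import optimize

from .models import (
    IvimParameters,
    RelaxometryParameters,
    SignalCurve,
    ivim_signal,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "FitError",
    "fit_monoexponential",
    "fit_ivim_segmented",
    "fit_r2star",
]


class FitError(RuntimeError):
    """Raised when a curve cannot be fitted (too few usable points)."""


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the segmented IVIM fit.

    ``b_split`` separates the perfusion-sensitive low-b segment from the
    diffusion-only high-b segment; by default the high-b segment owns the
    split point itself (b >= 200 s/mm^2), which stabilises the mono fit while
    the perfusion contribution there is negligible for physiological D*.
    """

    b_split: float = 200.0
    split_in_high: bool = True
    order: Literal["d_first", "low_b_first"] = "d_first"
    d_bounds: tuple[float, float] = (0.0, 5e-3)
    d_star_bounds: tuple[float, float] = (0.0, 0.5)
    f_bounds: tuple[float, float] = (0.0, 1.0)
    d_star_init: float = 20e-3
    xtol: float = 1e-10
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.b_split <= 0:
            raise ValueError("b_split must be positive")
        for lo, hi in (self.d_bounds, self.d_star_bounds, self.f_bounds):
            if not (0 <= lo < hi):
                raise ValueError("bounds must satisfy 0 <= low < high")


@dataclass
class FitResult:
    """A fitted parameter set with per-curve diagnostics."""

    params: Union[IvimParameters, RelaxometryParameters]
    SI0_hat: float
    rss: float
    n_points_used: dict[str, int] = field(default_factory=dict)
    converged: bool = True
    bounds_hit: dict[str, bool] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _log_linear(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """OLS of ln(y) on x over strictly positive y.

    Returns (slope, intercept_signal, rss_log, n_used); non-positive
    intensities are excluded (log undefined) and counted out.
    """
    keep = y > 0
    x_use, y_use = x[keep], y[keep]
    if x_use.size < 2:
        raise FitError("fewer than 2 usable points for log-linear fit")
    order = np.lexsort((y_use, x_use))  # canonical order: estimates are permutation-invariant
    x_use, y_use = x_use[order], y_use[order]
    slope, intercept = np.polyfit(x_use, np.log(y_use), 1)
    resid = np.log(y_use) - (slope * x_use + intercept)
    return float(slope), float(np.exp(intercept)), float(resid @ resid), int(x_use.size)


def fit_monoexponential(
    curve: SignalCurve,
    subset: Optional[np.ndarray] = None,
) -> tuple[float, float, float, int]:
    """Log-linear monoexponential fit; returns (decay constant, intercept, rss, n).

    ``subset`` is a boolean mask over the curve points; the decay constant is
    the magnitude of the fitted slope (D in mm^2/s for diffusion curves, a
    per-ms rate for relaxometry curves — see :func:`fit_r2star` for the Hz
    conversion).
    """
    x, y = curve.x, curve.y
    if subset is not None:
        x, y = x[subset], y[subset]
    slope, intercept, rss, n = _log_linear(x, y)
    return -slope, intercept, rss, n


def fit_ivim_segmented(curve: SignalCurve, config: FitConfig | None = None) -> FitResult:
    """Estimate (D, D*, f) from a multi-b diffusion curve by segmented fitting.

    See module docstring for the two orderings.  The perfusion fraction is
    clipped into [0, 1] (and flagged) when the intercept estimate falls
    outside; non-convergence of the D* search is reported via ``converged``
    rather than raised.
    """
    cfg = config or FitConfig()
    if curve.kind != "diffusion":
        raise ValueError("segmented IVIM fit requires a diffusion curve")
    b, y = curve.x, curve.y
    order = np.lexsort((y, b))
    b, y = b[order], y[order]
    if not np.any(b == 0):
        raise FitError("segmented fit requires the b=0 point")
    high = b >= cfg.b_split if cfg.split_in_high else b > cfg.b_split
    low = ~high
    if high.sum() < 2 or low.sum() < 1:
        raise FitError("curve does not cover both b-value segments")
    si0_obs = float(np.mean(y[b == 0]))
    if si0_obs <= 0:
        raise FitError("non-positive signal at b=0")

    flags: list[str] = []
    bounds_hit = {"D": False, "D_star": False, "f": False}

    if cfg.order == "d_first":
        slope, si0_extrap, rss_high, n_high = _log_linear(b[high], y[high])
        d_hat = -slope
        d_hat, hit = _clip(d_hat, cfg.d_bounds)
        bounds_hit["D"] = hit
        f_hat = 1.0 - si0_extrap / si0_obs
        if not cfg.f_bounds[0] <= f_hat <= cfg.f_bounds[1]:
            f_hat = float(np.clip(f_hat, *cfg.f_bounds))
            bounds_hit["f"] = True
            flags.append("f_clipped")
        d_star_hat, converged, rss_low, n_low = _fit_d_star(
            b[low], y[low], si0_obs, d_hat, f_hat, cfg
        )
        bounds_hit["D_star"] = d_star_hat in cfg.d_star_bounds
    else:  # low_b_first: literal low-b biexponential for (D*, f), D profiled
        (d_star_hat, f_hat), converged, rss_low, n_low = _fit_low_b_biexp(
            b[low], y[low], si0_obs, cfg
        )
        slope, _si0_extrap, rss_high, n_high = _log_linear(b[high], y[high])
        d_hat = -slope
        d_hat, hit = _clip(d_hat, cfg.d_bounds)
        bounds_hit["D"] = hit
        bounds_hit["D_star"] = d_star_hat in cfg.d_star_bounds
        bounds_hit["f"] = f_hat in cfg.f_bounds

    params = IvimParameters(D=d_hat, D_star=d_star_hat, f=f_hat)
    pred = ivim_signal(params, b, si0_obs)
    rss = float(np.sum((y - pred) ** 2))
    if abs(params.D_star - params.D) < 1e-6:
        flags.append("degenerate_compartments")
    return FitResult(
        params=params,
        SI0_hat=si0_obs,
        rss=rss,
        n_points_used={"low_b": int(low.sum()), "high_b": int(high.sum())},
        converged=converged,
        bounds_hit=bounds_hit,
        flags=flags,
    )


def _clip(value: float, bounds: tuple[float, float]) -> tuple[float, bool]:
    clipped = float(np.clip(value, *bounds))
    return clipped, clipped != value


def _fit_d_star(
    b_low: np.ndarray,
    y_low: np.ndarray,
    si0: float,
    d: float,
    f: float,
    cfg: FitConfig,
) -> tuple[float, bool, float, int]:
    """Bounded 1-D least squares for D* on the low-b segment, D and f fixed."""

    def sse(d_star: float) -> float:
        pred = si0 * ((1 - f) * np.exp(-b_low * d) + f * np.exp(-b_low * d_star))
        r = y_low - pred
        return float(r @ r)

    if f <= 0:  # no perfusion compartment: D* unidentifiable, keep initialization
        return cfg.d_star_init, True, sse(cfg.d_star_init), int(b_low.size)
    res = optimize.minimize_scalar(
        sse,
        bounds=cfg.d_star_bounds,
        method="bounded",
        options={"xatol": cfg.xtol, "maxiter": cfg.max_iter},
    )
    # ties (flat objective) resolve toward lower D*
    d_star = float(res.x)
    if sse(cfg.d_star_bounds[0]) <= res.fun:
        d_star = cfg.d_star_bounds[0]
    return d_star, bool(res.success), float(sse(d_star)), int(b_low.size)


def _fit_low_b_biexp(
    b_low: np.ndarray,
    y_low: np.ndarray,
    si0: float,
    cfg: FitConfig,
) -> tuple[tuple[float, float], bool, float, int]:
    """Low-b-first step: fit (D*, f) on b < split with D profiled as a nuisance."""

    def resid(theta: np.ndarray) -> np.ndarray:
        d_star, f, d = theta
        return y_low - si0 * ((1 - f) * np.exp(-b_low * d) + f * np.exp(-b_low * d_star))

    x0 = np.array([cfg.d_star_init, 0.2, 1e-3])
    lo = np.array([cfg.d_star_bounds[0], cfg.f_bounds[0], cfg.d_bounds[0]])
    hi = np.array([cfg.d_star_bounds[1], cfg.f_bounds[1], cfg.d_bounds[1]])
    res = optimize.least_squares(
        resid, x0, bounds=(lo, hi), xtol=cfg.xtol, max_nfev=cfg.max_iter * 3
    )
    d_star, f, _d = (float(v) for v in res.x)
    return (d_star, f), bool(res.success), float(res.cost * 2), int(b_low.size)


def fit_r2star(curve: SignalCurve) -> FitResult:
    """Estimate R2* (Hz) as the negative slope of ln(SI) versus TE.

    Echo times are in milliseconds, so the per-ms slope is scaled by 1000.
    A negative rate estimate (signal increasing with TE, possible under
    noise) is clipped to 0 and flagged.
    """
    if curve.kind != "relaxometry":
        raise ValueError("R2* fit requires a relaxometry curve")
    rate_per_ms, intercept, rss, n = fit_monoexponential(curve)
    r2s = rate_per_ms * 1e3
    flags: list[str] = []
    if r2s < 0:
        r2s = 0.0
        flags.append("negative_rate_clipped")
    return FitResult(
        params=RelaxometryParameters(R2_star=r2s, SI0=intercept),
        SI0_hat=intercept,
        rss=rss,
        n_points_used={"echoes": n},
        converged=True,
        bounds_hit={"R2_star": r2s == 0.0 and "negative_rate_clipped" in flags},
        flags=flags,
    )
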