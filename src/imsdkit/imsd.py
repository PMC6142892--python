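"""iMSD: from the correlation function to size and dynamics.

At each temporal lag tau, the spatial correlation G(xi, chi) is fit with an
isotropic Gaussian

    G(xi, chi) = A * exp(-(xi^2 + chi^2) / sigma_r^2) + y0 .

Convention note: the Gaussian is written WITHOUT a factor 2 in the
denominator, so that sigma_r^2(tau) itself is the iMSD and the Brownian
diffusion law reads sigma^2(tau) = sigma0^2 + 4 D tau.  (With the factor-2
convention every D and size would silently rescale.)  For emitters whose
rendered profile has Gaussian SD ``s``, the spatial autocorrelation at zero
displacement has sigma_r^2 = 4 s^2; equivalently, writing the spot profile
as exp(-r^2/sigma_s^2) with 1/e radius sigma_s = sqrt(2) s, the intercept is
2 sigma_s^2.

The iMSD curve sigma^2(tau) is then fit with a diffusion-law model:

    brownian    sigma^2(tau) = sigma0^2 + 4 D_M tau
    anomalous   sigma^2(tau) = sigma0^2 + 4 D_M tau^alpha

yielding the long-range diffusivity D_M, the anomalous exponent alpha
(alpha > 1 super-diffusive, < 1 sub-diffusive), and the offset sigma0^2
whose square root estimates the average diameter of the imaged structures.
The time-window analysis repeats the model fit over increasing temporal
windows (5/10/20% of the acquisition by default) to expose how the apparent
mode of motion depends on the observation timescale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import ImageStack, ResultsTable
from .stics import CorrelationFunction, compute_correlation, correlation_evolution

logger = logging.getLogger(__name__)

__all__ = [
    "LagFit",
    "IMSDCurve",
    "IMSDFit",
    "fit_gaussian_lag",
    "build_imsd",
    "fit_imsd",
    "size_from_intercept",
    "window_lag_count",
    "window_analysis",
    "WindowAnalysis",
    "results_table",
]


@dataclass(frozen=True)
class LagFit:
    """Gaussian fit of one correlation slice: sigma_r^2 (um^2), A, y0, r^2."""

    sigma2_um2: float
    amplitude: float
    offset: float
    r_squared: float
    valid: bool


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        return np.nan
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def fit_gaussian_lag(
    G_slice: np.ndarray,
    pixel_size_nm: float,
    exclude_zero_lag: bool = True,
    fit_radius_px: float | None = None,
) -> LagFit:
    """Least-squares Gaussian+offset fit of one spatial correlation slice.

    The zero-lag pixel carries uncorrelated shot noise and is excluded by
    default.  ``fit_radius_px`` restricts the fit to lags within that radius
    (default: the whole slice).  Non-convergence or an unphysical width is
    reported through ``valid=False``, never as an exception.
    """
    G_slice = np.asarray(G_slice, dtype=np.float64)
    side = G_slice.shape[0]
    if G_slice.ndim != 2 or G_slice.shape[1] != side or side % 2 == 0:
        raise ValueError(f"G_slice must be square with odd side, got {G_slice.shape}")
    L = side // 2
    xi, chi = np.meshgrid(np.arange(-L, L + 1), np.arange(-L, L + 1))
    r2 = (xi**2 + chi**2).astype(np.float64)
    mask = np.ones_like(r2, dtype=bool)
    if exclude_zero_lag:
        mask[L, L] = False
    if fit_radius_px is not None:
        mask &= r2 <= fit_radius_px**2
    if mask.sum() < 4 or not np.all(np.isfinite(G_slice)):
        return LagFit(np.nan, np.nan, np.nan, np.nan, False)

    y = G_slice[mask]
    x = r2[mask]
    if np.ptp(y) == 0:
        return LagFit(np.nan, np.nan, np.nan, np.nan, False)

    y0_0 = float(np.median(y[x >= np.percentile(x, 80)]))
    # estimate the peak from the zero-lag neighbourhood (shot-noise safe)
    neigh = [G_slice[L + dy, L + dx] for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0))]
    A0 = max(float(np.max(neigh)) - y0_0, 1e-3 * abs(y0_0) + 1e-12)
    w = np.clip(y - y0_0, 0.0, None)
    s2_0 = float(np.sum(w * x) / np.sum(w)) if np.sum(w) > 0 else max(1.0, L / 2) ** 2
    s2_0 = float(np.clip(s2_0, 0.25, (4.0 * L) ** 2))

    def model(r2v, A, s2, y0):
        return A * np.exp(-r2v / s2) + y0

    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=(A0, s2_0, y0_0),
            bounds=([0.0, 1e-3, -np.inf], [np.inf, (8.0 * L) ** 2, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return LagFit(np.nan, np.nan, np.nan, np.nan, False)
    A, s2, y0 = popt
    if not np.isfinite(s2) or s2 <= 0 or s2 >= (8.0 * L) ** 2 * 0.99 or A <= 0:
        return LagFit(np.nan, np.nan, np.nan, np.nan, False)
    r2_fit = _r_squared(y, model(x, *popt))
    sigma2_um2 = s2 * (pixel_size_nm / 1000.0) ** 2
    return LagFit(sigma2_um2, float(A), float(y0), r2_fit, True)


@dataclass
class IMSDCurve:
    """The iMSD: squared Gaussian radius of G (um^2) per temporal lag."""

    tau: np.ndarray
    sigma2: np.ndarray
    amplitude: np.ndarray
    offset: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray
    pixel_size_nm: float = np.nan

    def __post_init__(self) -> None:
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing")

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau_s": self.tau,
                "sigma2_um2": self.sigma2,
                "amplitude": self.amplitude,
                "offset": self.offset,
                "lag_r_squared": self.r_squared,
                "valid": self.valid.astype(int),
            }
        )


def build_imsd(
    corr: CorrelationFunction,
    exclude_zero_lag: bool = True,
    fit_radius_px: float | None = None,
    adaptive_radius: bool = True,
    min_lag_r_squared: float = 0.0,
) -> IMSDCurve:
    """Fit every temporal-lag slice of ``corr`` and assemble the iMSD curve.

    With ``adaptive_radius`` (default) the fit radius at each lag follows
    the width fitted at the previous lag (2 sigma, at least 5 px, capped at
    the available extent), so that narrow early-lag peaks are not drowned in
    far-lag noise while broad late-lag peaks still see their full extent.
    Lags whose Gaussian fit fails or returns an unphysical width are flagged
    invalid and excluded downstream; ``min_lag_r_squared`` optionally also
    rejects converged fits explaining less than that fraction of the
    variance (0 by default: converged lags are kept, and the relative-error
    weighting of the model fit handles their lower quality).
    """
    n = corr.n_tau
    out = {
        k: np.full(n, np.nan)
        for k in ("sigma2", "amplitude", "offset", "r_squared")
    }
    valid = np.zeros(n, dtype=bool)
    prev_s2_px: float | None = None
    for i in range(n):
        radius = fit_radius_px
        if adaptive_radius and prev_s2_px is not None:
            radius = float(np.clip(2.0 * np.sqrt(prev_s2_px), 5.0, corr.max_lag))
        lag = fit_gaussian_lag(
            corr.G[i],
            corr.pixel_size_nm,
            exclude_zero_lag=exclude_zero_lag,
            fit_radius_px=radius,
        )
        ok = lag.valid and (
            np.isnan(lag.r_squared) or lag.r_squared >= min_lag_r_squared
        )
        if ok:
            out["sigma2"][i] = lag.sigma2_um2
            out["amplitude"][i] = lag.amplitude
            out["offset"][i] = lag.offset
            out["r_squared"][i] = lag.r_squared
            valid[i] = True
            prev_s2_px = lag.sigma2_um2 / (corr.pixel_size_nm / 1000.0) ** 2
    if valid.sum() < 3:
        raise ValueError(
            f"only {int(valid.sum())} of {n} temporal lags produced a valid "
            "Gaussian fit; at least 3 are required for model fitting"
        )
    return IMSDCurve(
        tau=corr.tau,
        sigma2=out["sigma2"],
        amplitude=out["amplitude"],
        offset=out["offset"],
        r_squared=out["r_squared"],
        valid=valid,
        pixel_size_nm=corr.pixel_size_nm,
    )


@dataclass(frozen=True)
class IMSDFit:
    """Diffusion-law fit of an iMSD curve.

    ``D_M`` is in um^2/s for the brownian model and generalized um^2/s^alpha
    for the anomalous model.  ``size_nm = 1000*sqrt(sigma0_sq)`` is the
    intercept-derived average diameter.
    """

    model: str
    D_M: float
    alpha: float
    sigma0_sq: float
    size_nm: float
    r_squared: float
    tau_min: float
    tau_max: float
    n_points: int
    alpha_at_bound: bool = False
    label: str = ""
    window_fraction: float | None = None

    def predict(self, tau: np.ndarray) -> np.ndarray:
        return self.sigma0_sq + 4.0 * self.D_M * np.asarray(tau) ** self.alpha


_ALPHA_BOUNDS = (0.05, 2.0)


def _init_anomalous(tau: np.ndarray, s2: np.ndarray) -> tuple[float, float, float]:
    """Seed (D, alpha, sigma0^2) from a log-log regression of the increments."""
    s0 = max(s2[0] - (s2[1] - s2[0]) * tau[0] / (tau[1] - tau[0]), 0.0)
    if len(tau) >= 3:
        p = np.polyfit(tau[:3], s2[:3], 1)
        s0 = max(float(np.polyval(p, 0.0)), 0.0)
    d = s2 - s2[0]
    good = d > 0
    good[0] = False
    if good.sum() >= 2:
        slope, logc = np.polyfit(np.log(tau[good]), np.log(d[good]), 1)
        alpha0 = float(np.clip(slope, *_ALPHA_BOUNDS))
        D0 = float(np.exp(logc) / 4.0)
    else:
        alpha0, D0 = 1.0, max((s2[-1] - s2[0]) / (4.0 * (tau[-1] - tau[0])), 1e-8)
    return max(D0, 1e-10), alpha0, s0


def fit_imsd(
    curve: IMSDCurve,
    model: str = "anomalous",
    window: tuple[float, float] | None = None,
    weights: str | None = "relative",
    label: str = "",
    window_fraction: float | None = None,
) -> IMSDFit:
    """Nonlinear least-squares fit of a diffusion-law model to the iMSD.

    ``window=(tau_min, tau_max)`` restricts the fit in seconds (inclusive);
    default is every valid point.  ``weights="relative"`` (default) assumes
    a constant fractional error per iMSD point — the statistical uncertainty
    of a fitted correlation width grows with the width itself — so the fit
    is not dominated by the largest (and least certain) long-lag values;
    ``weights=None`` gives the plain unweighted fit.  The anomalous fit is
    multi-started from a log-log initialization plus perturbed copies; alpha
    is constrained to [0.05, 2] and flagged when it lands on a bound.
    """
    if model not in ("brownian", "anomalous"):
        raise ValueError(f"unknown model {model!r}")
    if weights not in (None, "relative"):
        raise ValueError(f"unknown weights mode {weights!r}")
    sel = curve.valid.copy()
    if window is not None:
        sel &= (curve.tau >= window[0] - 1e-12) & (curve.tau <= window[1] + 1e-12)
    tau = curve.tau[sel]
    s2 = curve.sigma2[sel]
    if len(tau) < 3:
        raise ValueError(f"need >= 3 valid points in the fit window, got {len(tau)}")
    sigma = np.abs(s2) if weights == "relative" else None

    if model == "brownian":
        def f(t, s0, D):
            return s0 + 4.0 * D * t

        slope0 = max((s2[-1] - s2[0]) / (tau[-1] - tau[0]), 1e-10)
        p0 = (max(s2[0] - slope0 * tau[0], 0.0), slope0 / 4.0)
        popt, _ = curve_fit(
            f, tau, s2, p0=p0, sigma=sigma,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
        s0, D = popt
        alpha = 1.0
        pred = f(tau, *popt)
        at_bound = False
    else:
        def f(t, s0, D, a):
            return s0 + 4.0 * D * t**a

        D0, a0, s00 = _init_anomalous(tau, s2)
        starts = [
            (s00, D0, a0),
            (s00, D0 * 2.0, float(np.clip(a0 + 0.2, *_ALPHA_BOUNDS))),
            (s00, max(D0 / 2.0, 1e-10), float(np.clip(a0 - 0.2, *_ALPHA_BOUNDS))),
        ]
        best = None
        errors = []
        for p0 in starts:
            try:
                popt, _ = curve_fit(
                    f,
                    tau,
                    s2,
                    p0=p0,
                    sigma=sigma,
                    bounds=([0.0, 0.0, _ALPHA_BOUNDS[0]], [np.inf, np.inf, _ALPHA_BOUNDS[1]]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError) as e:  # pragma: no cover - rare
                errors.append(f"start {p0}: {e}")
                continue
            resid = s2 - f(tau, *popt)
            if sigma is not None:
                resid = resid / sigma
            ssr = float(np.sum(resid**2))
            if best is None or ssr < best[0]:
                best = (ssr, popt)
        if best is None:
            raise RuntimeError(
                "anomalous iMSD fit failed to converge from all starts: "
                + "; ".join(errors)
            )
        s0, D, alpha = best[1]
        pred = f(tau, s0, D, alpha)
        at_bound = bool(
            alpha <= _ALPHA_BOUNDS[0] + 1e-6 or alpha >= _ALPHA_BOUNDS[1] - 1e-6
        )
        if at_bound:
            logger.warning("fitted alpha=%.4g is at a bound", alpha)

    return IMSDFit(
        model=model,
        D_M=float(D),
        alpha=float(alpha),
        sigma0_sq=float(s0),
        size_nm=size_from_intercept(float(s0)),
        r_squared=_r_squared(s2, pred),
        tau_min=float(tau[0]),
        tau_max=float(tau[-1]),
        n_points=len(tau),
        alpha_at_bound=at_bound,
        label=label,
        window_fraction=window_fraction,
    )


def size_from_intercept(sigma0_sq_um2: float, psf_sigma0_sq_um2: float = 0.0) -> float:
    """Average diameter (nm) from the iMSD intercept: 1000*sqrt(sigma0^2).

    The intercept is used literally (the square root of the y-axis intercept
    is the diameter estimate); an optional PSF contribution may be
    subtracted before the square root (off by default).
    """
    if sigma0_sq_um2 < 0:
        raise ValueError(f"sigma0_sq must be >= 0, got {sigma0_sq_um2}")
    if psf_sigma0_sq_um2 < 0:
        raise ValueError("psf_sigma0_sq must be >= 0")
    return 1000.0 * float(np.sqrt(max(sigma0_sq_um2 - psf_sigma0_sq_um2, 0.0)))


def window_lag_count(n_frames: int, fraction: float) -> int:
    """Number of temporal lags in a window covering ``fraction`` of the stack."""
    if not 0 < fraction <= 1:
        raise ValueError(f"window fraction must be in (0, 1], got {fraction}")
    n_lags = int(round(fraction * n_frames))
    if n_lags < 4:
        raise ValueError(
            f"window fraction {fraction} spans only {n_lags} lag(s) of "
            f"{n_frames} frames; at least 4 are required"
        )
    return n_lags


@dataclass
class WindowAnalysis:
    """Per-window diffusion-law fits plus the (alpha, size, D_M) fingerprint."""

    fits: list[IMSDFit]
    curve: IMSDCurve
    corr: CorrelationFunction
    fingerprint: pd.DataFrame = field(default_factory=pd.DataFrame)


def window_analysis(
    stack: ImageStack,
    fractions: Sequence[float] = (0.05, 0.10, 0.20),
    model: str = "anomalous",
    max_spatial_lag: int = 10,
    label: str = "",
    corr: CorrelationFunction | None = None,
    **imsd_kwargs,
) -> WindowAnalysis:
    """iMSD time-window analysis over several fractions of the acquisition.

    For each fraction f the diffusion-law model is fit over temporal lags
    from one frame time up to round(f*n_frames) frame times.  The correlation
    function is computed once, up to the largest window.
    """
    T = stack.n_frames
    dt = stack.meta.frame_time_s
    n_lags = {f: window_lag_count(T, f) for f in fractions}
    if corr is None:
        corr = compute_correlation(stack, max(n_lags.values()), max_spatial_lag)
    curve = build_imsd(corr, **imsd_kwargs)
    fits = []
    rows = []
    for f in fractions:
        fit = fit_imsd(
            curve,
            model=model,
            window=(dt, n_lags[f] * dt),
            label=label,
            window_fraction=f,
        )
        fits.append(fit)
        rows.append(
            {
                "acquisition": label,
                "window_fraction": f,
                "alpha": fit.alpha,
                "size_nm": fit.size_nm,
                "D_M": fit.D_M,
                "sigma0_sq_um2": fit.sigma0_sq,
                "r_squared": fit.r_squared,
            }
        )
    return WindowAnalysis(fits=fits, curve=curve, corr=corr, fingerprint=pd.DataFrame(rows))


def results_table(
    corr: CorrelationFunction,
    curve: IMSDCurve,
    fits: Sequence[IMSDFit],
    label: str = "",
) -> ResultsTable:
    """Assemble the spreadsheet-style ResultsTable from analysis products."""
    fitted = pd.DataFrame({"tau_s": curve.tau})
    fit_rows = []
    for k, fit in enumerate(fits):
        name = f"fit{k}_{fit.model}"
        if fit.window_fraction is not None:
            name += f"_w{fit.window_fraction:g}"
        fitted[name] = fit.predict(curve.tau)
        fit_rows.append(
            {
                "fit": name,
                "model": fit.model,
                "window_fraction": fit.window_fraction,
                "tau_min_s": fit.tau_min,
                "tau_max_s": fit.tau_max,
                "D_M": fit.D_M,
                "alpha": fit.alpha,
                "sigma0_sq_um2": fit.sigma0_sq,
                "size_nm": fit.size_nm,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
            }
        )
    return ResultsTable(
        correlation_evolution=correlation_evolution(corr),
        imsd=curve.to_dataframe(),
        fitted_curves=fitted,
        fits=pd.DataFrame(fit_rows),
        label=label,
    )
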