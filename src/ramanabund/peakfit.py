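"""Peak detection and the two quantification engines.

Total peak area (TPA) computes the net area of an isolated peak as the raw
channel sum between boundaries L and R minus a trapezoidal background whose
end ordinates are n-channel averages just inside the boundaries:

    A = sum_{i=L..R} x_i - (xbar_L + xbar_R) * (R - L + 1) / 2

Gaussian multi-peak fitting decomposes mixed/shoulder peaks as a sum of
area-parameterized Gaussians

    f(x) = sum_i A_i / (sigma_i * sqrt(pi/2)) * exp(-2 (x - mu_i)^2 / sigma_i^2)

where mu is the peak position, A the single-peak area and sigma the peak
width (twice the Gaussian standard deviation; FWHM = sigma * sqrt(2 ln 2));
each component integrates exactly to A.  Fitting is two-stage bounded least
squares: amplitudes/widths first with positions frozen at the seeds, then all
parameters jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks_cwt

from .io import Spectrum

SQRT_PI_OVER_2 = float(np.sqrt(np.pi / 2.0))


class ParameterError(ValueError):
    pass


class RangeError(ValueError):
    pass


class OverParameterizedError(ValueError):
    pass


@dataclass
class PeakComponent:
    mu: float
    area: float
    width: float  # sigma, twice the Gaussian SD

    @property
    def amplitude_at_mu(self) -> float:
        return self.area / (self.width * SQRT_PI_OVER_2)

    @property
    def fwhm(self) -> float:
        return self.width * float(np.sqrt(2.0 * np.log(2.0)))


@dataclass
class FitResult:
    components: list[PeakComponent]
    standard_errors: np.ndarray  # (area, mu, width) per component, flattened
    residuals: np.ndarray
    r_squared: float
    converged: bool
    window: tuple[float, float]
    rss_stage1: float = float("nan")
    rss: float = float("nan")
    offset: float = 0.0


@dataclass
class TpaResult:
    net_area: float
    background_area: float
    boundaries: tuple[int, int]
    n: int

    @property
    def total(self) -> float:
        return self.net_area + self.background_area


# ---------------------------------------------------------------------------
# detection


def detect_peaks_wavelet(spectrum: Spectrum,
                         scale_range: tuple[float, float] = (2.0, 20.0),
                         min_ridge_snr: float = 3.0) -> list[float]:
    """Peak positions from Ricker-wavelet CWT ridge lines, sorted ascending.

    ``scale_range`` is in cm^-1 and converted to channel widths internally.
    """
    lo, hi = scale_range
    if not (hi > lo > 0):
        raise ParameterError("scale_range must be an increasing positive pair")
    w = spectrum.wavenumbers
    if w.size < 3:
        return []
    step = float(np.median(np.diff(w)))
    widths = np.arange(max(1.0, lo / step), max(2.0, hi / step) + 1e-9)
    x = spectrum.intensities
    if np.allclose(x, x[0]):
        return []
    idx = find_peaks_cwt(x, widths, min_snr=min_ridge_snr)
    return sorted(float(w[i]) for i in np.atleast_1d(idx))


# ---------------------------------------------------------------------------
# TPA


def tpa(spectrum: Spectrum, L: int, R: int, n: int = 3) -> TpaResult:
    """Net peak area between channel indices L and R (inclusive).

    The background ordinate at L is the mean of the n channels ending at L
    (inclusive), at R the mean of the n channels starting at R; for n = 1
    these reduce to x[L] and x[R].
    """
    x = spectrum.intensities
    if not (0 <= L < R < x.size):
        raise RangeError(f"boundaries ({L}, {R}) outside the spectrum")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if L - n + 1 < 0 or R + n - 1 >= x.size:
        raise RangeError("background averaging window extends outside the axis")
    x_l = float(x[L - n + 1:L + 1].mean())
    x_r = float(x[R:R + n].mean())
    total = float(x[L:R + 1].sum())
    background = (x_l + x_r) * (R - L + 1) / 2.0
    return TpaResult(net_area=total - background, background_area=background,
                     boundaries=(L, R), n=n)


def tpa_window(spectrum: Spectrum, center_cm1: float, half_width_cm1: float,
               n: int = 3) -> TpaResult:
    """TPA with boundaries placed ``half_width`` cm^-1 either side of a center."""
    w = spectrum.wavenumbers
    L = int(np.searchsorted(w, center_cm1 - half_width_cm1, side="left"))
    R = int(np.searchsorted(w, center_cm1 + half_width_cm1, side="right")) - 1
    return tpa(spectrum, L, R, n=n)


# ---------------------------------------------------------------------------
# Gaussian mixture


def gaussian_mixture_value(components: list[PeakComponent],
                           x: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the area-parameterized Gaussian mixture at x."""
    if not components:
        raise ParameterError("component list must be non-empty")
    xa = np.asarray(x, dtype=float)
    out = np.zeros_like(xa)
    for c in components:
        if c.width <= 0:
            raise ParameterError("component width must be positive")
        out = out + c.area / (c.width * SQRT_PI_OVER_2) * np.exp(
            -2.0 * (xa - c.mu) ** 2 / c.width ** 2)
    return float(out) if np.isscalar(x) else out


def _pack(components: list[PeakComponent]) -> np.ndarray:
    return np.array([v for c in components for v in (c.area, c.mu, c.width)])


def _unpack(theta: np.ndarray) -> list[PeakComponent]:
    return [PeakComponent(area=theta[3 * i], mu=theta[3 * i + 1], width=theta[3 * i + 2])
            for i in range(theta.size // 3)]


def fit_gaussian_multi(spectrum: Spectrum, window: tuple[float, float],
                       seed_positions: list[float],
                       mu_slack: float = 5.0,
                       width_max: float | None = None,
                       with_offset: bool = False,
                       cost_tol: float = 1e-8,
                       max_evals: int = 500) -> FitResult:
    """Two-stage bounded Gaussian multi-peak fit within a window.

    Stage 1 freezes positions at the seeds and fits amplitudes/widths
    (amplitudes initialized from local TPA, widths from the half-width at half
    maximum); stage 2 releases all parameters with mu bounded to seed +-
    ``mu_slack`` cm^-1.  With ``with_offset`` an additive constant absorbs any
    residual flat background the baseline correction left in the window.
    Standard errors come from the residual-scaled inverse Gauss-Newton
    Hessian.  Non-convergence is flagged, not raised.
    """
    w = spectrum.wavenumbers
    lo, hi = window
    sel = (w >= lo) & (w <= hi)
    if sel.sum() < 3:
        raise ParameterError("fit window contains too few channels")
    wx = w[sel]
    y = spectrum.intensities[sel]
    step = float(np.median(np.diff(wx)))

    seeds = sorted(float(s) for s in seed_positions)
    if not seeds:
        raise ParameterError("at least one seed position required")
    if any(s < lo or s > hi for s in seeds):
        raise ParameterError("all seed positions must lie inside the window")
    # merge seeds closer than the grid spacing
    merged: list[float] = []
    for s in seeds:
        if merged and s - merged[-1] < step:
            merged[-1] = 0.5 * (merged[-1] + s)
        else:
            merged.append(s)
    seeds = merged
    n_par = 3 * len(seeds)
    if wx.size < 4 * n_par:
        raise OverParameterizedError(
            f"{len(seeds)} components need >= {4 * n_par} channels, window has {wx.size}")

    raw_integral = float(np.abs(y).sum() * step)
    area_hi = max(10.0 * raw_integral, 1e-12)
    width_lo = step
    width_hi = float(hi - lo) if width_max is None else min(float(width_max), float(hi - lo))

    # --- initialization
    areas0, widths0 = [], []
    for s in seeds:
        i = int(np.argmin(np.abs(wx - s)))
        amp = max(float(y[i]), 1e-12)
        # half width at half maximum scan
        half = amp / 2.0
        j = i
        while j + 1 < wx.size and y[j + 1] > half:
            j += 1
        k = i
        while k - 1 >= 0 and y[k - 1] > half:
            k -= 1
        hwhm = max(0.5 * (wx[min(j, wx.size - 1)] - wx[max(k, 0)]), step)
        sig0 = float(np.clip(2.0 * hwhm / np.sqrt(2.0 * np.log(2.0)), width_lo, width_hi))
        a0 = float(np.clip(amp * sig0 * SQRT_PI_OVER_2, 1e-9, area_hi))
        areas0.append(a0)
        widths0.append(sig0)

    y_lo, y_hi = float(y.min()), float(y.max())
    off0 = max(y_lo, 0.0) if with_offset else 0.0
    off_lb, off_ub = y_lo - (y_hi - y_lo), y_hi

    def model(theta_full: np.ndarray) -> np.ndarray:
        comps = _unpack(theta_full[:n_par])
        base = theta_full[n_par] if with_offset else 0.0
        return gaussian_mixture_value(comps, wx) + base

    # --- stage 1: mu frozen
    def resid1(p: np.ndarray) -> np.ndarray:
        theta = np.empty(n_par + (1 if with_offset else 0))
        theta[0:n_par:3] = p[0:2 * len(seeds):2]
        theta[1:n_par:3] = seeds
        theta[2:n_par:3] = p[1:2 * len(seeds):2]
        if with_offset:
            theta[n_par] = p[-1]
        return model(theta) - y

    p0 = np.empty(2 * len(seeds) + (1 if with_offset else 0))
    p0[0:2 * len(seeds):2] = areas0
    p0[1:2 * len(seeds):2] = widths0
    lb1 = np.empty_like(p0)
    ub1 = np.empty_like(p0)
    lb1[0:2 * len(seeds):2], ub1[0:2 * len(seeds):2] = 0.0, area_hi
    lb1[1:2 * len(seeds):2], ub1[1:2 * len(seeds):2] = width_lo, width_hi
    if with_offset:
        p0[-1] = off0
        lb1[-1], ub1[-1] = off_lb, off_ub
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol1 = least_squares(resid1, np.clip(p0, lb1, ub1), bounds=(lb1, ub1),
                             ftol=cost_tol, xtol=1e-12, max_nfev=max_evals)
    rss1 = float(2.0 * sol1.cost)

    # --- stage 2: all parameters free
    n_free = n_par + (1 if with_offset else 0)
    theta0 = np.empty(n_free)
    theta0[0:n_par:3] = sol1.x[0:2 * len(seeds):2]
    theta0[1:n_par:3] = seeds
    theta0[2:n_par:3] = sol1.x[1:2 * len(seeds):2]
    lb = np.empty(n_free)
    ub = np.empty(n_free)
    lb[0:n_par:3], ub[0:n_par:3] = 0.0, area_hi
    lb[1:n_par:3] = np.maximum(np.array(seeds) - mu_slack, lo)
    ub[1:n_par:3] = np.minimum(np.array(seeds) + mu_slack, hi)
    lb[2:n_par:3], ub[2:n_par:3] = width_lo, width_hi
    if with_offset:
        theta0[-1] = sol1.x[-1]
        lb[-1], ub[-1] = off_lb, off_ub
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol2 = least_squares(lambda t: model(t) - y, np.clip(theta0, lb, ub),
                             bounds=(lb, ub), ftol=cost_tol, xtol=1e-12,
                             max_nfev=max_evals)
    rss = float(2.0 * sol2.cost)
    resid = sol2.fun
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")

    dof = max(wx.size - n_free, 1)
    s2 = rss / dof
    JTJ = sol2.jac.T @ sol2.jac
    try:
        cov = np.linalg.inv(JTJ) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JTJ) * s2
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))[:n_par]

    return FitResult(components=_unpack(sol2.x[:n_par]), standard_errors=se,
                     residuals=resid, r_squared=r2,
                     converged=bool(sol2.status > 0), window=(float(lo), float(hi)),
                     rss_stage1=rss1, rss=rss,
                     offset=float(sol2.x[n_par]) if with_offset else 0.0)
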