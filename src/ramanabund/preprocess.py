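"""Spectral preprocessing: Savitzky-Golay smoothing, airPLS baseline removal,
min-max normalization, SNR estimation and SNR-distribution normality testing.

The chain is order-fixed and deterministic: smooth -> baseline -> normalize.

airPLS (adaptive iteratively reweighted penalized least squares) estimates the
fluorescence baseline z as the minimizer of

    sum_i w_i (x_i - z_i)^2 + lambda * sum_i (Delta^2 z_i)^2

with weights re-estimated each iteration: w_i = 0 where x_i >= z_i (peak
candidates), w_i = exp(t * (z_i - x_i) / |d-|_1) where x_i < z_i (t is the
iteration index and d- the vector of negative residuals).  Iteration stops when
|d-|_1 < 0.001 * |x|_1 or at the iteration cap.  The penalized system is
pentadiagonal and solved with a banded Cholesky-style solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.signal import savgol_filter
from scipy import stats

from .config import PipelineConfig
from .io import Spectrum, SpectrumSet


class ParameterError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass
class BaselineResult:
    baseline: np.ndarray
    corrected: np.ndarray
    iterations_used: int
    converged: bool


@dataclass
class SnrEntry:
    snr: float
    signal: float
    noise: float
    silent_window: tuple[float, float]


@dataclass
class SnrReport:
    entries: list[SnrEntry] = field(default_factory=list)
    ks_by_group: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return np.array([e.snr for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"snr": e.snr, "signal": e.signal, "noise": e.noise} for e in self.entries]
        )


# ---------------------------------------------------------------------------
# smoothing


def smooth_sg(spectrum: Spectrum, window: int = 7, order: int = 3) -> Spectrum:
    """Savitzky-Golay least-squares local-polynomial smoothing.

    Boundary samples are produced by evaluating the polynomial fitted to the
    first/last full window (scipy's ``interp`` mode), so no data are invented
    beyond the 400/2000 cm^-1 limits.  Polynomials of degree <= order are
    reproduced exactly.
    """
    if window % 2 == 0:
        raise ParameterError("SG window must be odd")
    if order >= window:
        raise ParameterError("SG order must be smaller than the window")
    if len(spectrum) < window:
        raise ParameterError("spectrum shorter than the SG window")
    sm = savgol_filter(spectrum.intensities, window, order, mode="interp")
    return spectrum.copy_with(sm, smoothed=True)


# ---------------------------------------------------------------------------
# baseline


def _whittaker_banded(lam: float, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonals of lam * D2'D2 for the second-difference penalty."""
    d0 = np.full(n, 6.0 * lam)
    d0[[0, -1]] = lam
    d0[[1, -2]] = 5.0 * lam
    d1 = np.full(n - 1, -4.0 * lam)
    d1[[0, -1]] = -2.0 * lam
    d2 = np.full(n - 2, lam)
    return d0, d1, d2


def baseline_airpls(spectrum: Spectrum, lam: float = 100.0,
                    max_iterations: int = 15) -> BaselineResult:
    """Estimate and subtract the fluorescence baseline with airPLS."""
    if lam <= 0:
        raise ParameterError("lambda must be positive")
    if max_iterations < 1:
        raise ParameterError("max_iterations must be >= 1")
    x = spectrum.intensities
    if not np.all(np.isfinite(x)):
        raise DegenerateDataError("non-finite intensities")
    n = x.size
    d0, d1, d2 = _whittaker_banded(lam, n)
    w = np.ones(n)
    z = x.copy()
    abs_x_sum = np.abs(x).sum()
    converged = False
    it = 0
    for t in range(1, max_iterations + 1):
        it = t
        ab = np.zeros((5, n))
        ab[0, 2:] = d2
        ab[1, 1:] = d1
        ab[2] = d0 + w
        ab[3, :-1] = d1
        ab[4, :-2] = d2
        try:
            z = solve_banded((2, 2), ab, w * x)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise DegenerateDataError(
                f"singular smoother system (try a different lambda): {exc}")
        d = x - z
        dneg = d[d < 0]
        dneg_sum = float(np.abs(dneg).sum())
        if dneg.size == 0 or dneg_sum < 0.001 * abs_x_sum:
            converged = True
            break
        w = np.where(d >= 0, 0.0, np.exp(t * np.abs(d) / dneg_sum))
        w[0] = w[-1] = np.exp(t * np.abs(dneg).max() / dneg_sum)
    return BaselineResult(baseline=z, corrected=x - z, iterations_used=it,
                          converged=converged)


# ---------------------------------------------------------------------------
# normalization


def normalize_minmax(spectrum: Spectrum) -> Spectrum:
    """Scale intensities to exactly [0, 1]; records the affine scale in meta."""
    x = spectrum.intensities
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DegenerateDataError("constant spectrum: min-max range is zero")
    return spectrum.copy_with((x - lo) / (hi - lo), normalized=True,
                              norm_scale=hi - lo, norm_offset=lo)


# ---------------------------------------------------------------------------
# SNR


def compute_snr(corrected: Spectrum,
                silent_window: tuple[float, float] = (1750.0, 1850.0),
                signal_max_cm1: float = 1800.0) -> SnrEntry:
    """SNR = max corrected intensity (signal region) / silent-region noise SD."""
    w = corrected.wavenumbers
    sil = (w >= silent_window[0]) & (w <= silent_window[1])
    if not sil.any():
        raise ParameterError("silent window outside the spectral axis")
    sig = w <= signal_max_cm1
    noise = float(corrected.intensities[sil].std())
    if noise <= 0:
        raise DegenerateDataError("zero noise in the silent region")
    signal = float(corrected.intensities[sig].max())
    return SnrEntry(snr=signal / noise, signal=signal, noise=noise,
                    silent_window=silent_window)


def ks_normality(values_by_group: dict, min_size: int = 8,
                 method: str = "plugin") -> dict:
    """Per-group KS normality test of SNR values.

    ``plugin`` (default) runs a one-sample KS test against a normal law with
    the group's estimated mean/SD; its p-values are anti-conservative because
    the reference parameters are estimated from the same data.  ``lilliefors``
    applies the proper small-sample correction (statsmodels).
    """
    out = {}
    for group, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size < min_size:
            raise DegenerateDataError(
                f"group {group!r}: need >= {min_size} values, got {v.size}")
        sd = v.std(ddof=1)
        if sd == 0:
            raise DegenerateDataError(f"group {group!r}: zero variance")
        if method == "plugin":
            stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
        elif method == "lilliefors":
            from statsmodels.stats.diagnostic import lilliefors

            stat, p = lilliefors(v, dist="norm")
        else:
            raise ParameterError(f"unknown method {method!r}")
        out[group] = (float(stat), float(p))
    return out


# ---------------------------------------------------------------------------
# full chain


def preprocess_spectrum(spectrum: Spectrum, config: PipelineConfig | None = None
                        ) -> tuple[Spectrum, SnrEntry]:
    """smooth -> airPLS baseline -> SNR on the corrected signal -> min-max."""
    cfg = config or PipelineConfig()
    sm = smooth_sg(spectrum, cfg.sg_window, cfg.sg_order)
    bl = baseline_airpls(sm, cfg.airpls_lambda, cfg.airpls_max_iterations)
    corrected = sm.copy_with(bl.corrected, baseline_corrected=True)
    snr = compute_snr(corrected, cfg.silent_window, cfg.snr_signal_max)
    return normalize_minmax(corrected), snr


def preprocess_set(sset: SpectrumSet, config: PipelineConfig | None = None
                   ) -> tuple[SpectrumSet, SnrReport]:
    """Preprocess every spectrum of a set; returns the processed set + SNR report.

    The per-spectrum min-max scale is recorded in the label column
    ``norm_scale`` so that quantities measured on normalized spectra can be
    mapped back to baseline-corrected units.
    """
    cfg = config or PipelineConfig()
    report = SnrReport()
    rows = []
    scales = []
    for i in range(len(sset)):
        proc, snr = preprocess_spectrum(sset.spectrum(i), cfg)
        rows.append(proc.intensities)
        scales.append(proc.meta["norm_scale"])
        report.entries.append(snr)
    labels = sset.labels.copy().reset_index(drop=True)
    labels["norm_scale"] = scales
    labels["snr"] = report.values
    if "culture_time_h" in labels.columns:
        groups = {t: report.values[(labels["culture_time_h"] == t).to_numpy()]
                  for t in labels["culture_time_h"].unique()}
        report.ks_by_group = {
            t: v for t, v in
            ((t, vals) for t, vals in groups.items() if len(vals) >= 8)
        }
        report.ks_by_group = ks_normality(report.ks_by_group) if report.ks_by_group else {}
    return SpectrumSet(sset.wavenumbers, np.vstack(rows), labels), report
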