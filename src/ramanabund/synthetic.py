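"""Synthetic single-cell Raman dataset generator with ground truth.

The generator emulates the statistical structure the pipeline assumes:
400-2000 cm^-1 spectra sampled at the 2 cm^-1 instrument resolution, a large
smooth fluorescence baseline (cubic polynomial + broad Gaussian), narrow
area-parameterized Gaussian bands, white Gaussian channel noise whose level is
set from a per-cell target peak signal-to-noise ratio drawn uniformly from
[3, 7], three replicate acquisitions per cell differing only by noise and a
<= 1 cm^-1 spectral jitter, and eleven culture times (0-24 h) mapped onto the
lag / log / stationary growth phases.

Band kinetics come in three flavours:

* growth-phase marker bands follow the class-level phase multipliers
  (protein 1.0 / 1.4 / 1.8, nucleic acid 1.0 / 1.6 / 1.2, excluded
  carbohydrate 1.0 / 1.1 / 1.5) raised to a band-specific response exponent
  gamma -- strongly induced "sentinel" bands have large gamma;
* metabolic "clock" bands carry deterministic zero-mean within-phase contrast
  patterns (orthogonal-design rows), so cells sampled at different hours
  inside one phase remain distinguishable while phase means are untouched;
* a stable CH-deformation reference band at 1450 cm^-1 anchors the intensity
  scale.

Band amplitudes are equalized on the stacked profile so that every band
reaches a comparable peak height at its loudest culture time; cell-to-cell
brightness is log-normal (CV 15%) with a small independent per-band
log-normal variation.  Ground truth (per cell x band areas, noise levels,
labels) is emitted alongside every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CULTURE_TIMES_H, PhaseBoundaries
from .io import SpectrumSet

SQRT_PI_OVER_2 = float(np.sqrt(np.pi / 2.0))


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class Band:
    center: float          # cm^-1
    width: float           # sigma in the area-parameterized convention
    biomolecule: str       # protein | nucleic_acid | excluded
    gamma: float = 1.0     # phase-response exponent (phase bands)
    kind: str = "phase"    # phase | clock | reference


#: Phase multipliers per biomolecule class (lag, log, stationary).
PHASE_MULTIPLIERS: dict[str, tuple[float, float, float]] = {
    "protein": (1.0, 1.4, 1.8),
    "nucleic_acid": (1.0, 1.6, 1.2),
    "excluded": (1.0, 1.1, 1.5),
}

# characteristic (assignment-table) bands + excluded 810/940, unassigned
# sentinel marker bands, the 1450 reference, and metabolic clock bands
DEFAULT_BANDS: tuple[Band, ...] = (
    Band(726, 7, "nucleic_acid", 1.6), Band(782, 7, "nucleic_acid", 1.0),
    Band(786, 7, "nucleic_acid", 0.5), Band(1096, 8, "nucleic_acid", 1.8),
    Band(1576, 7, "nucleic_acid", 0.8), Band(1586, 7, "nucleic_acid", 1.3),
    Band(760, 7, "protein", 0.5), Band(980, 8, "protein", 1.4),
    Band(1002, 6, "protein", 1.0), Band(1034, 7, "protein", 1.7),
    Band(810, 7, "excluded", 1.0), Band(940, 8, "excluded", 1.3),
    # sentinel markers (strongly induced; outside the assignment table)
    Band(645, 8, "nucleic_acid", 3.6), Band(1483, 8, "nucleic_acid", 4.0),
    Band(670, 7, "nucleic_acid", 2.6), Band(853, 8, "protein", 3.0),
    Band(1660, 9, "protein", 2.4), Band(1243, 8, "protein", 2.0),
    Band(877, 8, "excluded", 3.0), Band(1124, 8, "excluded", 2.4),
    # intensity reference
    Band(1450, 7, "protein", 0.0, kind="reference"),
    # metabolic clock bands
    Band(505, 8, "excluded", 0.0, "clock"), Band(540, 8, "excluded", 0.0, "clock"),
    Band(575, 8, "excluded", 0.0, "clock"), Band(620, 7, "protein", 0.0, "clock"),
    Band(1148, 7, "excluded", 0.0, "clock"), Band(1175, 7, "protein", 0.0, "clock"),
    Band(1210, 8, "protein", 0.0, "clock"), Band(1270, 7, "protein", 0.0, "clock"),
    Band(1320, 8, "nucleic_acid", 0.0, "clock"), Band(1355, 8, "nucleic_acid", 0.0, "clock"),
    Band(1395, 8, "nucleic_acid", 0.0, "clock"), Band(1510, 7, "nucleic_acid", 0.0, "clock"),
    Band(1535, 7, "nucleic_acid", 0.0, "clock"), Band(1620, 7, "protein", 0.0, "clock"),
    Band(1700, 8, "protein", 0.0, "clock"),
)

# zero-mean, max-abs-1 within-phase contrast patterns
_PAT3 = np.array([[-1, 0, 1], [1, -1, 0], [0, 1, -1],
                  [-1, 1, 0], [0, -1, 1], [1, 0, -1]], float)
_PAT4 = np.array([[1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1],
                  [-1, 1, -1, 1], [-1, -1, 1, 1], [-1, 1, 1, -1]], float)


@dataclass
class GeneratorDesign:
    axis_start: float = 400.0
    axis_stop: float = 2000.0
    axis_step: float = 2.0
    bands: tuple[Band, ...] = DEFAULT_BANDS
    culture_times: tuple[float, ...] = CULTURE_TIMES_H
    cells_per_time: int = 40
    replicates: int = 3
    cell_cv: float = 0.15          # shared log-normal brightness CV
    band_cv: float = 0.03          # independent per-band log-normal CV
    snr_range: tuple[float, float] = (3.0, 7.0)
    clock_depth: float = 1.0       # within-phase modulation depth (clock bands)
    marker_clock_depth: float = 0.0  # within-phase modulation of marker bands
    multiplier_floor: float = 0.05
    peak_loudness: float = 0.92    # stacked peak height relative to the reference
    baseline_amplitude: float = 30.0  # fluorescence scale, x reference peak
    jitter_cm1: float = 0.5
    phase_boundaries: PhaseBoundaries = field(default_factory=PhaseBoundaries)
    #: override of the class-level phase multipliers (lag, log, stationary)
    phase_multipliers: dict | None = None

    @property
    def axis(self) -> np.ndarray:
        return np.arange(self.axis_start, self.axis_stop + self.axis_step / 2,
                         self.axis_step)

    def validate(self) -> None:
        ax = self.axis
        for b in self.bands:
            if not (ax[0] < b.center < ax[-1]):
                raise DesignError(f"band {b.center:g} cm^-1 outside the axis")
            if b.width <= 0:
                raise DesignError(f"band {b.center:g}: width must be positive")
        for mult in PHASE_MULTIPLIERS.values():
            if any(m <= 0 for m in mult):
                raise DesignError("phase multipliers must be positive")
        if not (0 < self.snr_range[0] <= self.snr_range[1]):
            raise DesignError("snr_range must be a positive increasing pair")


@dataclass
class GroundTruth:
    areas: pd.DataFrame           # cells x bands, raw generated units
    labels: pd.DataFrame          # cell_id, culture_time_h, phase, snr_target
    noise_sigma: np.ndarray       # per cell: effective post-averaging noise SD
    band_table: pd.DataFrame      # center, width, class, kind, gamma
    multipliers: np.ndarray       # bands x times trajectory matrix
    baseline_amplitude: float = 30.0


# ---------------------------------------------------------------------------
# design expansion


def _phase_index(design: GeneratorDesign) -> np.ndarray:
    b = design.phase_boundaries
    return np.array([{"lag": 0, "log": 1, "stationary": 2}[b.phase_of(t)]
                     for t in design.culture_times])


def trajectory_matrix(design: GeneratorDesign) -> np.ndarray:
    """bands x culture-times multiplier matrix (deterministic)."""
    phase_idx = _phase_index(design)
    n_t = len(design.culture_times)
    M = np.zeros((len(design.bands), n_t))
    clock_i = 0
    for bi, band in enumerate(design.bands):
        if band.kind == "clock":
            for p in range(3):
                idx = np.flatnonzero(phase_idx == p)
                k = idx.size
                if k == 0:
                    continue
                if k <= 3:
                    pat = _PAT3[clock_i % len(_PAT3)][:k]
                else:
                    pat = _PAT4[(clock_i + p) % len(_PAT4)][:k]
                pat = pat - pat.mean()
                m = np.abs(pat).max()
                if m > 0:
                    pat = pat / m
                M[bi, idx] = 1.0 + design.clock_depth * pat
            clock_i += 1
        elif band.kind == "reference":
            M[bi, :] = 1.0
        else:
            table = design.phase_multipliers or PHASE_MULTIPLIERS
            mult = table[band.biomolecule]
            depth = design.marker_clock_depth
            for p in range(3):
                idx = np.flatnonzero(phase_idx == p)
                k = idx.size
                if depth > 0 and k > 0:
                    pat = (_PAT3[(bi + p) % len(_PAT3)][:k] if k <= 3
                           else _PAT4[(bi + p) % len(_PAT4)][:k])
                    pat = pat - pat.mean()
                    m = np.abs(pat).max()
                    if m > 0:
                        pat = pat / m
                    M[bi, idx] = mult[p] ** band.gamma * (1 + depth * pat)
                else:
                    M[bi, idx] = mult[p] ** band.gamma
    return np.maximum(M, design.multiplier_floor)


def _profiles(design: GeneratorDesign, jitter: float = 0.0) -> np.ndarray:
    """Unit-area band profiles (bands x channels)."""
    ax = design.axis
    mu = np.array([b.center for b in design.bands]) + jitter
    sig = np.array([b.width for b in design.bands])
    return np.exp(-2.0 * (ax[None, :] - mu[:, None]) ** 2 / sig[:, None] ** 2) \
        / (sig[:, None] * SQRT_PI_OVER_2)


def base_areas(design: GeneratorDesign, M: np.ndarray | None = None,
               rounds: int = 4) -> np.ndarray:
    """Equal-loudness base areas: each band's stacked peak reaches
    ``peak_loudness`` (reference = 1) at its loudest culture time."""
    if M is None:
        M = trajectory_matrix(design)
    sig = np.array([b.width for b in design.bands])
    is_ref = np.array([b.kind == "reference" for b in design.bands])
    amp = np.where(is_ref, 1.0, design.peak_loudness / M.max(axis=1))
    prof_unit_amp = _profiles(design) * (sig * SQRT_PI_OVER_2)[:, None]
    ax = design.axis
    for _ in range(rounds):
        stack = (amp[:, None] * M).T @ prof_unit_amp  # times x channels
        for bi, band in enumerate(design.bands):
            if is_ref[bi]:
                continue
            ci = int(np.argmin(np.abs(ax - band.center)))
            ti = int(np.argmax(M[bi]))
            local = stack[ti, ci]
            if local > 0:
                amp[bi] *= design.peak_loudness / local
    return amp * sig * SQRT_PI_OVER_2


def reference_peak_level(design: GeneratorDesign, M: np.ndarray,
                         areas: np.ndarray) -> float:
    prof = _profiles(design)
    return max(float((areas * M[:, t] @ prof).max())
               for t in range(len(design.culture_times)))


def baseline_profile(design: GeneratorDesign, scale: float) -> np.ndarray:
    """Smooth fluorescence: cubic polynomial plus a broad Gaussian hump."""
    ax = design.axis
    xx = (ax - ax[0]) / (ax[-1] - ax[0])
    poly = 0.5 + 0.8 * xx - 0.9 * xx ** 2 + 0.4 * xx ** 3
    hump = np.exp(-0.5 * ((ax - 900.0) / 450.0) ** 2)
    return scale * (poly + hump)


# ---------------------------------------------------------------------------
# generation


def generate_dataset(design: GeneratorDesign | None = None, seed: int = 42,
                     *, _null: bool = False) -> tuple[SpectrumSet, GroundTruth]:
    """Generate a replicate-level dataset; deterministic given (design, seed)."""
    d = design or GeneratorDesign()
    d.validate()
    rng = np.random.default_rng(seed)
    ax = d.axis
    M_struct = trajectory_matrix(d)
    areas_base = base_areas(d, M_struct)
    S_ref = reference_peak_level(d, M_struct, areas_base)
    M = np.ones_like(M_struct) if _null else M_struct

    n_bands = len(d.bands)
    spectra, label_rows = [], []
    truth_areas, truth_labels, noise_sigmas = [], [], []
    boundaries = d.phase_boundaries
    cell = 0
    for ti, t in enumerate(d.culture_times):
        for _ in range(d.cells_per_time):
            cf = rng.lognormal(0.0, d.cell_cv)
            cell_areas = areas_base * M[:, ti] * cf * \
                rng.lognormal(0.0, d.band_cv, n_bands)
            u = rng.uniform(*d.snr_range)
            # raw per-replicate noise; 3-replicate averaging + SG(7,3) smoothing
            # each shrink white noise by ~1/sqrt(3), so the post-chain level is
            # sigma_raw / 3
            sigma_raw = 3.0 * cf * S_ref / u
            base = baseline_profile(d, d.baseline_amplitude * cf * S_ref)
            cid = f"c{cell:04d}"
            for rep in range(d.replicates):
                jit = rng.uniform(-d.jitter_cm1, d.jitter_cm1)
                clean = cell_areas @ _profiles(d, jit)
                acquired = clean + base + rng.normal(0.0, sigma_raw, ax.size)
                spectra.append(acquired)
                label_rows.append({
                    "spectrum_id": f"{cid}r{rep}", "cell_id": cid,
                    "culture_time_h": float(t),
                    "phase": boundaries.phase_of(float(t)),
                    "replicate_index": rep,
                })
            truth_areas.append(cell_areas)
            truth_labels.append({"cell_id": cid, "culture_time_h": float(t),
                                 "phase": boundaries.phase_of(float(t)),
                                 "snr_target": float(u)})
            noise_sigmas.append(sigma_raw / 3.0)
            cell += 1

    band_cols = [f"{b.center:g}" for b in d.bands]
    truth = GroundTruth(
        areas=pd.DataFrame(truth_areas, columns=band_cols),
        labels=pd.DataFrame(truth_labels),
        noise_sigma=np.asarray(noise_sigmas),
        band_table=pd.DataFrame(
            [{"center": b.center, "width": b.width, "biomolecule": b.biomolecule,
              "kind": b.kind, "gamma": b.gamma} for b in d.bands]),
        multipliers=M,
        baseline_amplitude=d.baseline_amplitude)
    sset = SpectrumSet(ax, np.vstack(spectra), pd.DataFrame(label_rows))
    return sset, truth


def generate_null_dataset(design: GeneratorDesign | None = None, seed: int = 42
                          ) -> tuple[SpectrumSet, GroundTruth]:
    """As generate_dataset but with every multiplier forced to 1 (no phase or
    clock effects) -- the null configuration for statistical calibration."""
    return generate_dataset(design, seed, _null=True)


# ---------------------------------------------------------------------------
# targeted fit-level simulation


def simulate_shoulder_spectra(n_spectra: int = 100, snr: float = 5.0,
                              seed: int = 7,
                              mu: tuple[float, float] = (1096.8, 1102.2),
                              areas: tuple[float, float] = (1.12, 0.56),
                              widths: tuple[float, float] = (8.0, 8.0),
                              axis: np.ndarray | None = None,
                              replicates: int = 3,
                              ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate preprocessed shoulder-peak spectra for fit-recovery studies.

    Each spectrum emulates the quantification input of one cell: the mean of
    ``replicates`` acquisitions with white Gaussian noise at the stated peak
    signal-to-noise ratio, Savitzky-Golay smoothed with the pipeline settings
    (window 7, order 3).  The default truth is the 1096.8 cm^-1 nucleic-acid
    band with its 1102.2 cm^-1 shoulder (main area 1.12).  Returns
    (axis, spectra[n, channels], truth).
    """
    from scipy.signal import savgol_filter

    rng = np.random.default_rng(seed)
    ax = axis if axis is not None else np.arange(1060.0, 1140.0 + 0.5, 1.0)
    clean = np.zeros_like(ax)
    for m, a, s in zip(mu, areas, widths):
        clean += a / (s * SQRT_PI_OVER_2) * np.exp(-2.0 * (ax - m) ** 2 / s ** 2)
    sigma = clean.max() / snr
    out = np.empty((n_spectra, ax.size))
    for i in range(n_spectra):
        reps = clean[None, :] + rng.normal(0.0, sigma, (replicates, ax.size))
        out[i] = savgol_filter(reps.mean(axis=0), 7, 3, mode="interp")
    truth = {"mu": mu, "areas": areas, "widths": widths, "noise_sigma": sigma}
    return ax, out, truth
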