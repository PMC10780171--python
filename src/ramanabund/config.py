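"""Pipeline configuration.

All stage parameters live in one dataclass whose defaults are the values the
processing chain is specified with (Savitzky-Golay window 7 / order 3, airPLS
lambda 100 with at most 15 reweighting iterations, min-max normalization,
silent-region noise window around 1800 cm^-1, 80/20 stratified split with
3-fold cross-validated grid search, top-20 gain ranking).  Growth-phase
boundaries are expressed in culture hours and are configurable so organisms
with a shifted lag (e.g. yeast) can reuse the pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

#: Canonical culture-time sampling (hours) of the growth experiment.
CULTURE_TIMES_H: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8, 16, 24)

PHASES = ("lag", "log", "stationary")


@dataclass(frozen=True)
class PhaseBoundaries:
    """Growth-phase mapping: lag if t <= lag_end, log if t <= log_end, else stationary."""

    lag_end_h: float = 2.0
    log_end_h: float = 6.0

    def phase_of(self, t_hours: float) -> str:
        if t_hours <= self.lag_end_h:
            return "lag"
        if t_hours <= self.log_end_h:
            return "log"
        return "stationary"


#: Literature band assignments: wavenumber (cm^-1) -> biomolecule class.
#: 810 and 940 cm^-1 (phosphodiester / polysaccharide / amylose) are excluded
#: from the abundance analysis.
DEFAULT_ASSIGNMENTS: dict[float, str] = {
    726.0: "nucleic_acid",
    782.0: "nucleic_acid",
    786.0: "nucleic_acid",
    1096.0: "nucleic_acid",
    1576.0: "nucleic_acid",
    1586.0: "nucleic_acid",
    760.0: "protein",
    980.0: "protein",
    1002.0: "protein",
    1034.0: "protein",
    810.0: "excluded",
    940.0: "excluded",
}


@dataclass
class PipelineConfig:
    # smoothing
    sg_window: int = 7
    sg_order: int = 3
    # baseline
    airpls_lambda: float = 100.0
    airpls_max_iterations: int = 15
    # SNR
    silent_window: tuple[float, float] = (1750.0, 1850.0)
    snr_signal_max: float = 1800.0
    # peak detection / fitting
    cwt_scale_range: tuple[float, float] = (2.0, 20.0)
    cwt_min_ridge_snr: float = 3.0
    tpa_background_n: int = 3
    tpa_half_width: float = 14.0
    mixed_peak_window: float = 15.0
    fit_window_half_width: float = 20.0
    fit_max_width_cm1: float = 20.0
    # additive constant in quantification fits: absorbs residual flat
    # background left by baseline correction inside the window
    fit_additive_offset: bool = True
    # shoulder probe: flank asymmetry |y(w+d)-y(w-d)|/y(w) above the threshold
    # marks an unresolved shoulder even when wavelet detection cannot split it
    shoulder_probe_cm1: float = 8.0
    shoulder_asymmetry: float = 0.25
    # known shoulder companions (band knowledge): target -> companion positions
    known_shoulders: dict = field(
        default_factory=lambda: {1096.0: (1102.2,), 1096.8: (1102.2,)})
    # mu bound for fits seeded at a-priori known positions (spectral-jitter scale)
    targeted_mu_slack: float = 0.5
    # classifier
    seed: int = 42
    test_fraction: float = 0.2
    cv_folds: int = 3
    grid_n_estimators: tuple[int, ...] = (50, 90, 150)
    grid_max_depth: tuple[int, ...] = (3, 5, 7)
    grid_learning_rate: tuple[float, ...] = (0.1, 0.3)
    # feature extraction
    top_k: int = 20
    dedupe_window: float = 4.0
    assignment_tolerance: float = 2.0
    gain_mode: str = "total"  # "total" or "average"
    variance_keep: float = 0.95
    # phases
    phase_boundaries: PhaseBoundaries = field(default_factory=PhaseBoundaries)
    # abundance
    anova_bonferroni: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phase_boundaries"] = dataclasses.asdict(self.phase_boundaries)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phase_boundaries" in d and isinstance(d["phase_boundaries"], dict):
            d["phase_boundaries"] = PhaseBoundaries(**d["phase_boundaries"])
        for key in ("silent_window", "cwt_scale_range", "grid_n_estimators",
                    "grid_max_depth", "grid_learning_rate"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def phases_for_times(times: Sequence[float],
                     boundaries: PhaseBoundaries | None = None) -> list[str]:
    """Total, deterministic phase labelling for a sequence of culture times."""
    b = boundaries or PhaseBoundaries()
    return [b.phase_of(float(t)) for t in times]
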