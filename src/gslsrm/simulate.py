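"""Instrument-free synthetic fixtures: SRM traces and two-group cohorts.

Every generator is seed-deterministic, and every generated object
carries enough ground truth for parameter-recovery testing (closed-form
Gaussian peak areas; lognormal cohorts with a known fold change and a
binormal closed-form AUC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .biomarker import CohortSample
from .quant import SRMChromatogram

__all__ = [
    "PeakSpec",
    "CohortSpec",
    "simulate_chromatogram",
    "simulate_cohort",
    "theoretical_auc",
    "default_time_grid",
]


@dataclass(frozen=True)
class PeakSpec:
    """Gaussian peak on a linear baseline with additive Gaussian noise."""

    transition_id: str
    rt: float  # minutes
    sd: float  # minutes
    amplitude: float  # counts
    baseline_level: float = 0.0
    baseline_slope: float = 0.0  # counts per minute
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"peak sd must be positive, got {self.sd}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    @property
    def true_area(self) -> float:
        """Closed-form Gaussian area: amplitude x sd x sqrt(2 pi)."""
        return self.amplitude * self.sd * math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class CohortSpec:
    """Two lognormal groups differing by a multiplicative fold change."""

    n_per_group: int
    log_mean: float = 10.0  # control corrected-intensity, ln scale
    log_sd: float = 0.5
    fold_change: float = 5.0  # case multiplier on the natural scale
    creatinine_log_mean: float = 4.5  # ~90 mg/dL
    creatinine_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("need n >= 3 per group")
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")
        if self.log_sd <= 0 or self.creatinine_log_sd <= 0:
            raise ValueError("log-sds must be positive")


def default_time_grid(start: float = 0.0, stop: float = 45.0, step: float = 0.01) -> np.ndarray:
    """Time grid in minutes; 0.01-min default spacing (~1.7 Hz SRM cycling)."""
    return np.arange(start, stop + step / 2, step)


def simulate_chromatogram(spec: PeakSpec, t_grid: np.ndarray | None = None) -> SRMChromatogram:
    """Gaussian peak + linear baseline + seeded noise, clamped at zero counts."""
    t = default_time_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    if t.min() < 0 or t.max() > 45.0:
        raise ValueError("time grid must lie within the 0-45 min gradient span")
    rng = np.random.default_rng(spec.seed)
    signal = spec.amplitude * np.exp(-0.5 * ((t - spec.rt) / spec.sd) ** 2)
    baseline = spec.baseline_level + spec.baseline_slope * t
    noise = rng.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd > 0 else 0.0
    intensity = np.clip(signal + baseline + noise, 0.0, None)
    return SRMChromatogram(transition_id=spec.transition_id, time=t, intensity=intensity)


def simulate_cohort(spec: CohortSpec) -> tuple[list[CohortSample], np.ndarray]:
    """Draw a labeled cohort; returns (samples, true corrected intensities).

    Raw intensity is constructed as corrected x creatinine, so dividing
    by creatinine recovers the generative corrected value exactly.
    Sample order: all cases first, then all controls.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    mu_case = spec.log_mean + math.log(spec.fold_change)
    corrected = np.concatenate([
        rng.lognormal(mu_case, spec.log_sd, size=n),
        rng.lognormal(spec.log_mean, spec.log_sd, size=n),
    ])
    creatinine = rng.lognormal(spec.creatinine_log_mean, spec.creatinine_log_sd, size=2 * n)
    samples = [
        CohortSample(
            sample_id=f"{'case' if i < n else 'control'}{i % n + 1:03d}",
            group="case" if i < n else "control",
            intensity=corrected[i] * creatinine[i],
            creatinine=creatinine[i],
        )
        for i in range(2 * n)
    ]
    return samples, corrected


def theoretical_auc(spec: CohortSpec) -> float:
    """Binormal AUC on the log scale: Phi(ln(fold change) / (log_sd * sqrt(2)))."""
    effect = math.log(spec.fold_change)
    pooled = math.sqrt(2.0) * spec.log_sd
    return float(norm.cdf(effect / pooled))
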