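"""Chromatographic peak integration and semi-quantitative validation math.

The integrator is a deliberately simple, testable stand-in for vendor
peak-picking software: trapezoidal integration above a linear baseline
drawn between window-edge local minima, with a noise-floor detection
flag at 3x the median absolute deviation of the out-of-window signal.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SRMChromatogram",
    "Peak",
    "PeakAreaTable",
    "ND",
    "integrate_peak",
    "area_ratio_table",
    "matrix_factor",
    "recovery",
    "linearity",
    "detection_summary",
    "read_long_chromatograms",
    "write_area_table",
    "read_area_table",
    "round_sigfig",
]

#: Marker used for not-detected cells in exported tables.
ND = "ND"


@dataclass(frozen=True)
class SRMChromatogram:
    """A single transition's trace: time (minutes, strictly increasing) and intensity."""

    transition_id: str
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(f"time axis of {self.transition_id!r} is not strictly increasing")
        if np.any(y < 0):
            raise ValueError(f"negative intensities in {self.transition_id!r}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class Peak:
    """An integrated peak; ``detected=False`` means apex below the noise floor."""

    rt: float
    area: float
    height: float
    window: tuple[float, float]
    detected: bool = True


def integrate_peak(
    chrom: SRMChromatogram,
    window: tuple[float, float],
    noise_mad_factor: float = 3.0,
    edge_fraction: float = 0.1,
) -> Peak:
    """Integrate the trace over ``window`` above a linear edge-to-edge baseline.

    Baseline endpoints are the local intensity minima within the leading
    and trailing ``edge_fraction`` of the window; the area is the
    trapezoidal integral of the baseline-subtracted signal clamped at 0.
    A peak is flagged not-detected when its apex is below
    ``noise_mad_factor`` x MAD of the out-of-window intensities.
    """
    start, stop = window
    if not start < stop:
        raise ValueError(f"empty or inverted window ({start}, {stop})")
    t, y = chrom.time, chrom.intensity
    mask = (t >= start) & (t <= stop)
    if mask.sum() < 3:
        raise ValueError(
            f"window ({start}, {stop}) covers {int(mask.sum())} samples of "
            f"{chrom.transition_id!r}; need at least 3"
        )
    tw, yw = t[mask], y[mask]

    n_edge = max(2, int(math.ceil(edge_fraction * tw.size)))
    i_left = int(np.argmin(yw[:n_edge]))
    i_right = tw.size - n_edge + int(np.argmin(yw[-n_edge:]))
    t0, y0 = tw[i_left], yw[i_left]
    t1, y1 = tw[i_right], yw[i_right]
    if t1 > t0:
        baseline = y0 + (tw - t0) * (y1 - y0) / (t1 - t0)
    else:
        baseline = np.full_like(yw, y0)
    signal = np.clip(yw - baseline, 0.0, None)
    area = float(np.trapezoid(signal, tw))

    # apex from a 5-point moving average so single-point noise spikes don't
    # trip the detection floor; subtract the median smoothed residual, which
    # cancels the upward offset the minimum-based baseline leaves under noise
    w = min(5, signal.size)
    smooth = np.convolve(signal, np.ones(w) / w, mode="same")
    i_apex = int(np.argmax(smooth))
    height = max(float(smooth[i_apex] - np.median(smooth)), 0.0)
    rt = float(tw[i_apex])

    outside = y[~mask]
    noise = float(stats.median_abs_deviation(outside)) if outside.size else 0.0
    detected = height > noise_mad_factor * noise and height > 0.0
    if not detected:
        area = 0.0
    return Peak(rt=rt, area=area, height=height, window=(start, stop), detected=detected)


@dataclass
class PeakAreaTable:
    """Rectangular analyte x sample area table; NaN encodes not-detected."""

    data: pd.DataFrame  # index: analyte ids, columns: sample ids, values: areas or NaN

    def __post_init__(self) -> None:
        if (self.data.to_numpy(dtype=float, na_value=np.nan) < 0).any():
            raise ValueError("negative peak areas in table")

    @property
    def analytes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def round_sigfig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def area_ratio_table(
    numerator: PeakAreaTable, denominator: PeakAreaTable, sig: int = 3
) -> pd.DataFrame:
    """Per-analyte ratio%% = 100 x numerator / denominator, to ``sig`` significant figures.

    Not-detected or zero denominators yield NaN (undefined), never an
    exception: ND markers must not silently inflate ratios.
    """
    shared = [a for a in numerator.analytes if a in set(denominator.analytes)]
    if not shared:
        raise ValueError("no shared analyte ids between the two tables")
    num = numerator.data.loc[shared]
    den = denominator.data.loc[shared]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 100.0 * num.to_numpy(dtype=float) / den.to_numpy(dtype=float)
    ratio[~np.isfinite(ratio)] = np.nan
    out = pd.DataFrame(ratio, index=shared, columns=num.columns)
    return out.map(lambda v: round_sigfig(v, sig) if np.isfinite(v) else v)


def matrix_factor(
    area_std: float,
    area_matrix: float,
    area_spiked: float,
    convention: str = "standard",
) -> float:
    """Matrix factor in percent.

    ``standard``: 100 x (spiked - matrix) / std — the usual bioanalytical
    reading (spiked-minus-blank over neat standard). ``alternate``:
    100 x (spiked - std) / matrix, the other parse of the ambiguous
    published formula.
    """
    if min(area_std, area_matrix, area_spiked) < 0:
        raise ValueError("peak areas must be non-negative")
    if convention == "standard":
        if area_std == 0:
            raise ZeroDivisionError("area_std is zero; matrix factor undefined")
        return 100.0 * (area_spiked - area_matrix) / area_std
    if convention == "alternate":
        if area_matrix == 0:
            raise ZeroDivisionError("area_matrix is zero; matrix factor undefined")
        return 100.0 * (area_spiked - area_std) / area_matrix
    raise ValueError(f"unknown convention {convention!r}")


def recovery(area_processed: float, area_reference: float) -> float:
    """Recovery%% = 100 x processed / reference, reported to two decimals."""
    if area_reference <= 0:
        raise ValueError("area_reference must be positive")
    return round(100.0 * area_processed / area_reference, 2)


def linearity(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Unweighted OLS of area on concentration: (slope, intercept, Pearson r)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (concentration, area) points")
    conc, area = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("all concentrations are equal; calibration line undefined")
    fit = stats.linregress(conc, area)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def detection_summary(table: PeakAreaTable) -> pd.DataFrame:
    """Per-sample tally of detected vs not-detected analytes."""
    values = table.data
    detected = values.notna().sum(axis=0).astype(int)
    nd = values.isna().sum(axis=0).astype(int)
    return pd.DataFrame({"detected": detected, "not_detected": nd})


# ---------------------------------------------------------------------------
# I/O


def read_long_chromatograms(path: str | Path) -> list[SRMChromatogram]:
    """Read long-format delimited text (transition_id, time, intensity)."""
    df = pd.read_csv(path)
    required = {"transition_id", "time", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chromatogram file {path} missing columns: {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("transition_id", sort=False):
        grp = grp.sort_values("time")
        out.append(
            SRMChromatogram(
                transition_id=str(tid),
                time=grp["time"].to_numpy(dtype=float),
                intensity=grp["intensity"].to_numpy(dtype=float),
            )
        )
    return out


def write_area_table(table: PeakAreaTable, path: str | Path) -> None:
    """Write an area table as CSV with the ND marker for missing cells."""
    out = table.data.copy()
    out.index.name = "analyte"
    out.to_csv(path, na_rep=ND)


def read_area_table(path: str | Path) -> PeakAreaTable:
    """Read a CSV area table; ND cells become NaN."""
    df = pd.read_csv(path, index_col=0, na_values=[ND], thousands=",")
    return PeakAreaTable(df.astype(float))
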