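"""Aggregation time courses from ThT fluorescence and light scattering.

A spectral series is reduced to a scalar-per-time-point course by band
averaging: 475-485 nm for thioflavin-T emission (excited at 435 nm) and
550-555 nm for 90° light scattering at 550 nm incident light.  Plateau
values are summarized over a stated time window per replicate, then
across replicates as mean ± sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectralSeries, band_average

__all__ = [
    "THT_WINDOW_NM",
    "SCATTERING_WINDOW_NM",
    "TimeCourse",
    "WindowSummary",
    "timecourse",
    "tht_timecourse",
    "scattering_timecourse",
    "window_mean",
]

THT_WINDOW_NM = (475.0, 485.0)
SCATTERING_WINDOW_NM = (550.0, 555.0)


@dataclass
class TimeCourse:
    """(time, value, replicate) triples for one sample and modality."""

    modality: str
    data: pd.DataFrame  # columns: time_h, value, replicate
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        required = {"time_h", "value", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"TimeCourse missing columns {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("TimeCourse needs at least one point")
        if (self.data["time_h"] < 0).any():
            raise ValueError("negative times in TimeCourse")

    @property
    def replicates(self) -> list[int]:
        return sorted(self.data["replicate"].unique().tolist())

    def subset(self, replicates) -> "TimeCourse":
        keep = self.data[self.data["replicate"].isin(list(replicates))]
        return TimeCourse(self.modality, keep.reset_index(drop=True), self.window)


@dataclass
class WindowSummary:
    """Per-replicate plateau means with their grand mean ± SD."""

    per_replicate: dict[int, float]
    mean: float
    sd: float
    window: tuple[float, float]
    small_n: bool = False
    notes: list[str] = field(default_factory=list)


def timecourse(series: SpectralSeries, lo: float, hi: float) -> TimeCourse:
    """Band-average every spectrum of a series over [lo, hi]."""
    rows = [
        (s.time_h, band_average(s, lo, hi), s.replicate) for s in series
    ]
    df = pd.DataFrame(rows, columns=["time_h", "value", "replicate"])
    df = df.sort_values(["replicate", "time_h"]).reset_index(drop=True)
    return TimeCourse(series.modality, df, (lo, hi))


def tht_timecourse(series: SpectralSeries) -> TimeCourse:
    """ThT fibril signal: emission averaged between 475 and 485 nm."""
    if series.axis_kind != "wavelength_nm":
        raise ValueError("ThT time course requires an emission wavelength axis")
    return timecourse(series, *THT_WINDOW_NM)


def scattering_timecourse(series: SpectralSeries) -> TimeCourse:
    """Aggregate-mass signal: scattering averaged between 550 and 555 nm."""
    if series.axis_kind != "wavelength_nm":
        raise ValueError("scattering time course requires a wavelength axis")
    return timecourse(series, *SCATTERING_WINDOW_NM)


def window_mean(tc: TimeCourse, t_lo: float, t_hi: float) -> WindowSummary:
    """Per-replicate mean over the closed time window, plus grand stats.

    The grand mean is the arithmetic mean of the per-replicate means and
    the SD is the sample (ddof=1) SD across replicates.  A single
    replicate yields SD 0 with a small-sample flag rather than an error,
    so toy fixtures fail soft.
    """
    if not t_lo <= t_hi:
        raise ValueError(f"time window requires t_lo <= t_hi, got [{t_lo}, {t_hi}]")
    per: dict[int, float] = {}
    for rep, grp in tc.data.groupby("replicate"):
        inwin = grp[(grp["time_h"] >= t_lo) & (grp["time_h"] <= t_hi)]
        if len(inwin) == 0:
            raise ValueError(
                f"replicate {rep}: no time points in window [{t_lo}, {t_hi}] h"
            )
        per[int(rep)] = float(inwin["value"].mean())
    vals = np.array(list(per.values()))
    small_n = len(vals) == 1
    sd = 0.0 if small_n else float(vals.std(ddof=1))
    notes = ["n=1: SD reported as 0"] if small_n else []
    return WindowSummary(
        per_replicate=per,
        mean=float(vals.mean()),
        sd=sd,
        window=(t_lo, t_hi),
        small_n=small_n,
        notes=notes,
    )
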