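"""Spectral data model, delimited-text I/O, and shared spectral math.

Every downstream stage (ThT/scattering time courses, amide-I fits, CD
classification, RET difference spectra) works on :class:`Spectrum` and
:class:`SpectralSeries` objects built here.  Files are plain delimited
text with a small ``# key: value`` metadata header, in either a long
dialect (axis, intensity, time_h, replicate columns) or a wide dialect
(one intensity column per time point).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "SpectralSeries",
    "SpectraParseError",
    "read_spectra",
    "write_spectra",
    "band_average",
    "savitzky_golay",
    "combine",
]

AxisKind = Literal["wavelength_nm", "wavenumber_cm-1"]
_AXIS_KINDS = ("wavelength_nm", "wavenumber_cm-1")

#: Relative axis-alignment tolerance (fraction of axis span).
AXIS_ALIGN_RTOL = 1e-6


@dataclass
class Spectrum:
    """One acquisition: an ordered axis with one intensity per point.

    ``axis_kind`` is ``"wavelength_nm"`` for emission/CD/scattering or
    ``"wavenumber_cm-1"`` for FTIR.  Intensity units are carried as a
    label and never converted implicitly.
    """

    axis_kind: AxisKind
    axis: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    time_h: float = 0.0
    replicate: int = 0
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis_kind not in _AXIS_KINDS:
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        if self.axis.ndim != 1 or self.axis.size < 2:
            raise ValueError("axis must be 1-D with at least 2 points")
        if self.intensity.shape != self.axis.shape:
            raise ValueError(
                f"axis and intensity lengths differ: "
                f"{self.axis.size} vs {self.intensity.size}"
            )
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")

    @property
    def ascending(self) -> "Spectrum":
        """A view with the axis sorted ascending (copy if reversal needed)."""
        if self.axis[0] <= self.axis[-1]:
            return self
        return replace(self, axis=self.axis[::-1].copy(), intensity=self.intensity[::-1].copy())


@dataclass
class SpectralSeries:
    """Time- and replicate-indexed collection of spectra of one modality."""

    modality: str
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra:
            kind = self.spectra[0].axis_kind
            ref = self.spectra[0].axis
            for s in self.spectra:
                if s.axis_kind != kind:
                    raise ValueError("mixed axis kinds in one series")
                if s.axis.shape != ref.shape or not np.allclose(
                    s.axis, ref, rtol=0, atol=AXIS_ALIGN_RTOL * _span(ref)
                ):
                    raise ValueError("member axes differ within one series")
            for rep in {s.replicate for s in self.spectra}:
                times = [s.time_h for s in self.spectra if s.replicate == rep]
                if any(b < a for a, b in zip(times, times[1:])):
                    raise ValueError(
                        f"times not non-decreasing within replicate {rep}"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    @property
    def axis_kind(self) -> str:
        return self.spectra[0].axis_kind

    @property
    def replicates(self) -> list[int]:
        return sorted({s.replicate for s in self.spectra})

    @property
    def times(self) -> list[float]:
        return sorted({s.time_h for s in self.spectra})

    def subset(self, replicates: Iterable[int]) -> "SpectralSeries":
        keep = set(replicates)
        return SpectralSeries(
            self.modality, [s for s in self.spectra if s.replicate in keep]
        )

    def at(self, time_h: float, replicate: int | None = None, tol: float = 0.5) -> list[Spectrum]:
        """Spectra nearest to ``time_h`` within ``tol`` hours (per replicate)."""
        out = []
        reps = self.replicates if replicate is None else [replicate]
        for rep in reps:
            cands = [s for s in self.spectra if s.replicate == rep]
            if not cands:
                continue
            best = min(cands, key=lambda s: abs(s.time_h - time_h))
            if abs(best.time_h - time_h) <= tol:
                out.append(best)
        if not out:
            raise ValueError(
                f"no spectrum within {tol} h of t={time_h} h in series "
                f"{self.modality!r}"
            )
        return out


def _span(axis: np.ndarray) -> float:
    return float(abs(axis[-1] - axis[0]))


class SpectraParseError(ValueError):
    """Malformed spectra file (bad header, ragged rows, non-monotone axis)."""


def _read_header(lines: list[str]) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    else:
        i = len(lines)
    return meta, i


def read_spectra(path: str | Path, dialect: str = "long") -> SpectralSeries:
    """Read a delimited-text spectra file into a validated series.

    Parameters
    ----------
    dialect : {"long", "wide"}
        Long files carry ``axis, intensity, time_h, replicate`` columns;
        wide files carry the axis in the first column and one intensity
        column per time point, headed ``t=<hours>``.

    The first lines may be ``# key: value`` metadata (``modality``,
    ``axis_kind``, ``units``, ``sample_id``).
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    meta, start = _read_header(lines)
    modality = meta.get("modality", "unknown")
    axis_kind = meta.get("axis_kind", "wavelength_nm")
    units = meta.get("units", "a.u.")
    sample_id = meta.get("sample_id", path.stem)
    if axis_kind not in _AXIS_KINDS:
        raise SpectraParseError(
            f"{path}: unknown axis_kind {axis_kind!r} in header"
        )
    body = "\n".join(lines[start:])
    sep = "\t" if "\t" in (lines[start] if start < len(lines) else "") else ","
    try:
        # round_trip float parsing keeps write->read lossless
        df = pd.read_csv(io.StringIO(body), sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise SpectraParseError(f"{path}: {exc}") from None

    spectra: list[Spectrum] = []
    if dialect == "long":
        required = {"axis", "intensity", "time_h", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise SpectraParseError(
                f"{path}: missing required columns {sorted(missing)} "
                f"(line {start + 1})"
            )
        if df[["axis", "intensity"]].isna().any().any():
            bad = int(df[["axis", "intensity"]].isna().any(axis=1).idxmax())
            raise SpectraParseError(
                f"{path}: ragged/missing values near line {start + 2 + bad}"
            )
        for (rep, t), grp in df.groupby(["replicate", "time_h"], sort=True):
            axis = grp["axis"].to_numpy(float)
            d = np.diff(axis)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise SpectraParseError(
                    f"{path}: non-monotone axis for replicate {rep}, "
                    f"t={t} h (starting line {start + 2 + int(grp.index[0])})"
                )
            spectra.append(
                Spectrum(
                    axis_kind=axis_kind,
                    axis=axis,
                    intensity=grp["intensity"].to_numpy(float),
                    sample_id=sample_id,
                    time_h=float(t),
                    replicate=int(rep),
                    units=units,
                )
            )
    elif dialect == "wide":
        axis_col = df.columns[0]
        axis = df[axis_col].to_numpy(float)
        d = np.diff(axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraParseError(f"{path}: non-monotone axis column")
        for col in df.columns[1:]:
            name = str(col)
            t = float(name.split("=", 1)[1]) if name.startswith("t=") else float(name)
            spectra.append(
                Spectrum(
                    axis_kind=axis_kind,
                    axis=axis.copy(),
                    intensity=df[col].to_numpy(float),
                    sample_id=sample_id,
                    time_h=t,
                    replicate=0,
                    units=units,
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    spectra.sort(key=lambda s: (s.replicate, s.time_h))
    return SpectralSeries(modality, spectra)


def write_spectra(series: SpectralSeries, path: str | Path) -> None:
    """Write a series as a long-dialect CSV with metadata header."""
    path = Path(path)
    first = series.spectra[0]
    rows = []
    for s in series:
        for x, y in zip(s.axis, s.intensity):
            rows.append((x, y, s.time_h, s.replicate))
    df = pd.DataFrame(rows, columns=["axis", "intensity", "time_h", "replicate"])
    with path.open("w") as fh:
        fh.write(f"# modality: {series.modality}\n")
        fh.write(f"# axis_kind: {first.axis_kind}\n")
        fh.write(f"# units: {first.units}\n")
        fh.write(f"# sample_id: {first.sample_id}\n")
        # %.17g round-trips float64 exactly, so read-back is bitwise equal
        df.to_csv(fh, index=False, float_format="%.17g")


def band_average(s: Spectrum, lo: float, hi: float) -> float:
    """Mean intensity over the closed axis window [lo, hi].

    The closed interval matches the conventional "averaged between a and
    b nm" phrasing of spectroscopic methods sections.
    """
    if not lo < hi:
        raise ValueError(f"band window requires lo < hi, got [{lo}, {hi}]")
    mask = (s.axis >= lo) & (s.axis <= hi)
    if not mask.any():
        raise ValueError(
            f"empty band window [{lo}, {hi}]: axis spans "
            f"[{s.axis.min():g}, {s.axis.max():g}] {s.axis_kind}"
        )
    return float(s.intensity[mask].mean())


def _check_uniform(axis: np.ndarray, rtol: float = 1e-6) -> float:
    d = np.diff(axis)
    step = float(np.mean(d))
    if np.max(np.abs(d - step)) > rtol * _span(axis):
        raise ValueError(
            "axis is not uniformly spaced; resample before smoothing"
        )
    return step


def savitzky_golay(
    s: Spectrum,
    points: int = 13,
    order: int = 2,
    edge: str = "reflect",
) -> Spectrum:
    """Savitzky--Golay least-squares polynomial smoothing.

    The 13-point quadratic default is the classical smoothing filter used
    for UV fluorescence spectra.  ``edge`` is ``"reflect"`` (mirror
    padding) or ``"truncate"`` (fit shrinking polynomials at the ends).
    """
    if points % 2 != 1:
        raise ValueError(f"points must be odd, got {points}")
    if order >= points:
        raise ValueError(f"order ({order}) must be < points ({points})")
    _check_uniform(s.axis)
    mode = {"reflect": "mirror", "truncate": "interp"}.get(edge)
    if mode is None:
        raise ValueError(f"unknown edge policy {edge!r}")
    smoothed = savgol_filter(s.intensity, points, order, mode=mode)
    return replace(s, intensity=smoothed)


def combine(a: Spectrum, b: Spectrum, ca: float, cb: float) -> Spectrum:
    """Pointwise linear combination ``ca*a + cb*b`` on a common grid.

    If the axes agree within tolerance the combination is taken directly;
    otherwise both spectra are linearly interpolated onto the union of
    their axis points restricted to the overlapping range.
    """
    if a.axis_kind != b.axis_kind:
        raise ValueError(
            f"axis kinds differ: {a.axis_kind} vs {b.axis_kind}"
        )
    a = a.ascending
    b = b.ascending
    tol = AXIS_ALIGN_RTOL * max(_span(a.axis), _span(b.axis))
    if a.axis.shape == b.axis.shape and np.allclose(a.axis, b.axis, rtol=0, atol=tol):
        return replace(a, intensity=ca * a.intensity + cb * b.intensity)
    lo = max(a.axis[0], b.axis[0])
    hi = min(a.axis[-1], b.axis[-1])
    if lo >= hi:
        raise ValueError(
            f"disjoint axes: [{a.axis[0]:g}, {a.axis[-1]:g}] vs "
            f"[{b.axis[0]:g}, {b.axis[-1]:g}]"
        )
    grid = np.union1d(a.axis, b.axis)
    grid = grid[(grid >= lo) & (grid <= hi)]
    ia = np.interp(grid, a.axis, a.intensity)
    ib = np.interp(grid, b.axis, b.intensity)
    return replace(a, axis=grid, intensity=ca * ia + cb * ib)
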