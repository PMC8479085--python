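"""Inhibition-percentage statistic and per-timepoint t-test summaries.

The screening readout is the inhibition percentage

    IP = (1 - F*/F0) x 100 %,

where F0 is the plateau ThT signal of the parent peptide alone and
F* = F_tot - c * F_frag is the mixture plateau corrected for the signal
the fragment contributes on its own.  The correction factor c (default
0.7) is the ratio of the fragment concentration in the mixture to the
concentration of the pure-fragment reference measurement, under the
assumption that ThT fluorescence is linear in peptide concentration.
Negative IPs (fibrillogenesis enhancement) and IPs above 100 %
(over-correction) are reported and flagged, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fibrillogenesis import TimeCourse, window_mean

__all__ = [
    "DEFAULT_CORRECTION",
    "DEFAULT_PLATEAU_WINDOW_H",
    "InhibitionInput",
    "InhibitionResult",
    "TTestSummary",
    "corrected_mixture_signal",
    "inhibition_percentage",
    "ip_pipeline",
    "timepoint_ttests",
]

DEFAULT_CORRECTION = 0.7
DEFAULT_PLATEAU_WINDOW_H = (32.0, 48.0)


@dataclass(frozen=True)
class InhibitionInput:
    """Plateau signals entering one IP evaluation (arbitrary units)."""

    F_tot: float    # parent + fragment mixture
    F_frag: float   # fragment alone, at its reference concentration
    F0: float       # parent alone
    correction: float = DEFAULT_CORRECTION

    def __post_init__(self) -> None:
        if self.F0 <= 0:
            raise ValueError(f"F0 must be positive, got {self.F0}")
        if not 0.0 < self.correction <= 1.0:
            raise ValueError(
                f"correction must be in (0, 1], got {self.correction}"
            )


@dataclass
class InhibitionResult:
    """IP with replicate spread and provenance of its inputs."""

    ip: float                     # percent
    per_replicate: list[float]
    sd: float
    inputs: dict
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.per_replicate:
            mean = float(np.mean(self.per_replicate))
            if abs(mean - self.ip) > 1e-9 * max(1.0, abs(mean)):
                raise ValueError("ip must equal the mean of per-replicate IPs")


def corrected_mixture_signal(inp: InhibitionInput) -> float:
    """F* = F_tot - correction * F_frag (may be negative; caller flags)."""
    return inp.F_tot - inp.correction * inp.F_frag


def inhibition_percentage(inp: InhibitionInput) -> float:
    """IP = (1 - F*/F0) x 100, with F* the corrected mixture signal."""
    f_star = corrected_mixture_signal(inp)
    return (1.0 - f_star / inp.F0) * 100.0


def ip_pipeline(
    mix: TimeCourse,
    frag: TimeCourse,
    parent: TimeCourse,
    window: tuple[float, float] = DEFAULT_PLATEAU_WINDOW_H,
    correction: float = DEFAULT_CORRECTION,
) -> InhibitionResult:
    """Plateau-window IP from the three measured time courses.

    Each course is summarized by :func:`window_mean` over ``window``.
    When the three series carry the same number of replicates, IP is
    computed per matched replicate index and the spread is the sample SD
    of those per-replicate IPs; otherwise the grand means are used and
    the result carries an ``unpaired`` flag with no spread estimate.
    """
    t_lo, t_hi = window
    wm_mix = window_mean(mix, t_lo, t_hi)
    wm_frag = window_mean(frag, t_lo, t_hi)
    wm_parent = window_mean(parent, t_lo, t_hi)

    flags: list[str] = []
    reps_mix = sorted(wm_mix.per_replicate)
    reps_frag = sorted(wm_frag.per_replicate)
    reps_parent = sorted(wm_parent.per_replicate)
    paired = len(reps_mix) == len(reps_frag) == len(reps_parent)

    per: list[float] = []
    if paired:
        for rm, rf, rp in zip(reps_mix, reps_frag, reps_parent):
            inp = InhibitionInput(
                F_tot=wm_mix.per_replicate[rm],
                F_frag=wm_frag.per_replicate[rf],
                F0=wm_parent.per_replicate[rp],
                correction=correction,
            )
            per.append(inhibition_percentage(inp))
        ip = float(np.mean(per))
        sd = 0.0 if len(per) == 1 else float(np.std(per, ddof=1))
        if len(per) == 1:
            flags.append("small_n")
    else:
        inp = InhibitionInput(
            F_tot=wm_mix.mean,
            F_frag=wm_frag.mean,
            F0=wm_parent.mean,
            correction=correction,
        )
        ip = inhibition_percentage(inp)
        sd = 0.0
        flags.append("unpaired")

    if ip < 0:
        flags.append("negative_ip")
    if ip > 100:
        flags.append("over_correction")
    f_star = wm_mix.mean - correction * wm_frag.mean
    if f_star < 0:
        flags.append("negative_f_star")
    return InhibitionResult(
        ip=ip,
        per_replicate=per,
        sd=sd,
        inputs={
            "F_tot": wm_mix.mean,
            "F_frag": wm_frag.mean,
            "F0": wm_parent.mean,
            "F_star": f_star,
            "correction": correction,
            "window_h": list(window),
        },
        flags=flags,
    )


@dataclass
class TTestSummary:
    """Per-timepoint two-sample t-test p-values and their mean ± SD."""

    times: list[float]
    p_values: list[float]
    mean_p: float
    sd_p: float
    variant: str
    degenerate_times: list[float] = field(default_factory=list)


def timepoint_ttests(
    group_a: TimeCourse,
    group_b: TimeCourse,
    t_lo: float,
    t_hi: float,
    variant: str = "student",
    time_tol: float = 1e-6,
) -> TTestSummary:
    """Two-tailed two-sample t-test at every shared time point.

    ``variant`` is ``"student"`` (pooled variance, the conventional
    reading of a plain "t-test") or ``"welch"``.  The summary reports the
    per-timepoint p-values and their mean ± SD, the style in which
    screening studies quote "p = 0.021 ± 0.008" over a time range.

    Time points with zero variance in both groups give p = 1 when the
    two groups are exactly equal; otherwise the point is recorded as
    degenerate with p = nan and excluded from the mean.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")

    def groups(tc: TimeCourse) -> dict[float, np.ndarray]:
        out: dict[float, np.ndarray] = {}
        for t, grp in tc.data.groupby("time_h"):
            out[float(t)] = grp["value"].to_numpy(float)
        return out

    ga, gb = groups(group_a), groups(group_b)
    shared = []
    for ta in ga:
        if not t_lo <= ta <= t_hi:
            continue
        for tb in gb:
            if abs(ta - tb) <= time_tol:
                shared.append((ta, tb))
                break
    if not shared:
        raise ValueError(
            f"no shared time points in [{t_lo}, {t_hi}] h between the groups"
        )
    shared.sort()

    times, ps, degenerate = [], [], []
    for ta, tb in shared:
        a, b = ga[ta], gb[tb]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"t={ta} h: need >= 2 replicates per group "
                f"(got {len(a)} and {len(b)})"
            )
        if a.std() == 0.0 and b.std() == 0.0:
            # zero variance in both groups: all values equal within group
            if a[0] == b[0]:
                p = 1.0
            else:
                p = float("nan")
                degenerate.append(ta)
        else:
            res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
            p = float(res.pvalue)
        times.append(ta)
        ps.append(p)
    valid = np.array([p for p in ps if np.isfinite(p)])
    mean_p = float(valid.mean()) if valid.size else float("nan")
    sd_p = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
    return TTestSummary(times, ps, mean_p, sd_p, variant, degenerate)
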