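"""Synthetic multi-modality spectral datasets with known ground truth.

Raw kinetic spectra from peptide-screening assays are rarely deposited,
so every analysis stage here is validated against simulated data whose
ground truth is known by construction.  Aggregation follows the
Finke--Watzky two-step model (nucleation A -> B at rate ``k_n``,
autocatalytic growth A + B -> 2B at rate ``k_e``), which has a closed
form for the aggregated mass and reproduces lag-free saturating ThT
curves.  Observation models place emission bands where the analysis
windows read them: ThT near 480 nm, 90° scattering near 550 nm,
phenylalanine at 287 nm, tyrosine at 310 nm, and amide-I component bands
in the 1600-1700 cm⁻¹ region.

All generators are deterministic given their parameters and a master
seed; replicate noise streams are spawned from the master seed, so
changing the seed changes noise realizations but never the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .ret import RetExperiment
from .spectra import SpectralSeries, Spectrum
from .structure import AmideBandSet, DEFAULT_AMIDE_BANDS

__all__ = [
    "KineticParams",
    "ObservationModel",
    "MixtureTruth",
    "parent_kinetics",
    "fragment_kinetics",
    "simulate_aggregation",
    "aggregation_state",
    "simulate_tht_series",
    "simulate_scattering_series",
    "simulate_mixture",
    "simulate_emission_pair",
    "simulate_amide_series",
    "THT_GRID_NM",
    "SCATTERING_GRID_NM",
    "EMISSION_GRID_NM",
    "AMIDE_GRID_CM1",
]

#: Wavelength / wavenumber grids matching instrument acquisition ranges.
THT_GRID_NM = np.arange(450.0, 521.0, 1.0)
SCATTERING_GRID_NM = np.arange(530.0, 571.0, 1.0)
EMISSION_GRID_NM = np.arange(250.0, 351.0, 1.0)
AMIDE_GRID_CM1 = np.arange(1580.0, 1722.0, 2.0)

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class KineticParams:
    """Finke--Watzky two-step aggregation parameters.

    ``k_n`` is the pseudo-first-order nucleation rate (h⁻¹), ``k_e`` the
    autocatalytic growth rate (µM⁻¹ h⁻¹), ``A0`` the total peptide
    concentration (µM) and ``fibril_fraction_max`` the fraction of
    aggregated mass that ends up fibrillar (ThT-visible).
    """

    k_n: float = 0.01
    k_e: float = 0.01
    A0: float = 35.0
    fibril_fraction_max: float = 1.0

    def __post_init__(self) -> None:
        if self.k_n < 0 or self.k_e < 0:
            raise ValueError("rates must be >= 0")
        if self.A0 <= 0:
            raise ValueError("A0 must be > 0")
        if not 0.0 <= self.fibril_fraction_max <= 1.0:
            raise ValueError("fibril_fraction_max must be in [0, 1]")


def parent_kinetics() -> KineticParams:
    """Parent-peptide assay conditions: 35 µM, ThT saturation by ~1 day."""
    return KineticParams(k_n=0.01, k_e=0.01, A0=35.0)


def fragment_kinetics(A0: float = 100.0) -> KineticParams:
    """Aggregating-fragment conditions: slower, plateau by ~2 days."""
    return KineticParams(k_n=0.005, k_e=0.002, A0=A0)


@dataclass(frozen=True)
class ObservationModel:
    """Maps concentrations to spectra: band positions, gains, noise.

    ``tht_binding_capacity`` (a.u. per µM fibril) is per-peptide: the
    most hydrophobic fragments bind ThT more avidly than others.
    ``amorphous_fraction`` routes part of the aggregated mass into
    ThT-silent but scattering-visible aggregates.
    """

    tht_binding_capacity: float = 1.0       # a.u. per µM fibril
    scattering_coefficient: float = 1.0     # a.u. per µM aggregate
    amorphous_fraction: float = 0.0
    tht_centre_nm: float = 480.0
    tht_fwhm_nm: float = 20.0
    scattering_centre_nm: float = 550.0
    scattering_fwhm_nm: float = 60.0
    phe_centre_nm: float = 287.0
    phe_fwhm_nm: float = 30.0
    tyr_centre_nm: float = 310.0
    tyr_fwhm_nm: float = 34.0
    quench_drift_amp: float = 0.0           # fractional initial Tyr quench
    quench_drift_tau_h: float = 20.0
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "tht": 1.0,
            "scattering": 1.0,
            "emission": 0.5,
            "ftir": 0.0,
        }
    )

    def __post_init__(self) -> None:
        if self.tht_binding_capacity < 0 or self.scattering_coefficient < 0:
            raise ValueError("observation coefficients must be >= 0")
        if not 0.0 <= self.amorphous_fraction <= 1.0:
            raise ValueError("amorphous_fraction must be in [0, 1]")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class MixtureTruth:
    """Ground truth for mixture scenarios.

    ``true_inhibition`` is the fractional suppression of parent fibril
    mass in the mixture; ``interaction_efficiency`` is the Förster
    transfer-efficiency profile over time for RET pairs (a constant or a
    callable of time in hours).
    """

    true_inhibition: float = 0.0
    interaction_efficiency: float | Callable[[np.ndarray], np.ndarray] = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_inhibition <= 1.0:
            raise ValueError("true_inhibition must be in [0, 1]")

    def efficiency_at(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if callable(self.interaction_efficiency):
            e = np.asarray(self.interaction_efficiency(times), dtype=float)
        else:
            e = np.full_like(times, float(self.interaction_efficiency))
        if np.any((e < 0) | (e > 1)):
            raise ValueError("efficiency profile must stay in [0, 1]")
        return e


def _band(grid: np.ndarray, centre: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / _FWHM
    return np.exp(-0.5 * ((grid - centre) / sigma) ** 2)


def simulate_aggregation(p: KineticParams, times: np.ndarray) -> np.ndarray:
    """Closed-form Finke--Watzky fibril concentration (µM) at each time.

    B(t) = A0 - (k_n/k_e + A0) / (1 + (k_n/(k_e A0)) exp((k_n + k_e A0) t)),
    scaled by ``fibril_fraction_max``.  The pure-nucleation limit
    (k_e -> 0) reduces to first-order conversion A0 (1 - exp(-k_n t)).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be non-negative and non-decreasing")
    kn, ke, A0 = p.k_n, p.k_e, p.A0
    if kn == 0.0:
        b = np.zeros_like(times)
    elif ke * A0 < 1e-12 * kn:
        b = A0 * (1.0 - np.exp(-kn * times))
    else:
        rate = kn + ke * A0
        # exp overflow at large t is benign: the quotient goes to zero
        with np.errstate(over="ignore"):
            b = A0 - (kn / ke + A0) / (1.0 + (kn / (ke * A0)) * np.exp(rate * times))
    return p.fibril_fraction_max * b


def aggregation_state(
    p: KineticParams, times: np.ndarray, amorphous_fraction: float = 0.0
) -> dict[str, np.ndarray]:
    """Monomeric / fibrillar / amorphous mass balance over time (µM).

    The aggregated mass follows the Finke--Watzky closed form; a fixed
    fraction of it is amorphous (scattering-visible, ThT-silent).  The
    three pools sum to A0 at every time point.
    """
    aggregated = simulate_aggregation(replace(p, fibril_fraction_max=1.0), times)
    aggregated = aggregated * p.fibril_fraction_max
    fibrillar = (1.0 - amorphous_fraction) * aggregated
    amorphous = aggregated - fibrillar
    monomer = p.A0 - aggregated
    return {"monomer": monomer, "fibrillar": fibrillar, "amorphous": amorphous}


def _series_from_signal(
    signal: np.ndarray,
    times: np.ndarray,
    grid: np.ndarray,
    profile: np.ndarray,
    modality: str,
    sample_id: str,
    noise_sd: float,
    replicates: int,
    seed: int,
    units: str = "a.u.",
    axis_kind: str = "wavelength_nm",
) -> SpectralSeries:
    """Spectra = signal(t) * band profile + iid Gaussian noise."""
    streams = np.random.SeedSequence(seed).spawn(replicates)
    spectra = []
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        for t, amp in zip(times, signal):
            clean = amp * profile
            noisy = clean if noise_sd == 0.0 else clean + rng.normal(0.0, noise_sd, grid.size)
            spectra.append(
                Spectrum(
                    axis_kind=axis_kind,
                    axis=grid.copy(),
                    intensity=noisy,
                    sample_id=sample_id,
                    time_h=float(t),
                    replicate=rep,
                    units=units,
                )
            )
    return SpectralSeries(modality, spectra)


def simulate_tht_series(
    curve: np.ndarray,
    times: np.ndarray,
    obs: ObservationModel,
    replicates: int = 3,
    seed: int = 0,
    sample_id: str = "sample",
) -> SpectralSeries:
    """ThT emission series read from a fibril concentration curve (µM)."""
    signal = obs.tht_binding_capacity * np.asarray(curve, dtype=float)
    return _series_from_signal(
        signal,
        times,
        THT_GRID_NM,
        _band(THT_GRID_NM, obs.tht_centre_nm, obs.tht_fwhm_nm),
        "tht_emission",
        sample_id,
        obs.noise_sd.get("tht", 0.0),
        replicates,
        seed,
    )


def simulate_scattering_series(
    aggregate_curve: np.ndarray,
    times: np.ndarray,
    obs: ObservationModel,
    replicates: int = 3,
    seed: int = 0,
    sample_id: str = "sample",
) -> SpectralSeries:
    """90° light-scattering series read from total aggregate mass (µM)."""
    signal = obs.scattering_coefficient * np.asarray(aggregate_curve, dtype=float)
    return _series_from_signal(
        signal,
        times,
        SCATTERING_GRID_NM,
        _band(SCATTERING_GRID_NM, obs.scattering_centre_nm, obs.scattering_fwhm_nm),
        "light_scattering",
        sample_id,
        obs.noise_sd.get("scattering", 0.0),
        replicates,
        seed,
    )


def simulate_mixture(
    parent: KineticParams,
    frag: KineticParams,
    truth: MixtureTruth,
    obs_parent: ObservationModel,
    obs_frag: ObservationModel,
    times: np.ndarray | None = None,
    replicates: int = 3,
    seed: int = 0,
    frag_mixture_ratio: float = 0.7,
) -> tuple[SpectralSeries, SpectralSeries, SpectralSeries]:
    """ThT series for parent alone, fragment alone, and their mixture.

    The design mirrors the screening assay: the parent measured at its
    assay concentration, the fragment-alone reference at its own (higher)
    concentration, and the mixture holding the fragment at
    ``frag_mixture_ratio`` times the reference concentration.  Mixture
    fibril signal is ``(1 - true_inhibition)`` times the parent signal
    plus the fragment-alone signal scaled linearly by the concentration
    ratio (fluorescence assumed linear in peptide concentration, the
    same assumption the analysis correction factor makes).
    """
    if times is None:
        times = np.arange(0.0, 56.0, 4.0)
    times = np.asarray(times, dtype=float)
    fp = simulate_aggregation(parent, times)
    ff = simulate_aggregation(frag, times)
    sig_parent = obs_parent.tht_binding_capacity * fp
    sig_frag = obs_frag.tht_binding_capacity * ff
    sig_mix = (1.0 - truth.true_inhibition) * sig_parent + frag_mixture_ratio * sig_frag

    profile = _band(THT_GRID_NM, obs_parent.tht_centre_nm, obs_parent.tht_fwhm_nm)
    seeds = np.random.SeedSequence(seed).spawn(3)
    noise = obs_parent.noise_sd.get("tht", 0.0)
    parent_series = _series_from_signal(
        sig_parent, times, THT_GRID_NM, profile, "tht_emission",
        "parent", noise, replicates, _child_seed(seeds[0]),
    )
    frag_series = _series_from_signal(
        sig_frag, times, THT_GRID_NM, profile, "tht_emission",
        "fragment", noise, replicates, _child_seed(seeds[1]),
    )
    mix_series = _series_from_signal(
        sig_mix, times, THT_GRID_NM, profile, "tht_emission",
        "mixture", noise, replicates, _child_seed(seeds[2]),
    )
    return parent_series, frag_series, mix_series


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0])


def simulate_emission_pair(
    truth: MixtureTruth,
    obs: ObservationModel,
    times: np.ndarray | None = None,
    a_amplitude: float = 100.0,
    b_amplitude: float = 100.0,
    a_has_phe: bool = True,
    a_has_tyr: bool = False,
    b_has_phe: bool = False,
    b_has_tyr: bool = True,
    replicates: int = 1,
    seed: int = 0,
) -> RetExperiment:
    """Donor/acceptor emission series for a RET experiment.

    Individual peptides are simulated at full assay concentration; the
    mixture holds each at half concentration.  In the mixture the donor
    (Phe) band is scaled by ``1 - E(t)`` and the transferred quanta feed
    the acceptor (Tyr) band through an acceptor emission yield.  A slow
    multiplicative quench drift (water exposure vs. sequestration) acts
    on every Tyr contribution equally, so it cancels in the difference
    spectrum except through the RET term itself.
    """
    if times is None:
        times = np.arange(0.0, 52.0, 4.0)
    times = np.asarray(times, dtype=float)
    e_profile = truth.efficiency_at(times)
    grid = EMISSION_GRID_NM
    phe = _band(grid, obs.phe_centre_nm, obs.phe_fwhm_nm)
    tyr = _band(grid, obs.tyr_centre_nm, obs.tyr_fwhm_nm)
    q = 1.0 - obs.quench_drift_amp * np.exp(-times / obs.quench_drift_tau_h)
    acceptor_yield = 0.8

    noise = obs.noise_sd.get("emission", 0.0)
    seeds = np.random.SeedSequence(seed).spawn(3)
    streams = [
        np.random.SeedSequence(_child_seed(s)).spawn(replicates) for s in seeds
    ]

    def build(name: str, clean_for_t: Callable[[int], np.ndarray], k: int) -> SpectralSeries:
        spectra = []
        for rep, stream in enumerate(streams[k]):
            rng = np.random.default_rng(stream)
            for i, t in enumerate(times):
                clean = clean_for_t(i)
                noisy = clean if noise == 0.0 else clean + rng.normal(0.0, noise, grid.size)
                spectra.append(
                    Spectrum(
                        axis_kind="wavelength_nm",
                        axis=grid.copy(),
                        intensity=noisy,
                        sample_id=name,
                        time_h=float(t),
                        replicate=rep,
                    )
                )
        return SpectralSeries("uv_emission", spectra)

    def spec_a(i: int) -> np.ndarray:
        out = np.zeros_like(grid)
        if a_has_phe:
            out = out + a_amplitude * phe
        if a_has_tyr:
            out = out + a_amplitude * q[i] * tyr
        return out

    def spec_b(i: int) -> np.ndarray:
        out = np.zeros_like(grid)
        if b_has_phe:
            out = out + b_amplitude * phe
        if b_has_tyr:
            out = out + b_amplitude * q[i] * tyr
        return out

    def spec_mix(i: int) -> np.ndarray:
        e = e_profile[i]
        a_part = np.zeros_like(grid)
        if a_has_phe:
            a_part = a_part + a_amplitude * (1.0 - e) * phe
        if a_has_tyr:
            a_part = a_part + a_amplitude * q[i] * tyr
        b_part = np.zeros_like(grid)
        if b_has_phe:
            b_part = b_part + b_amplitude * phe
        if b_has_tyr:
            b_part = b_part + b_amplitude * q[i] * tyr
        transfer = a_amplitude * e * acceptor_yield * q[i] * tyr if a_has_phe else 0.0
        if np.any(np.asarray(transfer) != 0.0):
            a_part = a_part + transfer
        return 0.5 * a_part + 0.5 * b_part

    return RetExperiment(
        f_a=build("peptide_a", spec_a, 0),
        f_b=build("peptide_b", spec_b, 1),
        f_mix=build("mixture", spec_mix, 2),
    )


def fractions_at(
    trajectories: Mapping[str, tuple[float, float]],
    t: float,
    t_span: tuple[float, float],
) -> dict[str, float]:
    """Normalized structure fractions interpolated between start and end.

    Each class moves monotonically (linearly in time) from its start to
    its end fraction over ``t_span``; the result is renormalized to sum
    to one at every time point.
    """
    t0, t1 = t_span
    g = 0.0 if t1 <= t0 else min(max((t - t0) / (t1 - t0), 0.0), 1.0)
    raw = {k: s + (e - s) * g for k, (s, e) in trajectories.items()}
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("fraction trajectories sum to zero")
    return {k: v / total for k, v in raw.items()}


def simulate_amide_series(
    trajectories: Mapping[str, tuple[float, float]],
    bands: AmideBandSet = DEFAULT_AMIDE_BANDS,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    sample_id: str = "sample",
) -> SpectralSeries:
    """Amide-I FTIR series from structure-fraction trajectories.

    Each spectrum is the area-weighted sum of unit-area Gaussians at the
    band-set positions, with the weights given by the (normalized)
    trajectory fractions at that time, plus optional Gaussian noise.
    """
    if times is None:
        times = np.arange(0.0, 52.0, 4.0)
    times = np.asarray(times, dtype=float)
    labels = {b.label for b in bands.bands}
    unknown = set(trajectories) - labels
    if unknown:
        raise ValueError(f"trajectory classes {sorted(unknown)} not in band set")
    grid = AMIDE_GRID_CM1
    t_span = (float(times[0]), float(times[-1]))
    streams = np.random.SeedSequence(seed).spawn(replicates)
    spectra = []
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        for t in times:
            fr = fractions_at(trajectories, float(t), t_span)
            clean = np.zeros_like(grid)
            for b in bands.bands:
                f = fr.get(b.label, 0.0)
                if f:
                    sigma = b.width / _FWHM
                    clean = clean + f * _band(grid, b.centre, b.width) / (
                        sigma * np.sqrt(2.0 * np.pi)
                    )
            noisy = clean if noise_sd == 0.0 else clean + rng.normal(0.0, noise_sd, grid.size)
            spectra.append(
                Spectrum(
                    axis_kind="wavenumber_cm-1",
                    axis=grid.copy(),
                    intensity=noisy,
                    sample_id=sample_id,
                    time_h=float(t),
                    replicate=rep,
                    units="absorbance",
                )
            )
    return SpectralSeries("ftir_amide_i", spectra)
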