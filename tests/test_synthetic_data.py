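"""Ground-truth generators: kinetics, observation models, reproducibility."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fragscreen.fibrillogenesis import tht_timecourse
from fragscreen.spectra import read_spectra, write_spectra
from fragscreen.structure import classify_ftir, decompose_amide_i
from fragscreen.synthetic_data import (
    KineticParams,
    MixtureTruth,
    ObservationModel,
    aggregation_state,
    fractions_at,
    simulate_aggregation,
    simulate_amide_series,
    simulate_emission_pair,
    simulate_mixture,
    simulate_tht_series,
)

NOISELESS = ObservationModel(
    noise_sd={"tht": 0.0, "scattering": 0.0, "emission": 0.0, "ftir": 0.0}
)


def finke_watzky_ode(p: KineticParams, times: np.ndarray) -> np.ndarray:
    """Numerical integration of the two-step rate equations (oracle)."""

    def rhs(_t, y):
        a = y[0]
        b = p.A0 - a
        return [-p.k_n * a - p.k_e * a * b]

    sol = solve_ivp(
        rhs, (times[0], times[-1]), [p.A0], t_eval=times,
        rtol=1e-10, atol=1e-12, method="LSODA",
    )
    return p.fibril_fraction_max * (p.A0 - sol.y[0])


class TestSimulateAggregation:
    def test_no_fibrils_at_time_zero(self):
        assert simulate_aggregation(KineticParams(), np.array([0.0]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_mass_conservation_limit(self):
        p = KineticParams(A0=35.0, fibril_fraction_max=0.9)
        b = simulate_aggregation(p, np.array([1e4]))
        assert b[0] == pytest.approx(0.9 * 35.0, rel=1e-9)

    def test_closed_form_matches_ode_integration(self):
        times = np.linspace(0.0, 100.0, 101)
        p = KineticParams(k_n=0.01, k_e=0.01, A0=35.0)
        closed = simulate_aggregation(p, times)
        ode = finke_watzky_ode(p, times)
        assert np.max(np.abs(closed - ode)) < 1e-6 * p.A0

    def test_pure_first_order_limit(self):
        p = KineticParams(k_n=0.05, k_e=0.0, A0=10.0)
        times = np.linspace(0.0, 50.0, 11)
        expected = 10.0 * (1.0 - np.exp(-0.05 * times))
        assert np.allclose(simulate_aggregation(p, times), expected, rtol=1e-12)

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_aggregation(KineticParams(), np.array([4.0, 2.0]))


class TestAggregationState:
    def test_mass_balance_at_every_time_point(self):
        p = KineticParams(A0=35.0, fibril_fraction_max=0.8)
        times = np.linspace(0.0, 80.0, 41)
        state = aggregation_state(p, times, amorphous_fraction=0.3)
        total = state["monomer"] + state["fibrillar"] + state["amorphous"]
        assert np.max(np.abs(total - p.A0)) < 1e-9


class TestSimulateThtSeries:
    def test_zero_capacity_gives_flat_zero(self):
        times = np.arange(0.0, 12.0, 4.0)
        curve = simulate_aggregation(KineticParams(), times)
        obs = ObservationModel(
            tht_binding_capacity=0.0,
            noise_sd={"tht": 0.0},
        )
        series = simulate_tht_series(curve, times, obs, replicates=1)
        assert all(np.all(s.intensity == 0.0) for s in series)

    def test_zero_noise_recovers_curve_at_band_weighting(self):
        times = np.arange(0.0, 48.0, 4.0)
        p = KineticParams()
        curve = simulate_aggregation(p, times)
        obs = NOISELESS
        series = simulate_tht_series(curve, times, obs, replicates=1)
        tc = tht_timecourse(series)
        sigma = obs.tht_fwhm_nm / (2 * np.sqrt(2 * np.log(2)))
        grid = series.spectra[0].axis
        band = np.exp(-0.5 * ((grid - obs.tht_centre_nm) / sigma) ** 2)
        win = (grid >= 475) & (grid <= 485)
        factor = band[win].mean()
        assert np.allclose(
            tc.data["value"].to_numpy(), obs.tht_binding_capacity * curve * factor,
            rtol=1e-12, atol=1e-12,
        )

    def test_timecourse_noise_matches_sampling_theory(self):
        # SD of an 11-point window mean of iid noise is sd/sqrt(11)
        times = np.array([0.0])
        curve = np.array([0.0])
        obs = ObservationModel(noise_sd={"tht": 2.0})
        series = simulate_tht_series(curve, times, obs, replicates=200, seed=9)
        tc = tht_timecourse(series)
        sd = tc.data["value"].std(ddof=1)
        expected = 2.0 / np.sqrt(11)
        assert abs(sd - expected) / expected < 0.2

    def test_bit_reproducible_for_same_seed(self):
        times = np.arange(0.0, 12.0, 4.0)
        curve = simulate_aggregation(KineticParams(), times)
        a = simulate_tht_series(curve, times, ObservationModel(), replicates=2, seed=5)
        b = simulate_tht_series(curve, times, ObservationModel(), replicates=2, seed=5)
        c = simulate_tht_series(curve, times, ObservationModel(), replicates=2, seed=6)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.intensity, sb.intensity)
        assert any(
            not np.array_equal(sa.intensity, sc.intensity) for sa, sc in zip(a, c)
        )


class TestSimulateMixture:
    def test_null_inhibition_recovers_zero(self):
        from fragscreen.inhibition import ip_pipeline
        from fragscreen.fibrillogenesis import tht_timecourse as tcr

        p, f, m = simulate_mixture(
            KineticParams(), KineticParams(A0=100.0),
            MixtureTruth(true_inhibition=0.0), NOISELESS, NOISELESS, seed=1,
        )
        res = ip_pipeline(tcr(m), tcr(f), tcr(p))
        assert res.ip == pytest.approx(0.0, abs=1e-9)

    def test_full_inhibition_with_silent_fragment_recovers_100(self):
        from fragscreen.inhibition import ip_pipeline
        from fragscreen.fibrillogenesis import tht_timecourse as tcr

        silent = ObservationModel(tht_binding_capacity=0.0, noise_sd={"tht": 0.0})
        p, f, m = simulate_mixture(
            KineticParams(), KineticParams(A0=100.0),
            MixtureTruth(true_inhibition=1.0), NOISELESS, silent, seed=1,
        )
        res = ip_pipeline(tcr(m), tcr(f), tcr(p))
        assert res.ip == pytest.approx(100.0, abs=1e-9)

    def test_series_share_time_grid(self):
        p, f, m = simulate_mixture(
            KineticParams(), KineticParams(A0=100.0),
            MixtureTruth(true_inhibition=0.5),
            ObservationModel(), ObservationModel(), seed=2,
        )
        assert p.times == f.times == m.times


class TestSimulateEmissionPair:
    def test_constant_efficiency_closed_form_bookkeeping(self):
        amp, e = 80.0, 0.5
        exp = simulate_emission_pair(
            MixtureTruth(interaction_efficiency=e), NOISELESS,
            times=np.array([0.0, 4.0]), a_amplitude=amp,
        )
        # mixture donor amplitude is half of amp*(1-E); doubling restores
        # amp*(1-E), so the difference at the Phe peak is -amp*E
        grid = exp.f_mix.spectra[0].axis
        peak = np.argmin(np.abs(grid - 287.0))
        from fragscreen.ret import ret_difference

        d = ret_difference(exp, 4.0, sg_points=0)
        tyr_sigma = NOISELESS.tyr_fwhm_nm / (2 * np.sqrt(2 * np.log(2)))
        tyr_at_phe = np.exp(-0.5 * ((287.0 - NOISELESS.tyr_centre_nm) / tyr_sigma) ** 2)
        transferred = amp * e * 0.8 * tyr_at_phe  # acceptor yield 0.8
        assert d.intensity[peak] == pytest.approx(-amp * e + transferred, rel=1e-9)

    def test_quench_drift_cancels_without_interaction(self):
        obs = ObservationModel(
            quench_drift_amp=0.3,
            noise_sd={"emission": 0.0},
        )
        exp = simulate_emission_pair(
            MixtureTruth(interaction_efficiency=0.0), obs, times=np.array([0.0, 8.0])
        )
        from fragscreen.ret import ret_difference

        d = ret_difference(exp, 8.0)
        assert np.max(np.abs(d.intensity)) < 1e-10


class TestSimulateAmideSeries:
    def test_constant_fractions_round_trip(self):
        traj = {"beta_sheet": (0.3, 0.3), "unordered": (0.5, 0.5), "turn": (0.2, 0.2)}
        series = simulate_amide_series(traj, times=np.array([0.0]), noise_sd=0.0)
        fr = decompose_amide_i(series.spectra[0])
        for label, (start, _) in traj.items():
            assert fr.fractions[label] == pytest.approx(start, abs=1e-3)

    def test_crossover_trajectory_flips_label_at_crossover(self):
        traj = {"unordered": (0.7, 0.1), "beta_sheet": (0.1, 0.7), "turn": (0.2, 0.2)}
        times = np.linspace(0.0, 40.0, 9)
        series = simulate_amide_series(traj, times=times, noise_sd=0.0)
        labels = [classify_ftir(decompose_amide_i(s))[0] for s in series]
        # fractions cross at the midpoint (t = 20 h): unordered before,
        # beta after; tie at the crossover resolves to beta by priority
        switch = labels.index("beta_sheet")
        assert labels[: switch] == ["unordered"] * switch
        assert all(l == "beta_sheet" for l in labels[switch:])
        t_switch = times[switch]
        assert t_switch == pytest.approx(20.0, abs=5.0)

    def test_zero_trajectories_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fractions_at({"beta_sheet": (0.0, 0.0)}, 0.0, (0.0, 1.0))

    def test_generated_files_parse_cleanly(self, tmp_path):
        series = simulate_amide_series(
            {"beta_sheet": (0.2, 0.6), "unordered": (0.8, 0.4)},
            times=np.array([0.0, 8.0]), noise_sd=1e-4, seed=3,
        )
        path = tmp_path / "ftir.csv"
        write_spectra(series, path)
        back = read_spectra(path, "long")
        assert len(back) == len(series)
        assert back.modality == "ftir_amide_i"
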