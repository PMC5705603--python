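"""McConnell evolution, 2D FID simulation, processing and peak fitting."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from cheadyn.exchange import (
    ExchangeScheme,
    SpeciesState,
    fast_exchange_shift,
    p1_environment_populations,
    solve_species_concentrations,
)
from cheadyn.lineshape import (
    Acquisition,
    FID2D,
    PeakFitError,
    SpinParameters,
    evolution_matrix,
    fit_lorentzian2d,
    in_situ_shift_error,
    process_to_spectrum,
    simulate_fid2d,
)


@pytest.fixture(scope="module")
def study_system():
    spins = SpinParameters.at_temperature(303.0)
    scheme = ExchangeScheme.from_constants(0.5e-6, 1.0, 900e-6)
    species = solve_species_concentrations(scheme, 100e-6, 100e-6)
    return scheme, species, spins


class TestEvolutionMatrix:
    def test_exchange_columns_sum_to_zero(self, study_system):
        # column sums of L must reduce to i*2*pi*nu - R2: the exchange part
        # conserves magnetization exactly
        scheme, species, spins = study_system
        from cheadyn.lineshape import BOUND_STATE, _state_frequencies

        acq = Acquisition.from_spins(spins)
        for nucleus in ("h", "c"):
            L = evolution_matrix(scheme, species, spins, nucleus, acq)
            nu = _state_frequencies(spins, acq, nucleus)
            r2_free, r2_bound = spins.r2(nucleus)
            r2 = np.array([r2_bound if b else r2_free for b in BOUND_STATE])
            expected = 2j * np.pi * nu - r2
            assert np.allclose(L.sum(axis=0), expected, atol=1e-8)

    def test_eigenvalue_real_parts_nonpositive(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            scheme = ExchangeScheme.from_constants(
                10 ** rng.uniform(-8, -3), 10 ** rng.uniform(-2, 2), 10 ** rng.uniform(-5, -2)
            )
            species = solve_species_concentrations(
                scheme, 10 ** rng.uniform(-6, -3), 10 ** rng.uniform(-6, -3)
            )
            spins = SpinParameters.at_temperature(303.0)
            L = evolution_matrix(scheme, species, spins, "h")
            assert np.all(np.linalg.eigvals(L).real <= 1e-9)

    def test_empty_system_rejected(self, study_system):
        scheme, _, spins = study_system
        empty = SpeciesState(0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            evolution_matrix(scheme, empty, spins, "h")


class TestSimulateFid:
    def test_single_environment_monoexponential(self):
        # all CheA free: the direct-dimension trace is exp((2*pi*i*nu - R2) t)
        spins = SpinParameters.at_temperature(303.0)
        acq = Acquisition.from_spins(spins)
        scheme = ExchangeScheme.from_constants(1e-6, 1.0, 1e-4)
        species = SpeciesState(100e-6, 0, 0, 0, 0)
        fid = simulate_fid2d(scheme, species, spins, acq)
        t2 = acq.times("direct")
        nu = (spins.shifts_h[0] - acq.carrier_h_ppm) * spins.h_frequency_mhz
        expected = np.exp((2j * np.pi * nu - spins.r2_h_free) * t2)
        assert np.allclose(fid.data[0] / fid.data[0, 0], expected, atol=1e-10)

    def test_fast_exchange_two_site_against_matrix_exponential(self):
        # oracle: dense expm propagation of the same evolution matrix
        spins = SpinParameters.at_temperature(303.0)
        acq = Acquisition.from_spins(spins)
        scheme = ExchangeScheme.from_constants(1e-5, 1.0, 1e-2)
        species = solve_species_concentrations(scheme, 1e-4, 2e-4)
        L = evolution_matrix(scheme, species, spins, "h", acq)
        p = species.as_array() / species.total_chea
        fid = simulate_fid2d(scheme, species, spins, acq)
        times = acq.times("direct")
        ones = np.ones(4)
        oracle = np.array([ones @ expm(L * t) @ p for t in times[::37]])
        assert np.allclose(fid.data[0, ::37] / fid.data[0, 0], oracle / oracle[0], atol=1e-8)

    def test_two_phase_titration_trajectory(self, study_system):
        # 1H perturbation saturates near 1:1 CheY while the 13C shift keeps
        # moving downfield with excess CheY (ternary-state signature)
        spins = SpinParameters.at_temperature(303.0)
        acq = Acquisition.from_spins(spins)
        scheme = ExchangeScheme.from_constants(0.5e-6, 1.0, 900e-6)
        pos = {}
        for ratio in (1.0, 4.0, 9.0):
            species = solve_species_concentrations(scheme, 100e-6, ratio * 100e-6)
            spec = process_to_spectrum(simulate_fid2d(scheme, species, spins, acq))
            fit = fit_lorentzian2d(spec)
            pos[ratio] = (fit.ppm_h, fit.ppm_c)
        dh_late = abs(pos[9.0][0] - pos[1.0][0])
        dh_early = abs(pos[1.0][0] - spins.shifts_h[0])
        assert dh_late < 0.35 * dh_early  # 1H nearly saturated after 1:1
        assert pos[9.0][1] - pos[1.0][1] > 0.05  # 13C keeps shifting downfield


class TestProcessing:
    def test_on_grid_delta_signal_lands_in_single_bin(self):
        spins = SpinParameters.at_temperature(303.0)
        acq = Acquisition(n_direct=64, n_indirect=16, sw_direct=320.0, sw_indirect=160.0)
        nu_h = 5 * acq.sw_direct / 64   # exactly on the unpadded grid
        nu_c = 3 * acq.sw_indirect / 16
        t2, t1 = acq.times("direct"), acq.times("indirect")
        fid = FID2D(
            np.outer(np.exp(2j * np.pi * nu_c * t1), np.exp(2j * np.pi * nu_h * t2)),
            acq, spins,
        )
        spec = process_to_spectrum(fid, line_broadening_hz=0.0, zero_fill=1)
        ic, ih = np.unravel_index(np.argmax(spec.data), spec.data.shape)
        assert spec.hz_direct[ih] == pytest.approx(nu_h)
        assert spec.hz_indirect[ic] == pytest.approx(nu_c)

    def test_linewidth_matches_lorentzian(self):
        # FWHM of a decaying sinusoid is 1/(pi T2) plus the apodization
        spins = SpinParameters.at_temperature(303.0)
        acq = Acquisition(n_direct=2048, n_indirect=4, sw_direct=800.0, sw_indirect=400.0)
        r2 = 30.0
        lb = 2.0
        t2, t1 = acq.times("direct"), acq.times("indirect")
        fid = FID2D(np.outer(np.ones(4), np.exp(-r2 * t2)), acq, spins)
        spec = process_to_spectrum(fid, line_broadening_hz=lb, zero_fill=4)
        row = spec.data[np.argmax(spec.data.sum(axis=1))]
        half = row.max() / 2
        above = spec.hz_direct[row > half]
        fwhm = above.max() - above.min()
        expected = (r2 + math.pi * lb) / math.pi
        assert fwhm == pytest.approx(expected, rel=0.02)

    def test_processing_is_linear(self):
        rng = np.random.default_rng(0)
        spins = SpinParameters.at_temperature(303.0)
        acq = Acquisition(n_direct=32, n_indirect=8)
        f1 = FID2D(rng.standard_normal((8, 32)) + 1j * rng.standard_normal((8, 32)), acq, spins)
        f2 = FID2D(rng.standard_normal((8, 32)) + 1j * rng.standard_normal((8, 32)), acq, spins)
        combo = FID2D(2.0 * f1.data + 3.0 * f2.data, acq, spins)
        s = process_to_spectrum(combo).data
        s12 = 2.0 * process_to_spectrum(f1).data + 3.0 * process_to_spectrum(f2).data
        assert np.allclose(s, s12, atol=1e-12 * np.abs(s).max())

    def test_bad_zero_fill_rejected(self):
        spins = SpinParameters.at_temperature(303.0)
        acq = Acquisition(n_direct=32, n_indirect=8)
        fid = FID2D(np.ones((8, 32), complex), acq, spins)
        with pytest.raises(ValueError):
            process_to_spectrum(fid, zero_fill=0)


class TestLorentzianFit:
    def test_noiseless_peak_recovered_exactly(self):
        # synthesise the separable Lorentzian directly on the frequency grid
        spins = SpinParameters.at_temperature(303.0)
        acq = Acquisition.from_spins(spins)
        hz_d = np.fft.fftshift(np.fft.fftfreq(1024, 1.0 / acq.sw_direct))
        hz_i = np.fft.fftshift(np.fft.fftfreq(256, 1.0 / acq.sw_indirect))
        truth = dict(intensity=3.7e4, t2_h=1 / 50.0, t2_c=1 / 14.0, nu_h=-23.4, nu_c=41.7)
        gh, gc = np.meshgrid(hz_d, hz_i)
        lh = truth["t2_h"] / (1 + (2 * np.pi * (gh - truth["nu_h"]) * truth["t2_h"]) ** 2)
        lc = truth["t2_c"] / (1 + (2 * np.pi * (gc - truth["nu_c"]) * truth["t2_c"]) ** 2)
        from cheadyn.lineshape import Spectrum2D

        spec = Spectrum2D(truth["intensity"] * lh * lc, hz_d, hz_i, acq, spins)
        fit = fit_lorentzian2d(spec)
        assert fit.intensity == pytest.approx(truth["intensity"], rel=1e-6)
        assert fit.t2_h == pytest.approx(truth["t2_h"], rel=1e-6)
        assert fit.t2_c == pytest.approx(truth["t2_c"], rel=1e-6)
        assert fit.nu_h == pytest.approx(truth["nu_h"], abs=1e-5)
        assert fit.nu_c == pytest.approx(truth["nu_c"], abs=1e-5)

    def test_edge_peak_raises(self):
        spins = SpinParameters.at_temperature(303.0)
        acq = Acquisition(n_direct=64, n_indirect=16)
        data = np.zeros((16, 64))
        data[0, 0] = 1.0
        from cheadyn.lineshape import Spectrum2D

        hz_d = np.fft.fftshift(np.fft.fftfreq(64, 1.0 / acq.sw_direct))
        hz_i = np.fft.fftshift(np.fft.fftfreq(16, 1.0 / acq.sw_indirect))
        spec = Spectrum2D(data, hz_d, hz_i, acq, spins)
        with pytest.raises(PeakFitError):
            fit_lorentzian2d(spec)


class TestExchangeRegimes:
    def test_fast_exchange_peak_at_weighted_mean(self):
        # docking exchange at 2e4 s^-1 versus ~90 Hz of shift difference:
        # single line at the population average
        spins = SpinParameters.at_temperature(303.0)
        acq = Acquisition.from_spins(spins)
        scheme = ExchangeScheme.from_constants(0.5e-6, 1.0, 900e-6)
        species = solve_species_concentrations(scheme, 100e-6, 100e-6)
        w = p1_environment_populations(species)
        spec = process_to_spectrum(simulate_fid2d(scheme, species, spins, acq))
        fit = fit_lorentzian2d(spec)
        exp_h = fast_exchange_shift(w, spins.shifts_h)
        assert abs(fit.ppm_h - exp_h) * spins.h_frequency_mhz < 0.1

    def test_slow_exchange_resolves_two_peaks_with_population_ratio(self):
        # docking 100x slower than the frequency difference: two resolved
        # lines whose intensities mirror the populations
        spins = SpinParameters(
            shifts_h=(0.75, 0.55, 0.70), shifts_c=(13.0, 13.3, 14.2),
            r2_h_free=8.0, r2_h_bound=8.0, r2_c_free=8.0, r2_c_bound=8.0,
        )
        acq = Acquisition.from_spins(spins, n_direct=4096, sw_direct=600.0)
        dnu = abs(spins.shifts_h[0] - spins.shifts_h[1]) * spins.h_frequency_mhz
        k1 = 2.0  # populations 2:1 free:docked
        k_on1 = 0.01 * dnu / (1.0 + k1)
        scheme = ExchangeScheme(
            k_on0=2e8, k_off0=2e8 * 1e-9,   # saturate the tether
            k_on1=k_on1, k_off1=k1 * k_on1,
            k_on2=1e-3, k_off2=1e6,          # no ternary state
        )
        species = solve_species_concentrations(scheme, 1e-4, 1e-4)
        fid = simulate_fid2d(scheme, species, spins, acq)
        spec = process_to_spectrum(fid, line_broadening_hz=0.5)
        row = spec.data.sum(axis=0)
        nu_free = (spins.shifts_h[0] - acq.carrier_h_ppm) * spins.h_frequency_mhz
        nu_dock = (spins.shifts_h[1] - acq.carrier_h_ppm) * spins.h_frequency_mhz
        i_free = row[np.argmin(np.abs(spec.hz_direct - nu_free))]
        i_dock = row[np.argmin(np.abs(spec.hz_direct - nu_dock))]
        pops = species.as_array() / species.total_chea
        expected_ratio = (pops[0] + pops[1]) / pops[2]
        assert i_free / i_dock == pytest.approx(expected_ratio, rel=0.05)

    def test_integrated_intensity_conserved_across_regimes(self):
        # at fixed R2, total absorptive integral is set by relaxation, not
        # by the exchange regime
        spins = SpinParameters(
            shifts_h=(0.75, 0.55, 0.70), shifts_c=(13.0, 13.3, 14.2),
            r2_h_free=20.0, r2_h_bound=20.0, r2_c_free=20.0, r2_c_bound=20.0,
        )
        acq = Acquisition.from_spins(spins, n_direct=2048, n_indirect=256)
        integrals = []
        for k_on1 in (1e-1, 1e2, 1e5):
            scheme = ExchangeScheme(
                k_on0=2e8, k_off0=2e8 * 1e-9,
                k_on1=k_on1, k_off1=k_on1,
                k_on2=1e-3, k_off2=1e6,
            )
            species = solve_species_concentrations(scheme, 1e-4, 1e-4)
            spec = process_to_spectrum(simulate_fid2d(scheme, species, spins, acq))
            integrals.append(spec.data.sum())
        assert max(integrals) / min(integrals) == pytest.approx(1.0, abs=0.01)


class TestInSituError:
    def test_zero_noise_gives_zero_sd(self):
        out = in_situ_shift_error(
            nu_h=10.0, nu_c=-20.0, r2_h=45.0, r2_c=12.0, snr=math.inf,
            n_replicates=5, seed=0,
        )
        assert out["sd_h_hz"] == 0.0
        assert out["sd_c_hz"] == 0.0

    def test_sd_scales_with_noise_amplitude(self):
        common = dict(nu_h=10.0, nu_c=-20.0, r2_h=45.0, r2_c=12.0, n_replicates=100)
        lo = in_situ_shift_error(snr=40.0, seed=1, **common)
        hi = in_situ_shift_error(snr=20.0, seed=1, **common)
        for key in ("sd_h_hz", "sd_c_hz"):
            assert hi[key] / lo[key] == pytest.approx(2.0, rel=0.2)

    def test_replicate_count_validated(self):
        with pytest.raises(ValueError):
            in_situ_shift_error(
                nu_h=0, nu_c=0, r2_h=45, r2_c=12, snr=20, n_replicates=1
            )
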