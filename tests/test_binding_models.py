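"""1:1 equilibrium model, K_d fitting, species counting and simulation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepsense.binding_models import (
    BindingParams,
    SpectraMatrix,
    TitrationSeries,
    bootstrap_kd_ci,
    complex_concentration,
    estimate_n_species,
    fit_fluorescence,
    fit_mst,
    mst_response,
    predict_signal,
    simulate_spectra,
    simulate_titration,
)

TITRANTS = np.geomspace(1.2, 75.0, 12)  # the worked-example titration design
FIXED = 2.5

conc = st.floats(min_value=1e-3, max_value=1e4, allow_nan=False)


class TestComplexConcentration:
    def test_no_ligand_no_complex(self):
        _, _, al = complex_concentration(5.0, 0.0, 100.0)
        assert al == 0.0

    def test_equimolar_unit_kd(self):
        a, l, al = complex_concentration(1.0, 1.0, 1.0)
        assert al == pytest.approx((3 - math.sqrt(5)) / 2, rel=1e-14)
        # the root satisfies the mass-action law
        assert a * l / al == pytest.approx(1.0, rel=1e-12)

    def test_weak_binding_limit(self):
        a_tot, l_tot = 2.0, 3.0
        kd = 1e6 * max(a_tot, l_tot)
        _, _, al = complex_concentration(a_tot, l_tot, kd)
        assert al == pytest.approx(a_tot * l_tot / kd, rel=1e-5)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            complex_concentration(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            complex_concentration(1.0, 1.0, 0.0)

    @given(conc, conc, conc)
    def test_mass_conservation(self, a_tot, l_tot, kd):
        a, l, al = complex_concentration(a_tot, l_tot, kd)
        assert float(a + al) == pytest.approx(a_tot, rel=1e-12)
        assert float(l + al) == pytest.approx(l_tot, rel=1e-12)
        assert al >= 0 and a >= -1e-15 and l >= -1e-15

    @given(conc, conc)
    def test_complex_increases_with_titrant_decreases_with_kd(self, a_tot, kd):
        ligands = np.array([1.0, 2.0, 5.0, 20.0])
        _, _, al = complex_concentration(a_tot, ligands, kd)
        assert np.all(np.diff(al) > 0)
        _, _, al_weaker = complex_concentration(a_tot, ligands, kd * 10)
        assert np.all(al_weaker < al)


class TestForwardModels:
    def test_equal_coefficients_hide_binding(self):
        params = BindingParams(kd=50.0, q_free=2.0, q_complex=2.0, baseline=0.1)
        series = simulate_titration(params, FIXED, TITRANTS)
        assert np.ptp(series.signal) == pytest.approx(0.0, abs=1e-12)

    def test_low_and_saturating_titrant_limits(self):
        params = BindingParams(kd=50.0, q_free=1.0, q_complex=3.0, baseline=0.2)
        lo = TitrationSeries(FIXED, np.array([1e-9, 1.0]), np.zeros(2))
        assert predict_signal(params, lo)[0] == pytest.approx(
            params.baseline + params.q_free * FIXED, rel=1e-8
        )
        hi = TitrationSeries(FIXED, np.array([1.0, 1e9]), np.zeros(2))
        assert predict_signal(params, hi)[1] == pytest.approx(
            params.baseline + params.q_complex * FIXED, rel=1e-6
        )

    def test_mst_half_bound_at_kd_when_fixed_is_negligible(self):
        kd = 1000.0
        params = BindingParams(kd=kd, q_free=0.0, q_complex=1.0)
        series = TitrationSeries(0.01, np.array([1.0, kd]), np.zeros(2))
        frac = mst_response(params, series)[1]
        assert frac == pytest.approx(0.5, rel=1e-2)


class TestSimulate:
    def test_noiseless_equals_forward_model(self):
        truth = BindingParams(kd=850.0, q_free=1.0, q_complex=3.0)
        series = simulate_titration(truth, FIXED, TITRANTS)
        assert series.signal == pytest.approx(predict_signal(truth, series))

    def test_seed_reproducibility(self):
        truth = BindingParams(kd=850.0, q_free=1.0, q_complex=3.0)
        s1 = simulate_titration(truth, FIXED, TITRANTS, noise_sd=0.05, seed=42)
        s2 = simulate_titration(truth, FIXED, TITRANTS, noise_sd=0.05, seed=42)
        s3 = simulate_titration(truth, FIXED, TITRANTS, noise_sd=0.05, seed=43)
        assert np.array_equal(s1.signal, s2.signal)
        assert not np.array_equal(s1.signal, s3.signal)
        # noise rides on the same clean curve
        clean = simulate_titration(truth, FIXED, TITRANTS).signal
        assert np.abs(s1.signal - clean).max() < 1.0

    def test_seed_required_for_noise(self):
        truth = BindingParams(kd=850.0, q_free=1.0, q_complex=3.0)
        with pytest.raises(ValueError, match="seed"):
            simulate_titration(truth, FIXED, TITRANTS, noise_sd=0.05)

    def test_series_invariants(self):
        with pytest.raises(ValueError):
            TitrationSeries(0.0, np.array([1.0, 2.0]), np.zeros(2))
        with pytest.raises(ValueError):
            TitrationSeries(1.0, np.array([2.0, 1.0]), np.zeros(2))  # unsorted
        with pytest.raises(ValueError):
            TitrationSeries(1.0, np.array([0.0, 1.0]), np.zeros(2))  # zero level


class TestFits:
    @pytest.mark.parametrize("kd", [10.0, 850.0])
    def test_noiseless_fluorescence_recovery(self, kd):
        truth = BindingParams(kd=kd, q_free=1.0, q_complex=3.0)
        series = simulate_titration(truth, FIXED, TITRANTS)
        fit = fit_fluorescence(series)
        assert fit.converged
        assert fit.params.kd == pytest.approx(kd, rel=1e-6)
        assert fit.params.q_free == pytest.approx(1.0, rel=1e-6)
        assert fit.params.q_complex == pytest.approx(3.0, rel=1e-6)

    def test_noiseless_mst_recovery(self):
        truth = BindingParams(kd=816.0, q_free=800.0, q_complex=860.0)
        series = simulate_titration(
            truth, 10.0, np.geomspace(0.305, 10000.0, 16), mode="mst"
        )
        fit = fit_mst(series)
        assert fit.params.kd == pytest.approx(816.0, rel=1e-6)

    def test_fluorescence_and_mst_agree_on_shared_data(self):
        # with baseline 0 the two parameterizations describe the same curve
        truth = BindingParams(kd=120.0, q_free=1.0, q_complex=3.0)
        series = simulate_titration(truth, FIXED, TITRANTS)
        kd_f = fit_fluorescence(series).params.kd
        kd_m = fit_mst(series).params.kd
        assert kd_f == pytest.approx(kd_m, rel=1e-6)

    def test_constant_signal_rejected(self):
        series = TitrationSeries(FIXED, TITRANTS, np.full(12, 2.0))
        with pytest.raises(ValueError, match="constant"):
            fit_fluorescence(series)

    def test_too_few_points_rejected(self):
        series = TitrationSeries(FIXED, np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="4 titration points"):
            fit_fluorescence(series)

    def test_se_reported_under_noise(self):
        truth = BindingParams(kd=20.0, q_free=1.0, q_complex=3.0)
        series = simulate_titration(truth, FIXED, TITRANTS, noise_sd=0.02,
                                    seed=3, relative_noise=True)
        fit = fit_fluorescence(series)
        assert fit.converged and fit.kd_se > 0
        assert fit.n_points == 12 and fit.residuals.size == 12


class TestSpeciesCounting:
    WAVELENGTHS = np.linspace(300, 400, 50)

    def _shapes(self, n):
        centers = [320, 360, 390][:n]
        return np.array(
            [np.exp(-((self.WAVELENGTHS - c) ** 2) / 400.0) for c in centers]
        )

    def test_rank_two_spectra(self):
        c = np.column_stack([np.linspace(1, 0.2, 12), np.linspace(0.0, 0.8, 12)])
        m = simulate_spectra(c, self._shapes(2), self.WAVELENGTHS,
                             noise_sd=0.005, seed=1)
        assert estimate_n_species(m, noise_level=0.005) == 2

    def test_single_species(self):
        c = np.linspace(1, 0.2, 12)[:, None]
        m = simulate_spectra(c, self._shapes(1), self.WAVELENGTHS)
        assert estimate_n_species(m, noise_level=1e-6) == 1

    def test_pure_noise_counts_zero(self):
        rng = np.random.default_rng(11)
        m = SpectraMatrix(self.WAVELENGTHS,
                          rng.normal(0.0, 0.01, size=(12, 50)))
        assert estimate_n_species(m, noise_level=0.01) == 0

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            SpectraMatrix(self.WAVELENGTHS, np.zeros((1, 50)))
        bad = np.zeros((3, 50))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            SpectraMatrix(self.WAVELENGTHS, bad)


class TestBootstrap:
    def test_interval_contains_estimate_and_is_reproducible(self):
        truth = BindingParams(kd=20.0, q_free=1.0, q_complex=3.0)
        series = simulate_titration(truth, FIXED, TITRANTS, noise_sd=0.02,
                                    seed=5, relative_noise=True)
        fit = fit_fluorescence(series)
        lo, hi = bootstrap_kd_ci(series, fit, n_boot=50, seed=9)
        lo2, hi2 = bootstrap_kd_ci(series, fit, n_boot=50, seed=9)
        assert (lo, hi) == (lo2, hi2)
        assert lo <= fit.params.kd <= hi

    def test_noiseless_interval_degenerates(self):
        truth = BindingParams(kd=20.0, q_free=1.0, q_complex=3.0)
        series = simulate_titration(truth, FIXED, TITRANTS)
        fit = fit_fluorescence(series)
        lo, hi = bootstrap_kd_ci(series, fit, n_boot=30, seed=2)
        assert hi - lo == pytest.approx(0.0, abs=1e-6 * fit.params.kd)

    def test_interval_narrows_with_less_noise(self):
        truth = BindingParams(kd=20.0, q_free=1.0, q_complex=3.0)
        widths = []
        for noise in (0.04, 0.005):
            series = simulate_titration(truth, FIXED, TITRANTS, noise_sd=noise,
                                        seed=7, relative_noise=True)
            fit = fit_fluorescence(series)
            lo, hi = bootstrap_kd_ci(series, fit, n_boot=40, seed=13)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_seed_required(self):
        truth = BindingParams(kd=20.0, q_free=1.0, q_complex=3.0)
        series = simulate_titration(truth, FIXED, TITRANTS)
        fit = fit_fluorescence(series)
        with pytest.raises(ValueError, match="seed"):
            bootstrap_kd_ci(series, fit, n_boot=10)
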