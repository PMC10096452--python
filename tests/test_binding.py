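"""Stern-Volmer and global-absorbance association-constant estimation."""

import numpy as np
import pytest

from quenchkit import (
    SimulationScenario,
    Spectrum,
    SternVolmer,
    classify_association,
    global_absorbance_fit,
    simulate_absorbance_titration,
    simulate_fluorescence_titration,
    stern_volmer_fit,
)
from quenchkit.binding import InsufficientDataError
from quenchkit.io import TitrationPoint, TitrationSeries, ValidationError
from conftest import GUEST_GRID, static_scenario


def _series(K=3000.0, host=1e-5, eps_guest=0.0, noise=0.0, seed=0, **kw):
    scn = SimulationScenario(
        K_true=K, host_total=host, guest_grid=GUEST_GRID, eps_guest=eps_guest,
        noise_rel_F=noise, noise_rel_A=0.0, seed=seed, **kw,
    )
    return simulate_fluorescence_titration(scn)


class TestSternVolmer:
    def test_recovers_K_in_dilute_host_regime(self):
        # host 1e-6 M << guest: free ~ total, slope = K within 0.5%
        series = _series(host=1e-6)
        res = stern_volmer_fit(series, use_corrected=False)
        assert res.K == pytest.approx(3000.0, rel=5e-3)
        assert res.intercept == 1.0
        assert res.points_used == len(GUEST_GRID)

    def test_free_guest_iteration_removes_depletion_bias(self):
        series = _series(host=1e-5)
        biased = stern_volmer_fit(series, use_corrected=False)
        refined = stern_volmer_fit(series, use_corrected=False, use_free_guest=True)
        assert abs(refined.K - 3000.0) < abs(biased.K - 3000.0)
        assert refined.K == pytest.approx(3000.0, rel=1e-6)

    def test_flat_intensities_give_zero_slope_and_nan_r2(self):
        series = _series(K=0.0)
        res = stern_volmer_fit(series, use_corrected=False)
        assert res.K == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.r_squared)

    def test_uncorrected_fit_of_attenuated_data_is_curved(self):
        series = _series(K=3000.0, eps_guest=1500.0)
        res = stern_volmer_fit(series, use_corrected=False)
        assert res.curvature_flag  # upward curvature from the 10^(dA/2) factor

    def test_inflation_uncorrected_exceeds_corrected(self):
        series = _series(K=3000.0, eps_guest=1000.0)
        unc = stern_volmer_fit(series, use_corrected=False)
        cor = stern_volmer_fit(series, use_corrected=True)
        assert unc.K > cor.K
        assert cor.K == pytest.approx(3000.0, rel=0.03)

    def test_free_intercept_reports_systematic_offset(self):
        pts = [TitrationPoint(1e-6, g, 1000.0 / (1 + 3000 * g) * 1.05 if g else 1000.0)
               for g in GUEST_GRID]
        series = TitrationSeries(points=tuple(pts), lambda_ex=300, lambda_em=375)
        res = stern_volmer_fit(series, use_corrected=False, fix_intercept=False)
        assert res.intercept < 1.0  # all titrant ratios shrunk by the 5% offset

    def test_truncation_is_logged_not_silent(self, caplog):
        series = _series()
        with caplog.at_level("WARNING", logger="quenchkit"):
            res = stern_volmer_fit(series, use_corrected=False, max_points=8)
        assert res.points_used == 8
        assert any("truncated" in r.message for r in caplog.records)

    def test_nonpositive_intensity_rejected(self):
        pts = [TitrationPoint(1e-6, g, f) for g, f in
               zip((0.0, 1e-4, 2e-4, 3e-4), (1000.0, 500.0, 0.0, 100.0))]
        series = TitrationSeries(points=tuple(pts), lambda_ex=300, lambda_em=375)
        with pytest.raises(ValidationError):
            stern_volmer_fit(series, use_corrected=False)

    def test_too_few_points_rejected(self):
        est = SternVolmer()
        with pytest.raises(InsufficientDataError):
            est.fit([0.0, 1e-4, 2e-4], [1.0, 1.3, 1.6])

    def test_estimator_sklearn_interface(self):
        Q = np.linspace(0, 3e-4, 10)
        est = SternVolmer().fit(Q, 1 + 2000 * Q)
        assert est.K_ == pytest.approx(2000.0)
        np.testing.assert_allclose(est.predict(Q), 1 + 2000 * Q, rtol=1e-10)
        assert est.get_params() == {
            "fix_intercept": True,
            "curvature_alpha": 0.05,
            "shared_reference": True,
        }


def test_parameter_recovery_bias_and_spread():
    """Corrected Stern-Volmer on noisy inner-filter-attenuated static
    quenching: |bias| < 2% over replicates, spread consistent with stderr."""
    Ks, ses = [], []
    for rep in range(60):
        scn = static_scenario(host_total=1e-6, seed=1000 + rep)
        res = stern_volmer_fit(simulate_fluorescence_titration(scn),
                               use_corrected=True)
        Ks.append(res.K)
        ses.append(res.K_stderr)
    Ks = np.array(Ks)
    assert abs(Ks.mean() / 3000.0 - 1.0) < 0.02
    # empirical spread within a factor ~2 of the reported stderr
    assert 0.5 < Ks.std() / np.mean(ses) < 2.0


class TestGlobalAbsorbanceFit:
    wl = np.linspace(250, 400, 20)

    def _spectra(self, distinct=True):
        eH = Spectrum(self.wl, 2e4 * np.exp(-0.5 * ((self.wl - 300) / 25) ** 2))
        eG = Spectrum(self.wl, 1.5e4 * np.exp(-0.5 * ((self.wl - 340) / 30) ** 2))
        extra = 8e3 * np.exp(-0.5 * ((self.wl - 320) / 20) ** 2) if distinct else 0.0
        eHG = Spectrum(self.wl, eH.values + eG.values + extra)
        return eH, eG, eHG

    def _simulate(self, K, eH, eG, eHG, noise=0.0, seed=0):
        scn = SimulationScenario(
            K_true=K, host_total=1e-4,
            guest_grid=tuple(np.linspace(0, 2e-3, 10)),
            eps_host_spectrum=eH, eps_guest_spectrum=eG, eps_complex_spectrum=eHG,
            noise_rel_A=noise, seed=seed,
        )
        return simulate_absorbance_titration(scn)

    def test_noiseless_recovery_within_point1_percent(self):
        eH, eG, eHG = self._spectra()
        series, spectra = self._simulate(50.0, eH, eG, eHG)
        res = global_absorbance_fit(spectra, series.host_totals,
                                    series.guest_totals, eH, eG)
        assert res.K == pytest.approx(50.0, rel=1e-3)
        assert res.identifiable

    def test_degenerate_complex_spectrum_not_identifiable(self):
        eH, eG, eHG = self._spectra(distinct=False)
        series, spectra = self._simulate(50.0, eH, eG, eHG, noise=1e-3, seed=4)
        res = global_absorbance_fit(spectra, series.host_totals,
                                    series.guest_totals, eH, eG)
        assert not res.identifiable

    def test_wavelength_permutation_invariance(self):
        # fitting a reordered-but-identical wavelength subset changes nothing
        eH, eG, eHG = self._spectra()
        series, spectra = self._simulate(50.0, eH, eG, eHG, noise=1e-3, seed=9)
        full = global_absorbance_fit(spectra, series.host_totals,
                                     series.guest_totals, eH, eG)
        windowed = global_absorbance_fit(spectra, series.host_totals,
                                         series.guest_totals, eH, eG,
                                         wavelength_window=(250.0, 400.0))
        assert windowed.K == pytest.approx(full.K, rel=1e-9)

    def test_too_few_points_rejected(self):
        eH, eG, eHG = self._spectra()
        series, spectra = self._simulate(50.0, eH, eG, eHG)
        with pytest.raises(InsufficientDataError):
            global_absorbance_fit(spectra[:3], series.host_totals[:3],
                                  series.guest_totals[:3], eH, eG)


class TestClassification:
    @pytest.mark.parametrize(
        "K,se,expected",
        [
            (0.05, 0.01, "statistical"),   # below the statistical bound
            (3000.0, 150.0, "stable"),
            (5.0, 1.0, "weak"),
            (50.0, 40.0, "statistical"),   # not significantly above zero
        ],
    )
    def test_policy(self, K, se, expected):
        assert classify_association(K, se) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            classify_association(float("nan"), 1.0)
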