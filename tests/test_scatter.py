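"""Scatter basis shapes, window scaling coefficients, and their calibration."""

import numpy as np
import pytest

from thraquant.camera import STANDARD_WINDOWS, energy_grid, energy_resolution, window_integral
from thraquant.nuclides import EmissionLine, NuclideSpectrum, emission_lines
from thraquant.scatter import (
    ScatterCoefficients,
    calibrate_nu,
    load_scatter_basis,
    parametric_scatter,
    scatter_window_integrals,
)
from thraquant.unmixing import (
    ConjugateMeasurement,
    SpectralComponents,
    model_window_counts,
    solve_activities,
)

_ELECTRON_REST = 511.0


class TestLoadScatterBasis:
    def test_grid_matched_table_is_identity(self):
        grid = energy_grid()
        values = np.exp(-((grid - 150.0) / 80.0) ** 2)
        s = load_scatter_basis(grid, values, "Th227")
        np.testing.assert_allclose(s.values, values, rtol=1e-12)

    def test_two_kev_table_interpolates_midpoints(self):
        energies = np.arange(20.0, 601.0, 2.0)  # lands between bin centers
        values = np.linspace(1.0, 5.0, energies.size)
        s = load_scatter_basis(energies, values, "Ra223chain")
        grid = energy_grid()
        inner = (grid > energies[0]) & (grid < energies[-1])
        # linear data stays linear under linear interpolation
        np.testing.assert_allclose(
            s.values[inner],
            np.interp(grid[inner], energies, values),
            rtol=1e-12,
        )

    def test_resampled_integral_matches_trapezoid(self):
        rng = np.random.default_rng(7)
        energies = np.sort(rng.uniform(25, 590, 200))
        values = rng.uniform(0.5, 2.0, 200)
        s = load_scatter_basis(energies, values, "Th227")
        resampled_integral = s.values.sum() * 1.0  # 1 keV bins
        raw_integral = np.trapezoid(values, energies)
        assert resampled_integral == pytest.approx(raw_integral, rel=5e-3)

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            load_scatter_basis([100.0, 90.0], [1.0, 1.0], "Th227")
        with pytest.raises(ValueError):
            load_scatter_basis([90.0, 100.0], [1.0, -1.0], "Th227")


class TestParametricScatter:
    def test_monoenergetic_continuum_below_line(self, detector):
        spec = NuclideSpectrum("mono", (EmissionLine(364.0, 1.0),))
        s = parametric_scatter(spec, 20.0, detector)
        fwhm = float(energy_resolution(detector, 364.0))
        above = s.grid > 364.0 + 3 * fwhm
        assert np.all(s.values[above] < 1e-9)
        assert s.values[(s.grid > 150) & (s.grid < 360)].sum() > 0.5

    def test_normalized_to_unit_integral(self, detector):
        for label in ("Th227", "Ra223chain"):
            s = parametric_scatter(emission_lines(label), 20.0, detector)
            assert s.values.sum() == pytest.approx(1.0, abs=1e-3)

    def test_backscatter_kinematic_edge(self):
        """The continuum's low end sits at E₀/(1+2E₀/511) to <1 keV."""
        from thraquant.scatter import _klein_nishina_energy_pdf

        E0 = 236.0
        grid = energy_grid()
        pdf = _klein_nishina_energy_pdf(E0, grid)
        e_min_expected = E0 / (1 + 2 * E0 / _ELECTRON_REST)
        lowest = grid[np.flatnonzero(pdf > 0)[0]]
        assert lowest == pytest.approx(e_min_expected, abs=1.0)

    def test_continuous_and_bounded_support(self, detector):
        """No >20% bin-to-bin jump in the bulk; vanishes below 20 keV and
        above the highest line + 3·FWHM."""
        s = parametric_scatter(emission_lines("Th227"), 15.0, detector)
        assert np.all(s.values[s.grid < 20.0] == 0)
        e_max = max(l.energy for l in emission_lines("Th227").lines)
        fwhm = float(energy_resolution(detector, e_max))
        assert np.all(s.values[s.grid > e_max + 3 * fwhm] < 1e-9)
        # continuity: no bin-to-bin step larger than 20% of the peak value
        steps = np.abs(np.diff(s.values))
        assert np.all(steps < 0.2 * s.values.max())

    def test_rejects_nonpositive_thickness(self, detector):
        with pytest.raises(ValueError):
            parametric_scatter(emission_lines("Th227"), 0.0, detector)


class TestScatterWindowIntegrals:
    def test_unit_nu_is_identity(self, detector):
        s = parametric_scatter(emission_lines("Th227"), 20.0, detector)
        out = scatter_window_integrals(s, ScatterCoefficients())
        plain = np.array([window_integral(s, w) for w in STANDARD_WINDOWS])
        np.testing.assert_allclose(out, plain, rtol=1e-12)

    def test_nu_scales_only_its_window(self, detector):
        s = parametric_scatter(emission_lines("Th227"), 20.0, detector)
        nu = ScatterCoefficients()
        nu.set("Th227", [1.0, 2.0, 1.0, 1.0])
        out = scatter_window_integrals(s, nu)
        plain = np.array([window_integral(s, w) for w in STANDARD_WINDOWS])
        np.testing.assert_allclose(out[[0, 2, 3]], plain[[0, 2, 3]], rtol=1e-12)
        assert out[1] == pytest.approx(2 * plain[1], rel=1e-12)

    def test_matches_brute_force_bin_sum(self, detector):
        s = parametric_scatter(emission_lines("Ra223chain"), 20.0, detector)
        out = scatter_window_integrals(s, ScatterCoefficients())
        for j, w in enumerate(STANDARD_WINDOWS):
            brute = sum(
                v for e, v in zip(s.grid, s.values) if w.lo <= e < w.hi
            )
            assert out[j] == pytest.approx(brute, rel=1e-12)


class TestCalibrateNu:
    # Jaszczak-style calibration sets: parent-dominant at fill, daughter-grown
    # at two weeks (known activities, 20-min acquisitions)
    A_DAY0 = (0.54, 0.014)
    A_DAY14 = (0.321, 0.239)
    DUR = 1200.0

    def _counts(self, acts, comp):
        return model_window_counts(acts[0], acts[1], 1.0, self.DUR, comp)

    def test_self_consistency_unit_nu(self, components20):
        cal = calibrate_nu(
            (self._counts(self.A_DAY0, components20), self.DUR, self.A_DAY0),
            (self._counts(self.A_DAY14, components20), self.DUR, self.A_DAY14),
            components20,
        )
        np.testing.assert_allclose(cal.for_isotope("Th227"), 1.0, atol=1e-6)
        np.testing.assert_allclose(cal.for_isotope("Ra223chain"), 1.0, atol=1e-6)

    def test_recovers_injected_mismatch(self, components20):
        nu_true = ScatterCoefficients()
        nu_true.set("Ra223chain", [1.4, 1.0, 1.0, 1.0])
        comp_true = components20.with_nu(nu_true)
        cal = calibrate_nu(
            (self._counts(self.A_DAY0, comp_true), self.DUR, self.A_DAY0),
            (self._counts(self.A_DAY14, comp_true), self.DUR, self.A_DAY14),
            components20,
        )
        assert cal.for_isotope("Ra223chain")[0] == pytest.approx(1.4, abs=1e-3)
        np.testing.assert_allclose(cal.for_isotope("Th227"), 1.0, atol=1e-3)

    def test_reapplication_reproduces_calibration_counts(self, components20):
        """Applying calibrated ν back to its own (noise-free) calibration data
        reproduces the measured window counts to <0.1%."""
        nu_true = ScatterCoefficients()
        nu_true.set("Th227", [1.2, 0.9, 1.1, 1.3])
        nu_true.set("Ra223chain", [1.4, 1.1, 0.8, 1.2])
        comp_true = components20.with_nu(nu_true)
        meas0 = self._counts(self.A_DAY0, comp_true)
        meas14 = self._counts(self.A_DAY14, comp_true)
        cal = calibrate_nu(
            (meas0, self.DUR, self.A_DAY0),
            (meas14, self.DUR, self.A_DAY14),
            components20,
        )
        comp_cal = components20.with_nu(cal)
        np.testing.assert_allclose(
            self._counts(self.A_DAY0, comp_cal), meas0, rtol=1e-3
        )
        np.testing.assert_allclose(
            self._counts(self.A_DAY14, comp_cal), meas14, rtol=1e-3
        )

    def test_poisson_noise_median_recovery(self, components20):
        """Over 100 seeds at 20-min phantom count levels, the median
        recovered ν is within 10% of truth wherever the window's expected
        scatter counts exceed twice the Poisson noise; noise-dominated
        coefficients are statistically unbiased (median within 4 standard
        errors of 1)."""
        rng = np.random.default_rng(20260927)
        c0 = self._counts(self.A_DAY0, components20)
        c14 = self._counts(self.A_DAY14, components20)
        recovered = {"Th227": [], "Ra223chain": []}
        for _ in range(100):
            cal = calibrate_nu(
                (rng.poisson(c0).astype(float), self.DUR, self.A_DAY0),
                (rng.poisson(c14).astype(float), self.DUR, self.A_DAY14),
                components20,
            )
            for iso in recovered:
                recovered[iso].append(cal.for_isotope(iso))
        scatter_counts = {
            "Th227": self.A_DAY0[0] * components20.scatter_Th * self.DUR,
            "Ra223chain": self.A_DAY14[1] * components20.scatter_Ra * self.DUR,
        }
        noise = {"Th227": np.sqrt(c0), "Ra223chain": np.sqrt(c14)}
        for iso in recovered:
            arr = np.array(recovered[iso])
            med = np.median(arr, axis=0)
            identifiable = scatter_counts[iso] >= 2 * noise[iso]
            assert np.all(np.abs(med[identifiable] - 1.0) < 0.10)
            # noise-dominated windows: no systematic bias
            se_med = 1.2533 * arr.std(axis=0) / np.sqrt(arr.shape[0])
            weak = ~identifiable
            assert np.all(np.abs(med[weak] - 1.0) < 4 * se_med[weak])


def test_scatter_scale_absorbed_by_B(components20):
    """Scaling the scatter shape by any c>0 leaves activity estimates
    unchanged end-to-end: the fitted B absorbs the scale."""
    y = model_window_counts(0.4, 0.2, 1.5, 1200.0, components20)
    meas = ConjugateMeasurement.from_geometric_mean(y, 1200.0, 20.0)
    base = solve_activities(meas, components20)
    scaled = SpectralComponents(
        primary_Th=components20.primary_Th,
        primary_Ra=components20.primary_Ra,
        scatter_Th=3.7 * components20.scatter_Th,
        scatter_Ra=3.7 * components20.scatter_Ra,
        thickness=components20.thickness,
    )
    est = solve_activities(meas, scaled)
    assert est.A_Th227 == pytest.approx(base.A_Th227, rel=1e-4)
    assert est.A_Ra223 == pytest.approx(base.A_Ra223, rel=1e-4)
    assert est.B == pytest.approx(base.B / 3.7, rel=1e-3)
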