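"""Forward-model and fitting tests for two-site CPMG dispersion."""

import numpy as np
import pytest
from scipy.linalg import expm

from minorstate import dispersion as d

NU = np.arange(50.0, 751.0, 50.0)
T_CPMG = 0.040


class TestComputeR2eff:
    def test_equal_intensities_give_zero(self):
        assert d.compute_r2eff(100.0, 100.0, T_CPMG) == 0.0

    def test_analytic_values(self):
        assert d.compute_r2eff(np.exp(-0.4), 1.0, T_CPMG) == pytest.approx(10.0)
        # ln 2 / 0.04 by hand
        assert d.compute_r2eff(0.5, 1.0, T_CPMG) == pytest.approx(17.32868, abs=1e-4)

    def test_intensity_scale_invariance(self):
        a = d.compute_r2eff(37.0, 81.0, T_CPMG)
        b = d.compute_r2eff(74.0, 162.0, T_CPMG)
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            d.compute_r2eff(-1.0, 10.0, T_CPMG)
        with pytest.raises(ValueError):
            d.compute_r2eff(1.0, 0.0, T_CPMG)

    def test_error_propagation(self):
        r2, sd = d.compute_r2eff(50.0, 100.0, T_CPMG, i_cpmg_sd=1.0, i0_sd=2.0)
        expected = np.sqrt((1 / 50.0) ** 2 + (2 / 100.0) ** 2) / T_CPMG
        assert sd == pytest.approx(expected)


class TestForwardModel:
    def test_non_integer_echo_count_rejected(self):
        with pytest.raises(ValueError, match="permissible"):
            d.simulate_r2eff(750.0, 0.02, 100.0, 8.0, [63.0], T_CPMG)

    def test_no_minor_population_gives_flat_baseline(self):
        prof = d.simulate_r2eff(1e4, 0.0, 500.0, 8.0, NU, T_CPMG)
        np.testing.assert_allclose(prof, 8.0, atol=1e-10)

    def test_zero_shift_difference_gives_flat_baseline(self):
        prof = d.simulate_r2eff(1e4, 0.05, 0.0, 11.0, NU, T_CPMG)
        np.testing.assert_allclose(prof, 11.0, atol=1e-10)

    def test_fast_limit_matches_luz_meiboom_within_2pct(self):
        dw = d.dw_rad_per_s(2.0, 600.0)
        prof = d.simulate_r2eff(1e4, 0.02, dw, 8.0, NU, T_CPMG)
        rex = d.luz_meiboom_rex(1e4, 0.02, dw, NU)
        np.testing.assert_allclose(prof - 8.0, rex, rtol=0.02)

    def test_matches_scipy_expm_propagation(self):
        """Dual-route check: analytic 2x2 propagators vs scipy matrix
        exponentials with an explicit per-echo loop."""
        kex, p_b, r2 = 750.0, 0.02, 9.0
        dw = d.dw_rad_per_s(2.5, 600.0)
        L = d._evolution_matrix(kex, p_b, dw, r2)
        ref = []
        for nu in NU:
            n = int(round(2 * nu * T_CPMG))
            P = expm(L / (4.0 * nu))
            m = np.array([1 - p_b, p_b], dtype=complex)
            for _ in range(n):
                m = P @ np.conj(P @ m)
            ref.append(-np.log(abs(m.sum())) / T_CPMG)
        prof = d.simulate_r2eff(kex, p_b, dw, r2, NU, T_CPMG)
        np.testing.assert_allclose(prof, ref, atol=1e-10)

    def test_site_label_swap_symmetry(self):
        dw = d.dw_rad_per_s(3.0, 600.0)
        a = d.simulate_r2eff(750.0, 0.03, dw, 8.0, NU, T_CPMG)
        b = d.simulate_r2eff(750.0, 0.97, -dw, 8.0, NU, T_CPMG)
        np.testing.assert_allclose(a, b, atol=1e-10)

    @pytest.mark.parametrize("kex,dw_ppm", [(5000.0, 1.0), (1e4, 2.0), (2e4, 3.0)])
    def test_fast_exchange_profile_non_increasing(self, kex, dw_ppm):
        dw = d.dw_rad_per_s(dw_ppm, 600.0)
        prof = d.simulate_r2eff(kex, 0.02, dw, 8.0, NU, T_CPMG)
        assert np.all(np.diff(prof) <= 1e-9)
        # approaches the exchange-free baseline at high pulse rates
        assert prof[-1] - 8.0 < prof[0] - 8.0
        # low-nu limit: Rex ~ p_a p_b dw^2 / kex in the fast limit
        rex0 = 0.98 * 0.02 * dw**2 / kex
        assert prof[0] - 8.0 == pytest.approx(rex0, rel=0.05)


class TestSelection:
    def _series(self, rid, field, span):
        r2 = 8.0 + span * np.exp(-NU / 200.0) / np.exp(-NU[0] / 200.0)
        r2 = 8.0 + (r2 - r2.min()) / (r2.max() - r2.min()) * span
        return d.DispersionSeries(rid, field, NU, r2, np.full_like(NU, 0.2))

    def test_selection_rules(self):
        dataset = [
            self._series("flat", 600.0, 0.3), self._series("flat", 800.0, 0.3),
            self._series("oneweak", 600.0, 1.5), self._series("oneweak", 800.0, 0.8),
            self._series("good", 600.0, 2.0), self._series("good", 800.0, 2.0),
            self._series("single", 600.0, 3.0),
        ]
        included, excluded, spans = d.select_residues(dataset, span_min=1.0)
        assert included == ["good"]
        assert "flat" in excluded and "800" in excluded["oneweak"]
        assert "single field" in excluded["single"]


class TestAlpha:
    def test_quadratic_field_scaling_gives_196(self):
        # Rex proportional to B^2 at 600/800 -> alpha = 7 * (28/100) = 1.96
        r2b = {("r", 600.0): 8.0, ("r", 800.0): 8.0}
        ds = [
            d.DispersionSeries("r", 600.0, NU, 8.0 + 3.6 * np.ones_like(NU), np.ones_like(NU)),
            d.DispersionSeries("r", 800.0, NU, 8.0 + 6.4 * np.ones_like(NU), np.ones_like(NU)),
        ]
        est = d.compute_alpha(ds, r2b)
        assert est.per_residue["r"] == pytest.approx(1.96)

    def test_field_independent_rex_gives_zero(self):
        r2b = {("r", 600.0): 8.0, ("r", 800.0): 8.0}
        ds = [
            d.DispersionSeries("r", f, NU, 8.0 + 2.0 * np.ones_like(NU), np.ones_like(NU))
            for f in (600.0, 800.0)
        ]
        assert d.compute_alpha(ds, r2b).per_residue["r"] == pytest.approx(0.0)

    def test_slow_exchange_alpha_below_half(self):
        model = d.TwoSiteModel(kex=50.0, p_b=0.05, delta_omega={"r": 6.0},
                               r2_base={("r", 600.0): 8.0, ("r", 800.0): 8.0})
        ds = [d.DispersionSeries("r", f, NU,
                                 d.simulate_profile(model, "r", f, NU, T_CPMG),
                                 np.ones_like(NU))
              for f in (600.0, 800.0)]
        est = d.compute_alpha(ds, model.r2_base)
        assert est.per_residue["r"] < 0.5

    def test_negative_rex_skipped_with_reason(self):
        r2b = {("r", 600.0): 10.0, ("r", 800.0): 8.0}
        ds = [d.DispersionSeries("r", f, NU, np.full_like(NU, 9.0), np.ones_like(NU))
              for f in (600.0, 800.0)]
        est = d.compute_alpha(ds, r2b)
        assert "r" in est.skipped


class TestRates:
    def test_population_rate_identities(self):
        kf, kb = d.rates_from_populations(750.0, 0.02)
        assert kf == pytest.approx(15.0)
        assert d.population_from_rates(750.0, 15.0) == pytest.approx(0.02)
        # 4 s^-1 of 500 s^-1 -> 0.8%, i.e. 1% at nearest-percent rounding
        p = d.population_from_rates(500.0, 4.0)
        assert round(100 * p) == 1

    def test_symmetric_population_splits_rates_evenly(self):
        kf, kb = d.rates_from_populations(1000.0, 0.499999)
        assert kf == pytest.approx(kb, rel=1e-4)

    def test_forward_rate_exceeding_kex_rejected(self):
        with pytest.raises(ValueError):
            d.population_from_rates(100.0, 200.0)


class TestFitting:
    def test_single_residue_noiseless_recovery(self, noiseless_dispersion):
        dataset, truth = noiseless_dispersion
        rid = "R3"
        by_field = {s.field: s for s in dataset if s.residue_id == rid}
        fit = d.fit_single_residue(by_field, T_CPMG)
        assert fit.chi2 < 1e-6
        assert fit.model.kex == pytest.approx(truth.kex, rel=1e-3)
        assert d.papb_dw2(fit.model, rid) == pytest.approx(
            d.papb_dw2(truth, rid), rel=1e-3)

    def test_flat_profile_flagged_unidentifiable(self):
        ds = {f: d.DispersionSeries("r", f, NU, np.full_like(NU, 8.0),
                                    np.full_like(NU, 0.2))
              for f in (600.0, 800.0)}
        fit = d.fit_single_residue(ds, T_CPMG)
        assert fit.excluded_residues or fit.chi2 < 1e-6

    def test_global_noiseless_recovery(self, noiseless_dispersion):
        dataset, truth = noiseless_dispersion
        fit = d.fit_global(dataset, T_CPMG, exclude_reduced_chi2=None,
                           kex_starts=(300.0, 1000.0))
        assert fit.chi2 < 1e-6
        assert fit.model.kex == pytest.approx(truth.kex, rel=1e-4)
        assert fit.model.p_b == pytest.approx(truth.p_b, rel=1e-3)
        for rid, dw in truth.delta_omega.items():
            assert abs(fit.model.delta_omega[rid]) == pytest.approx(dw, rel=1e-3)

    def test_fixed_forward_rate_nesting(self, noiseless_dispersion):
        dataset, truth = noiseless_dispersion
        free = d.fit_global(dataset, T_CPMG, exclude_reduced_chi2=None,
                            kex_starts=(1000.0,))
        fixed = d.fit_global(dataset, T_CPMG, exclude_reduced_chi2=None,
                             fix_kf=30.0, kex_starts=(1000.0,))
        assert fixed.chi2 >= free.chi2 - 1e-9

    def test_underdetermined_system_rejected(self):
        nu = NU[:2]
        ds = []
        for rid in ("a", "b"):
            for f in (600.0, 800.0):
                ds.append(d.DispersionSeries(rid, f, nu, np.array([10.0, 8.0]),
                                             np.full(2, 0.2)))
        with pytest.raises(ValueError, match="under-determined"):
            d.fit_global(ds, T_CPMG, span_min=1.0, exclude_reduced_chi2=None)


class TestCorrelation:
    def _fit(self, p_b=0.02, kex=750.0, dws=(1.5, 2.0, 2.5, 3.0)):
        model = d.TwoSiteModel(
            kex=kex, p_b=p_b,
            delta_omega={f"r{i}": v for i, v in enumerate(dws)},
            r2_base={(f"r{i}", 600.0): 8.0 for i in range(len(dws))})
        return d.FitResult(model=model, chi2=0.0, n_data=10, n_params=2)

    def test_exact_construction_recovers_population(self):
        fit = self._fit(p_b=0.02)
        binding = dict(fit.model.delta_omega)  # exact shifts, no ring term
        out = d.correlate_with_binding_shifts(fit, binding)
        assert out["slope"] == pytest.approx(np.sqrt(0.98 * 0.02), rel=1e-6)
        assert out["p_a_p_b"] == pytest.approx(0.98 * 0.02, rel=1e-6)
        assert out["p_b"] == pytest.approx(0.02, rel=1e-6)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_population_and_forward_rate_from_slope(self):
        # p_a p_b = 0.02 at kex = 750 -> p_b = 0.0204, k_f = 15.3
        fit = self._fit()
        binding = {r: v / np.sqrt(0.98 * 0.02) * np.sqrt(0.02)
                   for r, v in fit.model.delta_omega.items()}
        # scale binding shifts so the through-origin slope^2 equals 0.02
        out = d.correlate_with_binding_shifts(fit, {
            r: np.sqrt(d.papb_dw2(fit.model, r)) / np.sqrt(0.02)
            for r in fit.model.delta_omega})
        assert out["p_a_p_b"] == pytest.approx(0.02, rel=1e-9)
        assert out["p_b"] == pytest.approx(0.0204, abs=2e-4)
        assert out["k_f"] == pytest.approx(15.3, abs=0.2)

    def test_ring_correction_applied(self):
        fit = self._fit()
        binding = {r: v + 0.15 for r, v in fit.model.delta_omega.items()}
        ring = {r: 0.15 for r in fit.model.delta_omega}
        out = d.correlate_with_binding_shifts(fit, binding, ring)
        assert out["p_b"] == pytest.approx(0.02, rel=1e-6)

    def test_too_few_common_residues_rejected(self):
        fit = self._fit()
        with pytest.raises(ValueError):
            d.correlate_with_binding_shifts(fit, {"r0": 1.0, "r1": 2.0})
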