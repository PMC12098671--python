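"""Wavelength selection, calibration model/results, quantification flows."""

import numpy as np
import pytest

from syncfluor.exceptions import NumericError, UnresolvableChannelsError
from syncfluor.fluorophores import default_models
from syncfluor.quant import (
    RecoveryRecord,
    analyze_mixture,
    fit_calibration,
    predict_concentration,
    round_half_up,
    select_measurement_wavelength,
    standard_addition,
    tablet_assay,
)
from syncfluor.simulate import (
    NOISELESS,
    NoiseModel,
    generate_calibration_panel,
    generate_mixture_panel,
    simulate_eem,
    simulate_tablet_panel,
    mixture_ratio_series,
)
from syncfluor.syncderiv import (
    amplitude_at,
    find_zero_crossings,
    first_derivative,
    synchronous_spectrum,
)

from conftest import derivative_panel


class TestSelectMeasurementWavelength:
    def test_anchors_within_ten_nm(self, wavelengths):
        """Auto-selected channels sit at the instrument anchors: ATO read
        near 384 nm (ASP's crossing), ASP near 365 nm (ATO's crossing)."""
        assert abs(wavelengths["ATO"] - 384.0) <= 10.0
        assert abs(wavelengths["ASP"] - 365.0) <= 10.0

    def test_matches_exhaustive_scan_oracle(self, cfg):
        """Selection equals an independent brute-force scan of the same
        rule (grid minimax + crossing refinement)."""
        panels = {
            m.name: generate_calibration_panel(
                m.name, cfg.calibration_levels[m.name][:3],
                noise=NOISELESS, seed=0, background=0.0,
            )
            for m in default_models()
        }
        derivs = {n: derivative_panel(p, cfg) for n, p in panels.items()}
        ref = max(derivs["ATO"], key=lambda t: t[0])[1]
        interferent = [d for _, d in derivs["ASP"]]
        got = select_measurement_wavelength(interferent, ref, 0.3)

        # oracle: plain loops over the shared grid
        g = ref.edge_guard
        lam = ref.wavelengths[g:-g]
        ref_abs = np.abs(ref.amplitudes[g:-g])
        floor = 0.3 * ref_abs.max()
        best_i, best_val, best_ref = None, np.inf, -np.inf
        for i in range(len(lam)):
            if ref_abs[i] < floor:
                continue
            worst = max(abs(d.amplitudes[g:-g][i]) for d in interferent)
            if worst < best_val * (1 - 1e-12) or (
                abs(worst - best_val) <= 1e-12 * max(worst, 1e-300)
                and ref_abs[i] > best_ref
            ):
                best_i, best_val, best_ref = i, worst, ref_abs[i]
        expected = lam[best_i]
        top = max(interferent, key=lambda d: np.abs(d.amplitudes[g:-g]).max())
        near = [
            x for x in find_zero_crossings(top)
            if abs(x - expected) <= lam[1] - lam[0]
        ]
        if near:
            expected = min(near, key=lambda x: abs(x - expected))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_zero_interferent_degenerates_to_analyte_argmax(self, cfg):
        asp, ato = default_models()
        blank = simulate_eem([], background=0.0)
        zero_d = [
            first_derivative(synchronous_spectrum(blank, 80.0), 15)
            for _ in range(3)
        ]
        ref_eem = simulate_eem([(asp, 6.0)], background=0.0)
        ref = first_derivative(synchronous_spectrum(ref_eem, 80.0), 15)
        got = select_measurement_wavelength(zero_d, ref, 0.3)
        g = ref.edge_guard
        lam = ref.wavelengths[g:-g]
        expected = lam[np.argmax(np.abs(ref.amplitudes[g:-g]))]
        assert got == expected

    def test_unresolvable_when_floor_unreachable(self, cfg):
        blank = simulate_eem([], background=0.0)
        zero = first_derivative(synchronous_spectrum(blank, 80.0), 15)
        with pytest.raises(UnresolvableChannelsError, match="unresolvable"):
            select_measurement_wavelength([zero] * 3, zero, 0.3)


class TestCalibration:
    def test_exact_line(self):
        res = fit_calibration([0, 1, 2], [1, 3, 5], "X", 384.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_identical_levels_rejected(self):
        with pytest.raises(NumericError, match="distinct"):
            fit_calibration([2, 2, 2], [1, 2, 3], "X", 384.0)

    def test_sigma_unavailable_without_replicates(self):
        res = fit_calibration([0, 1, 2], [1, 3, 5], "X", 384.0)
        assert res.sigma_intercept is None

    def test_sigma_from_replicate_curves(self):
        levels = [0, 1, 2, 0, 1, 2, 0, 1, 2]
        reps = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        amps = [1.0, 3.0, 5.0, 1.1, 3.1, 5.1, 0.9, 2.9, 4.9]
        res = fit_calibration(levels, amps, "X", 384.0, replicate_ids=reps)
        assert res.sigma_intercept == pytest.approx(0.1, rel=1e-9)

    def test_noiseless_panels_hit_printed_r2_floor(self, noiseless_curves):
        """Noiseless 6-level calibration must reach the determination
        coefficients a validated run reports (r^2 >= 0.9998)."""
        for curve in noiseless_curves.values():
            assert curve.r_squared >= 0.9998

    def test_slope_matches_closed_form_chain(self, cfg, noiseless_curves):
        """The fitted sensitivity equals the closed-form synchronous trace
        of the analyte pushed through the same derivative operator."""
        from scipy.signal import savgol_filter

        for model in default_models():
            curve = noiseless_curves[model.name]
            grid = np.arange(
                300.0, 500.0 + 0.5, 1.0
            )  # emission overlap for dl=80
            trace = model.brightness * np.exp(
                -((grid - cfg.delta_lambda - model.ex_max) ** 2)
                / (2 * model.ex_width**2)
                - ((grid - model.em_max) ** 2) / (2 * model.em_width**2)
            )
            d = savgol_filter(
                trace, cfg.derivative_interval, 2, deriv=1, delta=1.0,
                mode="interp",
            )
            oracle = float(
                np.interp(curve.measurement_wavelength, grid, d)
            )
            assert curve.slope == pytest.approx(oracle, rel=0.005)

    def test_summary_mentions_key_quantities(self, noiseless_curves):
        text = noiseless_curves["ATO"].summary()
        assert "slope" in text and "r^2" in text and "ATO" in text


class TestPrediction:
    def test_printed_regression_inversion(self):
        """Inverting the published ATO line: amplitude 4.4169 with slope
        0.2138 and intercept 3.9893 gives 2.0 ug/mL."""
        res = fit_calibration(
            [0.4, 2.0, 6.0],
            [0.2138 * c + 3.9893 for c in (0.4, 2.0, 6.0)],
            "ATO", 384.0,
        )
        est = res.predict(4.4169)
        assert est.value == pytest.approx(2.0, abs=1e-4)

    def test_amplitude_equal_intercept_flags_below_range(self):
        res = fit_calibration([1, 2, 3], [3.0, 5.0, 7.0], "X", 384.0)
        est = res.predict(res.intercept)
        assert est.value == pytest.approx(0.0)
        assert est.below_range and not est.in_range

    def test_zero_slope_rejected(self):
        res = fit_calibration([1, 2, 3], [5.0, 5.0, 5.0], "X", 384.0)
        assert res.slope == pytest.approx(0.0)
        with pytest.raises(NumericError, match="slope"):
            res.predict(5.0)

    def test_predict_fit_identity_on_perfect_line(self):
        levels = np.array([1.0, 2.0, 4.0, 8.0])
        amps = -0.7 * levels + 0.3  # negative-slope channel is legal
        res = fit_calibration(levels, amps, "X", 384.0)
        for c, a in zip(levels, amps):
            assert res.predict(a).value == pytest.approx(c, rel=1e-12)

    def test_held_out_noiseless_prediction(self, cfg, noiseless_curves):
        """Round-trip through the full pipeline on concentrations not in
        the calibration set recovers truth to 0.5%."""
        asp, ato = default_models()
        for model, conc in ((asp, 3.3), (ato, 1.7)):
            eem = simulate_eem([(model, conc)], background=2.0)
            d = first_derivative(
                synchronous_spectrum(eem, cfg.delta_lambda),
                cfg.derivative_interval,
            )
            curve = noiseless_curves[model.name]
            est = curve.predict(
                amplitude_at(d, curve.measurement_wavelength)
            )
            assert est.value == pytest.approx(conc, rel=5e-3)

    def test_functional_alias(self, noiseless_curves):
        curve = noiseless_curves["ASP"]
        a = curve.predict(curve.intercept + curve.slope * 4.0)
        b = predict_concentration(curve, curve.intercept + curve.slope * 4.0)
        assert a.value == b.value


class TestMixtureAnalysis:
    def test_noiseless_ratio_series_recoveries(self, cfg, noiseless_curves):
        panel = generate_mixture_panel(
            mixture_ratio_series(), noise=NOISELESS, seed=0
        )
        for spec, eem in panel:
            res = analyze_mixture(eem, noiseless_curves, cfg)
            for analyte, r in res.items():
                assert 98.0 <= r.recovery.percent_recovery <= 102.0

    def test_blank_flags_below_range(self, cfg, noiseless_curves):
        blank = generate_mixture_panel(
            [(0.0, 0.0)], noise=NOISELESS, seed=0
        )[0][1]
        res = analyze_mixture(blank, noiseless_curves, cfg)
        for r in res.values():
            assert r.estimate.below_range
            assert r.recovery is None

    def test_recovery_arithmetic_printed_row(self):
        rec = RecoveryRecord.compute(1.875, 1.899)
        assert round_half_up(rec.percent_recovery) == 101.28

    def test_mismatched_delta_lambda_rejected(self, cfg, noiseless_curves):
        from syncfluor.spectra_io import perturbed

        eem = generate_mixture_panel([(1.875, 0.5)], noise=NOISELESS,
                                     seed=0)[0][1]
        with pytest.raises(ValueError, match="delta-lambda"):
            analyze_mixture(
                eem, noiseless_curves, perturbed(cfg, delta_lambda=60.0)
            )

    def test_interferent_invariance_of_channel(self, cfg, noiseless_curves):
        """At each analyte's wavelength the derivative amplitude moves by
        <1% of the analyte's mid-range signal while the co-analyte spans a
        3-fold concentration range."""
        asp, ato = default_models()
        for analyte, inter, mid_conc, span in (
            (ato, asp, 3.0, (8 / 3, 8.0)),
            (asp, ato, 5.5, (2.0, 6.0)),
        ):
            lam = noiseless_curves[analyte.name].measurement_wavelength
            amps = []
            for c in span:
                eem = simulate_eem(
                    [(analyte, mid_conc), (inter, c)], background=0.0
                )
                d = first_derivative(
                    synchronous_spectrum(eem, cfg.delta_lambda), 15
                )
                amps.append(amplitude_at(d, lam))
            ref_eem = simulate_eem([(analyte, mid_conc)], background=0.0)
            ref_amp = amplitude_at(
                first_derivative(
                    synchronous_spectrum(ref_eem, cfg.delta_lambda), 15
                ),
                lam,
            )
            assert abs(amps[1] - amps[0]) < 0.01 * abs(ref_amp)

    def test_recovery_invariant_to_coanalyte(self, cfg, noiseless_curves):
        """Pipeline-level specificity: each analyte's recovery shifts by
        <1% relative when the co-analyte concentration triples."""
        asp, ato = default_models()
        found = []
        for c_asp in (2.0, 6.0):
            eem = simulate_eem([(asp, c_asp), (ato, 2.0)], background=2.0)
            res = analyze_mixture(eem, noiseless_curves, cfg)
            found.append(res["ATO"].estimate.value)
        assert abs(found[1] - found[0]) / found[0] < 0.01


class TestStandardAddition:
    def test_printed_table_row(self):
        rec = standard_addition(75.21, 7.5, 75.21 + 7.637)
        assert rec.found == pytest.approx(7.637)
        assert round_half_up(rec.percent_recovery) == 101.83

    def test_perfect_spike_is_hundred(self):
        rec = standard_addition(10.0, 2.5, 12.5)
        assert rec.percent_recovery == pytest.approx(100.0)

    def test_negative_pure_found_flagged(self):
        rec = standard_addition(10.0, 1.0, 9.5)
        assert rec.flagged and rec.found < 0

    def test_zero_added_rejected(self):
        with pytest.raises(ValueError):
            standard_addition(10.0, 0.0, 10.0)


class TestTabletAssay:
    def _nominal(self):
        ato = [0.5, 1.0, 1.5, 2.0, 2.5]
        return {"ATO": ato, "ASP": [3.75 * c for c in ato]}

    def test_content_at_claim_noiseless(self, cfg, noiseless_curves):
        panel = simulate_tablet_panel(
            {"ATO": 1.0, "ASP": 1.0}, noise=NOISELESS, seed=0
        )
        res = tablet_assay(
            [e for _, e in panel], noiseless_curves, cfg, self._nominal()
        )
        for block in res.values():
            assert block["mean_percent_recovery"] == pytest.approx(100, abs=0.5)

    def test_99_percent_content(self, cfg, noiseless_curves):
        panel = simulate_tablet_panel(
            {"ATO": 0.99, "ASP": 0.99}, noise=NOISELESS, seed=0
        )
        res = tablet_assay(
            [e for _, e in panel], noiseless_curves, cfg, self._nominal()
        )
        for block in res.values():
            assert block["mean_percent_recovery"] == pytest.approx(99, abs=0.6)

    def test_noisy_rsd_within_limit(self, cfg, noisy_curves):
        panel = simulate_tablet_panel(
            {"ATO": 1.0, "ASP": 1.0}, noise=NoiseModel(), seed=21
        )
        res = tablet_assay(
            [e for _, e in panel], noisy_curves, cfg, self._nominal()
        )
        for block in res.values():
            assert block["percent_rsd"] <= 2.0

    def test_wrong_level_count_warns(self, cfg, noiseless_curves):
        panel = simulate_tablet_panel(
            {"ATO": 1.0, "ASP": 1.0},
            dilution_concs_ato=[1.0, 2.0], noise=NOISELESS, seed=0,
        )
        nominal = {"ATO": [1.0, 2.0], "ASP": [3.75, 7.5]}
        with pytest.warns(UserWarning, match="5 dilution levels"):
            tablet_assay(
                [e for _, e in panel], noiseless_curves, cfg, nominal
            )
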