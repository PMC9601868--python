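import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pinmap.binding import (EquilibriumSeries, KineticParams, Sensorgram,
                            equilibrium_response, fit_equilibrium,
                            fit_two_state, fold_change, fold_change_table,
                            read_equilibrium_csv, read_sensorgram_csv,
                            simulate_two_state, write_equilibrium_csv,
                            write_sensorgram_csv)
from pinmap.datasets import POINT_MUTANTS, TURN_FACE_MUTANTS, WILD_TYPE_KD
from pinmap.synthetic import generate_equilibrium_series


class TestEquilibriumResponse:
    def test_half_saturation_at_kd(self):
        assert equilibrium_response(14.6e-9, 14.6e-9, 100.0) == pytest.approx(50.0)

    def test_zero_concentration(self):
        assert equilibrium_response(0.0, 1e-8, 100.0) == 0.0

    def test_nine_kd_gives_ninety_percent(self):
        assert equilibrium_response(9 * 2e-8, 2e-8, 80.0) == pytest.approx(0.9 * 80.0)

    def test_monotone_in_concentration_and_rmax(self):
        c = np.logspace(-10, -5, 30)
        r = equilibrium_response(c, 1e-8, 100.0)
        assert np.all(np.diff(r) > 0)
        assert np.all(equilibrium_response(c, 1e-8, 120.0) > r)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_response(1e-8, 0.0, 100.0)


class TestFitEquilibrium:
    def test_noiseless_recovery(self):
        kd = 14.6e-9
        concs = [kd * f for f in (0.1, 0.3, 1, 3, 10, 30, 100)]
        series = generate_equilibrium_series(kd, 100.0, concs, 0.0, 0)
        fit = fit_equilibrium(series)
        assert fit.converged
        assert fit.kd_apparent == pytest.approx(kd, rel=1e-3)
        assert fit.params["rmax"] == pytest.approx(100.0, rel=1e-3)

    def test_half_saturation_point_pins_kd(self):
        kd = 5e-8
        concs = np.array([kd / 20, kd / 5, kd, kd * 5, kd * 20, kd * 100])
        series = EquilibriumSeries(concs, equilibrium_response(concs, kd, 100.0))
        fit = fit_equilibrium(series)
        assert fit.kd_apparent == pytest.approx(kd, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_equilibrium(EquilibriumSeries(np.array([1e-9, 1e-7]),
                                              np.array([1.0, 50.0])))

    def test_narrow_series_rejected(self):
        concs = np.array([1e-8, 1.5e-8, 2e-8])
        with pytest.raises(ValueError, match="factor of 10"):
            fit_equilibrium(EquilibriumSeries(concs, concs * 1e9))

    def test_uninformative_series_flagged(self):
        # all concentrations far below Kd: the isotherm is a straight line
        kd = 1e-4
        concs = np.array([1e-9, 1e-8, 1e-7])
        series = EquilibriumSeries(concs, equilibrium_response(concs, kd, 100.0))
        fit = fit_equilibrium(series)
        assert not fit.converged
        assert fit.message


class TestSimulateTwoState:
    def params(self, **kw):
        defaults = dict(ka1=1e5, kd1=1e-2, ka2=0.0, kd2=0.0, rmax=100.0)
        defaults.update(kw)
        return KineticParams(**defaults)

    def test_reduces_to_1to1_closed_form(self):
        p = self.params()
        conc = 1e-7
        t = np.linspace(0.0, 60.0, 121)
        sg = simulate_two_state(p, conc, t, 60.0)
        req = p.rmax * conc / (conc + p.kd1 / p.ka1)
        expected = req * (1.0 - np.exp(-(p.ka1 * conc + p.kd1) * t))
        assert np.abs(sg.response - expected).max() < 1e-6

    def test_plateau_equals_equilibrium_response(self):
        p = self.params(ka2=0.0, kd2=0.0)
        conc = 5e-8
        t = np.linspace(0.0, 5e4, 200)
        sg = simulate_two_state(p, conc, t, 5e4)
        assert sg.response[-1] == pytest.approx(
            equilibrium_response(conc, p.kd1 / p.ka1, p.rmax), rel=1e-6)

    def test_zero_concentration_flat(self):
        p = self.params(ka2=1e-3, kd2=1e-3)
        t = np.linspace(0.0, 660.0, 331)
        sg = simulate_two_state(p, 0.0, t, 60.0)
        assert np.all(sg.response == 0.0)

    def test_response_bounded_and_starts_at_zero(self):
        p = KineticParams(2e5, 1e-2, 5e-3, 2.062e-3, 100.0)
        t = np.linspace(0.0, 660.0, 661)
        sg = simulate_two_state(p, 1e-6, t, 60.0)
        assert sg.response[0] == 0.0
        assert np.all(sg.response >= 0.0) and np.all(sg.response <= p.rmax + 1e-9)

    def test_site_conservation(self):
        p = KineticParams(2e5, 1e-2, 5e-3, 2.062e-3, 100.0)
        t = np.linspace(0.0, 660.0, 661)
        sg = simulate_two_state(p, 1e-6, t, 60.0)
        assert np.all(sg.response <= p.rmax + 1e-6)

    def test_kd_apparent_formula(self):
        p = KineticParams(2e5, 1e-2, 5e-3, 2.062e-3, 100.0)
        expected = (p.kd1 / p.ka1) * p.kd2 / (p.kd2 + p.ka2)
        assert p.kd_apparent == pytest.approx(expected, rel=1e-12)


class TestFitTwoState:
    def make_curves(self, params, concs, n_t=221):
        t = np.linspace(0.0, 660.0, n_t)
        return [simulate_two_state(params, c, t, 60.0) for c in concs]

    def test_noiseless_global_recovery(self):
        params = KineticParams(2e5, 1e-2, 5e-3, 2.062e-3, 100.0)
        curves = self.make_curves(params, [5e-9, 2e-8, 1e-7])
        fit = fit_two_state(curves)
        assert fit.converged
        assert fit.kd_apparent == pytest.approx(params.kd_apparent, rel=0.01)

    def test_nesting_matches_simple_1to1_fit(self):
        # data generated without the conformational step: the two-state fit
        # must land on the same apparent Kd as the plain encounter ratio
        params = KineticParams(1e5, 2e-3, 0.0, 0.0, 100.0)
        curves = self.make_curves(params, [1e-8, 4e-8, 1.6e-7])
        fit = fit_two_state(curves)
        assert fit.kd_apparent == pytest.approx(params.kd1 / params.ka1,
                                                rel=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_two_state([])


class TestFoldChange:
    @pytest.mark.parametrize("kd_mut, expected", [
        (2.7e-6, 185),
        (6.5e-6, 445),
        (14.6e-9, 1),
    ])
    def test_reference_ratios(self, kd_mut, expected):
        assert fold_change(kd_mut, WILD_TYPE_KD).fold == expected

    @settings(max_examples=30, deadline=None)
    @given(st.floats(1e-10, 1e-3), st.floats(1e-10, 1e-3), st.floats(0.01, 100))
    def test_scale_invariance(self, a, b, s):
        assert fold_change(a * s, b * s).fold == fold_change(a, b).fold

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1e-8)

    def test_round_half_up(self):
        assert fold_change(2.5e-8, 1e-8).fold == 3
        assert fold_change(2.4999e-8, 1e-8).fold == 2


class TestFoldChangeTable:
    def test_alanine_scan_folds(self):
        entries = [(n, kd) for n, kd, _ in POINT_MUTANTS
                   if n in {"K290A", "V294A", "K297A", "M298A", "I300A",
                            "M304A", "K305A", "R312A"}]
        table = fold_change_table(entries, WILD_TYPE_KD)
        folds = {r.name: r.fold for r in table.rows}
        assert folds == {"K290A": 3, "V294A": 8, "K297A": 4, "M298A": 22,
                         "I300A": 2, "M304A": 2, "K305A": 2, "R312A": 2}

    def test_binding_deficient_row(self):
        table = fold_change_table([("K297E", None)], WILD_TYPE_KD)
        row = table.rows[0]
        assert row.qualitative == "binding_deficient"
        assert row.fold is None and row.ratio is None

    def test_empty_table(self):
        table = fold_change_table([], WILD_TYPE_KD)
        assert table.rows == []
        assert list(table.to_frame().columns)  # header only

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fold_change_table([("X", 1e-8), ("X", 2e-8)], WILD_TYPE_KD)

    def test_discrepancy_flagging(self):
        # stated folds computed from unrounded estimates disagree with the
        # ratio of the rounded Kd values and must be flagged, not echoed
        table = fold_change_table(TURN_FACE_MUTANTS, WILD_TYPE_KD)
        by_name = {r.name: r for r in table.rows}
        assert by_name["Turns 1-2"].fold == 185
        assert not by_name["Turns 1-2"].discrepant
        assert by_name["Turns 3-4"].fold == 75
        assert by_name["Turns 3-4"].discrepant  # stated value was 77
        frame = table.to_frame()
        note = frame.loc[frame["name"] == "Turns 3-4", "note"].item()
        assert "unrounded" in note


class TestCsvIO:
    def test_sensorgram_round_trip(self, tmp_path):
        sg = Sensorgram(np.linspace(0, 660, 67), np.linspace(0, 50, 67),
                        2.5e-8, 60.0)
        path = tmp_path / "sg.csv"
        write_sensorgram_csv(sg, path)
        back = read_sensorgram_csv(path)
        assert back.analyte_conc == pytest.approx(2.5e-8)
        assert back.t_inject_end == 60.0
        assert np.allclose(back.response, sg.response, rtol=1e-5)

    def test_equilibrium_round_trip(self, tmp_path):
        series = EquilibriumSeries(np.logspace(-9, -6, 8),
                                   np.linspace(1, 90, 8))
        path = tmp_path / "eq.csv"
        write_equilibrium_csv(series, path)
        back = read_equilibrium_csv(path)
        assert np.allclose(back.concs, series.concs)
        assert np.allclose(back.req, series.req)
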