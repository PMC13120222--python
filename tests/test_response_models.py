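"""Treatment statistics: sigmoid fits, substrate-control regressions with the
excluded-temperature rule, and pooled-variance t-tests against a textbook
oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from leafvoc import (
    build_report,
    compare_treatments,
    fit_sigmoid,
    fit_substrate_control,
    significance_stars,
)
from leafvoc.response_models import logistic4


class TestFitSigmoid:
    def test_parameter_recovery_at_2pct_noise(self):
        rng = np.random.default_rng(2)
        truth = dict(y_min=1.0, y_max=13.0, t_mid=36.0, scale=1.5)
        t = np.linspace(20.0, 45.0, 24)
        y = logistic4(t, *truth.values())
        y = y * (1 + 0.02 * rng.standard_normal(t.size))
        fit = fit_sigmoid(t, y)
        assert fit.converged
        assert fit.y_min == pytest.approx(truth["y_min"], rel=0.10, abs=0.1)
        assert fit.y_max == pytest.approx(truth["y_max"], rel=0.10)
        assert fit.t_mid_c == pytest.approx(truth["t_mid"], rel=0.10)
        assert fit.slope_scale_c == pytest.approx(truth["scale"], rel=0.10)

    def test_constant_data_degenerate(self):
        t = np.array([25.0, 30.0, 35.0, 40.0] * 3)
        fit = fit_sigmoid(t, np.full(12, 7.0))
        assert "degenerate" in fit.flags
        assert fit.y_max == pytest.approx(fit.y_min)

    def test_too_few_distinct_temperatures_rejected(self):
        with pytest.raises(ValueError, match="distinct temperatures"):
            fit_sigmoid([25, 25, 30, 30, 35], [1, 1, 2, 2, 3])

    def test_fahrenheit_reparameterisation_consistent(self):
        """Fitting against a converted temperature axis gives identical
        predictions at matched temperatures."""
        t_c = np.linspace(20.0, 45.0, 24)
        y = logistic4(t_c, 1.0, 13.0, 36.0, 1.5)
        t_f = t_c * 9 / 5 + 32
        fit_c = fit_sigmoid(t_c, y)
        fit_f = fit_sigmoid(t_f, y)
        probe_c = np.array([26.0, 33.0, 39.0])
        np.testing.assert_allclose(
            fit_c.predict(probe_c),
            fit_f.predict(probe_c * 9 / 5 + 32),
            rtol=1e-4,
        )

    def test_prediction_invariant_to_data_order(self):
        rng = np.random.default_rng(5)
        t = np.linspace(22.0, 42.0, 20)
        y = logistic4(t, 2.0, 10.0, 34.0, 2.0) + 0.05 * rng.standard_normal(20)
        perm = rng.permutation(20)
        fit1 = fit_sigmoid(t, y)
        fit2 = fit_sigmoid(t[perm], y[perm])
        probe = np.linspace(22, 42, 7)
        np.testing.assert_allclose(fit1.predict(probe), fit2.predict(probe),
                                   rtol=1e-8)

    def test_decreasing_response_fits_monotone(self):
        t = np.linspace(20.0, 45.0, 24)
        y = logistic4(t, 14.0, 1.0, 36.0, 1.2)  # declining assimilation
        fit = fit_sigmoid(t, y)
        pred = fit.predict(np.linspace(20, 45, 100))
        assert np.all(np.diff(pred) <= 1e-9)
        assert fit.y_max >= fit.y_min


class TestSubstrateControl:
    def test_exact_proportionality_recovered(self):
        """Emission generated as exactly k*S over 25-35 C gives r2 = 1 and
        the generating slope."""
        k = 0.03
        s = np.array([100.0, 150.0, 200.0, 260.0, 320.0, 380.0])
        temps = np.array([25.0, 25.0, 30.0, 30.0, 35.0, 35.0])
        fit = fit_substrate_control(s, k * s, temps, exclude_temps=(40.0,))
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(k, rel=1e-9)
        assert fit.n_used == 6
        assert fit.excluded.empty

    def test_exclusion_changes_slope_and_is_recorded(self):
        """A decoupled 40 C cluster pulls the slope when included; excluding
        it restores the coupled regime, and the excluded points are echoed."""
        rng = np.random.default_rng(3)
        s_low = np.linspace(100, 300, 9)
        temps_low = np.repeat([25.0, 30.0, 35.0], 3)
        y_low = 0.03 * s_low + 0.01 * rng.standard_normal(9)
        s_hot = np.array([320.0, 340.0, 360.0])
        y_hot = 0.08 * s_hot  # decoupled high-velocity regime
        s = np.concatenate([s_low, s_hot])
        y = np.concatenate([y_low, y_hot])
        temps = np.concatenate([temps_low, [40.0] * 3])
        with_excl = fit_substrate_control(s, y, temps, exclude_temps=(40.0,))
        without = fit_substrate_control(s, y, temps, exclude_temps=())
        assert without.slope > with_excl.slope
        assert len(with_excl.excluded) == 3
        assert set(with_excl.excluded["t_leaf_c"]) == {40.0}
        # the decoupled points lie above the coupled fit
        assert np.all(y_hot > with_excl.predict(s_hot))

    def test_all_points_excluded_rejected(self):
        with pytest.raises(ValueError, match="all points excluded"):
            fit_substrate_control([1, 2, 3], [1, 2, 3], [40, 40, 40],
                                  exclude_temps=(40.0,))

    def test_single_x_value_rejected(self):
        with pytest.raises(ValueError, match="single x value"):
            fit_substrate_control([5, 5, 5, 9], [1, 2, 3, 4],
                                  [25, 25, 30, 40], exclude_temps=(40.0,))


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test (two-tailed)."""
    from scipy.stats import t as tdist
    n1, n2 = len(a), len(b)
    v1 = np.var(a, ddof=1)
    v2 = np.var(b, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t_stat = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * tdist.sf(abs(t_stat), df)
    return t_stat, df, p


def cell_table(values_by_cell):
    rows = []
    for (temp, co2), values in values_by_cell.items():
        for i, v in enumerate(values):
            rows.append({"t_leaf_c": temp, "co2_umol_mol": co2,
                         "replicate": i, "y": v})
    return pd.DataFrame(rows)


class TestCompareTreatments:
    def test_matches_textbook_oracle_to_1e10(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        table = cell_table({(30.0, 400.0): a, (30.0, 800.0): b})
        (comp,) = compare_treatments(table, "y")
        t_exp, df_exp, p_exp = pooled_t_oracle(a, b)
        assert comp.t_stat == pytest.approx(t_exp, abs=1e-10)
        assert comp.df == df_exp
        assert comp.p_value == pytest.approx(p_exp, abs=1e-10)

    def test_identical_samples_give_t0_p1(self):
        vals = [1.0, 2.0, 3.0]
        table = cell_table({(25.0, 400.0): vals, (25.0, 800.0): vals})
        (comp,) = compare_treatments(table, "y")
        assert comp.t_stat == 0.0
        assert comp.p_value == 1.0
        assert comp.stars == "ns"

    def test_df_is_n1_plus_n2_minus_2(self):
        rng = np.random.default_rng(0)
        table = cell_table({(35.0, 400.0): rng.random(6),
                            (35.0, 800.0): rng.random(6)})
        (comp,) = compare_treatments(table, "y")
        assert comp.df == 10

    def test_underreplicated_cell_skipped_with_note(self):
        table = cell_table({
            (25.0, 400.0): [1.0], (25.0, 800.0): [2.0, 3.0],
            (30.0, 400.0): [1.0, 2.0], (30.0, 800.0): [2.0, 3.0],
        })
        comps = compare_treatments(table, "y")
        assert len(comps) == 2
        skipped = [c for c in comps if c.note]
        assert len(skipped) == 1 and skipped[0].temperature_c == 25.0
        assert math.isnan(skipped[0].p_value)

    def test_type_one_error_rate_near_nominal(self):
        """Under a shared null distribution across CO2 levels, the rejection
        rate at alpha=0.05 sits at 0.05 within sampling error."""
        rng = np.random.default_rng(123)
        n_exp, rejections, total = 400, 0, 0
        for _ in range(n_exp):
            table = cell_table({
                (t, c): rng.normal(10.0, 2.0, 6)
                for t in (25.0, 30.0, 35.0, 40.0) for c in (400.0, 800.0)
            })
            for comp in compare_treatments(table, "y"):
                total += 1
                if comp.p_value < 0.05:
                    rejections += 1
        rate = rejections / total
        assert abs(rate - 0.05) <= 0.02

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.5) == "ns"


def synthetic_leaf_summary(rng=None):
    rng = rng or np.random.default_rng(9)
    rows = []
    for temp in (25.0, 30.0, 35.0, 40.0):
        for co2 in (400.0, 800.0):
            for rep in range(6):
                k = 0.02 + 0.0015 * (temp - 25) + 0.001 * rng.random()
                s = 100 + 8 * (temp - 25) + 20 * rng.random()
                row = {
                    "trace_id": f"leaf_T{temp:g}_C{co2:g}_r{rep}",
                    "t_leaf_c": temp, "co2_umol_mol": co2, "replicate": rep,
                    "a_net": 14 - 0.3 * (temp - 25) + rng.random(),
                    "e_iso": k * s,
                    "s_pool_nmol_m2": s,
                    "k_loglin_s": k,
                    "flags": "",
                }
                for g in ("isoprene", "lox", "carbonyls", "methanol",
                          "acids", "ethanol"):
                    row[f"flux_{g}"] = rng.random() + (temp - 25) * 0.1
                rows.append(row)
    return pd.DataFrame(rows)


class TestBuildReport:
    def test_full_experiment_yields_four_tables_with_8_cells(self):
        report = build_report(synthetic_leaf_summary())
        for name in ("fig1", "fig2", "fig4"):
            cells = set(map(tuple, report[name][
                ["t_leaf_c", "co2_umol_mol"]].drop_duplicates().values))
            assert len(cells) == 8
        assert len(report["fig3"]) == 4  # 2 CO2 x 2 predictors
        assert report["ttests"]["p_value"].notna().sum() > 0
        assert not report["sigmoid_params"].empty

    def test_empty_summary_returns_empty_tables_not_error(self):
        empty = synthetic_leaf_summary().iloc[0:0]
        report = build_report(empty)
        assert all(df.empty for df in report.values())

    def test_flagged_leaves_dropped_by_default_kept_on_request(self):
        df = synthetic_leaf_summary()
        df.loc[0, "flags"] = "baseline-not-reached;truncated-integral"
        rep_drop = build_report(df, drop_flagged=True)
        rep_keep = build_report(df, drop_flagged=False)
        n_drop = rep_drop["fig2"]["n"].sum()
        n_keep = rep_keep["fig2"]["n"].sum()
        assert n_keep == n_drop + 1

    def test_report_regeneration_is_deterministic(self):
        df = synthetic_leaf_summary()
        r1 = build_report(df)
        r2 = build_report(df.copy())
        for name in r1:
            pd.testing.assert_frame_equal(r1[name], r2[name])
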