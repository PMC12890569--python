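"""Force-displacement analytics, concordance and group statistics."""

import numpy as np
import pytest

from cutsim import analysis as ana
from cutsim.reference import (
    damage_count_table,
    physical_force_table,
    simulated_force_table,
)


def _line(slope, d_max, n=200):
    d = np.linspace(0.0, d_max, n)
    return ana.FDCurve(d, slope * d)


class TestToeIn:
    def test_curve_at_threshold_unchanged(self):
        c = ana.FDCurve([0.0, 1.0, 2.0], [50.0, 100.0, 200.0])
        out = ana.normalize_toe_in(c, 50.0)
        assert np.allclose(out.displacement_mm, c.displacement_mm)

    def test_flat_toe_shifts_origin(self):
        d = np.concatenate([np.linspace(0, 0.5, 6), 0.5 + np.linspace(0.1, 5, 50)])
        f = np.concatenate([np.full(6, 10.0), 50.0 + 300.0 * np.linspace(0.1, 5, 50)])
        out = ana.normalize_toe_in(ana.FDCurve(d, f), 50.0)
        assert out.displacement_mm[0] == 0.0
        # origin moved by the 0.5 mm toe plus the first step above threshold
        assert out.force_N[0] >= 50.0
        assert d[np.argmax(f >= 50.0)] == pytest.approx(0.6)

    def test_threshold_above_curve_max_raises(self):
        with pytest.raises(ValueError):
            ana.normalize_toe_in(_line(10.0, 1.0), 1e6)


class TestForceAtCutout:
    def test_interpolation_on_a_line(self):
        assert ana.force_at_cutout(_line(300.0, 7.0)) == pytest.approx(2100.0)

    def test_extrapolation_on_a_truncated_line(self):
        assert ana.force_at_cutout(_line(300.0, 6.5)) == pytest.approx(2100.0)

    def test_affine_curves_exact_under_any_truncation(self):
        for d_max in (3.2, 4.5, 5.9, 6.999):
            d = np.linspace(0.0, d_max, 137)
            c = ana.FDCurve(d, 123.0 + 217.0 * d)
            assert ana.force_at_cutout(c) == pytest.approx(123.0 + 217.0 * 7.0)

    def test_slope_change_uses_post_3mm_segment_only(self):
        # 500 N/mm below 3 mm, 200 N/mm beyond; truncated at 6 mm
        d = np.linspace(0.0, 6.0, 601)
        f = np.where(d < 3.0, 500.0 * d, 1500.0 + 200.0 * (d - 3.0))
        est = ana.force_at_cutout(ana.FDCurve(d, f))
        assert est == pytest.approx(1500.0 + 200.0 * 4.0, rel=1e-6)

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            ana.force_at_cutout(_line(300.0, 2.0))


class TestLinCCC:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = ana.lin_ccc(x, x)
        assert (r.rho_c, r.pearson_rho, r.bias_factor_Cb) == (1.0, 1.0, 1.0)

    def test_location_shift_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        c = 2.0
        r = ana.lin_ccc(x, x + c)
        u = c / x.std()
        assert r.pearson_rho == pytest.approx(1.0)
        assert r.bias_factor_Cb == pytest.approx(2.0 / (2.0 + u**2), abs=1e-12)

    def test_five_point_fixture_matches_defining_formula(self):
        x = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        y = np.array([2.5, 3.9, 6.2, 7.4, 10.6])
        r = ana.lin_ccc(x, y)
        sxy = ((x - x.mean()) * (y - y.mean())).mean()
        direct = 2 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2)
        assert r.rho_c == pytest.approx(direct, abs=1e-12)
        assert r.rho_c == pytest.approx(r.pearson_rho * r.bias_factor_Cb, abs=1e-10)

    def test_ccc_bounded_by_pearson(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30) + 1.0
            r = ana.lin_ccc(x, y)
            assert abs(r.rho_c) <= abs(r.pearson_rho) + 1e-12
            assert 0 < r.bias_factor_Cb <= 1.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            ana.lin_ccc(np.ones(5), np.arange(5.0))


class TestMatchCurves:
    def test_identical_curves_pair_equal(self):
        c = _line(300.0, 7.0)
        fp, fs = ana.match_curves(c, c)
        assert np.allclose(fp, fs)

    def test_linear_curves_pair_exactly(self):
        fp, fs = ana.match_curves(_line(2.0, 5.0), _line(3.0, 6.0), grid_step_mm=0.5)
        assert np.allclose(fs, 1.5 * fp)

    def test_grid_step_larger_than_overlap_raises(self):
        with pytest.raises(ValueError):
            ana.match_curves(_line(1.0, 0.3), _line(1.0, 0.4), grid_step_mm=5.0)

    def test_disjoint_ranges_raise(self):
        a = ana.FDCurve([0.0, 1.0], [0.0, 10.0])
        b = ana.FDCurve([2.0, 3.0], [0.0, 10.0])
        with pytest.raises(ValueError):
            ana.match_curves(a, b)


class TestHeatmap:
    def test_single_particle_counts_zero(self):
        assert ana.heatmap_density(np.zeros((1, 3)))[0] == 0

    def test_two_particles_within_radius(self):
        pts = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        assert np.array_equal(ana.heatmap_density(pts, 6.0), [1, 1])

    def test_matches_all_pairs_brute_force(self, rng):
        pts = rng.uniform(0, 30, size=(1000, 3))
        counts = ana.heatmap_density(pts, 6.0)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        brute = (d2 <= 36.0).sum(axis=1) - 1
        assert np.array_equal(counts, brute)


class TestGroupStats:
    def test_printed_static_groups_give_p_087(self):
        phys = physical_force_table()
        static = phys[phys["mode"] == "static"]
        groups = [
            ana.GroupSummary(r.device, int(r.n), float(r.mean_N), float(r.sd_N))
            for r in static.itertuples()
        ]
        res = ana.group_stats(groups)
        assert res["p"] == pytest.approx(0.87, abs=0.005)

    def test_identical_groups_give_t0_p1(self):
        g = ana.GroupSummary("a", 5, 10.0, 2.0)
        res = ana.group_stats([g, ana.GroupSummary("b", 5, 10.0, 2.0)])
        assert res["t"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_three_point_hand_example(self):
        a = ana.GroupSummary("a", 3, 2.0, 1.0)  # {1,2,3}
        b = ana.GroupSummary("b", 3, 3.0, 1.0)  # {2,3,4}
        res = ana.group_stats([a, b])
        assert res["t"] == pytest.approx(-1.225, abs=1e-3)
        assert res["df"] == 4
        assert res["p"] == pytest.approx(0.288, abs=2e-3)

    def test_four_group_anova_detects_device_difference(self):
        phys = physical_force_table()
        dyn = phys[phys["mode"] == "dynamic"]
        groups = [
            ana.GroupSummary(r.device, int(r.n), float(r.mean_N), float(r.sd_N))
            for r in dyn.itertuples()
        ]
        res = ana.group_stats(groups)
        assert res["test"] == "anova"
        assert res["p"] < 0.001

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ana.group_stats(
                [ana.GroupSummary("a", 3, 1.0, 0.0), ana.GroupSummary("b", 3, 1.0, 0.0)]
            )


class TestDamageSummaryAndReport:
    def test_combined_volume_from_printed_counts(self):
        s = ana.damage_summary(26_490, 3_502, 400.0)
        assert round(s.yielding_volume_mL, 3) == 1.695
        assert round(s.failed_volume_mL, 3) == 0.224
        assert round(s.combined_volume_mL, 3) == 1.919

    def test_all_damage_rows_reproduce(self):
        expected = {
            "DHS": (1.695, 0.224, 1.919),
            "Gamma3": (1.931, 0.267, 2.198),
            "PFNA-II": (2.303, 0.228, 2.531),
            "TFNA": (2.188, 0.208, 2.396),
        }
        for row in damage_count_table().itertuples():
            s = ana.damage_summary(int(row.yielding), int(row.failed),
                                   float(row.resolution_um))
            y, f, c = expected[row.device]
            assert round(s.yielding_volume_mL, 3) == y
            assert round(s.failed_volume_mL, 3) == f
            assert round(s.combined_volume_mL, 3) == c

    def test_percent_volume_vs_reference(self):
        counts = damage_count_table().set_index("device")
        ref = ana.damage_summary(int(counts.loc["DHS", "yielding"]),
                                 int(counts.loc["DHS", "failed"]), 400.0)
        expected = {"Gamma3": 15, "PFNA-II": 32, "TFNA": 25}
        for device, pct in expected.items():
            s = ana.damage_summary(int(counts.loc[device, "yielding"]),
                                   int(counts.loc[device, "failed"]), 400.0,
                                   reference=ref)
            assert round(s.percent_volume_vs_reference) == pct

    def test_zero_counts_give_empty_summary(self):
        s = ana.damage_summary(0, 0, 400.0)
        assert s.combined_volume_mL == 0.0

    def test_simulated_force_percent_vs_reference(self):
        sim = simulated_force_table()
        dyn = sim[sim["mode"] == "dynamic"].set_index("device")["force_N"]
        pct = ana.percent_vs_reference(dyn.to_dict(), "DHS")
        assert round(pct["Gamma3"], 1) == 2.9
        assert round(pct["PFNA-II"]) == 10
        assert round(pct["TFNA"], 1) == 2.6

    def test_sim_vs_physical_percent_errors(self):
        comp = ana.comparison_report(physical_force_table(), simulated_force_table())
        comp = comp.set_index(["device", "mode"])["percent_error"]
        expected = {
            ("DHS", "static"): 0.87,
            ("Gamma3", "static"): 3.28,
            ("DHS", "dynamic"): 3.92,
            ("Gamma3", "dynamic"): 12.00,
            ("PFNA-II", "dynamic"): 8.93,
            ("TFNA", "dynamic"): 3.53,
        }
        for key, val in expected.items():
            assert comp[key] == pytest.approx(val, abs=0.005)

    def test_physical_dynamic_differences_vs_gamma3(self):
        phys = physical_force_table()
        dyn = phys[phys["mode"] == "dynamic"].set_index("device")["mean_N"]
        pct = ana.percent_vs_reference(dyn.astype(float).to_dict(), "Gamma3")
        assert pct["DHS"] == pytest.approx(13.27, abs=0.005)
        assert pct["PFNA-II"] == pytest.approx(10.31, abs=0.005)
        assert pct["TFNA"] == pytest.approx(15.72, abs=0.005)

    def test_identical_sim_and_physical_give_zero_error(self):
        import pandas as pd

        phys = pd.DataFrame(
            [{"device": "X", "mode": "static", "mean_N": 1000.0}]
        )
        sim = pd.DataFrame([{"device": "X", "mode": "static", "force_N": 1000.0}])
        comp = ana.comparison_report(phys, sim)
        assert comp["percent_error"].iloc[0] == 0.0
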