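"""Correlation, regression, ANOVA and Bonferroni post-hoc: closed-form
examples, scipy as the independent oracle, and the classical identities."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from compartquant.containers import CHANNEL_A, CHANNEL_B, CYTOPLASM, NUCLEUS
from compartquant.stats import (AnovaResult, PairedSample, RegressionResult,
                                anova_vs_control_table, bonferroni_vs_control,
                                correlation_table, linear_fit, one_way_anova,
                                pearson_r, significance_stars)


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (6, 4, 2), -1.0),
        ((1, 2, 3, 4), (2, 1, 4, 3), 0.6),   # Σdxdy=3, √(5·5)=5
    ])
    def test_hand_computed_values(self, x, y, expected):
        assert pearson_r(PairedSample(x, y)) == pytest.approx(expected)

    def test_constant_input_flagged_undefined(self):
        assert pearson_r(PairedSample([1, 1, 1], [1, 2, 3])) is None
        assert pearson_r(PairedSample([1, 2, 3], [5, 5, 5])) is None

    def test_matches_brute_force_covariance_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 400))
            x, y = rng.normal(size=n), rng.normal(size=n)
            # brute-force double-loop covariance
            cov = sum((xi - x.mean()) * (yj - y.mean())
                      for xi, yj in zip(x, y)) / n
            oracle = cov / (x.std() * y.std())
            assert pearson_r(PairedSample(x, y)) == pytest.approx(
                oracle, abs=1e-12)

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=40), rng.normal(size=40)
        r0 = pearson_r(PairedSample(x, y))
        assert pearson_r(PairedSample(a * x + b, y)) == pytest.approx(
            r0, abs=1e-9)
        assert pearson_r(PairedSample(-a * x + b, y)) == pytest.approx(
            -r0, abs=1e-9)

    def test_duplication_invariance(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r1 = pearson_r(PairedSample(x, y))
        r2 = pearson_r(PairedSample(np.tile(x, 2), np.tile(y, 2)))
        assert r2 == pytest.approx(r1, abs=1e-12)


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = linear_fit(PairedSample(x, 2 * x + 1))
        assert (res.slope, res.intercept) == pytest.approx((2.0, 1.0))
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_y_flags_r_squared(self):
        res = linear_fit(PairedSample([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared is None

    def test_constant_x_raises(self):
        with pytest.raises(ValueError, match="constant x"):
            linear_fit(PairedSample([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))

    def test_r_squared_equals_pearson_squared(self, rng):
        x = rng.normal(size=50)
        y = 0.8 * x + rng.normal(size=50)
        res = linear_fit(PairedSample(x, y))
        r = pearson_r(PairedSample(x, y))
        assert res.r_squared == pytest.approx(r ** 2, abs=1e-10)

    def test_matches_scipy_linregress(self, rng):
        x, y = rng.normal(size=80), rng.normal(size=80)
        res = linear_fit(PairedSample(x, y))
        ref = sps.linregress(x, y)
        assert res.slope == pytest.approx(ref.slope, abs=1e-10)
        assert res.intercept == pytest.approx(ref.intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(ref.rvalue ** 2, abs=1e-10)


class TestAnova:
    def test_equal_groups_f_zero_p_one(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f == 0.0 and res.p == 1.0

    def test_brute_force_sum_of_squares(self):
        # SSB = 150, MSW = 1, df = (1, 4)
        res = one_way_anova({"a": [1, 2, 3], "b": [11, 12, 13]})
        assert res.f == pytest.approx(150.0)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_all_identical_flagged(self):
        res = one_way_anova({"a": [5, 5], "b": [5, 5]})
        assert res.f is None and res.p is None

    def test_group_too_small_named(self):
        with pytest.raises(ValueError, match="'tiny'"):
            one_way_anova({"a": [1, 2, 3], "tiny": [1]})

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=9)
        res = one_way_anova({"a": a, "b": b})
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert res.f == pytest.approx(t ** 2, abs=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        groups = {k: rng.normal(loc=i, size=rng.integers(5, 30))
                  for i, k in enumerate("abcd")}
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups.values())
        assert res.f == pytest.approx(f, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-12)


class TestBonferroni:
    def test_multiplication_and_cap(self, rng):
        control = rng.normal(size=30)
        groups = {"control": control}
        for i in range(4):
            groups[f"g{i}"] = rng.normal(0.3 * i, 1.0, size=30)
        adj = bonferroni_vs_control(groups, "control")
        for label, vals in groups.items():
            if label == "control":
                continue
            _, raw = sps.ttest_ind(vals, control, equal_var=True)
            assert adj[label] == pytest.approx(min(1.0, 4 * raw))
            assert adj[label] >= raw

    def test_identical_group_adjusts_to_one(self):
        g = {"control": [1.0, 2.0, 3.0], "same": [1.0, 2.0, 3.0]}
        assert bonferroni_vs_control(g, "control")["same"] == 1.0

    def test_missing_control_raises(self):
        with pytest.raises(KeyError):
            bonferroni_vs_control({"a": [1, 2]}, "control")

    def test_stars_convention(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.5) == "ns"
        assert significance_stars(None) == ""


def synthetic_measurements(rho_by_comp: dict[str, float], n: int,
                           rng: np.random.Generator,
                           condition="control") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measurement + N/C tables with known per-compartment A/B correlation."""
    rows = []
    for comp, rho in rho_by_comp.items():
        z0 = rng.standard_normal(n)
        xa = np.sqrt(rho) * z0 + np.sqrt(1 - rho) * rng.standard_normal(n)
        xb = np.sqrt(rho) * z0 + np.sqrt(1 - rho) * rng.standard_normal(n)
        for i in range(n):
            rows.append(("f", i + 1, condition, "rep1", CHANNEL_A, comp,
                         10 + xa[i], 1.0 + xa[i]))
            rows.append(("f", i + 1, condition, "rep1", CHANNEL_B, comp,
                         10 + xb[i], 1.0 + xb[i]))
    m = pd.DataFrame(rows, columns=["field_id", "cell_id", "condition",
                                    "replicate", "channel", "compartment",
                                    "mean_intensity", "normalized"])
    from compartquant.quantify import nc_ratio_table
    return m, nc_ratio_table(m)


class TestCorrelationTable:
    def test_null_correlation_stays_small(self, rng):
        m, nc = synthetic_measurements({NUCLEUS: 0.0, CYTOPLASM: 0.0}, 200, rng)
        grid = correlation_table(m, nc, ["control"])
        sub = grid[grid["quantity"].isin([NUCLEUS, CYTOPLASM])]
        assert (sub["r"].abs() < 0.2).all()

    def test_strong_cytoplasmic_correlation_detected(self, rng):
        m, nc = synthetic_measurements({NUCLEUS: 0.0, CYTOPLASM: 0.9}, 200, rng)
        grid = correlation_table(m, nc, ["control"])
        cyt = grid[grid["quantity"] == CYTOPLASM]["r"].item()
        assert cyt >= 0.8

    def test_duplication_leaves_r_unchanged(self, rng):
        m, nc = synthetic_measurements({NUCLEUS: 0.5, CYTOPLASM: 0.5}, 80, rng)
        g1 = correlation_table(m, nc, ["control"])
        m2 = pd.concat([m, m.assign(field_id="f2")], ignore_index=True)
        nc2 = pd.concat([nc, nc.assign(field_id="f2")], ignore_index=True)
        g2 = correlation_table(m2, nc2, ["control"])
        assert np.allclose(g1["r"], g2["r"], atol=1e-12)
        assert g1["low_n"].all()   # n = 80 < 115 flagged

    def test_anova_table_marks_shifted_condition(self, rng):
        rows = []
        for rep in ("rep1", "rep2", "rep3"):
            for cond, shift in (("control", 0.0), ("hs", 3.0)):
                offset = {"rep1": 0.0, "rep2": 0.02, "rep3": -0.02}[rep]
                for i in range(20):
                    rows.append(("f", i, cond, rep, CHANNEL_A, NUCLEUS,
                                 10.0, 1.0 + shift + offset
                                 + 0.01 * rng.standard_normal()))
        m = pd.DataFrame(rows, columns=["field_id", "cell_id", "condition",
                                        "replicate", "channel", "compartment",
                                        "mean_intensity", "normalized"])
        table = anova_vs_control_table(m, "control", unit="replicate")
        hs = table[table["condition"] == "hs"]
        assert (hs["p_adj_vs_control"] < 0.05).all()
        assert set(hs["stars"]) <= {"*", "**", "***"}
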