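"""Size-energy regressions and percentage summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppiface.group_stats import (class_elec_ratio, regress,
                                 regress_multivariate, regression_table,
                                 summarize, summary_table)
from ppiface.synthetic_data import (LinearRelation, TableSpec,
                                    build_energy_table)


def frame_from_energy(sizes, e, component="vdw"):
    df = pd.DataFrame({"interface_size": sizes})
    for comp in ("vdw", "hbond", "elec"):
        df[f"e_{comp}"] = e if comp == component else -1.0
    df["e_total"] = df[["e_vdw", "e_hbond", "e_elec"]].sum(axis=1)
    return df


class TestRegress:
    def test_perfect_line(self):
        sizes = np.arange(20, 40)
        fit = regress(frame_from_energy(sizes, -2.0 * sizes), component="vdw")
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.p_value < 1e-10
        assert fit.n == 20

    def test_independent_predictor_low_r2(self):
        rng = np.random.default_rng(42)
        sizes = rng.integers(20, 121, size=200)
        e = -rng.permutation(2.0 * sizes)   # breaks any size-energy link
        fit = regress(frame_from_energy(sizes, e), component="vdw")
        assert fit.r2 < 0.05

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(7)
        sizes = rng.integers(20, 121, size=100)
        e = -(1.5 * sizes + rng.normal(0, 20, 100))
        df = frame_from_energy(sizes, e)
        fit = regress(df, component="vdw")
        r, _ = stats.pearsonr(sizes.astype(float), -e)
        assert fit.r2 == pytest.approx(r ** 2, abs=1e-10)

    def test_closed_form_population_r2_recovered(self):
        """Mean fitted r^2 over replicates matches the planted population
        R^2 = slope^2 Var(size) / (slope^2 Var(size) + sigma^2)."""
        fitted = []
        for seed in range(60):
            spec = TableSpec(
                n_complexes=278, group_sizes=None, seed=seed,
                relations={"vdw": LinearRelation(2.0, 30.0, population_r2=0.87),
                           "hbond": LinearRelation(0.4, 8.0, sigma=5.0),
                           "elec": LinearRelation(0.25, 5.0, sigma=5.0)})
            df = build_energy_table(spec)
            fitted.append(regress(df, component="vdw").r2)
        assert np.mean(fitted) == pytest.approx(0.87, abs=0.02)

    def test_row_order_invariance(self):
        df = build_energy_table(TableSpec(n_complexes=50, group_sizes=None,
                                          seed=3))
        shuffled = df.sample(frac=1.0, random_state=1)
        a = regress(df, component="hbond")
        b = regress(shuffled, component="hbond")
        assert a.r2 == pytest.approx(b.r2, abs=1e-12)
        assert a.slope == pytest.approx(b.slope, abs=1e-12)

    def test_energy_rescaling(self):
        """Percent statistics invariant, slopes equivariant, under unit change."""
        df = build_energy_table(TableSpec(n_complexes=80, group_sizes=None,
                                          seed=4))
        scaled = df.copy()
        for col in ("e_vdw", "e_hbond", "e_elec", "e_total"):
            scaled[col] = 4.184 * scaled[col]   # kcal -> kJ
        a, b = regress(df, component="vdw"), regress(scaled, component="vdw")
        assert b.slope == pytest.approx(4.184 * a.slope, rel=1e-9)
        assert b.r2 == pytest.approx(a.r2, abs=1e-12)
        sa, sb = summarize(df)[0], summarize(scaled)[0]
        assert sb.mean_pct_vdw == pytest.approx(sa.mean_pct_vdw, abs=1e-9)

    def test_f_pvalue_matches_permutation_null(self):
        rng = np.random.default_rng(11)
        sizes = rng.integers(20, 121, size=24)
        e = -(0.8 * sizes + rng.normal(0, 35, 24))
        df = frame_from_energy(sizes, e)
        fit = regress(df, component="vdw")
        r_obs = abs(stats.pearsonr(sizes.astype(float), -e)[0])
        n_perm, hits = 2000, 0
        for _ in range(n_perm):
            r = abs(stats.pearsonr(sizes.astype(float),
                                   -rng.permutation(e))[0])
            hits += r >= r_obs
        p_perm = (hits + 1) / (n_perm + 1)
        assert fit.p_value == pytest.approx(p_perm, abs=0.03)

    def test_too_few_points_rejected(self):
        df = frame_from_energy(np.array([20, 30]), np.array([-40.0, -60.0]))
        with pytest.raises(ValueError, match=">= 3"):
            regress(df, component="vdw")

    def test_zero_variance_predictor_rejected(self):
        df = frame_from_energy(np.array([30, 30, 30]),
                               np.array([-40.0, -60.0, -50.0]))
        with pytest.raises(ValueError, match="variance"):
            regress(df, component="vdw")

    def test_caveat_modes(self):
        sizes = np.array([20, 40, 60, 80, 100])
        e_elec = np.array([-10.0, -20.0, 5.0, -40.0, -50.0])  # one repulsive
        df = frame_from_energy(sizes, e_elec, component="elec")
        zero = regress(df, component="elec", caveat="zero")
        excl = regress(df, component="elec", caveat="exclude")
        assert zero.n == 5 and excl.n == 4

    def test_multivariate_fit_runs(self):
        df = build_energy_table(TableSpec(n_complexes=100, group_sizes=None,
                                          seed=8))
        out = regress_multivariate(df)
        assert 0.0 <= out["r2"] <= 1.0
        assert set(out["coef"]) == {"const", "vdw", "hbond", "elec"}


class TestSummaries:
    def test_mean_and_population_sd(self):
        df = pd.DataFrame({"pct_vdw": [70.0, 80.0], "pct_hbond": [20.0, 10.0],
                           "pct_elec": [10.0, 10.0]})
        s = summarize(df)[0]
        assert s.mean_pct_vdw == 75.0 and s.sd_pct_vdw == 5.0
        assert s.mean_pct_hbond == 15.0 and s.sd_pct_hbond == 5.0
        assert s.n == 2

    def test_pct_target_recovery_within_clt_error(self):
        spec = TableSpec(n_complexes=278, group_sizes=None, seed=21,
                         pct_targets={"vdw": (74.93, 11.37),
                                      "hbond": (15.03, 6.54)})
        s = summarize(build_energy_table(spec))[0]
        se = 11.37 / np.sqrt(278)
        assert abs(s.mean_pct_vdw - 74.93) < 3 * se + 0.3  # truncation slack
        assert s.sd_pct_vdw == pytest.approx(11.37, abs=1.5)

    def test_group_means_sum_near_100(self):
        df = build_energy_table(TableSpec(seed=2))
        for s in summarize(df, "function"):
            total = s.mean_pct_vdw + s.mean_pct_hbond + s.mean_pct_elec
            assert total <= 100.0 + 1e-9

    def test_planted_class_ratio(self):
        a = build_energy_table(TableSpec(
            n_complexes=150, group_sizes=None, seed=31, polarity_class="A",
            pct_targets={"vdw": (76.0, 5.0), "hbond": (15.0, 3.0)}))
        b = build_energy_table(TableSpec(
            n_complexes=150, group_sizes=None, seed=32, polarity_class="B",
            pct_targets={"vdw": (71.5, 5.0), "hbond": (15.0, 3.0)}))
        # planted elec means: A = 100-76-15 = 9, B = 100-71.5-15 = 13.5
        df = pd.concat([a, b], ignore_index=True)
        assert class_elec_ratio(df) == pytest.approx(1.5, abs=0.12)

    def test_empty_group_omitted(self):
        df = build_energy_table(TableSpec(n_complexes=20, group_sizes=None,
                                          seed=5))
        df.loc[:, "pct_vdw"] = np.nan
        assert summarize(df) == []

    def test_tables_have_expected_shape(self):
        df = build_energy_table(TableSpec(seed=6))
        reg = regression_table(df, "function")
        assert len(reg) == 6
        assert {"r2_total", "r2_vdw", "r2_hbond", "r2_elec"} <= set(reg.columns)
        summ = summary_table(summarize(df, "rollup"))
        assert set(summ.group) == {"obligatory", "non-obligatory", "immune"}
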