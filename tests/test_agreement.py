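"""Method-comparison statistics: ICC, Passing-Bablok, Lin's CCC, Bland-Altman."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventrivol.agreement import (
    PairedSeries,
    agreement_report,
    bland_altman,
    icc_agreement,
    lin_ccc,
    loa_from_moments,
    passing_bablok,
)


def icc_a_k_oracle(x, y):
    """ICC(A,k) by explicit summation ANOVA (independent of the implementation)."""
    n = len(x)
    k = 2
    grand = (sum(x) + sum(y)) / (n * k)
    rows = [(a + b) / 2 for a, b in zip(x, y)]
    cols = [sum(x) / n, sum(y) / n]
    ss_rows = k * sum((r - grand) ** 2 for r in rows)
    ss_cols = n * sum((c - grand) ** 2 for c in cols)
    ss_tot = sum((v - grand) ** 2 for v in list(x) + list(y))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


def pb_oracle(x, y):
    """Passing-Bablok slope/intercept by literal enumeration of the definition."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] == x[i]:
                continue
            s = (y[j] - y[i]) / (x[j] - x[i])
            if s != -1.0:
                slopes.append(s)
    slopes.sort()
    big_n = len(slopes)
    k_off = sum(1 for s in slopes if s < -1.0)
    if big_n % 2 == 1:
        b = slopes[(big_n + 1) // 2 + k_off - 1]
    else:
        b = 0.5 * (slopes[big_n // 2 + k_off - 1] + slopes[big_n // 2 + k_off])
    a = statistics.median(yi - b * xi for xi, yi in zip(x, y))
    return a, b


class TestICC:
    def test_identity_series_scores_one(self):
        s = PairedSeries(np.arange(1, 11.0), np.arange(1, 11.0))
        assert icc_agreement(s).value == pytest.approx(1.0)

    def test_toy_table_matches_summation_oracle(self):
        x, y = [1, 3, 5, 7], [2, 3, 6, 7]
        s = PairedSeries(x, y)
        assert icc_agreement(s).value == pytest.approx(icc_a_k_oracle(x, y), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x = rng.normal(10, 4, n)
        y = x + rng.normal(0, 1, n)
        s = PairedSeries(x, y)
        assert icc_agreement(s).value == pytest.approx(
            icc_a_k_oracle(list(x), list(y)), abs=1e-10
        )

    def test_high_agreement_simulation(self):
        rng = np.random.default_rng(0)
        subj = rng.normal(0, 10, 200)
        s = PairedSeries(subj + rng.normal(0, 0.5, 200),
                         subj + rng.normal(0, 0.5, 200))
        assert icc_agreement(s).value > 0.99

    def test_matches_pingouin_icc2k_with_ci(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(1)
        subj = rng.normal(20, 8, 60)
        x = subj + rng.normal(0, 1.5, 60)
        y = 1.05 * subj + rng.normal(0.5, 1.5, 60)
        est = icc_agreement(PairedSeries(x, y))
        df = pd.DataFrame({
            "t": np.tile(np.arange(60), 2),
            "r": np.repeat(["a", "b"], 60),
            "v": np.concatenate([x, y]),
        })
        row = pg.intraclass_corr(df, targets="t", raters="r", ratings="v")
        row = row[row.Type == "ICC(A,k)"].iloc[0]
        assert est.value == pytest.approx(row.ICC, abs=1e-10)
        assert est.ci_low == pytest.approx(row.CI95[0], abs=5e-3)
        assert est.ci_high == pytest.approx(row.CI95[1], abs=5e-3)

    def test_degenerate_no_subject_variance_warns(self):
        # identical subjects, pure method offset: no between-subject spread
        with pytest.warns(UserWarning, match="between-subject"):
            est = icc_agreement(PairedSeries([5, 5, 5, 5], [6, 6, 6, 6]))
        assert est.value == 0.0


class TestPassingBablok:
    def test_identity_line(self):
        a, b, _ = passing_bablok(PairedSeries([1, 2, 3, 4.0], [1, 2, 3, 4.0]))
        assert b.value == 1.0 and a.value == 0.0

    def test_hand_enumerated_three_points(self):
        a, b, _ = passing_bablok(PairedSeries([1, 2, 3.0], [1, 2, 4.0]))
        assert b.value == 1.5  # slopes {1, 1.5, 2}
        assert a.value == -0.5  # median(-0.5, -1, -0.5)

    def test_exact_linear_map(self):
        x = np.arange(1, 12.0)
        a, b, _ = passing_bablok(PairedSeries(x, 2 * x + 3))
        assert b.value == pytest.approx(2.0)
        assert a.value == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 31))
        x = rng.uniform(1, 50, n)
        y = 0.9 * x + rng.normal(0, 2, n)
        a, b, _ = passing_bablok(PairedSeries(x, y))
        oa, ob = pb_oracle(list(x), list(y))
        assert b.value == pytest.approx(ob, abs=1e-12)
        assert a.value == pytest.approx(oa, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 10, 20)
        y = 1.1 * x + rng.normal(0, 0.5, 20)
        a1, b1, _ = passing_bablok(PairedSeries(x, y))
        a2, b2, _ = passing_bablok(PairedSeries(3 * x, 3 * y))
        assert b2.value == pytest.approx(b1.value, abs=1e-12)
        assert a2.value == pytest.approx(3 * a1.value, abs=1e-12)

    def test_identical_x_rejected_and_weak_correlation_flagged(self):
        with pytest.raises(ValueError):
            passing_bablok(PairedSeries([2, 2, 2.0], [1, 2, 3.0]))
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 30)
        _, _, flags = passing_bablok(PairedSeries(x, rng.uniform(0, 10, 30)))
        assert any("correlation" in f for f in flags)

    @pytest.mark.parametrize("a_true", [0.0, 0.5])
    @pytest.mark.parametrize("b_true", [0.9, 1.0, 1.1])
    def test_ci_covers_truth_in_most_runs(self, a_true, b_true):
        # noise split across both arms: the estimator assumes errors in
        # both variables, so y-only noise would bias the slope upward
        covered = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            t = rng.uniform(5, 30, 200)
            sd = 0.1 * t.mean() / np.sqrt(2)
            x = t + rng.normal(0, sd, 200)
            y = a_true + b_true * t + rng.normal(0, sd, 200)
            ia, ib, _ = passing_bablok(PairedSeries(x, y))
            if ia.ci_low <= a_true <= ia.ci_high and ib.ci_low <= b_true <= ib.ci_high:
                covered += 1
        assert covered >= 2


class TestLinCCC:
    def test_identity_scores_one(self):
        assert lin_ccc(PairedSeries([1, 2, 3.0], [1, 2, 3.0])) == pytest.approx(1.0)

    def test_perfect_reversal_scores_minus_one(self):
        x = np.array([-2, -1, 0, 1, 2.0])
        assert lin_ccc(PairedSeries(x, -x)) == pytest.approx(-1.0)

    def test_hand_moment_oracle(self):
        x = np.array([1, 2, 3, 4.0])
        y = np.array([2, 2, 3, 5.0])
        expected = (2 * ((x - x.mean()) * (y - y.mean())).mean()
                    / (x.var() + y.var() + (x.mean() - y.mean()) ** 2))
        assert lin_ccc(PairedSeries(x, y)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_exceeds_pearson_in_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(10, 3, 50)
        y = 0.8 * x + rng.normal(2, 1, 50)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(lin_ccc(PairedSeries(x, y))) <= abs(r) + 1e-12


class TestBlandAltman:
    def test_printed_moments_reproduce_limits(self):
        lo, hi = loa_from_moments(0.61, 2.28, 230)
        assert round(lo.value, 2) == -3.86
        assert round(hi.value, 2) == 5.08
        assert round(hi.ci_low, 2) == 4.57
        assert round(hi.ci_high, 2) == 5.59

    def test_loa_se_formula(self):
        lo, hi = loa_from_moments(0.0, 1.0, 12)
        se = 1.0 * math.sqrt(3 / 12)
        assert hi.ci_high - hi.value == pytest.approx(1.96 * se, abs=1e-12)

    def test_identical_series(self):
        x = np.array([1, 2, 3, 4, 5.0])
        ba = bland_altman(PairedSeries(x, x))
        assert ba.bias == 0.0 and ba.sd == 0.0
        assert ba.n_above == 0 and ba.n_below == 0 and ba.pct_within == 100.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(3, 60))
    def test_tallies_partition_n(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(10, 3, n)
        y = x + rng.normal(0.5, 1, n)
        ba = bland_altman(PairedSeries(x, y))
        assert ba.n_above + ba.n_below <= n
        assert ba.pct_within == pytest.approx(100 * (n - ba.n_above - ba.n_below) / n)
        if ba.sd > 0:
            assert ba.loa_lower.value < ba.bias < ba.loa_upper.value


class TestAgreementReport:
    def test_near_identical_simulated_series(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 30, 100)
        y = x + rng.normal(0, 0.1, 100)
        rep = agreement_report(PairedSeries(x, y))
        assert rep.icc.value > 0.99
        assert abs(rep.pb_intercept.value) < 0.1
        assert abs(rep.pb_slope.value - 1) < 0.05
        assert rep.ccc > 0.99

    def test_identical_series_perfect_everywhere(self):
        x = np.arange(1, 21.0)
        rep = agreement_report(PairedSeries(x, x))
        assert rep.icc.value == pytest.approx(1.0)
        assert rep.pb_slope.value == 1.0 and rep.pb_intercept.value == 0.0
        assert rep.ccc == pytest.approx(1.0)
        assert rep.bland_altman.sd == 0.0

    def test_subgroups_partition_global_n(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 20, 24)
        y = x + rng.normal(0, 0.5, 24)
        keys = [("p", i, "left" if i % 2 else "right") for i in range(24)]
        rep = agreement_report(PairedSeries(x, y, keys=keys))
        assert sum(s["n"] for s in rep.subgroups.values()) == rep.n
        assert set(rep.subgroups) == {"left", "right"}

    def test_small_subgroup_omitted_with_note(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 20, 10)
        y = x + rng.normal(0, 0.5, 10)
        keys = [("p", i, "left" if i < 8 else "right") for i in range(10)]
        rep = agreement_report(PairedSeries(x, y, keys=keys))
        assert "right" not in rep.subgroups
        assert any("right" in f for f in rep.flags)

    def test_report_serialises_to_json_and_text(self):
        x = np.arange(1, 11.0)
        rep = agreement_report(PairedSeries(x, x + 0.1))
        import json

        parsed = json.loads(rep.to_json())
        assert parsed["n"] == 10
        assert "ICC" in rep.summary()
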