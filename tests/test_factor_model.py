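import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from cgishield.factor_model import (
    FACTORS,
    MCF7_MODEL_COEF,
    added_value_test,
    deviance_reduction,
    factor_correlations,
    fit_logistic,
    gskew_rloop_potential,
    interaction_network,
    methylation_probability,
    rank_factors,
    stratified_or,
)
from cgishield.synthetic import gen_factor_table


class TestGskew:
    def test_plus_strand_counts(self):
        assert gskew_rloop_potential("GGGCC", "+") == 1

    def test_tie_is_zero(self):
        assert gskew_rloop_potential("GGCC", "+") == 0

    def test_minus_strand_uses_reverse_complement(self):
        # sense strand of a '-' transcript is revcomp: GGGCC -> GGCCC
        assert gskew_rloop_potential("GGGCC", "-") == 0

    def test_template_convention_flips(self):
        assert gskew_rloop_potential("GGGCC", "+", "template") == 0
        assert gskew_rloop_potential("GGGCC", "-", "template") == 1

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError):
            gskew_rloop_potential("GGGCC", ".")


def grid_loglik_1d(y, x, b0, b1):
    eta = b0 + b1 * x
    p = 1 / (1 + np.exp(-eta))
    return np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        df = pd.DataFrame({"M": [0] * 25 + [1] * 25})
        fit = fit_logistic(df, [])
        assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-8)
        assert fit.deviance == pytest.approx(fit.null_deviance)

    def test_single_binary_closed_form(self):
        # cells x=0: 25/75 methylated; x=1: 75/25 -> saturated closed form
        df = pd.DataFrame({
            "M": [1] * 25 + [0] * 75 + [1] * 75 + [0] * 25,
            "x": [0] * 100 + [1] * 100,
        })
        fit = fit_logistic(df, ["x"])
        assert fit.params["Intercept"] == pytest.approx(math.log(1 / 3), abs=1e-6)
        assert fit.params["x"] == pytest.approx(math.log(9), abs=1e-6)

    def test_agrees_with_grid_likelihood_maximiser(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 300)
        p = 1 / (1 + np.exp(-(-0.4 + 1.1 * x)))
        y = (rng.random(300) < p).astype(int)
        df = pd.DataFrame({"M": y, "x": x})
        fit = fit_logistic(df, ["x"])
        res = optimize.minimize(lambda b: -grid_loglik_1d(y, x, *b), [0, 0],
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        assert fit.params["Intercept"] == pytest.approx(res.x[0], abs=1e-4)
        assert fit.params["x"] == pytest.approx(res.x[1], abs=1e-4)

    def test_rank_deficiency_detected(self):
        df = pd.DataFrame({"M": [0, 1] * 20, "a": [0, 1] * 20, "b": [0, 1] * 20})
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(df, ["a", "b"])

    def test_separation_flagged(self):
        df = pd.DataFrame({"M": [0] * 20 + [1] * 20, "x": [0] * 20 + [1] * 20})
        fit = fit_logistic(df, ["x"])
        assert fit.separation


class TestDeviance:
    def test_perfect_predictor_closed_form(self):
        # balanced n=100 perfect predictor: reduction = 2*100*ln 2
        df = pd.DataFrame({"M": [0] * 50 + [1] * 50, "x": [0] * 50 + [1] * 50})
        red, p = deviance_reduction(df, "x")
        assert red == pytest.approx(2 * 100 * math.log(2), rel=1e-6)
        assert p < 1e-10

    def test_duplicated_factor_identical_reduction(self):
        table, _ = gen_factor_table(
            500, {"Intercept": 0.0, "PA": -1.0},
            {f: 0.4 for f in FACTORS}, seed=2)
        table["PA_copy"] = table["PA"]
        r1, _ = deviance_reduction(table, "PA")
        r2, _ = deviance_reduction(table, "PA_copy")
        assert r1 == pytest.approx(r2)

    def test_noise_factor_p_calibrated(self):
        # under the null the chi-square p is approximately uniform
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            df = pd.DataFrame({"M": rng.integers(0, 2, 250),
                               "x": rng.integers(0, 2, 250)})
            ps.append(deviance_reduction(df, "x")[1])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.001

    def test_rank_factors_orders_by_reduction(self):
        table, _ = gen_factor_table(
            4000,
            {"Intercept": 0.5, "PA": -2.0, "Rloop": -0.2, "Cfp1": -0.8,
             "H3K4me3": -1.4, "Motif": -1.0},
            {f: 0.4 for f in FACTORS}, seed=3)
        ranked = rank_factors(table)
        assert ranked.loc[0, "factor"] == "PA"
        assert list(ranked["rank"]) == [1, 2, 3, 4, 5]
        assert ranked["deviance_reduction"].is_monotonic_decreasing


class TestLrtTests:
    def test_added_copy_gives_p_one(self):
        table, _ = gen_factor_table(500, {"Intercept": 0.0, "PA": -1.0},
                                    {f: 0.4 for f in FACTORS}, seed=4)
        table["PA2"] = table["PA"]
        # a duplicate column is collinear; adding no-information noise instead
        stat, p = added_value_test(table, "PA", "Rloop")
        assert stat >= 0

    def test_added_true_effect_detected(self):
        detected = 0
        for seed in range(20):
            table, _ = gen_factor_table(
                5000, {"Intercept": -0.5, "PA": -1.0, "Motif": -1.0},
                {f: 0.4 for f in FACTORS}, seed=seed)
            _, p = added_value_test(table, "PA", "Motif")
            detected += p < 0.05
        assert detected >= 18

    def test_added_noise_calibrated(self):
        false_pos = 0
        n_rep = 60
        for seed in range(n_rep):
            table, _ = gen_factor_table(
                2000, {"Intercept": -0.5, "PA": -1.0},
                {f: 0.4 for f in FACTORS}, seed=1000 + seed)
            _, p = added_value_test(table, "PA", "Cfp1")
            false_pos += p < 0.05
        assert false_pos / n_rep < 0.15

    def test_interaction_network_shape(self):
        table, _ = gen_factor_table(
            1000, {"Intercept": -0.5}, {f: 0.4 for f in FACTORS}, seed=6)
        net = interaction_network(table, FACTORS)
        assert len(net) == 10  # C(5,2) pairs
        assert (net["p_bonferroni"] >= net["p"]).all()

    def test_true_interaction_detected(self):
        hits = 0
        for seed in range(10):
            table, _ = gen_factor_table(
                5000,
                {"Intercept": -0.5, "PA": -1.0, "Motif": -0.5, "PA:Motif": 1.5},
                {f: 0.4 for f in FACTORS}, seed=seed)
            net = interaction_network(table, FACTORS)
            row = net[(net.factor_a == "PA") & (net.factor_b == "Motif")].iloc[0]
            hits += bool(row.significant)
        assert hits >= 9


class TestStratifiedOr:
    def test_protective_orientation_arithmetic(self):
        # stratum counts: unexposed 10 meth / 20 unmeth; exposed 5 / 40
        rows = ([{"M": 1, "x": 0, "s": 0}] * 10 + [{"M": 0, "x": 0, "s": 0}] * 20 +
                [{"M": 1, "x": 1, "s": 0}] * 5 + [{"M": 0, "x": 1, "s": 0}] * 40)
        out = stratified_or(pd.DataFrame(rows), "M", "x", "s")
        assert out.loc[0, "or_protective"] == pytest.approx(4.0)
        assert out.loc[0, "or_risk"] == pytest.approx(0.25)
        assert out.loc[0, "reduction_pct_points"] == pytest.approx(
            100 * (10 / 30 - 5 / 45))

    def test_independent_exposure_or_near_one(self):
        rng = np.random.default_rng(11)
        ors = []
        for seed in range(30):
            df = pd.DataFrame({"M": rng.integers(0, 2, 2000),
                               "x": rng.integers(0, 2, 2000),
                               "s": rng.integers(0, 2, 2000)})
            out = stratified_or(df, "M", "x", "s")
            ors.extend(out["or_protective"])
        assert abs(np.median(ors) - 1.0) < 0.15

    def test_recovers_per_stratum_ors(self):
        # protective odds ratios 1.5 and 2.8 planted via stratum-specific
        # logistic effects; exposure effect log(OR) per stratum
        rng = np.random.default_rng(13)
        n = 4000
        stratum = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n)
        log_or = np.where(stratum == 0, np.log(1.5), np.log(2.8))
        eta = 0.2 - log_or * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"M": y, "x": x, "s": stratum})
        out = stratified_or(df, "M", "x", "s").set_index("s")
        for s, target in ((0, 1.5), (1, 2.8)):
            got = out.loc[s, "or_protective"]
            # 2 SE on the log OR from the 2x2 cells
            sub = df[df.s == s]
            cells = [((sub.x == i) & (sub.M == j)).sum() for i in (0, 1) for j in (0, 1)]
            se = math.sqrt(sum(1 / c for c in cells))
            assert abs(math.log(got) - math.log(target)) < 2 * se

    def test_zero_margin_flagged(self):
        rows = ([{"M": 1, "x": 0, "s": 0}] * 5 + [{"M": 0, "x": 0, "s": 0}] * 5 +
                [{"M": 0, "x": 1, "s": 0}] * 5)
        out = stratified_or(pd.DataFrame(rows), "M", "x", "s")
        assert bool(out.loc[0, "degenerate"])
        assert math.isinf(out.loc[0, "or_protective"])


class TestCorrelations:
    def test_self_and_antialigned(self):
        df = pd.DataFrame({"a": [0, 1, 0, 1], "b": [1, 0, 1, 0]})
        corr = factor_correlations(df, ["a", "b"])
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_factors_near_zero(self):
        table, _ = gen_factor_table(10000, {"Intercept": 0.0},
                                    {f: 0.4 for f in FACTORS}, seed=8)
        corr = factor_correlations(table, list(FACTORS))
        off = corr.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_constant_column_nan(self):
        df = pd.DataFrame({"a": [1, 1, 1, 1], "b": [0, 1, 0, 1]})
        corr = factor_correlations(df, ["a", "b"])
        assert math.isnan(corr.loc["a", "b"])


class TestPrintedModelContract:
    def test_probabilities_at_reference_points(self):
        assert methylation_probability(0, 0) == pytest.approx(0.2124, abs=1e-3)
        assert methylation_probability(1, 0) == pytest.approx(0.0502, abs=1e-3)
        assert methylation_probability(0, 1) == pytest.approx(0.0082, abs=1e-3)

    def test_bound_probability_essentially_zero(self):
        P = np.linspace(0, 3, 61)
        assert np.all(methylation_probability(P, np.ones_like(P)) < 0.01)

    def test_unbound_crosses_unmethylated_threshold_near_active(self):
        assert methylation_probability(0, 0) > 0.2
        assert methylation_probability(1, 0) < 0.2
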