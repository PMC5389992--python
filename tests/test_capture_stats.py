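import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlcapture import (
    capture_learning_report,
    condition_means,
    exclude_chance_performers,
    linear_trend,
    pairwise_bonferroni,
    partial_spearman,
    rm_anova_oneway,
    spearman,
)

from .oracles import linear_contrast_F, partial_corr_residualized, rm_anova_ss


def _learning_with_rate(n_better: int, n_total: int = 300) -> pd.DataFrame:
    rows = []
    for t in range(n_total):
        chosen = "A" if t < n_better else "B"
        rows.append(
            {
                "subject_id": "s01",
                "trial_index": t + 1,
                "pair": "AB",
                "chosen": chosen,
                "unchosen": "B" if chosen == "A" else "A",
                "reward": 1,
                "omitted": False,
            }
        )
    return pd.DataFrame(rows)


class TestExclusion:
    @pytest.mark.parametrize(
        "n_better, retained",
        [(150, False), (243, True), (300, True)],
    )
    def test_binomial_rule(self, n_better, retained):
        keep, report = exclude_chance_performers(_learning_with_rate(n_better))
        assert (len(keep) == 1) is retained
        assert report.loc[0, "n_better"] == n_better


def _capture_rows(sid, cond_rts, correct=True):
    rows = []
    for cond, rts in cond_rts.items():
        for i, rt in enumerate(rts):
            rows.append(
                {
                    "subject_id": sid,
                    "trial_index": len(rows) + 1,
                    "condition": cond,
                    "correct": correct if not isinstance(correct, dict)
                    else correct.get((cond, i), True),
                    "rt_ms": rt,
                }
            )
    return rows


class TestConditionMeans:
    def test_slowing_scores_by_hand(self):
        cap = pd.DataFrame(
            _capture_rows(
                "s01",
                {"high": [700, 720], "none": [650, 670], "low": [660, 680]},
            )
        )
        summary = condition_means(cap)
        row = summary.iloc[0]
        assert row["slowing_high"] == pytest.approx(50.0)
        assert row["slowing_low"] == pytest.approx(10.0)
        assert row["slowing_diff"] == pytest.approx(40.0)

    def test_identical_rts_zero_slowing(self):
        cap = pd.DataFrame(
            _capture_rows("s01", {c: [600, 600] for c in ("high", "low", "none")})
        )
        row = condition_means(cap).iloc[0]
        assert row["slowing_high"] == 0 and row["slowing_diff"] == 0

    def test_incorrect_trials_excluded_from_rt_but_not_accuracy(self):
        cap = pd.DataFrame(
            _capture_rows(
                "s01",
                {"high": [700, 9999], "none": [650, 650], "low": [660, 660]},
                correct={("high", 1): False},
            )
        )
        row = condition_means(cap).iloc[0]
        assert row["mean_rt_high"] == pytest.approx(700.0)
        assert row["accuracy_high"] == pytest.approx(0.5)

    def test_missing_condition_names_subject(self):
        cap = pd.DataFrame(
            _capture_rows("s07", {"high": [700], "none": [650]})
        )
        cap = cap[cap["condition"] != "low"]
        with pytest.raises(ValueError, match="s07"):
            condition_means(cap)


class TestRmAnova:
    def test_no_condition_effect_gives_zero_F(self):
        table = pd.DataFrame({"none": [1.0, 2.0, 3.0], "low": [1.0, 2.0, 3.0],
                              "high": [1.0, 2.0, 3.0]})
        res = rm_anova_oneway(table)
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_ss_oracle_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            k = int(rng.integers(2, 5))
            table = pd.DataFrame(rng.normal(size=(n, k)))
            res = rm_anova_oneway(table)
            F, df1, df2, eta = rm_anova_ss(table)
            assert res.F == pytest.approx(F, abs=1e-9)
            assert (res.df_effect, res.df_error) == (df1, df2)
            assert res.partial_eta_sq == pytest.approx(eta, abs=1e-9)

    def test_study_sized_degrees_of_freedom(self):
        table = pd.DataFrame(np.random.default_rng(32).normal(size=(20, 3)))
        res = rm_anova_oneway(table)
        assert (res.df_effect, res.df_error) == (2, 38)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(33)
        wide = pd.DataFrame(
            rng.normal(size=(10, 3)), columns=["none", "low", "high"]
        )
        long = wide.reset_index().melt(
            id_vars="index", var_name="cond", value_name="rt"
        )
        theirs = pg.rm_anova(
            data=long, dv="rt", within="cond", subject="index", detailed=False
        )
        res = rm_anova_oneway(wide)
        assert res.F == pytest.approx(float(theirs["F"].iloc[0]), abs=1e-6)
        assert res.p == pytest.approx(float(theirs["p_unc"].iloc[0]), abs=1e-6)

    def test_incomplete_table_rejected(self):
        table = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            rm_anova_oneway(table)


class TestLinearTrend:
    def test_perfectly_linear_noise_free_effect(self):
        table = pd.DataFrame(
            {"none": [600.0] * 5, "low": [610.0] * 5, "high": [620.0] * 5}
        )
        res = linear_trend(table)
        assert res.F == np.inf and res.p == 0.0

    def test_no_effect_gives_zero(self):
        table = pd.DataFrame({c: [600.0, 650.0] for c in ("none", "low", "high")})
        res = linear_trend(table)
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_contrast_oracle(self):
        rng = np.random.default_rng(34)
        for _ in range(100):
            table = pd.DataFrame(
                rng.normal(size=(8, 3)), columns=["none", "low", "high"]
            )
            res = linear_trend(table)
            assert res.F == pytest.approx(
                linear_contrast_F(table[["none", "low", "high"]]), abs=1e-9
            )
            assert (res.df_effect, res.df_error) == (1, 7)

    def test_study_sized_degrees_of_freedom(self):
        table = pd.DataFrame(
            np.random.default_rng(35).normal(size=(20, 3)),
            columns=["none", "low", "high"],
        )
        assert (linear_trend(table).df_effect, linear_trend(table).df_error) == (1, 19)

    def test_wrong_level_count_rejected(self):
        with pytest.raises(ValueError):
            linear_trend(
                pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0]}),
                order=("a", "b"),
            )


class TestPairwiseBonferroni:
    def test_identical_columns(self):
        table = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in ("none", "low", "high")})
        res = pairwise_bonferroni(table)
        assert (res["t"] == 0).all()
        assert (res["p_bonferroni"] == 1.0).all()

    def test_hand_computed_t(self):
        # differences 10, 12, 8, 10: mean 10, sd 1.633, t = 12.247, df 3
        table = pd.DataFrame(
            {"a": [110.0, 112.0, 108.0, 110.0], "b": [100.0, 100.0, 100.0, 100.0]}
        )
        res = pairwise_bonferroni(table)
        row = res.iloc[0]
        assert row["t"] == pytest.approx(12.247, abs=1e-3)
        assert row["df"] == 3

    def test_correction_never_below_raw(self):
        rng = np.random.default_rng(36)
        table = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        res = pairwise_bonferroni(table)
        assert (res["p_bonferroni"] >= res["p_raw"]).all()
        assert (res["p_bonferroni"] <= 1.0).all()


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_hand_rank_arithmetic(self):
        # ranks of y are y itself; sum d^2 = 8 -> 1 - 48/120
        rho, _ = spearman([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert rho == pytest.approx(0.6, abs=1e-12)

    def test_symmetry_and_length_validation(self):
        x = [1, 4, 2, 8, 5, 7]
        y = [2, 1, 4, 3, 6, 5]
        assert spearman(x, y) == spearman(y, x)
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])

    @given(
        scale=st.floats(0.1, 10),
        shift=st.floats(-5, 5),
        cube=st.booleans(),
    )
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_monotone_transforms(self, scale, shift, cube):
        rng = np.random.default_rng(37)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        fx = scale * x + shift
        if cube:
            fx = fx**3
        assert spearman(fx, y)[0] == pytest.approx(spearman(x, y)[0], abs=1e-12)


class TestPartialSpearman:
    def test_identical_vectors_with_irrelevant_control(self):
        rng = np.random.default_rng(38)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        rho, p = partial_spearman(x, x, z)
        assert rho == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-6

    def test_control_explains_shared_variance(self):
        rng = np.random.default_rng(39)
        z = rng.normal(size=200)
        y = z + 0.3 * rng.normal(size=200)
        x = rng.normal(size=200)
        rho, _ = partial_spearman(x, y, z)
        assert abs(rho) < 0.2

    def test_formula_equals_residualize_then_correlate(self):
        rng = np.random.default_rng(40)
        for _ in range(50):
            x, y, z = rng.normal(size=(3, 25))
            y = y + 0.5 * z
            x = x + 0.3 * z
            rho, _ = partial_spearman(x, y, z)
            assert rho == pytest.approx(
                partial_corr_residualized(x, y, z), abs=1e-10
            )

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(41)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "z"])
        rho, p = partial_spearman(df["x"], df["y"], df["z"])
        theirs = pg.partial_corr(
            data=df, x="x", y="y", covar="z", method="spearman"
        )
        assert rho == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(theirs["p_val"].iloc[0]), abs=1e-6)

    def test_constant_control_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.arange(6.0), np.arange(6.0), np.ones(6))


class TestCaptureLearningReport:
    def _inputs(self, n=20, coupled=True, seed=42):
        rng = np.random.default_rng(seed)
        alpha_high = rng.uniform(0.02, 0.5, n)
        alpha_low = rng.uniform(0.02, 0.5, n)
        noise = rng.normal(0, 5, n)
        slowing_high = (400 * alpha_high if coupled else np.zeros(n)) + noise
        slowing_low = 100 * alpha_low + rng.normal(0, 5, n)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i:02d}" for i in range(n)],
                "alpha_high": alpha_high,
                "alpha_low": alpha_low,
                "alpha_diff": alpha_high - alpha_low,
                "slowing_high": slowing_high,
                "slowing_low": slowing_low,
                "slowing_diff": slowing_high - slowing_low,
                "ab_accuracy": rng.uniform(0.5, 1.0, n),
                "final_q_a": rng.uniform(0.5, 1.0, n),
            }
        )

    def test_planted_coupling_detected(self):
        report = capture_learning_report(self._inputs(coupled=True))
        battery = report["slowing_high_vs_alpha_high_partial"]
        assert battery["rho_pcor"] > 0.6
        assert battery["p"] < 0.01
        assert "slowing_diff_vs_alpha_diff_loo" in report
        assert "slowing_high_vs_ab_accuracy" in report

    def test_null_coupling_not_strongly_detected(self):
        report = capture_learning_report(self._inputs(coupled=False, seed=43))
        assert abs(report["slowing_high_vs_alpha_high_partial"]["rho_pcor"]) < 0.5

    def test_constant_slowing_flagged_degenerate(self):
        inputs = self._inputs()
        inputs["slowing_high"] = 10.0
        report = capture_learning_report(inputs)
        assert "degenerate" in report

    def test_misaligned_inputs_rejected(self):
        inputs = self._inputs().drop(columns=["alpha_diff"])
        with pytest.raises(ValueError, match="alpha_diff"):
            capture_learning_report(inputs)
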