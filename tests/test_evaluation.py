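import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vespasam import evaluation as ev


class TestStandardizedMae:
    def test_identity_is_zero(self):
        obs = np.array([1.0, 5.0, 9.0])
        assert ev.standardized_mae(obs, obs) == 0.0

    def test_hand_computed_value(self):
        # MAE = 1, mean obs = 2 -> 0.5
        assert ev.standardized_mae([2, 3, 4], [1, 2, 3]) == pytest.approx(0.5)

    @given(c=st.floats(0.01, 100))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        obs = rng.uniform(1, 10, 15)
        pred = obs + rng.normal(0, 1, 15)
        base = ev.standardized_mae(pred, obs)
        assert ev.standardized_mae(c * pred, c * obs) == pytest.approx(base, rel=1e-9)

    def test_zero_mean_observation_rejected(self):
        with pytest.raises(ValueError):
            ev.standardized_mae([1.0, 2.0], [0.0, 0.0])


class TestDiscrimination:
    def test_perfect_calibration(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r, slope = ev.discrimination(x, x)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_linear_case(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        r, slope = ev.discrimination(pred, 2 * pred)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pred = rng.uniform(0, 50, 20)
            obs = rng.uniform(0, 50, 20)
            r, slope = ev.discrimination(pred, obs)
            xc = pred - pred.mean()
            yc = obs - obs.mean()
            slope_oracle = np.sum(xc * yc) / np.sum(xc * xc)
            r_oracle = np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2))
            assert slope == pytest.approx(slope_oracle, rel=1e-12)
            assert r == pytest.approx(r_oracle, rel=1e-12)

    def test_slope_convention_flag(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        obs = 2 * pred
        _, cal = ev.discrimination(pred, obs, slope_convention="obs_on_pred")
        _, rev = ev.discrimination(pred, obs, slope_convention="pred_on_obs")
        assert cal == pytest.approx(2.0)
        assert rev == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ev.discrimination([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def brute_force_auc(scores, labels):
    """Pairwise oracle: average over all (positive, negative) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert ev.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert ev.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_tie_case_matches_pairwise_oracle(self):
        scores = [0.1, 0.4, 0.4, 0.8, 0.4, 0.9, 0.2, 0.8, 0.6, 0.4, 0.3, 0.7]
        labels = [0, 0, 1, 1, 0, 1, 0, 0, 1, 1, 0, 1]
        assert ev.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), rel=1e-12
        )

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(6, 25))
            scores = rng.choice(np.linspace(0, 1, 8), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert ev.auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), rel=1e-12
            )

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        base = ev.auc(scores, labels)
        assert ev.auc(np.exp(3 * scores), labels) == pytest.approx(base, rel=1e-12)
        assert ev.auc(np.log(scores + 0.01), labels) == pytest.approx(base, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.auc([0.1, 0.2], [1, 1])


# Published per-variant mean metrics of the four abundance variants
# (accuracy, Pearson r, slope) and the two occurrence variants' AUC,
# used as a fixed input to the selection rules.
REPORTED_SAM_SUMMARY = pd.DataFrame(
    {
        "variant": ["rf_raw", "rf_log1p", "gbm_raw", "gbm_log1p"],
        "accuracy": [0.956, 0.537, 1.114, 0.599],
        "pearson_r": [0.271, 0.470, 0.158, 0.344],
        "slope": [0.557, 0.867, 0.234, 0.477],
    }
)


class TestRankSelect:
    def test_reported_summary_selects_rf_log(self):
        assert ev.rank_select(REPORTED_SAM_SUMMARY) == "rf_log1p"

    def test_reported_auc_selects_rf_sdm(self):
        aucs = pd.Series({"sdm_rf": 0.732, "sdm_gbm": 0.649})
        assert ev.select_best_sdm(aucs) == "sdm_rf"

    def test_dominant_variant_always_wins(self):
        summary = pd.DataFrame(
            {
                "variant": ["a", "b", "c"],
                "accuracy": [0.2, 0.9, 1.5],
                "pearson_r": [0.9, 0.5, 0.1],
                "slope": [1.02, 0.5, 3.0],
            }
        )
        assert ev.rank_select(summary) == "a"

    def test_invariant_to_row_order(self):
        shuffled = REPORTED_SAM_SUMMARY.sample(frac=1.0, random_state=3).reset_index(
            drop=True
        )
        assert ev.rank_select(shuffled) == "rf_log1p"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ev.rank_select(REPORTED_SAM_SUMMARY.iloc[0:0])


def brute_force_kruskal_h(groups):
    """Hand-rank oracle with tie correction."""
    values = np.concatenate(groups)
    n = len(values)
    ranks = stats.rankdata(values)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalDunn:
    def test_h_matches_hand_rank_oracle(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([11.0, 12.0, 13.0])]
        values = np.concatenate(groups)
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        res = ev.kruskal_dunn(values, labels)
        assert res["H"] == pytest.approx(brute_force_kruskal_h(groups), rel=1e-10)
        assert res["df"] == 1

    def test_h_oracle_with_ties_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            sizes = rng.integers(4, 10, size=3)
            groups = [rng.integers(0, 6, size=s).astype(float) for s in sizes]
            values = np.concatenate(groups)
            labels = np.concatenate(
                [np.full(s, f"g{i}") for i, s in enumerate(sizes)]
            )
            if np.ptp(values) == 0:
                continue
            res = ev.kruskal_dunn(values, labels)
            assert res["H"] == pytest.approx(brute_force_kruskal_h(groups), rel=1e-9)

    def test_no_variation_gives_zero_h(self):
        res = ev.kruskal_dunn([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert res["H"] == 0.0
        letters = set(res["letters"].values())
        assert len(letters) == 1  # all groups share one letter

    def test_separated_groups_all_distinct_letters(self):
        values = np.concatenate(
            [np.arange(10), np.arange(100, 110), np.arange(1000, 1010)]
        ).astype(float)
        labels = np.array(["lo"] * 10 + ["mid"] * 10 + ["hi"] * 10)
        res = ev.kruskal_dunn(values, labels)
        letters = res["letters"]
        assert len({letters["lo"], letters["mid"], letters["hi"]}) == 3

    def test_null_rejection_rate_controlled(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            values = rng.standard_normal(60)
            labels = np.repeat(["a", "b", "c"], 20)
            res = ev.kruskal_dunn(values, labels)
            rejections += res["p"] < 0.05
        assert rejections <= 3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ev.kruskal_dunn([1.0, 2.0], ["a", "a"])

    def test_bonferroni_adjustment_capped(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal(40)
        labels = np.repeat(["a", "b", "c", "d"], 10)
        res = ev.kruskal_dunn(values, labels)
        assert len(res["pairwise"]) == 6
        assert (res["pairwise"]["p_adjusted"] <= 1.0).all()
        assert (res["pairwise"]["p_adjusted"] >= res["pairwise"]["p"] - 1e-15).all()


class TestCorrelationTest:
    @pytest.mark.parametrize(
        "r, df, expected",
        [(0.322, 157, 4.268), (0.629, 157, 10.134)],
    )
    def test_t_matches_reported_values(self, r, df, expected):
        assert ev.t_from_r(r, df) == pytest.approx(expected, abs=0.01)

    def test_zero_correlation_zero_t(self):
        for df in (5, 50, 500):
            assert ev.t_from_r(0.0, df) == 0.0

    def test_perfect_correlation_infinite_t(self):
        res = ev.correlation_test([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert math.isinf(res.t) and res.t > 0
        assert res.p == 0.0

    def test_matches_scipy_pearsonr(self, rng):
        x = rng.standard_normal(40)
        y = x + rng.standard_normal(40)
        res = ev.correlation_test(x, y)
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-8)
        assert res.df == 38

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ev.correlation_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def tiny_sites():
    rng = np.random.default_rng(3)
    n = 80
    driver = rng.uniform(0, 4, n)
    mu = np.expm1(driver)
    counts = rng.poisson(mu)
    counts[driver < 0.8] = 0
    return pd.DataFrame(
        {
            "site_id": np.arange(n),
            "cov_a": driver,
            "cov_b": rng.standard_normal(n),
            "mean_count": counts.astype(float),
        }
    )


class TestReplicateEvaluation:
    def test_single_replicate_reduces_to_one_split(self, tiny_sites):
        rows, summary = ev.replicate_evaluation(
            tiny_sites, ["cov_a", "cov_b"], variants=["gbm_log1p"], n_rep=1, base_seed=0
        )
        assert len(rows) == 1
        assert rows.loc[0, "accuracy"] == pytest.approx(
            summary.loc[0, "accuracy_mean"]
        )

    def test_summary_mean_is_mean_of_rows(self, tiny_sites):
        rows, summary = ev.replicate_evaluation(
            tiny_sites,
            ["cov_a", "cov_b"],
            variants=["gbm_raw", "sdm_gbm"],
            n_rep=5,
            base_seed=1,
        )
        for variant in ("gbm_raw", "sdm_gbm"):
            sub = rows[rows["variant"] == variant]
            expected = sub["accuracy"].mean()
            got = summary.set_index("variant").loc[variant, "accuracy_mean"]
            assert got == pytest.approx(expected, rel=1e-12)

    def test_transformed_evaluation_scale_option(self, tiny_sites):
        """The log1p variant can be scored on its fitting scale, where the
        scaled MAE differs from the back-transformed (count) scale."""
        kwargs = dict(variants=["gbm_log1p"], n_rep=2, base_seed=4)
        _, count_scale = ev.replicate_evaluation(
            tiny_sites, ["cov_a", "cov_b"], **kwargs
        )
        _, log_scale = ev.replicate_evaluation(
            tiny_sites, ["cov_a", "cov_b"], sam_eval_scale="transformed", **kwargs
        )
        a = count_scale.loc[0, "accuracy_mean"]
        b = log_scale.loc[0, "accuracy_mean"]
        assert np.isfinite(a) and np.isfinite(b) and a != b

    def test_sdm_rows_carry_auc_sam_rows_do_not(self, tiny_sites):
        rows, _ = ev.replicate_evaluation(
            tiny_sites,
            ["cov_a", "cov_b"],
            variants=["gbm_log1p", "sdm_gbm"],
            n_rep=2,
            base_seed=2,
        )
        sdm = rows[rows["variant"] == "sdm_gbm"]
        sam = rows[rows["variant"] == "gbm_log1p"]
        assert sdm["auc"].notna().all()
        assert sam["auc"].isna().all()
        assert (sdm["accuracy"] > 0).all()
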