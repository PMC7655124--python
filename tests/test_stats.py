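import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hippofeat.features import FEATURE_NAMES
from hippofeat.filtering import ParameterError
from hippofeat.stats import (
    InsufficientDataError,
    group_test_eh_vs_neh,
    hanley_mcneil_p,
    paired_rest_task_test,
    roc_auc,
    roc_result,
    run_battery,
)


def _feature_table(rest_eh, task_eh, rest_neh, task_neh, feature="r_rate"):
    rows = []
    for label, cond, values in [
        ("EH", "rest", rest_eh), ("EH", "task", task_eh),
        ("NEH", "rest", rest_neh), ("NEH", "task", task_neh),
    ]:
        for i, v in enumerate(values):
            row = {
                "channel_id": f"{label}{i}", "subject_id": f"s{i}",
                "hippocampus_id": f"{label}h{i // 2}", "label": label,
                "condition": cond, "task_name": None,
            }
            row.update(dict.fromkeys(FEATURE_NAMES, np.nan))
            row[feature] = v
            rows.append(row)
    return pd.DataFrame(rows)


class TestPairedTest:
    def test_identical_conditions_give_null_result(self):
        vals = list(np.arange(10.0))
        df = _feature_table(vals, vals, [1.0], [1.0])
        res = paired_rest_task_test(df, "r_rate", "EH")
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.n == 10

    def test_constant_shift_becomes_significant(self, rng):
        rest = rng.normal(10, 0.01, 30)
        task = rest - 2.0
        df = _feature_table(list(rest), list(task), [1.0], [1.0])
        res = paired_rest_task_test(df, "r_rate", "EH")
        assert res.p_value < 1e-10
        assert res.statistic > 0

    def test_insufficient_pairs_rejected(self):
        df = _feature_table([1.0], [2.0], [1.0], [1.0])
        with pytest.raises(InsufficientDataError):
            paired_rest_task_test(df, "r_rate", "EH")


class TestMannWhitney:
    def test_u_statistic_matches_pair_counting(self):
        eh = [3.1, 4.5, 2.2, 5.0, 3.3]
        neh = [1.1, 2.5, 3.0, 0.5, 2.0]
        df = _feature_table(eh, [0] * 5, neh, [0] * 5)
        res = group_test_eh_vs_neh(df, "r_rate", "rest")
        u_brute = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in eh for b in neh
        )
        assert res.statistic == pytest.approx(u_brute)

    def test_separated_groups_reach_minimal_p(self):
        eh = list(np.arange(10.0) + 100)
        neh = list(np.arange(10.0))
        df = _feature_table(eh, [0] * 10, neh, [0] * 10)
        res = group_test_eh_vs_neh(df, "r_rate", "rest")
        u, p_min = sps.mannwhitneyu(eh, neh, alternative="two-sided")
        assert res.p_value == pytest.approx(p_min)
        assert res.p_value < 2e-4

    def test_null_distribution_is_calibrated(self, rng):
        # identical distributions: p-values roughly uniform
        ps = []
        for _ in range(40):
            eh = list(rng.standard_normal(15))
            neh = list(rng.standard_normal(15))
            df = _feature_table(eh, [0] * 15, neh, [0] * 15)
            ps.append(group_test_eh_vs_neh(df, "r_rate", "rest").p_value)
        assert np.median(ps) > 0.1

    def test_empty_group_rejected(self):
        df = _feature_table([1.0, 2.0], [1.0, 2.0], [], [])
        with pytest.raises(InsufficientDataError):
            group_test_eh_vs_neh(df, "r_rate", "rest")


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_six_point_fixture_matches_brute_force(self):
        scores = np.array([0.3, 0.1, 0.5, 0.3, 0.9, 0.2])
        labels = np.array([1, 0, 1, 0, 1, 0])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        brute = np.mean([
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        ])
        assert roc_auc(scores, labels) == pytest.approx(brute)

    def test_random_fixtures_match_pair_counting_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.standard_normal(n), 1)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            brute = np.mean(
                [1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg]
            )
            assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_negation_complements(self, rng):
        scores = rng.standard_normal(30)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_auc([1, 2, 3], [1, 1, 1])


def _hm_reference(a, n_pos, n_neg):
    """Independently coded Hanley-McNeil closed form."""
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    se = np.sqrt(
        (a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2))
        / (n_pos * n_neg)
    )
    z = (a - 0.5) / se
    return 2 * (1 - sps.norm.cdf(abs(z)))


class TestHanleyMcNeil:
    def test_chance_auc_gives_p_one(self):
        assert hanley_mcneil_p(0.5, 20, 20) == 1.0

    @pytest.mark.parametrize("auc", [0.55, 0.65, 0.75, 0.9, 0.99])
    def test_matches_independent_formula(self, auc):
        assert hanley_mcneil_p(auc, 20, 20) == pytest.approx(
            _hm_reference(auc, 20, 20), abs=1e-12
        )

    @pytest.mark.parametrize("auc", [0.6, 0.75, 0.95])
    def test_symmetric_about_half(self, auc):
        assert hanley_mcneil_p(auc, 15, 15) == pytest.approx(
            hanley_mcneil_p(1 - auc, 15, 15), abs=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            hanley_mcneil_p(1.2, 5, 5)
        with pytest.raises(ParameterError):
            hanley_mcneil_p(0.5, 0, 5)


class TestBattery:
    def test_roc_scopes_include_difference(self, rng):
        eh_r = list(rng.normal(10, 1, 10))
        eh_t = list(rng.normal(5, 1, 10))
        neh_r = list(rng.normal(10, 1, 10))
        neh_t = list(rng.normal(10, 1, 10))
        df = _feature_table(eh_r, eh_t, neh_r, neh_t)
        res = roc_result(df, "r_rate", "diff")
        assert res.auc > 0.9  # EH drops under task, NEH does not
        assert res.n_pos == 10 and res.n_neg == 10

    def test_run_battery_shapes(self, cohort_features):
        tests, rocs = run_battery(cohort_features)
        assert set(tests.columns) >= {"feature", "comparison", "statistic", "p_value", "n"}
        assert set(rocs["scope"]) == {"rest", "task", "diff"}
        assert ((rocs.auc >= 0) & (rocs.auc <= 1)).all()
        assert ((tests.p_value >= 0) & (tests.p_value <= 1)).all()


def test_significance_heatmap_builds(cohort_features):
    from hippofeat.report import plot_significance_heatmap

    tests, rocs = run_battery(cohort_features)
    fig = plot_significance_heatmap(tests, rocs, title="synthetic cohort")
    assert len(fig.axes) >= 2
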