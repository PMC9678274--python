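"""Bootstrap machinery, ANOVAs, t tests and trust summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import facebias as fb
from facebias.errors import (
    ConfigurationError,
    DegenerateDataError,
    EmptySelectionError,
    PanelValidationError,
)

from conftest import make_panel, mixed_anova_oracle, single_reviewer_rows


class TestBootstrapMetric:
    def test_same_seed_identical(self, study1_panel):
        a = fb.bootstrap_metric(study1_panel, "mask", "SAME", "c", B=1000, seed=9)
        b = fb.bootstrap_metric(study1_panel, "mask", "SAME", "c", B=1000, seed=9)
        assert a == b

    def test_invariant_to_record_order(self, study1_panel):
        shuffled = fb.ReviewerPanel(
            study1_panel.records.sample(frac=1.0, random_state=0),
            study1_panel.roster,
        )
        a = fb.bootstrap_metric(study1_panel, "mask", "SAME", "d_prime", B=1000, seed=3)
        b = fb.bootstrap_metric(shuffled, "mask", "SAME", "d_prime", B=1000, seed=3)
        assert a == b

    def test_zero_variance_metric_zero_width_ci(self):
        rows = []
        ratings = _fixed_ratings()
        for i in range(4):  # four clones of the same reviewer
            rows += single_reviewer_rows(ratings, reviewer=f"r{i}")
        panel = make_panel(rows)
        res = fb.bootstrap_metric(panel, "mask", "SAME", "accuracy", B=1000, seed=1)
        assert res.ci_low == res.ci_high == res.estimate

    def test_too_few_reviewers_rejected(self):
        panel = make_panel(single_reviewer_rows(_fixed_ratings()))
        with pytest.raises(DegenerateDataError):
            fb.bootstrap_metric(panel, "mask", "SAME", "c", B=1000, seed=0)

    def test_small_B_rejected(self, study1_panel):
        with pytest.raises(ConfigurationError):
            fb.bootstrap_metric(study1_panel, "mask", "SAME", "c", B=100, seed=0)

    def test_callable_metric_supported(self, study1_panel):
        res = fb.bootstrap_metric(
            study1_panel, "mask", "SAME", lambda r: r.tpr - r.fpr, B=1000, seed=4
        )
        rates = fb.condition_rates(study1_panel, "mask", "SAME")
        assert res.estimate == pytest.approx(rates.tpr - rates.fpr)


class TestShiftTests:
    def test_estimate_matches_bias_shift(self, study1_panel):
        res = fb.shift_test(study1_panel, "mask", "c", B=1000, seed=0)
        shift = fb.bias_shift(
            fb.condition_rates(study1_panel, "mask", "SAME"),
            fb.condition_rates(study1_panel, "mask", "DIFFERENT"),
        )
        assert res.estimate == pytest.approx(shift.delta_c)

    def test_rate_shift_sign_convention(self, study1_panel):
        res = fb.shift_test(study1_panel, "mask", "tpr", B=1000, seed=0)
        rs = fb.condition_rates(study1_panel, "mask", "SAME")
        rd = fb.condition_rates(study1_panel, "mask", "DIFFERENT")
        assert res.estimate == pytest.approx(rs.tpr - rd.tpr)

    def test_cross_condition_antisymmetric_estimate(self, study1_panel):
        ab = fb.cross_condition_shift_test(
            study1_panel, study1_panel, "c", B=1000, seed=0,
            condition_a="mask", condition_b="no_mask",
        )
        ba = fb.cross_condition_shift_test(
            study1_panel, study1_panel, "c", B=1000, seed=0,
            condition_a="no_mask", condition_b="mask",
        )
        assert ab.estimate == pytest.approx(-ba.estimate)

    def test_identical_panels_not_significant(self, study1_panel):
        res = fb.cross_condition_shift_test(
            study1_panel, study1_panel, "c", B=2000, seed=1,
            condition_a="mask", condition_b="mask",
        )
        assert res.estimate == 0.0
        assert res.p_two_sided > 0.5

    def test_separated_generators_detected(self):
        cfg_hi = fb.SimulationConfig(
            conditions={"mask": fb.ConditionSpec(500, 0.9, 0.45)}, seed=21
        )
        cfg_lo = fb.SimulationConfig(
            conditions={"no_mask": fb.ConditionSpec(500, 0.9, 0.0)}, seed=22
        )
        pa, _ = fb.attention_filter(fb.simulate_panel(cfg_hi))
        pb, _ = fb.attention_filter(fb.simulate_panel(cfg_lo))
        res = fb.cross_condition_shift_test(pa, pb, "c", B=2000, seed=2)
        assert res.p_two_sided < 0.05
        assert res.estimate > 0


class TestMixedAnova:
    def test_label_invariant_identical_groups_give_zero_between(self):
        rows = []
        ratings = _fixed_ratings()
        for cond in ("no_mask", "mask"):
            for i in range(4):
                rows += _two_label_rows(
                    ratings, condition=cond, reviewer=f"{cond}{i}",
                    variant="A" if i % 2 == 0 else "B",
                )
        # identical reviewers everywhere -> no between or within variance
        panel = make_panel(rows)
        res = fb.mixed_anova_accuracy(panel, ("no_mask", "mask"))
        assert res["between"].F == pytest.approx(0.0, abs=1e-9) or np.isnan(
            res["between"].F
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_sums_of_squares_oracle(self, seed):
        cfg = fb.SimulationConfig(
            conditions={
                "no_mask": fb.ConditionSpec(8, 1.7, 0.2),
                "mask": fb.ConditionSpec(8, 0.9, 0.4),
            },
            seed=100 + seed,
        )
        panel, _ = fb.attention_filter(fb.simulate_panel(cfg))
        res = fb.mixed_anova_accuracy(panel, ("no_mask", "mask"))

        y = np.empty((2, 8, 2))
        scored = panel.scored
        for g, cond in enumerate(("no_mask", "mask")):
            sub = scored[scored["condition"] == cond]
            for s, rid in enumerate(sorted(sub["reviewer_id"].unique())):
                for w, label in enumerate(("SAME", "DIFFERENT")):
                    cell = sub[
                        (sub["reviewer_id"] == rid)
                        & (sub["algorithm_decision"] == label)
                    ]
                    y[g, s, w] = ((cell["rating"] >= 1) == cell["mated"]).mean()
        oracle = mixed_anova_oracle(y)
        for effect in ("between", "within", "interaction"):
            F, df1, df2 = oracle[effect]
            assert res[effect].F == pytest.approx(F, rel=1e-6), effect
            assert (res[effect].df_num, res[effect].df_den) == (df1, df2)

    def test_between_df_is_total_reviewers_minus_two(self, study1_panel):
        res = fb.mixed_anova_accuracy(study1_panel, ("no_mask", "mask"))
        n = study1_panel.n_reviewers("no_mask") + study1_panel.n_reviewers("mask")
        assert res["between"].df_den == n - 2


class TestOnewayAnova:
    def test_two_group_case_equals_squared_t(self, study1_panel):
        sub = fb.ReviewerPanel(
            study1_panel.records[
                study1_panel.records["condition"].isin(["no_mask", "mask"])
            ],
            study1_panel.roster,
        )
        res = fb.oneway_anova_abs_confidence(sub)
        a = fb.inference.reviewer_abs_confidence(sub, "no_mask")
        b = fb.inference.reviewer_abs_confidence(sub, "mask")
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res["condition"].F == pytest.approx(t.statistic**2)
        assert res["condition"].p == pytest.approx(t.pvalue)

    def test_identical_reviewers_give_zero_F(self):
        rows = []
        for cond in ("no_mask", "mask"):
            for i in range(3):
                rows += single_reviewer_rows(
                    _fixed_ratings(), condition=cond, reviewer=f"{cond}{i}"
                )
        res = fb.oneway_anova_abs_confidence(make_panel(rows))
        assert res["condition"].F == 0.0
        assert res["condition"].p == 1.0

    def test_single_reviewer_condition_rejected(self):
        rows = single_reviewer_rows(_fixed_ratings(), condition="mask")
        rows += single_reviewer_rows(
            _fixed_ratings(), condition="no_mask", reviewer="x1"
        ) + single_reviewer_rows(
            _fixed_ratings(), condition="no_mask", reviewer="x2"
        )
        with pytest.raises(DegenerateDataError):
            fb.oneway_anova_abs_confidence(make_panel(rows))

    def test_null_panel_p_not_extreme(self, study1_panel):
        """Degrees of freedom follow the design."""
        res = fb.oneway_anova_abs_confidence(study1_panel)
        n = study1_panel.n_reviewers()
        assert res["condition"].df_num == 2
        assert res["condition"].df_den == n - 3


class TestPairLevelTests:
    def test_posthoc_identical_groups(self, study1_panel):
        res = fb.pairwise_posthoc(study1_panel, ("mask", "mask"))
        assert res.p == pytest.approx(1.0)

    def test_posthoc_large_separation(self):
        rows = []
        hi = {pid: 3 if i % 2 else -3 for i, pid in enumerate(_scored_ids())}
        lo = {pid: 1 if i % 2 else 0 for i, pid in enumerate(_scored_ids())}
        for i in range(6):
            rows += single_reviewer_rows(hi, condition="mask", reviewer=f"m{i}")
            rows += single_reviewer_rows(lo, condition="no_mask", reviewer=f"n{i}")
        # tiny within-group jitter so variances are non-zero
        panel_rows = []
        for j, r in enumerate(rows):
            rating = r[5]
            if j % 13 == 0 and abs(rating) < 3:
                rating += 1
            panel_rows.append(r[:5] + (rating,))
        res = fb.pairwise_posthoc(make_panel(panel_rows), ("mask", "no_mask"))
        assert res.p < 0.001

    def test_per_pair_shift_identical_label_groups(self, study1_panel):
        pid = _scored_ids()[0]
        res = fb.per_pair_shift_test(study1_panel, "mask", pid)
        assert np.isfinite(res.t)

    def test_per_pair_null_rate_close_to_alpha(self):
        hits = total = 0
        for s in range(40):
            cfg = fb.SimulationConfig(
                conditions={"mask": fb.ConditionSpec(60, 0.9, 0.0)}, seed=400 + s
            )
            panel, _ = fb.attention_filter(fb.simulate_panel(cfg))
            hits += fb.count_significant_pairs(panel, "mask")
            total += 12
        assert hits / total == pytest.approx(0.05, abs=0.03)

    def test_strong_coupling_most_pairs_significant(self):
        cfg = fb.SimulationConfig(
            conditions={"mask": fb.ConditionSpec(1000, 0.9, 0.6)}, seed=77
        )
        panel, _ = fb.attention_filter(fb.simulate_panel(cfg))
        assert fb.count_significant_pairs(panel, "mask") >= 9

    def test_pairlevel_identical_vectors(self):
        v = np.linspace(-1, 1, 12)
        res = fb.pairlevel_paired_test(v, v)
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_pairlevel_constant_offset_degenerate(self):
        v = np.linspace(-1, 1, 12)
        res = fb.pairlevel_paired_test(v + 0.3, v)
        assert res.degenerate and np.isinf(res.t) and res.t > 0

    def test_pairlevel_matches_one_sample_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(size=12)
        res = fb.pairlevel_paired_test(a, b)
        one = stats.ttest_1samp(a - b, 0.0)
        assert res.t == pytest.approx(one.statistic)
        assert res.p == pytest.approx(one.pvalue)
        assert res.df == 11

    def test_pairlevel_length_mismatch_rejected(self):
        with pytest.raises(PanelValidationError):
            fb.pairlevel_paired_test(np.ones(12), np.ones(11))

    def test_per_pair_delta_mu_alignment(self, study1_panel):
        mu = fb.per_pair_delta_mu(study1_panel, "mask")
        assert len(mu) == 12
        assert list(mu.index) == sorted(mu.index)


class TestTrust:
    def test_proportion_counting(self):
        trust = pd.DataFrame(
            {
                "reviewer_id": list("abcd"),
                "condition": ["control"] * 4,
                "phase": ["pre"] * 4,
                "agrees": [True, True, True, False],
            }
        )
        assert fb.trust_proportion(trust, "control", "pre") == 0.75

    def test_empty_selection_rejected(self):
        trust = pd.DataFrame(columns=["reviewer_id", "condition", "phase", "agrees"])
        with pytest.raises(EmptySelectionError):
            fb.trust_proportion(trust, "control", "pre")

    def test_pre_post_difference(self):
        cfg = fb.study2_config(seed=3)
        trust = fb.simulate_trust(cfg)
        pre = fb.trust_proportion(trust, "alg65", "pre")
        post = fb.trust_proportion(trust, "alg65", "post")
        assert pre - post == pytest.approx(0.69 - 0.45, abs=0.12)


def _two_label_rows(ratings, condition="mask", reviewer="r1", variant="A"):
    """One reviewer with 3 mated + 3 non-mated pairs under each label."""
    roster = fb.default_roster()
    scored = roster[~roster["is_attention"]]
    mated = list(scored.loc[scored["mated"], "pair_id"])
    nonmated = list(scored.loc[~scored["mated"], "pair_id"])
    same = set(mated[:3]) | set(nonmated[:3])
    if variant == "B":
        same = set(mated[3:]) | set(nonmated[3:])
    return [
        (condition, variant, reviewer, pid,
         "SAME" if pid in same else "DIFFERENT", rating)
        for pid, rating in ratings.items()
    ]


def _fixed_ratings():
    ids = _scored_ids()
    values = [3, 2, -1, 2, 3, 1, -2, -3, 0, -1, -3, -2]
    return dict(zip(ids, values))


def _scored_ids():
    roster = fb.default_roster()
    return list(roster.loc[~roster["is_attention"], "pair_id"])


def test_shift_table_schema(study1_panel):
    table = fb.shift_table(study1_panel, B=1000, seed=0)
    assert set(table.columns) == {
        "condition", "metric", "estimate", "ci_low", "ci_high", "p", "significant"
    }
    assert set(table["condition"]) == {"no_mask", "mask"}
    assert len(table) == 6


def test_summary_table_schema(study1_panel):
    table = fb.summary_table(study1_panel, B=1000, seed=0)
    assert len(table) == 5  # control + 2 labels x 2 conditions
    for name in ("pct_correct", "fpr", "tpr", "d_prime", "c"):
        assert {name, f"{name}_ci_low", f"{name}_ci_high"} <= set(table.columns)
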