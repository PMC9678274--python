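"""Resampling and classical inference for criterion-shift analyses.

The exchangeable unit throughout is the reviewer: bootstrap confidence
intervals resample reviewers with replacement (paired across the two
algorithm-label cells within a condition, independently across conditions),
recompute the reviewer-averaged statistic per replicate, and report 95%
percentile intervals. Two-sided bootstrap p-values double the fraction of
replicates on the far side of zero.

Classical tests mirror the study's designs: a balanced mixed two-way ANOVA
on per-reviewer accuracy (between: condition; within: algorithm label), a
one-way between-subjects ANOVA on mean absolute confidence with Welch
pairwise post-hocs, per-pair two-sample t tests of label-conditioned rating
shifts, and a paired t across the 12 face pairs for comparing shift profiles
between conditions.

Every random routine derives its generator from (master seed, condition,
metric) so results do not depend on execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from scipy.stats import norm

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    EmptySelectionError,
    PanelValidationError,
)
from .panel import ReviewerPanel
from .sdt import DEFAULT_THETA, _check_theta, reviewer_rates

B_DEFAULT = 10_000
B_MIN = 1000
ALPHA = 0.05

RATE_METRICS = ("tpr", "fpr", "d_prime", "c", "accuracy", "pct_correct")
SHIFT_METRICS = ("tpr", "fpr", "c")


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    B: int
    seed: int


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    effects: tuple[AnovaEffect, ...]

    def __getitem__(self, name: str) -> AnovaEffect:
        for eff in self.effects:
            if eff.name == name:
                return eff
        raise KeyError(name)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    kind: str  # "paired" | "two_sample"
    degenerate: bool = False


def subseed(master: int, *tags) -> np.random.Generator:
    """Deterministic sub-stream keyed by (master seed, string tags)."""
    crc = zlib.crc32("|".join(str(t) for t in tags).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(master) & 0x7FFFFFFF, crc]))


# ---------------------------------------------------------------------------
# reviewer-level statistics and vectorized replicate evaluation
# ---------------------------------------------------------------------------


def _cell_stats(
    panel: ReviewerPanel,
    condition: str,
    decision_label: str | None,
    theta: float,
) -> pd.DataFrame:
    """Per-reviewer tpr/fpr/accuracy for one condition x label cell."""
    per = reviewer_rates(panel, condition, decision_label, theta)
    acc = (per["hits"] + (per["n_nonmated"] - per["fas"])) / (
        per["n_mated"] + per["n_nonmated"]
    )
    return per.assign(accuracy=acc)


def _guard_rates(rates: np.ndarray, n_total: float) -> np.ndarray:
    low, high = 0.5 / (n_total + 1), (n_total + 0.5) / (n_total + 1)
    return np.clip(rates, low, high)


def _eval_metric(metric, tpr, fpr, acc, n_mated, n_nonmated):
    if callable(metric):
        from .sdt import ConfusionRates

        values = [
            metric(ConfusionRates(float(t), float(f), int(n_mated), int(n_nonmated)))
            for t, f in zip(np.atleast_1d(tpr), np.atleast_1d(fpr))
        ]
        return np.asarray(values, dtype=float)
    if metric in ("accuracy", "pct_correct"):
        return np.atleast_1d(np.asarray(acc, dtype=float))
    tpr_g = _guard_rates(np.atleast_1d(np.asarray(tpr, float)), n_mated)
    fpr_g = _guard_rates(np.atleast_1d(np.asarray(fpr, float)), n_nonmated)
    if metric == "tpr":
        return np.atleast_1d(np.asarray(tpr, float))
    if metric == "fpr":
        return np.atleast_1d(np.asarray(fpr, float))
    if metric == "d_prime":
        return norm.ppf(tpr_g) - norm.ppf(fpr_g)
    if metric == "c":
        return -(norm.ppf(tpr_g) + norm.ppf(fpr_g)) / 2.0
    raise ConfigurationError(f"unknown metric {metric!r}; use one of {RATE_METRICS}")


def _percentile_ci(reps: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def _doubled_tail_p(reps: np.ndarray) -> float:
    p = 2.0 * min(float(np.mean(reps <= 0.0)), float(np.mean(reps >= 0.0)))
    return min(1.0, p)


def _check_B(B: int) -> None:
    if B < B_MIN:
        raise ConfigurationError(f"B must be at least {B_MIN}, got {B}")


def bootstrap_metric(
    panel: ReviewerPanel,
    condition: str,
    decision_label: str | None,
    metric,
    theta: float = DEFAULT_THETA,
    B: int = B_DEFAULT,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap over reviewers of a rate-derived scalar.

    ``metric`` is one of {"tpr","fpr","d_prime","c","accuracy"} or a callable
    receiving a :class:`~facebias.sdt.ConfusionRates`. Deterministic given
    ``seed``; the p-value refers to the statistic differing from zero.
    """
    _check_theta(theta)
    _check_B(B)
    per = _cell_stats(panel, condition, decision_label, theta)
    n = len(per)
    if n < 2:
        raise DegenerateDataError(
            f"need at least 2 reviewers to resample, found {n} in "
            f"{condition!r}/{decision_label!r}"
        )
    nm, nn = float(per["n_mated"].sum()), float(per["n_nonmated"].sum())
    tpr, fpr, acc = (per[k].to_numpy() for k in ("tpr", "fpr", "accuracy"))

    rng = subseed(seed, condition, decision_label, _metric_tag(metric), theta)
    idx = rng.integers(0, n, size=(B, n))
    reps = _eval_metric(metric, tpr[idx].mean(1), fpr[idx].mean(1), acc[idx].mean(1), nm, nn)
    est = float(_eval_metric(metric, tpr.mean(), fpr.mean(), acc.mean(), nm, nn)[0])
    lo, hi = _percentile_ci(reps)
    return BootstrapResult(est, lo, hi, _doubled_tail_p(reps), B, seed)


def _metric_tag(metric) -> str:
    return metric if isinstance(metric, str) else getattr(metric, "__name__", "custom")


def _paired_label_stats(panel, condition, theta):
    same = _cell_stats(panel, condition, "SAME", theta)
    diff = _cell_stats(panel, condition, "DIFFERENT", theta)
    common = same.index.intersection(diff.index)
    if len(common) < 2:
        raise DegenerateDataError(
            f"condition {condition!r} needs >= 2 reviewers with both labels"
        )
    return same.loc[common], diff.loc[common]


def _shift_reps(metric, same, diff, idx):
    nm, nn = float(same["n_mated"].sum()), float(same["n_nonmated"].sum())
    out = {}
    for tag, cell in (("same", same), ("diff", diff)):
        tpr = cell["tpr"].to_numpy()[idx].mean(-1)
        fpr = cell["fpr"].to_numpy()[idx].mean(-1)
        acc = cell["accuracy"].to_numpy()[idx].mean(-1)
        out[tag] = _eval_metric(metric, tpr, fpr, acc, nm, nn)
    if metric == "c":
        return out["diff"] - out["same"]
    # rate shifts are same-minus-different: positive = pulled toward "same"
    return out["same"] - out["diff"]


def shift_test(
    panel: ReviewerPanel,
    condition: str,
    metric: str = "c",
    theta: float = DEFAULT_THETA,
    B: int = B_DEFAULT,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap test of the label-induced shift within one condition.

    The statistic follows the package's sign conventions: delta_c =
    c(different) - c(same); TPR/FPR shifts are same-minus-different. The
    reviewer resample is paired across label cells, since every reviewer
    rates trials under both labels.
    """
    if metric not in SHIFT_METRICS:
        raise ConfigurationError(f"shift metric must be one of {SHIFT_METRICS}")
    _check_theta(theta)
    _check_B(B)
    same, diff = _paired_label_stats(panel, condition, theta)
    n = len(same)
    rng = subseed(seed, condition, "shift", metric, theta)
    idx = rng.integers(0, n, size=(B, n))
    reps = _shift_reps(metric, same, diff, idx)
    est = float(_shift_reps(metric, same, diff, np.arange(n)[None, :])[0])
    lo, hi = _percentile_ci(reps)
    return BootstrapResult(est, lo, hi, _doubled_tail_p(reps), B, seed)


def cross_condition_shift_test(
    panel_a: ReviewerPanel,
    panel_b: ReviewerPanel,
    metric: str = "c",
    theta: float = DEFAULT_THETA,
    B: int = B_DEFAULT,
    seed: int = 0,
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> BootstrapResult:
    """Bootstrap test of shift(A) - shift(B) across two conditions.

    Reviewers are resampled independently within each condition's pool. When
    a condition name is omitted the panel must contain exactly one
    algorithm-labelled condition.
    """
    if metric not in SHIFT_METRICS:
        raise ConfigurationError(f"shift metric must be one of {SHIFT_METRICS}")
    _check_theta(theta)
    _check_B(B)
    cond_a = condition_a or _sole_labelled_condition(panel_a)
    cond_b = condition_b or _sole_labelled_condition(panel_b)
    same_a, diff_a = _paired_label_stats(panel_a, cond_a, theta)
    same_b, diff_b = _paired_label_stats(panel_b, cond_b, theta)
    rng = subseed(seed, "cross", cond_a, cond_b, metric, theta)
    idx_a = rng.integers(0, len(same_a), size=(B, len(same_a)))
    idx_b = rng.integers(0, len(same_b), size=(B, len(same_b)))
    reps = _shift_reps(metric, same_a, diff_a, idx_a) - _shift_reps(
        metric, same_b, diff_b, idx_b
    )
    est_a = float(_shift_reps(metric, same_a, diff_a, np.arange(len(same_a))[None, :])[0])
    est_b = float(_shift_reps(metric, same_b, diff_b, np.arange(len(same_b))[None, :])[0])
    lo, hi = _percentile_ci(reps)
    return BootstrapResult(est_a - est_b, lo, hi, _doubled_tail_p(reps), B, seed)


def _sole_labelled_condition(panel: ReviewerPanel) -> str:
    labelled = sorted(
        panel.records.loc[
            panel.records["algorithm_decision"] != "NONE", "condition"
        ].unique()
    )
    if len(labelled) != 1:
        raise ConfigurationError(
            f"cannot infer condition; panel holds {labelled}; pass condition_a/b"
        )
    return labelled[0]


# ---------------------------------------------------------------------------
# ANOVA and t tests
# ---------------------------------------------------------------------------


def mixed_anova_accuracy(
    panel: ReviewerPanel,
    between: tuple[str, str],
    theta: float = DEFAULT_THETA,
) -> AnovaResult:
    """Mixed two-way ANOVA on accuracy: between-subjects condition, within-
    subjects algorithm label (one accuracy per reviewer per label).

    The between effect is tested against subjects-within-groups (df_den =
    total reviewers - 2); within and interaction against the label x subject
    residual.
    """
    _check_theta(theta)
    scored = panel.scored
    rows = []
    for cond in between:
        sub = scored[scored["condition"] == cond]
        if sub.empty:
            raise EmptySelectionError(f"no records for condition {cond!r}")
        for label in ("SAME", "DIFFERENT"):
            cell = sub[sub["algorithm_decision"] == label]
            acc = ((cell["rating"] > theta) == cell["mated"]).groupby(
                cell["reviewer_id"]
            ).mean()
            for rid, a in acc.items():
                rows.append((rid, cond, label, a))
    long = pd.DataFrame(rows, columns=["reviewer_id", "group", "label", "accuracy"])
    counts = long.groupby("reviewer_id")["label"].nunique()
    if (counts != 2).any():
        raise DegenerateDataError(
            f"reviewer {counts[counts != 2].index[0]!r} lacks one label cell"
        )
    table = pg.mixed_anova(
        data=long, dv="accuracy", within="label", subject="reviewer_id", between="group"
    )
    name_map = {"group": "between", "label": "within", "Interaction": "interaction"}
    effects = tuple(
        AnovaEffect(
            name=name_map[row["Source"]],
            F=float(row["F"]),
            df_num=int(row["DF1"]),
            df_den=int(row["DF2"]),
            p=float(row["p-unc"] if "p-unc" in table.columns else row["p_unc"]),
        )
        for _, row in table.iterrows()
    )
    return AnovaResult(effects)


def reviewer_abs_confidence(panel: ReviewerPanel, condition: str) -> pd.Series:
    """Per-reviewer mean |rating| over the scored trials of one condition."""
    scored = panel.scored
    sub = scored[scored["condition"] == condition]
    if sub.empty:
        raise EmptySelectionError(f"no records for condition {condition!r}")
    return sub["rating"].abs().groupby(sub["reviewer_id"]).mean()


def oneway_anova_abs_confidence(
    panel: ReviewerPanel, conditions: list[str] | None = None
) -> AnovaResult:
    """One-way between-subjects ANOVA on per-reviewer mean |rating|."""
    conds = conditions or panel.conditions()
    if len(conds) < 2:
        raise ConfigurationError("need at least two conditions")
    groups = [reviewer_abs_confidence(panel, c).to_numpy() for c in conds]
    for c, g in zip(conds, groups):
        if len(g) < 2:
            raise DegenerateDataError(f"condition {c!r} has fewer than 2 reviewers")
    F, p = stats.f_oneway(*groups)
    k, N = len(groups), sum(len(g) for g in groups)
    if not np.isfinite(F):  # all values identical across every group
        F, p = 0.0, 1.0
    return AnovaResult(
        (AnovaEffect("condition", float(F), k - 1, N - k, float(p)),)
    )


def pairwise_posthoc(panel: ReviewerPanel, condition_pair: tuple[str, str]) -> TTestResult:
    """Welch two-sample t on per-reviewer mean |rating| between two
    conditions (uncorrected, mirroring the study's bare pairwise p-values)."""
    a = reviewer_abs_confidence(panel, condition_pair[0]).to_numpy()
    b = reviewer_abs_confidence(panel, condition_pair[1]).to_numpy()
    return _welch(a, b)


def _welch(a: np.ndarray, b: np.ndarray) -> TTestResult:
    if np.std(a) == 0 and np.std(b) == 0:
        same = float(np.mean(a)) == float(np.mean(b))
        return TTestResult(0.0 if same else np.inf, float(len(a) + len(b) - 2),
                           1.0 if same else 0.0, "two_sample", degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), "two_sample")


def per_pair_shift_test(panel: ReviewerPanel, condition: str, pair_id) -> TTestResult:
    """Two-sample t on raw ratings of one face pair, grouped by the
    algorithm label under which reviewers saw it."""
    scored = panel.scored
    sub = scored[(scored["condition"] == condition) & (scored["pair_id"] == pair_id)]
    a = sub.loc[sub["algorithm_decision"] == "DIFFERENT", "rating"].to_numpy(float)
    b = sub.loc[sub["algorithm_decision"] == "SAME", "rating"].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError(
            f"pair {pair_id!r} lacks ratings under both labels in {condition!r}"
        )
    return _welch(a, b)


def count_significant_pairs(
    panel: ReviewerPanel, condition: str, alpha: float = ALPHA
) -> int:
    """Number of scored face pairs whose label-conditioned rating shift is
    significant at ``alpha`` (the per-condition count the study reports)."""
    scored = panel.scored
    pairs = sorted(scored.loc[scored["condition"] == condition, "pair_id"].unique())
    return sum(
        per_pair_shift_test(panel, condition, pid).p < alpha for pid in pairs
    )


def per_pair_delta_mu(panel: ReviewerPanel, condition: str) -> pd.Series:
    """Per-pair confidence shift mu(different) - mu(same), indexed by pair."""
    scored = panel.scored
    sub = scored[scored["condition"] == condition]
    if sub.empty:
        raise EmptySelectionError(f"no records for condition {condition!r}")
    mu = sub.groupby(["pair_id", "algorithm_decision"])["rating"].mean().unstack()
    if not {"SAME", "DIFFERENT"} <= set(mu.columns):
        raise DegenerateDataError(f"condition {condition!r} lacks both labels")
    return (mu["DIFFERENT"] - mu["SAME"]).rename("delta_mu").sort_index()


def pairlevel_paired_test(delta_mu_a, delta_mu_b) -> TTestResult:
    """Paired t across aligned per-pair shift vectors (12 pairs => df = 11)."""
    a = np.asarray(delta_mu_a, dtype=float)
    b = np.asarray(delta_mu_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PanelValidationError(
            f"shift vectors must be 1-d and aligned, got {a.shape} vs {b.shape}"
        )
    diff = a - b
    df = len(diff) - 1
    if np.std(diff) <= 1e-12 * max(1.0, float(np.abs(diff).max(initial=0.0))):
        if np.allclose(diff, 0.0):
            return TTestResult(0.0, df, 1.0, "paired", degenerate=True)
        sign = np.sign(float(diff.mean()))
        return TTestResult(sign * np.inf, df, 0.0, "paired", degenerate=True)
    res = stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), df, float(res.pvalue), "paired")


def trust_proportion(trust: pd.DataFrame, condition: str, phase: str) -> float:
    """Fraction of reviewers agreeing to trust (themselves / the algorithm)."""
    sel = trust[(trust["condition"] == condition) & (trust["phase"] == phase)]
    if sel.empty:
        raise EmptySelectionError(
            f"no trust records for condition={condition!r}, phase={phase!r}"
        )
    return float(sel["agrees"].mean())


# ---------------------------------------------------------------------------
# tidy tables
# ---------------------------------------------------------------------------


def summary_table(
    panel: ReviewerPanel,
    theta: float = DEFAULT_THETA,
    B: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Machine twin of the per-condition performance tables.

    One row per condition x algorithm-decision cell with reviewer count,
    point estimates and 95% bootstrap CIs for % correct, FPR, TPR, d' and c.
    """
    _check_theta(theta)
    _check_B(B)
    rows = []
    scored = panel.scored
    for cond in panel.conditions():
        sub = scored[scored["condition"] == cond]
        labels = sorted(set(sub["algorithm_decision"].unique()) - {"NONE"}) or [None]
        for label in labels:
            per = _cell_stats(panel, cond, label, theta)
            n = len(per)
            nm, nn = float(per["n_mated"].sum()), float(per["n_nonmated"].sum())
            tpr, fpr, acc = (per[k].to_numpy() for k in ("tpr", "fpr", "accuracy"))
            rng = subseed(seed, cond, label, "summary", theta)
            idx = rng.integers(0, n, size=(B, n))
            t_r, f_r, a_r = tpr[idx].mean(1), fpr[idx].mean(1), acc[idx].mean(1)
            row = {
                "study": int(panel.records["study"].iloc[0]),
                "condition": cond,
                "decision_label": label if label else "NONE",
                "n": n,
                "theta": theta,
            }
            for name in ("pct_correct", "fpr", "tpr", "d_prime", "c"):
                est = float(_eval_metric(name, tpr.mean(), fpr.mean(), acc.mean(), nm, nn)[0])
                lo, hi = _percentile_ci(_eval_metric(name, t_r, f_r, a_r, nm, nn))
                row[name] = est
                row[f"{name}_ci_low"] = lo
                row[f"{name}_ci_high"] = hi
            rows.append(row)
    return pd.DataFrame(rows)


def shift_table(
    panel: ReviewerPanel,
    conditions: list[str] | None = None,
    metrics: tuple[str, ...] = SHIFT_METRICS,
    theta: float = DEFAULT_THETA,
    B: int = B_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Machine twin of the shift-comparison figure: one row per condition x
    metric with the bootstrap estimate, CI, p and a significance flag."""
    conds = conditions or [
        c
        for c in panel.conditions()
        if (panel.records.loc[panel.records["condition"] == c, "algorithm_decision"]
            != "NONE").any()
    ]
    rows = []
    for cond in conds:
        for metric in metrics:
            res = shift_test(panel, cond, metric, theta, B, seed)
            rows.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "estimate": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p_two_sided,
                    "significant": res.p_two_sided < ALPHA,
                }
            )
    return pd.DataFrame(rows)
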