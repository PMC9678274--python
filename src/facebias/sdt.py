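"""Equal-variance Gaussian signal detection statistics on rating panels.

Ratings on the -3..+3 similarity-confidence scale are binarized at a
half-integer threshold theta (default 0.5: ratings of +1 and above mean
"same person"). From each reviewer's mated / non-mated trial counts we form
true- and false-positive rates, average them with equal weight across
reviewers, and summarise a condition x algorithm-decision cell with

    d' = z(TPR) - z(FPR)          (sensitivity)
    c  = -(z(TPR) + z(FPR)) / 2   (criterion; higher = more evidence
                                   needed to answer "same")

where z is the probit (inverse standard normal CDF). The criterion shift

    delta_c = c_different - c_same

between trials labelled "DIFFERENT PEOPLE" versus "SAME PERSON" by the
algorithm is the cognitive-bias statistic of interest: a positive shift means
the algorithm's decision pulls reviewer responses toward agreement with it.

Rates of exactly 0 or 1 cannot be probit-transformed. The package's default
is to average *unadjusted* per-reviewer rates (identical to pooled counting
under the balanced design) and apply the correction (h + 0.5) / (n + 1) only
when the aggregate rate itself is extreme; per-reviewer correction is
available via ``adjust="reviewer"`` but with 3-6 trial denominators it biases
rates toward 0.5 and is not used by the headline statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    EmptySelectionError,
)
from .panel import ReviewerPanel

#: binarization thresholds lying strictly between adjacent rating values
THETA_GRID = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
DEFAULT_THETA = 0.5

_ADJUST_MODES = ("none", "reviewer")


@dataclass(frozen=True)
class ConfusionRates:
    """TPR/FPR (reviewer-averaged unless built from one reviewer) plus the
    total mated / non-mated trial counts behind them."""

    tpr: float
    fpr: float
    n_mated: int
    n_nonmated: int


@dataclass(frozen=True)
class BiasShift:
    """Label-conditioned shifts; positive values mean the algorithm label
    pulls responses toward 'same person'."""

    delta_c: float
    delta_tpr: float
    delta_fpr: float


@dataclass(frozen=True)
class ConfidenceSummary:
    """Mean absolute confidence and label-conditioned mean ratings."""

    mu_abs: float
    mu_same: float | None
    mu_different: float | None
    delta_mu: float | None


def _check_theta(theta: float) -> float:
    if theta not in THETA_GRID:
        raise ConfigurationError(
            f"theta must be one of {THETA_GRID}, got {theta!r}"
        )
    return theta


def binarize(rating, theta: float = DEFAULT_THETA):
    """True iff the rating indicates 'same person' at threshold theta.

    Works element-wise on arrays. At the default theta = 0.5, ratings of 1
    and greater mean "same"; 0 and below mean "different".
    """
    _check_theta(theta)
    return np.asarray(rating) > theta if np.ndim(rating) else rating > theta


def adjust_extreme(hits: int, n: int) -> float:
    """hits/n, with extreme counts (0 or n) mapped to (hits + 0.5)/(n + 1)."""
    if n < 1:
        raise DegenerateDataError("cannot form a rate from zero trials")
    if not 0 <= hits <= n:
        raise ValueError(f"hits must lie in [0, {n}], got {hits}")
    if hits in (0, n):
        return (hits + 0.5) / (n + 1)
    return hits / n


def dprime(tpr: float, fpr: float) -> float:
    """Sensitivity d' = z(TPR) - z(FPR)."""
    _check_open_unit(tpr, "tpr")
    _check_open_unit(fpr, "fpr")
    return float(norm.ppf(tpr) - norm.ppf(fpr))


def criterion(tpr: float, fpr: float) -> float:
    """Criterion c = -(z(TPR) + z(FPR)) / 2."""
    _check_open_unit(tpr, "tpr")
    _check_open_unit(fpr, "fpr")
    return float(-(norm.ppf(tpr) + norm.ppf(fpr)) / 2.0)


def _check_open_unit(rate: float, name: str) -> None:
    if not 0.0 < rate < 1.0:
        raise DegenerateDataError(
            f"{name} = {rate} is outside (0, 1); apply an extreme-rate "
            "adjustment before the probit transform"
        )


def probit_safe_rates(rates: ConfusionRates) -> tuple[float, float]:
    """Rates guarded for the probit: an aggregate rate of exactly 0 or 1 is
    nudged using the pooled trial count behind it."""
    tpr, fpr = rates.tpr, rates.fpr
    if tpr in (0.0, 1.0):
        tpr = adjust_extreme(round(tpr * rates.n_mated), rates.n_mated)
    if fpr in (0.0, 1.0):
        fpr = adjust_extreme(round(fpr * rates.n_nonmated), rates.n_nonmated)
    return tpr, fpr


# ---------------------------------------------------------------------------
# Panel-level rate computation
# ---------------------------------------------------------------------------


def _select(panel: ReviewerPanel, condition: str, decision_label: str | None) -> pd.DataFrame:
    scored = panel.scored
    sel = scored[scored["condition"] == condition]
    if decision_label is not None:
        sel = sel[sel["algorithm_decision"] == decision_label]
    if sel.empty:
        raise EmptySelectionError(
            f"no scored records for condition={condition!r}, "
            f"decision_label={decision_label!r}"
        )
    return sel


def reviewer_rates(
    panel: ReviewerPanel,
    condition: str,
    decision_label: str | None = None,
    theta: float = DEFAULT_THETA,
    adjust: str = "none",
) -> pd.DataFrame:
    """Per-reviewer hit/false-alarm counts and rates for one condition cell.

    Returns a DataFrame indexed by reviewer_id with columns ``hits, n_mated,
    fas, n_nonmated, tpr, fpr``. ``decision_label`` of None pools all scored
    trials (the control condition's only option).
    """
    _check_theta(theta)
    if adjust not in _ADJUST_MODES:
        raise ConfigurationError(f"adjust must be one of {_ADJUST_MODES}")
    sel = _select(panel, condition, decision_label)
    same = sel["rating"].to_numpy() > theta
    mated = sel["mated"].to_numpy()
    tallies = pd.DataFrame(
        {
            "hits": same & mated,
            "n_mated": mated,
            "fas": same & ~mated,
            "n_nonmated": ~mated,
        },
        index=sel["reviewer_id"],
    )
    per = tallies.groupby(level="reviewer_id", sort=True).sum().astype(int)
    degenerate = (per["n_mated"] == 0) | (per["n_nonmated"] == 0)
    if degenerate.any():
        rid = per.index[degenerate][0]
        which = "mated" if per.loc[rid, "n_mated"] == 0 else "non-mated"
        raise DegenerateDataError(
            f"reviewer {rid!r} has zero {which} trials under label "
            f"{decision_label!r}"
        )
    per["tpr"] = per["hits"] / per["n_mated"]
    per["fpr"] = per["fas"] / per["n_nonmated"]
    if adjust == "reviewer":
        for rate, hit, tot in (("tpr", "hits", "n_mated"), ("fpr", "fas", "n_nonmated")):
            extreme = (per[hit] == 0) | (per[hit] == per[tot])
            per.loc[extreme, rate] = (per.loc[extreme, hit] + 0.5) / (
                per.loc[extreme, tot] + 1
            )
    return per


def condition_rates(
    panel: ReviewerPanel,
    condition: str,
    decision_label: str | None = None,
    theta: float = DEFAULT_THETA,
    adjust: str = "none",
) -> ConfusionRates:
    """Equal-weight reviewer average of TPR/FPR for one condition cell."""
    per = reviewer_rates(panel, condition, decision_label, theta, adjust)
    return ConfusionRates(
        tpr=float(per["tpr"].mean()),
        fpr=float(per["fpr"].mean()),
        n_mated=int(per["n_mated"].sum()),
        n_nonmated=int(per["n_nonmated"].sum()),
    )


def bias_shift(rates_same: ConfusionRates, rates_diff: ConfusionRates) -> BiasShift:
    """Criterion and rate shifts between algorithm-label cells.

    delta_c = c(different) - c(same); rate shifts are same-minus-different so
    a positive value means the label pulls responses toward "same".
    """
    c_same = criterion(*probit_safe_rates(rates_same))
    c_diff = criterion(*probit_safe_rates(rates_diff))
    return BiasShift(
        delta_c=c_diff - c_same,
        delta_tpr=rates_same.tpr - rates_diff.tpr,
        delta_fpr=rates_same.fpr - rates_diff.fpr,
    )


def accuracy(
    panel: ReviewerPanel,
    condition: str,
    decision_label: str | None = None,
    theta: float = DEFAULT_THETA,
) -> float:
    """Reviewer-averaged fraction of trials whose binarized decision matches
    the pair's true mated status."""
    _check_theta(theta)
    sel = _select(panel, condition, decision_label)
    correct = (sel["rating"] > theta) == sel["mated"]
    return float(correct.groupby(sel["reviewer_id"]).mean().mean())


def reviewer_accuracy(
    panel: ReviewerPanel,
    condition: str,
    decision_label: str | None = None,
    theta: float = DEFAULT_THETA,
) -> pd.Series:
    """Per-reviewer accuracy (one value per reviewer), for ANOVA designs."""
    _check_theta(theta)
    sel = _select(panel, condition, decision_label)
    correct = (sel["rating"] > theta) == sel["mated"]
    return correct.groupby(sel["reviewer_id"]).mean().rename("accuracy")


def confidence_summary(panel: ReviewerPanel, condition: str) -> ConfidenceSummary:
    """Mean |rating| plus label-conditioned mean ratings and their shift.

    For the control condition (no algorithm labels) the label-conditioned
    fields and delta_mu are None rather than an error.
    """
    sel = _select(panel, condition, None)
    mu_abs = float(sel["rating"].abs().mean())
    labels = set(sel["algorithm_decision"].unique())
    if labels == {"NONE"}:
        return ConfidenceSummary(mu_abs, None, None, None)
    mu_same = float(sel.loc[sel["algorithm_decision"] == "SAME", "rating"].mean())
    mu_diff = float(sel.loc[sel["algorithm_decision"] == "DIFFERENT", "rating"].mean())
    return ConfidenceSummary(mu_abs, mu_same, mu_diff, mu_diff - mu_same)
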