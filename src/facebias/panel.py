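"""Trial-level data model and I/O for reviewer panels.

A *panel* is the set of per-trial records produced by a cohort of reviewers,
each of whom rated the same roster of face pairs on a 7-point
similarity-confidence scale (coded as integers -3..+3, 0 = "I am not sure").
Every reviewer belongs to exactly one experimental condition and one survey
variant; in non-control conditions each trial additionally carries the
algorithm's prior identity decision ("SAME" / "DIFFERENT").

The roster mixes scored face pairs (GFMT and MEDS sources) with two easy
celebrity *attention* pairs used to screen out inattentive reviewers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    PanelFormatError,
    PanelValidationError,
)

CONDITIONS = ("control", "no_mask", "mask", "alg65", "alg95")
SOURCES = ("GFMT", "MEDS", "CELEBRITY")
DECISIONS = ("SAME", "DIFFERENT", "NONE")
VARIANTS = ("A", "B")

#: canonical column order of the task-data CSV dialect
TASK_COLUMNS = (
    "study",
    "condition",
    "variant",
    "reviewer_id",
    "pair_id",
    "source",
    "mated",
    "algorithm_decision",
    "rating",
    "is_attention",
)

#: canonical column order of the trust-data CSV dialect
TRUST_COLUMNS = ("reviewer_id", "condition", "phase", "agrees")

ROSTER_COLUMNS = ("pair_id", "source", "mated", "is_attention")

RATING_MIN, RATING_MAX = -3, 3


@dataclass(frozen=True)
class Dialect:
    """Maps canonical column names onto the (possibly renamed) file header.

    ``columns`` maps canonical name -> file column name; canonical names not
    listed are looked up verbatim. ``true_values``/``false_values`` govern how
    boolean columns (``mated``, ``is_attention``, ``agrees``) are parsed.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    true_values: Sequence[str] = ("true", "t", "1", "yes", "y", "mated")
    false_values: Sequence[str] = ("false", "f", "0", "no", "n", "nonmated", "non-mated")

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def parse_bool(self, value) -> bool:
        if isinstance(value, (bool,)):
            return bool(value)
        text = str(value).strip().lower()
        if text in self.true_values:
            return True
        if text in self.false_values:
            return False
        raise PanelValidationError(f"cannot interpret {value!r} as a boolean")


DEFAULT_DIALECT = Dialect()


@dataclass
class ReviewerPanel:
    """Validated per-trial records plus the face-pair roster they refer to.

    ``records`` has columns ``study, condition, variant, reviewer_id, pair_id,
    algorithm_decision, rating``; ``roster`` has columns ``pair_id, source,
    mated, is_attention``. Row order never affects downstream statistics.
    """

    records: pd.DataFrame
    roster: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.roster = (
            self.roster.drop_duplicates()
            .sort_values("pair_id")
            .reset_index(drop=True)
        )
        validate_panel(self)

    # -- convenience accessors -------------------------------------------------

    @property
    def merged(self) -> pd.DataFrame:
        """Records joined with roster metadata (mated, source, is_attention)."""
        return self.records.merge(self.roster, on="pair_id", how="left")

    @property
    def scored(self) -> pd.DataFrame:
        """Merged records with attention trials removed."""
        merged = self.merged
        return merged[~merged["is_attention"]].reset_index(drop=True)

    def conditions(self) -> list[str]:
        return sorted(self.records["condition"].unique())

    def n_reviewers(self, condition: str | None = None) -> int:
        rec = self.records
        if condition is not None:
            rec = rec[rec["condition"] == condition]
        return rec["reviewer_id"].nunique()

    def subset(self, condition: str) -> "ReviewerPanel":
        rec = self.records[self.records["condition"] == condition]
        if rec.empty:
            raise PanelValidationError(f"no records for condition {condition!r}")
        return ReviewerPanel(rec.copy(), self.roster.copy())


def validate_panel(panel: ReviewerPanel) -> None:
    rec, roster = panel.records, panel.roster
    missing = [c for c in TASK_COLUMNS if c not in set(rec.columns) | set(ROSTER_COLUMNS)]
    if missing:
        raise PanelFormatError(f"records missing required columns: {missing}")
    for col in ROSTER_COLUMNS:
        if col not in roster.columns:
            raise PanelFormatError(f"roster missing required column: {col!r}")

    bad_rating = ~rec["rating"].isin(range(RATING_MIN, RATING_MAX + 1))
    if bad_rating.any():
        idx = int(rec.index[bad_rating][0])
        raise PanelValidationError(
            f"rating outside [{RATING_MIN}, {RATING_MAX}] at record row {idx}: "
            f"{rec.loc[idx, 'rating']!r}"
        )
    bad_cond = ~rec["condition"].isin(CONDITIONS)
    if bad_cond.any():
        raise PanelValidationError(
            f"unknown condition {rec.loc[rec.index[bad_cond][0], 'condition']!r}"
        )
    bad_dec = ~rec["algorithm_decision"].isin(DECISIONS)
    if bad_dec.any():
        raise PanelValidationError(
            f"unknown algorithm_decision "
            f"{rec.loc[rec.index[bad_dec][0], 'algorithm_decision']!r}"
        )
    control = rec["condition"] == "control"
    if (control & (rec["algorithm_decision"] != "NONE")).any():
        raise PanelValidationError("control records must carry algorithm_decision NONE")
    if (~control & (rec["algorithm_decision"] == "NONE")).any():
        raise PanelValidationError(
            "non-control records must carry a SAME/DIFFERENT algorithm decision"
        )

    # attention flag is synonymous with the celebrity source
    if not (roster["is_attention"] == (roster["source"] == "CELEBRITY")).all():
        raise PanelValidationError("is_attention must hold exactly for CELEBRITY pairs")
    if roster["pair_id"].duplicated().any():
        raise PanelValidationError("roster pair_id values conflict across records")

    unknown = set(rec["pair_id"]) - set(roster["pair_id"])
    if unknown:
        raise PanelValidationError(f"records reference pairs absent from roster: {sorted(unknown)[:3]}")

    # one condition and one variant per reviewer
    per_reviewer = rec.groupby("reviewer_id")[["condition", "variant"]].nunique()
    multi = per_reviewer[(per_reviewer > 1).any(axis=1)]
    if not multi.empty:
        raise PanelValidationError(
            f"reviewer {multi.index[0]!r} appears in more than one condition/variant"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_panel(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> ReviewerPanel:
    """Read a task-data CSV (one row per reviewer x face-pair trial).

    Raises :class:`PanelFormatError` when a required column is absent and
    :class:`PanelValidationError` when a field value is out of range (the
    message names the offending row).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {}
    for canonical in TASK_COLUMNS:
        col = dialect.file_column(canonical)
        if col not in df.columns:
            raise PanelFormatError(f"missing required column {col!r} in {path}")
        rename[col] = canonical
    df = df.rename(columns=rename)[list(TASK_COLUMNS)]

    try:
        df["rating"] = df["rating"].astype(int)
    except ValueError as exc:
        raise PanelValidationError(f"non-integer rating in {path}: {exc}") from exc
    try:
        df["study"] = df["study"].astype(int)
    except ValueError as exc:
        raise PanelValidationError(f"non-integer study in {path}: {exc}") from exc
    for col in ("mated", "is_attention"):
        df[col] = df[col].map(dialect.parse_bool)

    roster = df[list(ROSTER_COLUMNS)].drop_duplicates()
    records = df[[c for c in TASK_COLUMNS if c not in ("source", "mated", "is_attention")]]
    return ReviewerPanel(records.copy(), roster.copy())


def write_panel(panel: ReviewerPanel, path: str | Path) -> None:
    """Write the canonical task-data CSV; ``read_panel`` inverts it exactly."""
    out = panel.merged[list(TASK_COLUMNS)]
    out.to_csv(path, index=False)


def read_trust(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read trust-question records (reviewer_id, condition, phase, agrees)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {}
    for canonical in TRUST_COLUMNS:
        col = dialect.file_column(canonical)
        if col not in df.columns:
            raise PanelFormatError(f"missing required column {col!r} in {path}")
        rename[col] = canonical
    df = df.rename(columns=rename)[list(TRUST_COLUMNS)]
    if not df["phase"].isin(("pre", "post")).all():
        raise PanelValidationError("trust phase must be 'pre' or 'post'")
    df["agrees"] = df["agrees"].map(dialect.parse_bool)
    return df


def write_trust(trust: pd.DataFrame, path: str | Path) -> None:
    trust[list(TRUST_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Attention-check exclusion
# ---------------------------------------------------------------------------


def attention_filter(panel: ReviewerPanel) -> tuple[ReviewerPanel, list]:
    """Drop reviewers who failed either celebrity attention trial.

    Correctness uses the same theta = 0.5 binarization as scoring: a mated
    attention pair is answered correctly iff rating >= 1, a non-mated pair iff
    rating <= 0. Attention trials are removed from the surviving records, so
    downstream stages see only the 12 scored pairs. Reviewers with no
    attention-trial records (e.g. a panel already filtered) are retained,
    which makes the filter idempotent.

    Returns the filtered panel and the sorted list of excluded reviewer ids.
    """
    roster = panel.roster
    n_attention = int(roster["is_attention"].sum())
    if n_attention != 2:
        raise ConfigurationError(
            f"roster must contain exactly 2 attention pairs, found {n_attention}"
        )
    merged = panel.merged
    att = merged[merged["is_attention"]]
    correct = (att["mated"] & (att["rating"] >= 1)) | (
        ~att["mated"] & (att["rating"] <= 0)
    )
    failed = att.loc[~correct, "reviewer_id"].unique()
    excluded = sorted(failed)

    keep = ~panel.records["reviewer_id"].isin(failed)
    attention_ids = set(roster.loc[roster["is_attention"], "pair_id"])
    keep &= ~panel.records["pair_id"].isin(attention_ids)
    filtered = ReviewerPanel(panel.records[keep].copy(), roster.copy())
    return filtered, excluded
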