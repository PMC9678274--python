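"""Synthetic reviewer panels from a criterion-shift Gaussian observer.

Each simulated reviewer is an equal-variance signal detection observer: a
trial presents latent familiarity x ~ N(d_i, 1) for a mated pair or N(0, 1)
for a non-mated pair, and the observer maps x onto the 7-point scale through
six increasing response criteria. The algorithm's displayed decision couples
to behaviour as a pure criterion translation: every criterion moves by
+delta_c/2 when the label reads "DIFFERENT PEOPLE" and by -delta_c/2 for
"SAME PERSON", so the injected delta_c is recovered (in expectation) as the
measured criterion shift at every threshold, while sensitivity is untouched —
the minimal mechanism consistent with decisions shifting c but not accuracy.

Reviewer heterogeneity enters as truncated-normal spread on d_i and a shared
normal offset on the criteria vector, giving the across-reviewer variance a
subject-level bootstrap needs. Attention (celebrity) trials are answered
correctly unless the reviewer is simulated as inattentive, in which case both
attention responses are sign-flipped and the reviewer will be excluded by the
attention filter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .panel import ReviewerPanel

#: Spacing of the base response criteria in criterion units. One step of the
#: confidence scale corresponds to 0.35 in c, chosen between the two measured
#: criterion-shift magnitudes (0.21 without masks, 0.45 with) so that a shift
#: larger than one scale step produces overlapping adjacent isobias bands and
#: a smaller shift does not, matching the observed band geometry.
CRITERION_STEP = 0.35
BASE_CRITERIA = tuple(CRITERION_STEP * k for k in (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5))


def default_roster() -> pd.DataFrame:
    """The 14-pair study roster: 8 GFMT + 4 MEDS scored pairs (6 mated / 6
    non-mated) plus 2 celebrity attention pairs (1 mated / 1 non-mated)."""
    rows = []
    for i in range(8):
        rows.append((f"gfmt{i + 1:02d}", "GFMT", i < 4, False))
    for i in range(4):
        rows.append((f"meds{i + 1:02d}", "MEDS", i < 2, False))
    rows.append(("celeb01", "CELEBRITY", True, True))
    rows.append(("celeb02", "CELEBRITY", False, True))
    return pd.DataFrame(rows, columns=["pair_id", "source", "mated", "is_attention"])


@dataclass(frozen=True)
class ConditionSpec:
    """Generative parameters for one experimental condition."""

    n_reviewers: int
    d_prime: float
    delta_c: float = 0.0
    criterion_offset: float = 0.0
    has_algorithm: bool = True

    def validate(self, name: str) -> None:
        if self.n_reviewers < 1:
            raise ConfigurationError(f"{name}: n_reviewers must be >= 1")
        if self.d_prime < 0:
            raise ConfigurationError(f"{name}: d_prime must be >= 0")
        if not self.has_algorithm and self.delta_c != 0.0:
            raise ConfigurationError(
                f"{name}: a control condition cannot carry a label coupling"
            )


@dataclass
class SimulationConfig:
    """Full generative specification of a synthetic study panel.

    ``base_criteria`` are the six increasing cut points (in criterion units,
    relative to the midpoint d'/2 of the two latent distributions) that
    partition the familiarity axis into the seven ratings. ``sd_d_prime`` and
    ``sd_criterion`` are the reviewer-heterogeneity scales; set both to 0 for
    homogeneous observers. ``attention_error_rate`` is the probability that a
    reviewer is inattentive (fails both celebrity trials).
    """

    conditions: Mapping[str, ConditionSpec]
    study: int = 1
    base_criteria: tuple[float, ...] = BASE_CRITERIA
    sd_d_prime: float = 0.3
    sd_criterion: float = 0.2
    attention_error_rate: float = 0.0
    seed: int = 0
    roster: pd.DataFrame = field(default_factory=default_roster)

    def validate(self) -> None:
        crit = np.asarray(self.base_criteria, dtype=float)
        if crit.size != 6 or np.any(np.diff(crit) <= 0):
            raise ConfigurationError("base_criteria must be 6 strictly increasing values")
        if not 0.0 <= self.attention_error_rate < 1.0:
            raise ConfigurationError("attention_error_rate must lie in [0, 1)")
        if min(self.sd_d_prime, self.sd_criterion) < 0:
            raise ConfigurationError("heterogeneity scales must be non-negative")
        if not self.conditions:
            raise ConfigurationError("at least one condition is required")
        for name, spec in self.conditions.items():
            spec.validate(name)
        scored = self.roster[~self.roster["is_attention"]]
        if len(scored) != 12 or int(scored["mated"].sum()) != 6:
            raise ConfigurationError("roster must hold 12 scored pairs, 6 mated")
        if int(self.roster["is_attention"].sum()) != 2:
            raise ConfigurationError("roster must hold exactly 2 attention pairs")


def study1_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-1-like panel: control plus algorithm conditions without and with
    face masks, at the condition sizes and (d', delta_c) the study reports
    (n = 49/51/50; d' approx 1.56 / 1.70 / 0.93; delta_c 0.21 / 0.45)."""
    conditions = {
        "control": ConditionSpec(49, 1.56, 0.0, criterion_offset=0.12, has_algorithm=False),
        "no_mask": ConditionSpec(51, 1.70, 0.21, criterion_offset=-0.13),
        "mask": ConditionSpec(50, 0.93, 0.45, criterion_offset=0.16),
    }
    return SimulationConfig(conditions=conditions, study=1, seed=seed, **overrides)


def study2_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-2-like panel: masked algorithm conditions with 65%/95% stated
    accuracy plus an unmasked control (n = 162/172/163; delta_c 0.16 / 0.25)."""
    conditions = {
        "alg65": ConditionSpec(162, 0.95, 0.16, criterion_offset=-0.01),
        "alg95": ConditionSpec(172, 1.00, 0.25, criterion_offset=-0.03),
        "control": ConditionSpec(163, 1.54, 0.0, criterion_offset=0.01, has_algorithm=False),
    }
    return SimulationConfig(conditions=conditions, study=2, seed=seed, **overrides)


def _condition_rng(seed: int, condition: str, tag: str = "panel") -> np.random.Generator:
    # order-independent sub-stream per condition
    crc = zlib.crc32(f"{tag}:{condition}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, crc]))


def simulate_panel(config: SimulationConfig) -> ReviewerPanel:
    """Draw a full multi-condition panel; deterministic given config.seed."""
    config.validate()
    roster = config.roster
    scored = roster[~roster["is_attention"]].sort_values("pair_id")
    mated_ids = list(scored.loc[scored["mated"], "pair_id"])
    nonmated_ids = list(scored.loc[~scored["mated"], "pair_id"])
    attention = roster[roster["is_attention"]].sort_values("pair_id")
    base = np.asarray(config.base_criteria, dtype=float)

    # label layout: variant A shows SAME on the first half of each mated /
    # non-mated block, variant B on the complementary half
    same_pairs = {
        "A": set(mated_ids[:3]) | set(nonmated_ids[:3]),
        "B": set(mated_ids[3:]) | set(nonmated_ids[3:]),
    }

    frames = []
    for name in sorted(config.conditions):
        spec = config.conditions[name]
        rng = _condition_rng(config.seed, name)
        n = spec.n_reviewers
        d_i = np.clip(rng.normal(spec.d_prime, config.sd_d_prime, n), 0.0, None)
        offset_i = rng.normal(0.0, config.sd_criterion, n)
        inattentive = rng.random(n) < config.attention_error_rate
        variants = np.where(np.arange(n) % 2 == 0, "A", "B")

        pair_ids = mated_ids + nonmated_ids
        mated_flags = np.array([True] * 6 + [False] * 6)
        n_trials = len(pair_ids)

        # (n, 12) latent draws and per-trial label shifts
        x = rng.standard_normal((n, n_trials)) + np.where(mated_flags, d_i[:, None], 0.0)
        if spec.has_algorithm:
            is_same_label = np.array(
                [[pid in same_pairs[v] for pid in pair_ids] for v in variants]
            )
            shift = np.where(is_same_label, -spec.delta_c / 2.0, spec.delta_c / 2.0)
            labels = np.where(is_same_label, "SAME", "DIFFERENT")
        else:
            shift = np.zeros((n, n_trials))
            labels = np.full((n, n_trials), "NONE")

        # effective criteria: base grid centred on d'/2, plus reviewer offset,
        # condition offset and the label-coupled translation
        centre = (d_i[:, None] / 2.0 + offset_i[:, None] + spec.criterion_offset)[..., None]
        crit = base[None, None, :] + centre + shift[..., None]
        ratings = (x[..., None] > crit).sum(axis=2) - 3

        rids = [f"{name}-r{i:04d}" for i in range(n)]
        rec = pd.DataFrame(
            {
                "study": config.study,
                "condition": name,
                "variant": np.repeat(variants, n_trials),
                "reviewer_id": np.repeat(rids, n_trials),
                "pair_id": pair_ids * n,
                "algorithm_decision": labels.ravel(),
                "rating": ratings.ravel().astype(int),
            }
        )
        frames.append(rec)

        # attention trials: +/-3 when attentive, sign-flipped when not
        att_rows = []
        for i, rid in enumerate(rids):
            for _, pair in attention.iterrows():
                correct = 3 if pair["mated"] else -3
                rating = -correct if inattentive[i] else correct
                att_rows.append(
                    (
                        config.study,
                        name,
                        variants[i],
                        rid,
                        pair["pair_id"],
                        labels[i, 0] if spec.has_algorithm else "NONE",
                        rating,
                    )
                )
        frames.append(
            pd.DataFrame(
                att_rows,
                columns=[
                    "study",
                    "condition",
                    "variant",
                    "reviewer_id",
                    "pair_id",
                    "algorithm_decision",
                    "rating",
                ],
            )
        )

    records = pd.concat(frames, ignore_index=True)
    return ReviewerPanel(records, roster.copy())


#: pre/post trust-agreement probabilities echoing the reported proportions
DEFAULT_TRUST_PROBS: dict[str, dict[str, float]] = {
    "control": {"pre": 0.77, "post": 0.68},
    "no_mask": {"pre": 0.69},
    "mask": {"pre": 0.69},
    "alg65": {"pre": 0.69, "post": 0.45},
    "alg95": {"pre": 0.69, "post": 0.53},
}


def simulate_trust(
    config: SimulationConfig,
    trust_probs: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Independent Bernoulli trust responses per reviewer and phase.

    ``trust_probs`` maps condition -> phase ("pre"/"post") -> probability of
    agreeing to trust the algorithm (or oneself, in the control condition).
    Conditions absent from the mapping contribute no records.
    """
    config.validate()
    probs = DEFAULT_TRUST_PROBS if trust_probs is None else trust_probs
    rows = []
    for name in sorted(config.conditions):
        if name not in probs:
            continue
        spec = config.conditions[name]
        rng = _condition_rng(config.seed, name, tag="trust")
        for phase in ("pre", "post"):
            if phase not in probs[name]:
                continue
            p = float(probs[name][phase])
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"trust probability out of [0,1]: {p}")
            agrees = rng.random(spec.n_reviewers) < p
            for i in range(spec.n_reviewers):
                rows.append((f"{name}-r{i:04d}", name, phase, bool(agrees[i])))
    return pd.DataFrame(rows, columns=["reviewer_id", "condition", "phase", "agrees"])
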