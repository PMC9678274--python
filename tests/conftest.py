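"""Shared fixtures: hand-built toy panels and cached large simulations."""

import numpy as np
import pandas as pd
import pytest

import facebias as fb


def make_panel(rows, roster=None):
    """Build a ReviewerPanel from (condition, variant, reviewer, pair, decision,
    rating) tuples against the default 14-pair roster."""
    roster = roster if roster is not None else fb.default_roster()
    rec = pd.DataFrame(
        rows,
        columns=["condition", "variant", "reviewer_id", "pair_id",
                 "algorithm_decision", "rating"],
    )
    rec.insert(0, "study", 1)
    return fb.ReviewerPanel(rec, roster)


def single_reviewer_rows(ratings_by_pair, condition="mask", reviewer="r1",
                         variant="A", decision="SAME"):
    return [
        (condition, variant, reviewer, pid, decision, rating)
        for pid, rating in ratings_by_pair.items()
    ]


def mixed_anova_oracle(y):
    """Brute-force sums of squares for a balanced 2-group x subject x
    2-level-within design. ``y`` has shape (groups, subjects, levels).
    Returns dict of (F, df_num, df_den) per effect."""
    a, n, b = y.shape
    grand = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_w = y.mean(axis=(0, 1))
    m_gs = y.mean(axis=2)
    m_gw = y.mean(axis=1)
    ss_between = b * n * np.sum((m_g - grand) ** 2)
    ss_subj = b * np.sum((m_gs - m_g[:, None]) ** 2)
    ss_within = a * n * np.sum((m_w - grand) ** 2)
    ss_inter = n * np.sum((m_gw - m_g[:, None] - m_w[None, :] + grand) ** 2)
    resid = y - m_gs[:, :, None] - m_gw[:, None, :] + m_g[:, None, None]
    ss_err = np.sum(resid**2)
    df_subj, df_err = a * (n - 1), a * (n - 1) * (b - 1)
    return {
        "between": (ss_between / (a - 1) / (ss_subj / df_subj), a - 1, df_subj),
        "within": (ss_within / (b - 1) / (ss_err / df_err), b - 1, df_err),
        "interaction": (
            ss_inter / ((a - 1) * (b - 1)) / (ss_err / df_err),
            (a - 1) * (b - 1),
            df_err,
        ),
    }


def homogeneous_config(condition, n, d_prime, delta_c, seed):
    return fb.SimulationConfig(
        conditions={condition: fb.ConditionSpec(n, d_prime, delta_c)},
        sd_d_prime=0.0,
        sd_criterion=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mask_panel_5000():
    """Homogeneous observers, d'=0.9, delta_c=0.45, n=5000."""
    cfg = homogeneous_config("mask", 5000, 0.9, 0.45, seed=101)
    panel, _ = fb.attention_filter(fb.simulate_panel(cfg))
    return panel


@pytest.fixture(scope="session")
def nomask_panel_5000():
    """Homogeneous observers, d'=1.7, delta_c=0.21, n=5000."""
    cfg = homogeneous_config("no_mask", 5000, 1.7, 0.21, seed=102)
    panel, _ = fb.attention_filter(fb.simulate_panel(cfg))
    return panel


@pytest.fixture(scope="session")
def null_panel_5000():
    """Default heterogeneity, d'=0.9, delta_c=0, n=5000."""
    cfg = fb.SimulationConfig(
        conditions={"mask": fb.ConditionSpec(5000, 0.9, 0.0)}, seed=103
    )
    panel, _ = fb.attention_filter(fb.simulate_panel(cfg))
    return panel


@pytest.fixture(scope="session")
def study1_panel():
    panel, _ = fb.attention_filter(fb.simulate_panel(fb.study1_config(seed=42)))
    return panel
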