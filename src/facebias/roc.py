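"""Rating-scale ROC curves and constant-criterion (isobias) geometry.

Sweeping the binarization threshold across the six half-integer values of the
confidence scale traces an empirical ROC curve per condition x algorithm
label. An *isobias curve* is the locus of (FPR, TPR) points sharing one
criterion value c as sensitivity d' varies:

    FPR = Phi(-d'/2 - c),   TPR = Phi(d'/2 - c)

Curves for distinct c never intersect, so the region between the curves for
the "SAME"- and "DIFFERENT"-label criteria at one threshold — an *isobias
band* — can be compared with another band purely in criterion space: two
bands overlap in ROC space exactly when their criterion intervals intersect.
Band overlap between adjacent thresholds signals that the algorithm-induced
criterion shift is comparable to a full step of the confidence scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, PanelValidationError
from .panel import ReviewerPanel
from .sdt import (
    THETA_GRID,
    condition_rates,
    criterion,
    probit_safe_rates,
)

#: default d' grid for rendering isobias polylines
D_MAX_DEFAULT = 4.0
N_SAMPLES_DEFAULT = 201


@dataclass
class ROCCurve:
    """Empirical ROC points over the threshold sweep, anchored at (0,0) and
    (1,1). Anchors carry theta = +inf (strictest: nothing called "same") and
    -inf (most permissive). Points are sorted by FPR."""

    condition: str
    decision_label: str | None
    points: pd.DataFrame  # columns: theta, fpr, tpr

    def __post_init__(self) -> None:
        pts = self.points.sort_values(["fpr", "tpr"], kind="stable")
        self.points = pts.reset_index(drop=True)


@dataclass
class IsobiasCurve:
    """Polyline of the constant-criterion locus for one c over a d' grid."""

    c: float
    d_grid: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass(frozen=True)
class IsobiasBand:
    """Criterion interval spanned by the two algorithm labels at one theta."""

    theta: float
    c_same: float
    c_different: float

    @property
    def c_low(self) -> float:
        return min(self.c_same, self.c_different)

    @property
    def c_high(self) -> float:
        return max(self.c_same, self.c_different)

    @property
    def width(self) -> float:
        return self.c_high - self.c_low


def roc_curve(
    panel: ReviewerPanel,
    condition: str,
    decision_label: str | None = None,
    thetas: tuple[float, ...] = THETA_GRID,
) -> ROCCurve:
    """One reviewer-averaged (FPR, TPR) point per threshold, plus anchors."""
    rows = []
    for theta in thetas:
        rates = condition_rates(panel, condition, decision_label, theta)
        rows.append((theta, rates.fpr, rates.tpr))
    rows.append((np.inf, 0.0, 0.0))
    rows.append((-np.inf, 1.0, 1.0))
    pts = pd.DataFrame(rows, columns=["theta", "fpr", "tpr"])
    return ROCCurve(condition, decision_label, pts)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the anchored, FPR-sorted ROC polyline."""
    pts = curve.points
    fpr = pts["fpr"].to_numpy()
    tpr = pts["tpr"].to_numpy()
    if np.any(np.diff(fpr) < 0):
        raise PanelValidationError("ROC points must be sorted by FPR")
    for anchor in ((0.0, 0.0), (1.0, 1.0)):
        n = int(((fpr == anchor[0]) & (tpr == anchor[1])).sum())
        if n != 1:
            raise PanelValidationError(
                f"ROC curve must contain anchor {anchor} exactly once, found {n}"
            )
    return float(np.trapezoid(tpr, fpr))


def isobias_curve(
    c: float,
    d_max: float = D_MAX_DEFAULT,
    n_samples: int = N_SAMPLES_DEFAULT,
) -> IsobiasCurve:
    """Constant-criterion polyline from d' = 0 (where TPR = FPR = Phi(-c),
    on the chance diagonal) out to d_max."""
    if d_max <= 0:
        raise ConfigurationError("d_max must be positive")
    if n_samples < 2:
        raise ConfigurationError("n_samples must be at least 2")
    d = np.linspace(0.0, d_max, n_samples)
    return IsobiasCurve(
        c=c,
        d_grid=d,
        fpr=norm.cdf(-d / 2.0 - c),
        tpr=norm.cdf(d / 2.0 - c),
    )


def isobias_point(c: float, d: float) -> tuple[float, float]:
    """(FPR, TPR) on the criterion-c locus at sensitivity d."""
    return float(norm.cdf(-d / 2.0 - c)), float(norm.cdf(d / 2.0 - c))


def band(theta: float, c_same: float, c_different: float) -> IsobiasBand:
    """Isobias band for one threshold; the interval orientation is kept but
    c_low/c_high expose the ordered endpoints."""
    return IsobiasBand(theta=theta, c_same=c_same, c_different=c_different)


def bands_overlap(a: IsobiasBand, b: IsobiasBand) -> bool:
    """True iff the two closed criterion intervals intersect (symmetric).

    Because isobias curves for distinct c never cross, this interval test is
    exactly ROC-space region overlap.
    """
    return a.c_low <= b.c_high and b.c_low <= a.c_high


def empirical_bands(
    panel: ReviewerPanel,
    condition: str,
    thetas: tuple[float, ...] = THETA_GRID,
) -> list[IsobiasBand]:
    """Per-threshold bands from the measured criteria under each label."""
    out = []
    for theta in thetas:
        c_s = criterion(*probit_safe_rates(condition_rates(panel, condition, "SAME", theta)))
        c_d = criterion(*probit_safe_rates(condition_rates(panel, condition, "DIFFERENT", theta)))
        out.append(IsobiasBand(theta=theta, c_same=c_s, c_different=c_d))
    return out


def adjacent_band_overlaps(bands: list[IsobiasBand]) -> list[bool]:
    """Overlap flags for consecutive-threshold band pairs (theta-sorted)."""
    ordered = sorted(bands, key=lambda b: b.theta)
    return [bands_overlap(a, b) for a, b in zip(ordered, ordered[1:])]


def export_geometry(
    panel: ReviewerPanel,
    condition: str,
    thetas: tuple[float, ...] = THETA_GRID,
    d_max: float = D_MAX_DEFAULT,
    n_samples: int = N_SAMPLES_DEFAULT,
) -> pd.DataFrame:
    """Tidy frame of ROC points and isobias band polylines for one condition.

    Columns: series ("roc"/"isobias"), decision_label, theta, c_same,
    c_different, d, fpr, tpr — renderable by any plotting front end; the
    core carries no plotting dependency.
    """
    frames = []
    for label in ("SAME", "DIFFERENT"):
        pts = roc_curve(panel, condition, label, thetas).points.copy()
        pts.insert(0, "series", "roc")
        pts.insert(1, "decision_label", label)
        pts["c_same"] = np.nan
        pts["c_different"] = np.nan
        pts["d"] = np.nan
        frames.append(pts)
    for b in empirical_bands(panel, condition, thetas):
        for tag, c in (("SAME", b.c_same), ("DIFFERENT", b.c_different)):
            curve = isobias_curve(c, d_max=d_max, n_samples=n_samples)
            frames.append(
                pd.DataFrame(
                    {
                        "series": "isobias",
                        "decision_label": tag,
                        "theta": b.theta,
                        "fpr": curve.fpr,
                        "tpr": curve.tpr,
                        "c_same": b.c_same,
                        "c_different": b.c_different,
                        "d": curve.d_grid,
                    }
                )
            )
    cols = ["series", "decision_label", "theta", "c_same", "c_different", "d", "fpr", "tpr"]
    return pd.concat(frames, ignore_index=True)[cols]
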