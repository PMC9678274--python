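"""End-to-end orchestration: ingest or simulate, filter, summarise, infer.

`run` composes the full analysis — attention filtering, the per-condition
SDT summary table, ROC/isobias geometry, bootstrap shift inference, the
study's ANOVAs and, when trust data are present, trust proportions — into a
:class:`StudyReport` whose artifacts (CSV tables plus a JSON report) are
byte-identical across runs with the same inputs and master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigurationError, FaceBiasError
from .inference import (
    mixed_anova_accuracy,
    oneway_anova_abs_confidence,
    shift_table,
    summary_table,
    trust_proportion,
)
from .panel import attention_filter, read_panel, read_trust
from .roc import adjacent_band_overlaps, empirical_bands, export_geometry
from .sdt import DEFAULT_THETA, THETA_GRID, confidence_summary
from .simulate import SimulationConfig, simulate_panel, simulate_trust

#: between-subjects contrasts for the mixed ANOVA, tried in order
_ANOVA_CONTRASTS = (("no_mask", "mask"), ("alg65", "alg95"))


@dataclass
class RunConfig:
    """Inputs and knobs for one end-to-end run.

    ``data`` is either a task-data CSV path or a :class:`SimulationConfig`;
    ``trust`` an optional trust-data CSV path (ignored when simulating —
    trust records are then generated alongside the panel).
    """

    data: str | Path | SimulationConfig
    trust: str | Path | None = None
    thetas: tuple[float, ...] = THETA_GRID
    theta: float = DEFAULT_THETA
    B: int = 2000
    seed: int = 0
    out_dir: str | Path | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.theta not in self.thetas:
            raise ConfigurationError("decision threshold must belong to the theta grid")


@dataclass
class StudyReport:
    summary: pd.DataFrame
    shifts: pd.DataFrame
    bands: pd.DataFrame
    geometry: pd.DataFrame
    anova: dict
    confidence: dict
    trust: pd.DataFrame | None
    excluded: list
    provenance: dict
    log: list[str] = field(default_factory=list)


def _config_digest(config: RunConfig) -> str:
    if isinstance(config.data, SimulationConfig):
        payload = {
            "kind": "simulation",
            "study": config.data.study,
            "seed": config.data.seed,
            "base_criteria": list(config.data.base_criteria),
            "sd_d_prime": config.data.sd_d_prime,
            "sd_criterion": config.data.sd_criterion,
            "attention_error_rate": config.data.attention_error_rate,
            "conditions": {
                k: asdict(v) for k, v in sorted(config.data.conditions.items())
            },
        }
    else:
        payload = {"kind": "file", "path": str(config.data)}
    payload.update(
        {"theta": config.theta, "thetas": list(config.thetas), "B": config.B,
         "seed": config.seed}
    )
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run(config: RunConfig) -> StudyReport:
    """Execute filter -> rates -> SDT -> ROC/isobias -> inference.

    Any stage failure is re-raised with the stage name prepended. When
    ``config.out_dir`` is set, CSV tables, a JSON report and a plain-text log
    are written there.
    """
    log: list[str] = []

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            try:
                wrapped = type(exc)(f"[stage {name}] {exc}")
            except TypeError:
                wrapped = FaceBiasError(f"[stage {name}] {exc}")
            raise wrapped from exc
        log.append(f"stage {name}: ok")
        return result

    if isinstance(config.data, SimulationConfig):
        panel = stage("simulate", simulate_panel, config.data)
        trust = stage("simulate_trust", simulate_trust, config.data)
        log.append(f"simulated panel: seed={config.data.seed}")
    else:
        panel = stage("ingest", read_panel, config.data)
        trust = stage("ingest_trust", read_trust, config.trust) if config.trust else None

    panel, excluded = stage("attention_filter", attention_filter, panel)
    log.append(f"attention filter excluded {len(excluded)} reviewers")

    summary = stage(
        "summary", summary_table, panel, theta=config.theta, B=config.B, seed=config.seed
    )
    shifts = stage(
        "shifts", shift_table, panel, theta=config.theta, B=config.B, seed=config.seed
    )

    labelled = list(shifts["condition"].unique())
    band_rows, geo_frames = [], []
    for cond in labelled:
        for b, overlaps_next in zip(
            bands := empirical_bands(panel, cond, config.thetas),
            adjacent_band_overlaps(bands) + [False],
        ):
            band_rows.append(
                {
                    "condition": cond,
                    "theta": b.theta,
                    "c_same": b.c_same,
                    "c_different": b.c_different,
                    "width": b.width,
                    "overlaps_next": overlaps_next,
                }
            )
        geo = export_geometry(panel, cond, config.thetas)
        geo.insert(0, "condition", cond)
        geo_frames.append(geo)
    bands_df = pd.DataFrame(band_rows)
    geometry = (
        pd.concat(geo_frames, ignore_index=True) if geo_frames else pd.DataFrame()
    )
    log.append(f"isobias bands for conditions: {labelled}")

    anova: dict = {}
    for pair in _ANOVA_CONTRASTS:
        if set(pair) <= set(panel.conditions()):
            res = stage("mixed_anova", mixed_anova_accuracy, panel, pair, config.theta)
            anova["accuracy_mixed"] = {
                "between": pair,
                "effects": {
                    e.name: {"F": e.F, "df": [e.df_num, e.df_den], "p": e.p}
                    for e in res.effects
                },
            }
            break
    if len(panel.conditions()) >= 2:
        res = stage("oneway_anova", oneway_anova_abs_confidence, panel)
        eff = res["condition"]
        anova["abs_confidence_oneway"] = {
            "F": eff.F, "df": [eff.df_num, eff.df_den], "p": eff.p
        }

    confidence = {}
    for cond in panel.conditions():
        cs = stage("confidence", confidence_summary, panel, cond)
        confidence[cond] = {
            "mu_abs": cs.mu_abs,
            "mu_same": cs.mu_same,
            "mu_different": cs.mu_different,
            "delta_mu": cs.delta_mu,
        }

    trust_summary = None
    if trust is not None and not trust.empty:
        t_rows = []
        for (cond, phase), _ in trust.groupby(["condition", "phase"]):
            t_rows.append(
                {
                    "condition": cond,
                    "phase": phase,
                    "proportion": trust_proportion(trust, cond, phase),
                }
            )
        trust_summary = pd.DataFrame(t_rows).sort_values(
            ["condition", "phase"]
        ).reset_index(drop=True)

    provenance = {
        "package_version": __version__,
        "config_sha256": _config_digest(config),
        "master_seed": config.seed,
        "B": config.B,
        "theta": config.theta,
        "theta_grid": list(config.thetas),
        "n_reviewers": {c: panel.n_reviewers(c) for c in panel.conditions()},
        "excluded_reviewers": len(excluded),
    }
    report = StudyReport(
        summary=summary,
        shifts=shifts,
        bands=bands_df,
        geometry=geometry,
        anova=anova,
        confidence=confidence,
        trust=trust_summary,
        excluded=excluded,
        provenance=provenance,
        log=log,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary.to_csv(out / "summary.csv", index=False)
    report.shifts.to_csv(out / "shifts.csv", index=False)
    report.bands.to_csv(out / "bands.csv", index=False)
    report.geometry.to_csv(out / "geometry.csv", index=False)
    if report.trust is not None:
        report.trust.to_csv(out / "trust.csv", index=False)
    payload = {
        "provenance": report.provenance,
        "anova": report.anova,
        "confidence": report.confidence,
        "excluded_reviewers": list(report.excluded),
        "shifts": report.shifts.to_dict(orient="records"),
        "trust": None
        if report.trust is None
        else report.trust.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(report.log) + "\n")


def make_table(report: StudyReport, which: str = "study1") -> pd.DataFrame:
    """Human-facing performance table, 2-dp strings with CI in parentheses.

    Conditions expected for the requested study but absent from the run are
    kept as explicit gap-marker rows rather than silently omitted.
    """
    layouts = {
        "study1": [("control", "NONE"), ("no_mask", "DIFFERENT"), ("no_mask", "SAME"),
                   ("mask", "DIFFERENT"), ("mask", "SAME")],
        "study2": [("alg65", "DIFFERENT"), ("alg65", "SAME"),
                   ("alg95", "DIFFERENT"), ("alg95", "SAME"), ("control", "NONE")],
    }
    if which not in layouts:
        raise ConfigurationError(f"which must be one of {sorted(layouts)}")

    def fmt(row, name):
        return (
            f"{row[name]:.2f} ({row[f'{name}_ci_low']:.2f}–"
            f"{row[f'{name}_ci_high']:.2f})"
        )

    rows = []
    summary = report.summary.set_index(["condition", "decision_label"])
    for cond, label in layouts[which]:
        base = {"Condition": cond, "Algorithm Decision": label.title()}
        if (cond, label) not in summary.index:
            rows.append({**base, "n": "—", "% Correct (95% CI)": "missing"})
            continue
        row = summary.loc[(cond, label)]
        rows.append(
            {
                **base,
                "n": int(row["n"]),
                "% Correct (95% CI)": fmt(row, "pct_correct"),
                "FPR (95% CI)": fmt(row, "fpr"),
                "TPR (95% CI)": fmt(row, "tpr"),
                "d' (95% CI)": fmt(row, "d_prime"),
                "c (95% CI)": fmt(row, "c"),
            }
        )
    return pd.DataFrame(rows)
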