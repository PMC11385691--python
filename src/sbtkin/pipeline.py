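"""End-to-end analysis pipeline: fit curves at several test durations,
project the fits onto the full horizon, derive classifiers, and evaluate
single and consensus diagnostic rules across the standard clinical
groupings.

The analysis runs three stages over a dataset (read from CSV or generated
synthetically):

1. Duration comparison — each curve is truncated to each candidate test
   duration, fitted by penalized ML, and the fitted model is projected over
   the full horizon to score its misfit against all the data (projection
   NLL, no penalty).  Larger projection NLL at a short duration means the
   short test mispredicts the later curve.
2. cPDR evaluation-time selection — using the full-duration fits, the
   cumulative recovery at each candidate evaluation time (60/90/120/240
   min) is scored by AUC per grouping; the table is reported (the default
   classifier remains cPDR90, the conventional choice).
3. Classifier evaluation — per grouping x duration: ROC/AUC for every
   classifier, Youden-optimal thresholds, and the consensus battery's
   confusion metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import pk_model
from .cohort import CohortConfig, CohortDataset, cohort_to_frame, generate_cohort, ground_truth_frame
from .evaluate import (
    ORIENTATIONS,
    STANDARD_GROUPINGS,
    Grouping,
    LabeledScores,
    evaluate_grouping,
    roc_and_auc,
)
from .fitting import (
    BreathCurve,
    FitConfig,
    FitError,
    FitResult,
    InsufficientDataError,
    fit_curve,
    projection_nll,
    truncate_curve,
)

__all__ = [
    "AnalysisConfig",
    "EvaluationReport",
    "SchemaError",
    "read_breath_csv",
    "write_breath_csv",
    "run_analysis",
    "write_report",
]

logger = logging.getLogger("sbtkin")

REQUIRED_COLUMNS = ("participant_id", "condition", "time_min", "pdr_pct_per_h")


class SchemaError(ValueError):
    """Input table violates the breath-curve CSV schema."""


def read_breath_csv(path) -> list[BreathCurve]:
    """Read long-format breath observations into BreathCurve records.

    Schema (one row per sample): ``participant_id``, ``condition``,
    ``time_min`` (minutes, >= 0), ``pdr_pct_per_h``, optional ``exclude``
    (0/1, default 0).  Times are converted to hours.  Rows must be grouped
    with strictly increasing times within each (participant, condition);
    duplicates or out-of-order times raise ``SchemaError`` naming the rows.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "condition": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if "exclude" not in df.columns:
        df["exclude"] = 0
    dup = df.duplicated(subset=["participant_id", "condition", "time_min"])
    if dup.any():
        raise SchemaError(
            f"{path}: duplicate (participant, condition, time) at rows "
            f"{df.index[dup].tolist()}"
        )
    curves = []
    for (pid, cond), grp in df.groupby(["participant_id", "condition"], sort=True):
        t_min = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t_min) <= 0):
            bad = grp.index[1:][np.diff(t_min) <= 0].tolist()
            raise SchemaError(
                f"{path}: times out of order for ({pid}, {cond}) at rows {bad}"
            )
        curves.append(
            BreathCurve(
                participant_id=str(pid),
                condition=str(cond),
                times=t_min / 60.0,
                values=grp["pdr_pct_per_h"].to_numpy(dtype=float),
                excluded=grp["exclude"].to_numpy(dtype=float).astype(bool),
            )
        )
    return curves


def write_breath_csv(curves: Sequence[BreathCurve], path) -> None:
    """Inverse of :func:`read_breath_csv` (hours converted back to minutes)."""
    rows = []
    for c in curves:
        for t, v, e in zip(c.times, c.values, c.excluded):
            rows.append(
                {
                    "participant_id": c.participant_id,
                    "condition": c.condition,
                    "time_min": t * 60.0,
                    "pdr_pct_per_h": v,
                    "exclude": int(e),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one full analysis run.

    Exactly one of ``input_csv`` and ``cohort`` provides the data.
    ``durations_min`` are the candidate test durations; ``cpdr_times_min``
    the candidate cPDR evaluation times scored in the selection step.
    ``omega_hours`` is the test length defining T50's half-recovery target;
    ``consensus_subset`` the classifiers entering the consensus battery.
    """

    input_csv: str | None = None
    cohort: CohortConfig | None = None
    durations_min: tuple[int, ...] = (60, 90, 120, 240)
    classifiers: tuple[str, ...] = ("rho", "cpdr90", "t50", "tpeak")
    consensus_subset: tuple[str, ...] = ("rho", "cpdr90", "t50")
    cpdr_times_min: tuple[int, ...] = (60, 90, 120, 240)
    omega_hours: float = 4.0
    groupings: tuple[Grouping, ...] = STANDARD_GROUPINGS
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.cohort is None):
            raise ValueError("provide exactly one of input_csv or cohort")
        if len(self.durations_min) == 0 or len(self.classifiers) == 0:
            raise ValueError("durations and classifiers must be non-empty")


@dataclass(frozen=True)
class EvaluationReport:
    """All tables produced by one analysis run."""

    fits: pd.DataFrame
    classifiers: pd.DataFrame
    projection: pd.DataFrame
    cpdr_selection: pd.DataFrame
    auc_grid: pd.DataFrame
    metrics: dict[int, pd.DataFrame]  # duration_min -> consensus table
    roc_points: pd.DataFrame
    skipped: pd.DataFrame
    config: AnalysisConfig
    ground_truth: pd.DataFrame | None = None


def _fit_row(pid: str, cond: str, dur: int, fit: FitResult) -> dict:
    p = fit.params
    return {
        "participant_id": pid,
        "condition": cond,
        "duration_min": dur,
        "rho_per_h": p.rho,
        "pi_ratio": p.pi_ratio,
        "pi_rho_per_h": p.pi_rho,
        "kappa": p.kappa,
        "nll": fit.nll,
        "objective": fit.objective,
        "penalty_applied": fit.penalty_applied,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
    }


def run_analysis(config: AnalysisConfig) -> EvaluationReport:
    """Execute the full three-stage analysis; deterministic given the seed."""
    truth = None
    if config.cohort is not None:
        dataset = generate_cohort(config.cohort)
        curves = list(dataset.curves)
        truth = ground_truth_frame(dataset)
    else:
        curves = read_breath_csv(config.input_csv)

    horizon_min = max(config.durations_min)
    fit_rows, cls_rows, proj_rows, skipped = [], [], [], []
    fits: dict[tuple[str, str, int], FitResult] = {}
    for curve in curves:
        for dur in config.durations_min:
            key = (curve.participant_id, curve.condition, dur)
            try:
                trunc = truncate_curve(curve, dur / 60.0)
                fit = fit_curve(trunc, config.fit)
            except (InsufficientDataError, FitError) as exc:
                logger.warning("skipping %s at %d min: %s", key, dur, exc)
                skipped.append(
                    {
                        "participant_id": curve.participant_id,
                        "condition": curve.condition,
                        "duration_min": dur,
                        "reason": str(exc),
                    }
                )
                continue
            fits[key] = fit
            fit_rows.append(_fit_row(curve.participant_id, curve.condition, dur, fit))
            proj_rows.append(
                {
                    "participant_id": curve.participant_id,
                    "condition": curve.condition,
                    "duration_min": dur,
                    "projection_nll": projection_nll(fit, curve, config.fit),
                }
            )
            cs = pk_model.classifier_set(
                fit.params, omega=config.omega_hours, eval_horizon=config.omega_hours
            )
            cls_rows.append(
                {
                    "participant_id": curve.participant_id,
                    "condition": curve.condition,
                    "duration_min": dur,
                    "rho": cs.rho,
                    "cpdr90": cs.cpdr90,
                    "t50": cs.t50,
                    "tpeak": cs.tpeak,
                }
            )

    fits_df = pd.DataFrame(fit_rows)
    cls_df = pd.DataFrame(cls_rows)
    proj_df = pd.DataFrame(proj_rows)
    skipped_df = pd.DataFrame(
        skipped, columns=["participant_id", "condition", "duration_min", "reason"]
    )

    # stage 2: cPDR evaluation-time selection from full-duration fits
    sel_rows = []
    full = fits_df.loc[fits_df["duration_min"] == horizon_min]
    for tau in config.cpdr_times_min:
        col = []
        for _, row in full.iterrows():
            p = pk_model.ModelParams(
                rho=row["rho_per_h"], pi_ratio=row["pi_ratio"], kappa=row["kappa"]
            )
            col.append(pk_model.cumulative_pdr(p, tau / 60.0))
        scored = full[["participant_id", "condition"]].copy()
        scored["cpdr"] = col
        for grouping in config.groupings:
            mask = scored["condition"].isin(grouping.negatives + grouping.positives)
            sub = scored.loc[mask]
            data = LabeledScores(
                ids=tuple(sub["participant_id"]),
                scores=sub["cpdr"].to_numpy(),
                labels=sub["condition"].isin(grouping.positives).astype(int).to_numpy(),
                orientation=-1,
            )
            sel_rows.append(
                {
                    "cpdr_time_min": tau,
                    "grouping": grouping.name,
                    "auc": roc_and_auc(data).auc,
                }
            )
    sel_df = pd.DataFrame(sel_rows)

    # stage 3: ROC/AUC grid and consensus metrics per grouping x duration
    auc_rows, roc_rows = [], []
    metrics: dict[int, pd.DataFrame] = {}
    for dur in config.durations_min:
        per_grouping = []
        for grouping in config.groupings:
            res = evaluate_grouping(
                cls_df, grouping, config.consensus_subset, duration=dur
            )
            per_grouping.append(res["metrics"])
            for name in config.classifiers:
                data = _labeled(cls_df, grouping, name, dur)
                rr = roc_and_auc(data)
                auc_rows.append(
                    {
                        "classifier": name,
                        "grouping": grouping.name,
                        "duration_min": dur,
                        "auc": rr.auc,
                    }
                )
                for thr, tpr, fpr in zip(rr.thresholds, rr.tpr, rr.fpr):
                    roc_rows.append(
                        {
                            "classifier": name,
                            "grouping": grouping.name,
                            "duration_min": dur,
                            "threshold": thr,
                            "tpr": tpr,
                            "fpr": fpr,
                        }
                    )
        tbl = pd.concat(per_grouping, ignore_index=True)
        tbl.insert(0, "duration_min", dur)
        metrics[dur] = tbl

    return EvaluationReport(
        fits=fits_df,
        classifiers=cls_df,
        projection=proj_df,
        cpdr_selection=sel_df,
        auc_grid=pd.DataFrame(auc_rows),
        metrics=metrics,
        roc_points=pd.DataFrame(roc_rows),
        skipped=skipped_df,
        config=config,
        ground_truth=truth,
    )


def _labeled(
    cls_df: pd.DataFrame, grouping: Grouping, classifier: str, dur: int
) -> LabeledScores:
    sub = cls_df.loc[
        np.isclose(cls_df["duration_min"], dur)
        & cls_df["condition"].isin(grouping.negatives + grouping.positives)
    ]
    return LabeledScores(
        ids=tuple(sub["participant_id"]),
        scores=sub[classifier].to_numpy(dtype=float),
        labels=sub["condition"].isin(grouping.positives).astype(int).to_numpy(),
        orientation=ORIENTATIONS.get(classifier, +1),
    )


def _config_echo(config: AnalysisConfig) -> dict:
    echo = asdict(config)
    echo["groupings"] = [asdict(g) for g in config.groupings]
    return echo


def write_report(report: EvaluationReport, outdir) -> dict:
    """Write all report tables as CSV plus a JSON manifest; idempotent.

    The manifest records the config echo, seed, a config hash and every
    written file with its row count.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "roc_points").mkdir(exist_ok=True)

    files: dict[str, int] = {}

    def dump(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False, float_format="%.10g")
        files[name] = len(df)

    dump(report.fits, "fits.csv")
    dump(report.classifiers, "classifiers.csv")
    dump(report.projection, "projection_nll.csv")
    dump(report.cpdr_selection, "cpdr_selection.csv")
    dump(report.auc_grid, "auc_grid.csv")
    dump(report.skipped, "skipped.csv")
    for dur, tbl in report.metrics.items():
        dump(tbl, f"metrics_{dur}.csv")
    if report.ground_truth is not None:
        dump(report.ground_truth, "ground_truth.csv")
    if len(report.roc_points):
        for (name, grp), sub in report.roc_points.groupby(["classifier", "grouping"]):
            dump(sub, f"roc_points/{name}_{grp}.csv")

    echo = _config_echo(report.config)
    cfg_json = json.dumps(echo, sort_keys=True, default=str)
    manifest = {
        "config": echo,
        "seed": report.config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
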