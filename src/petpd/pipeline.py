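"""End-to-end orchestration: simulate → PD metrics → mRECIST → ROC.

`run_analysis` takes the two analysis-facing tables (longitudinal tumor
volumes and pre/post SUVs), derives per-animal target engagement,
classifies therapeutic response, and — when both responders and
nonresponders are present — runs the ROC/Youden threshold analysis and
stratified response rates. Animals that cannot be classified by mRECIST
are reported and excluded from the ROC, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from petpd import __version__
from petpd.errors import ValidationError
from petpd.mrecist import classify_table
from petpd.pdmetrics import compute_pd_table
from petpd.roc import ScoredCohort, analyze, stratified_response_rate
from petpd.simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class AnalysisReport:
    """Machine-readable result of one pipeline run."""

    per_animal: pd.DataFrame
    roc_summary: dict | None
    strata_summary: dict | None
    roc_points: pd.DataFrame | None
    unclassifiable: list[str]
    notices: list[str]
    provenance: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "n_animals": int(len(self.per_animal)),
            "n_unclassifiable": len(self.unclassifiable),
            "unclassifiable": self.unclassifiable,
            "roc": self.roc_summary,
            "strata": self.strata_summary,
            "notices": self.notices,
            "provenance": self.provenance,
        }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"per_animal": out / "per_animal.csv", "summary": out / "summary.json"}
        self.per_animal.to_csv(paths["per_animal"], index=False)
        if self.roc_points is not None:
            paths["roc"] = out / "roc.csv"
            self.roc_points.to_csv(paths["roc"], index=False)
        paths["summary"].write_text(json.dumps(self.summary_dict(), indent=2, default=float))
        return paths


def _require_columns(table: pd.DataFrame, cols: set[str], name: str) -> None:
    missing = cols - set(table.columns)
    if missing:
        raise ValidationError(f"{name} is missing columns {sorted(missing)}")


def run_analysis(
    growth_table: pd.DataFrame,
    suv_table: pd.DataFrame,
    statistic: str = "suv_mean",
    score_column: str = "te_pct",
    negate_score: bool = False,
    min_day: float = 10.0,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Run the full PD → mRECIST → ROC chain on joined tables.

    Parameters
    ----------
    growth_table
        Long-form ``animal_id, day, volume_mm3`` (extra columns kept).
    suv_table
        Long-form ``animal_id, timepoint, suv_mean, suv_max``.
    statistic
        Which SUV statistic drives the PD metrics.
    score_column
        Column of the per-animal table to feed the ROC (``te_pct`` by
        default; e.g. ``delta_suv`` or ``suv_post`` for alternatives).
    negate_score
        Negate the score first, for scores where lower values predict
        response. ROC orientation is never auto-detected.
    """
    _require_columns(growth_table, {"animal_id", "day", "volume_mm3"}, "growth table")
    _require_columns(suv_table, {"animal_id", "timepoint", statistic}, "SUV table")

    pd_table = compute_pd_table(suv_table, statistic=statistic)
    mrecist_table = classify_table(growth_table, min_day=min_day)

    growth_ids = set(growth_table["animal_id"].astype(str))
    suv_ids = set(pd_table["animal_id"].astype(str))
    if growth_ids != suv_ids:
        only_growth = sorted(growth_ids - suv_ids)
        only_suv = sorted(suv_ids - growth_ids)
        raise ValidationError(
            f"animal_ids do not join: growth-only {only_growth}, suv-only {only_suv}"
        )

    per_animal = pd_table.merge(mrecist_table, on="animal_id", validate="1:1")
    unclassifiable = per_animal.loc[
        per_animal["label"] == "unclassifiable", "animal_id"
    ].tolist()

    notices: list[str] = []
    roc_summary = strata_summary = None
    roc_points = None
    classified = per_animal[per_animal["label"] != "unclassifiable"]
    labels = classified["responder"].astype(int)
    if labels.nunique() < 2:
        notices.append("ROC skipped: responder labels are single-class")
        logger.warning(notices[-1])
    else:
        if score_column not in classified.columns:
            raise ValidationError(f"score column {score_column!r} not in per-animal table")
        scores = classified[score_column].astype(float)
        if negate_score:
            scores = -scores
        cohort = ScoredCohort.from_arrays(
            scores.tolist(), labels.tolist(), classified["animal_id"].tolist()
        )
        roc = analyze(cohort)
        strata = stratified_response_rate(cohort, roc.youden_threshold)
        roc_summary = {
            "score_column": score_column,
            "negated": negate_score,
            "auc": roc.auc,
            "youden_threshold": roc.youden_threshold,
            "youden_j": roc.youden_j,
        }
        strata_summary = {
            "threshold": roc.youden_threshold,
            "rate_below_pct": strata["rate_below"],
            "rate_at_or_above_pct": strata["rate_at_or_above"],
            "counts_below": list(strata["counts_below"]),
            "counts_at_or_above": list(strata["counts_at_or_above"]),
        }
        roc_points = pd.DataFrame(
            {"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}
        )

    prov = {
        "software_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "n_input_animals": len(per_animal),
        "n_excluded_from_roc": len(unclassifiable),
        **(provenance or {}),
    }
    return AnalysisReport(
        per_animal=per_animal,
        roc_summary=roc_summary,
        strata_summary=strata_summary,
        roc_points=roc_points,
        unclassifiable=unclassifiable,
        notices=notices,
        provenance=prov,
    )


def config_hash(config: SimConfig) -> str:
    """Stable short hash of a resolved configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_simulation(
    config: SimConfig | None = None,
    out_dir: str | Path = "results/cohort",
    seed: int | None = None,
) -> dict[str, Path]:
    """Simulate a cohort and write growth.csv, suv.csv, truth.csv plus the
    resolved config; idempotent for a fixed (config, seed)."""
    config = config if config is not None else SimConfig()
    if seed is not None:
        config.seed = int(seed)
    cohort = simulate_cohort(config)
    paths = cohort.write(out_dir)
    cfg_path = Path(out_dir) / "config.yaml"
    config.to_yaml(cfg_path)
    paths["config"] = cfg_path
    return paths
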