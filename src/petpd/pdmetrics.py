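"""Pharmacodynamic metrics linking pre/post-treatment tracer uptake to
drug-target engagement.

A receptor-targeted tracer imaged before and after drug reports how much
of the target the drug has made inaccessible. With ``SUV_pre`` and
``SUV_post`` the tumor uptake before and after a single dose:

    accessible target (%)   = 100 × SUV_post / SUV_pre
    target engagement TE (%) = 100 × (SUV_pre − SUV_post) / SUV_pre
    ΔSUV                    = SUV_post − SUV_pre

The two percentages sum to exactly 100 for every input. TE is positive
when uptake falls (the drug engaged the target), zero for unchanged
uptake, and negative when post-treatment uptake exceeds baseline — a
point above the diagonal of a post-vs-pre scatter, meaning no measurable
engagement. Negative TE is preserved, never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from petpd.errors import ValidationError

#: Uptake statistics supported in parallel; mean is the default readout.
SUV_STATISTICS = ("suv_mean", "suv_max")


@dataclass(frozen=True)
class SUVRecord:
    """One animal's paired pre/post-treatment uptake for one SUV statistic."""

    animal_id: str
    suv_pre: float
    suv_post: float
    statistic: Literal["suv_mean", "suv_max"] = "suv_mean"

    def __post_init__(self) -> None:
        if self.suv_pre <= 0:
            raise ValidationError(f"{self.animal_id}: suv_pre must be > 0")
        if self.suv_post < 0:
            raise ValidationError(f"{self.animal_id}: suv_post must be >= 0")


@dataclass(frozen=True)
class PDMetrics:
    """Derived pharmacodynamic readouts for one animal."""

    animal_id: str
    accessible_pct: float
    te_pct: float
    delta_suv: float
    statistic: str = "suv_mean"


def accessible_fraction(suv_pre: float, suv_post: float) -> float:
    """Accessible (tracer-visible) target as % of baseline: 100·post/pre."""
    _validate(suv_pre, suv_post)
    return 100.0 * suv_post / suv_pre


def target_engagement(suv_pre: float, suv_post: float) -> float:
    """Target engagement in %: 100·(pre − post)/pre.

    Scale-invariant in the pair; ≤ 100 always (100 only when post = 0);
    negative exactly when post > pre.
    """
    _validate(suv_pre, suv_post)
    return 100.0 * (suv_pre - suv_post) / suv_pre


def delta_suv(suv_pre: float, suv_post: float) -> float:
    """Raw uptake change, post − pre (negative when uptake falls)."""
    if not (math.isfinite(suv_pre) and math.isfinite(suv_post)):
        raise ValidationError("SUV values must be finite")
    return suv_post - suv_pre


def compute_pd_metrics(record: SUVRecord) -> PDMetrics:
    """All three readouts for one animal."""
    return PDMetrics(
        animal_id=record.animal_id,
        accessible_pct=accessible_fraction(record.suv_pre, record.suv_post),
        te_pct=target_engagement(record.suv_pre, record.suv_post),
        delta_suv=delta_suv(record.suv_pre, record.suv_post),
        statistic=record.statistic,
    )


def compute_pd_table(suv_table, statistic: str = "suv_mean"):
    """Per-animal PD metrics from a long-form SUV table.

    Parameters
    ----------
    suv_table : pandas.DataFrame
        Columns ``animal_id, timepoint, suv_mean, suv_max`` with one
        ``pre`` and one ``post`` row per animal.
    statistic
        ``"suv_mean"`` or ``"suv_max"``.

    Returns
    -------
    pandas.DataFrame
        Columns ``animal_id, statistic, suv_pre, suv_post, delta_suv,
        accessible_pct, te_pct``.
    """
    import pandas as pd

    if statistic not in SUV_STATISTICS:
        raise ValidationError(f"statistic must be one of {SUV_STATISTICS}")
    wide = suv_table.pivot(index="animal_id", columns="timepoint", values=statistic)
    missing = wide.index[wide.isna().any(axis=1)].tolist()
    if missing or not {"pre", "post"} <= set(wide.columns):
        raise ValidationError(f"animals missing a pre or post row: {missing or 'all'}")
    rows = []
    for animal_id, (post, pre) in wide[["post", "pre"]].iterrows():
        m = compute_pd_metrics(
            SUVRecord(str(animal_id), float(pre), float(post), statistic)  # type: ignore[arg-type]
        )
        rows.append(
            {
                "animal_id": m.animal_id,
                "statistic": statistic,
                "suv_pre": pre,
                "suv_post": post,
                "delta_suv": m.delta_suv,
                "accessible_pct": m.accessible_pct,
                "te_pct": m.te_pct,
            }
        )
    return pd.DataFrame(rows).sort_values("animal_id", ignore_index=True)


def _validate(suv_pre: float, suv_post: float) -> None:
    if not (math.isfinite(suv_pre) and math.isfinite(suv_post)):
        raise ValidationError("SUV values must be finite")
    if suv_pre <= 0:
        raise ValidationError("suv_pre must be > 0")
    if suv_post < 0:
        raise ValidationError("suv_post must be >= 0")
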