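"""Mouse-adapted mRECIST classification of longitudinal tumor growth.

Each animal contributes a growth curve: tumor volume at day 0 (baseline)
and on later measurement days. Two summary statistics drive the class
label, both restricted to days at or after a minimum follow-up day
(default 10):

* ``BestResponse`` — the lowest percent volume change ΔVol_t = 100 ×
  (V_t − V_0)/V_0 over eligible days.
* ``BestAvgResponse`` — for each eligible day t, average ΔVol over all
  measurements from day 0 through t inclusive; take the lowest such
  average.

Labels (first match wins, all comparisons strict):

=======  ==================  =====================
label    BestResponse        BestAvgResponse
=======  ==================  =====================
mCR      < −95 %             < −40 %
mPR      < −50 %             < −20 %
mSD      < 35 %              < 30 %
mPD      otherwise
=======  ==================  =====================

mPD animals are nonresponders (0); mSD or better are responders (1).
Animals with no measurement at or after the minimum day are
unclassifiable and raise rather than defaulting silently.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from petpd.errors import ClassificationUnavailableError, ValidationError

#: Default minimum follow-up day for BestResponse / BestAvgResponse.
MIN_DAY = 10.0

#: Class labels in decreasing order of response depth.
LABELS = ("mCR", "mPR", "mSD", "mPD")

# (label, best_response cutoff, best_avg_response cutoff), checked in order.
_CRITERIA = (("mCR", -95.0, -40.0), ("mPR", -50.0, -20.0), ("mSD", 35.0, 30.0))


@dataclass(frozen=True)
class GrowthCurve:
    """One animal's (day, volume) series, starting at baseline day 0."""

    animal_id: str
    days: tuple[float, ...]
    volumes_mm3: tuple[float, ...]

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        vols = np.asarray(self.volumes_mm3, dtype=float)
        if days.size != vols.size:
            raise ValidationError(f"{self.animal_id}: days and volumes differ in length")
        if days.size < 2:
            raise ValidationError(f"{self.animal_id}: need at least 2 measurements")
        if days[0] != 0:
            raise ValidationError(f"{self.animal_id}: first measurement must be day 0")
        if np.any(np.diff(days) <= 0):
            raise ValidationError(f"{self.animal_id}: days must be strictly increasing")
        if np.any(vols <= 0):
            raise ValidationError(f"{self.animal_id}: volumes must be positive")


@dataclass(frozen=True)
class MRECISTResult:
    animal_id: str
    delta_vol_pct: tuple[float, ...]
    best_response: float
    best_avg_response: float
    label: str
    responder: int


def percent_volume_change(curve: GrowthCurve) -> np.ndarray:
    """ΔVol_t = 100 × (V_t − V_0)/V_0 per measurement day; exactly 0 at day 0."""
    vols = np.asarray(curve.volumes_mm3, dtype=float)
    out = 100.0 * (vols - vols[0]) / vols[0]
    out[0] = 0.0
    return out


def _eligible_mask(curve: GrowthCurve, min_day: float) -> np.ndarray:
    days = np.asarray(curve.days, dtype=float)
    mask = days >= min_day
    if not mask.any():
        raise ClassificationUnavailableError(
            f"{curve.animal_id}: no measurement at or after day {min_day}"
        )
    return mask


def best_response(curve: GrowthCurve, min_day: float = MIN_DAY) -> float:
    """Lowest ΔVol_t over days ≥ ``min_day`` (inclusive boundary)."""
    dv = percent_volume_change(curve)
    return float(dv[_eligible_mask(curve, min_day)].min())


def best_avg_response(curve: GrowthCurve, min_day: float = MIN_DAY) -> float:
    """Lowest prefix-average ΔVol over eligible days.

    For each day t ≥ ``min_day``, average ΔVol over every measurement
    from day 0 through t inclusive (day 0's exact zero participates);
    return the minimum of those averages.
    """
    dv = percent_volume_change(curve)
    mask = _eligible_mask(curve, min_day)
    prefix_means = np.cumsum(dv) / np.arange(1, dv.size + 1)
    return float(prefix_means[mask].min())


def classify(best_response_pct: float, best_avg_response_pct: float) -> str:
    """mRECIST label from the two summary statistics (precedence mCR→mPR→mSD)."""
    if not (np.isfinite(best_response_pct) and np.isfinite(best_avg_response_pct)):
        raise ValidationError("response statistics must be finite")
    for label, br_cut, bar_cut in _CRITERIA:
        if best_response_pct < br_cut and best_avg_response_pct < bar_cut:
            return label
    return "mPD"


def responder_flag(label: str) -> int:
    """1 for mSD or better, 0 for mPD (nonresponder)."""
    if label not in LABELS:
        raise ValidationError(f"unknown label {label!r}")
    return 0 if label == "mPD" else 1


def classify_curve(curve: GrowthCurve, min_day: float = MIN_DAY) -> MRECISTResult:
    """Full mRECIST result for one growth curve."""
    dv = percent_volume_change(curve)
    br = best_response(curve, min_day)
    bar = best_avg_response(curve, min_day)
    label = classify(br, bar)
    return MRECISTResult(
        animal_id=curve.animal_id,
        delta_vol_pct=tuple(dv),
        best_response=br,
        best_avg_response=bar,
        label=label,
        responder=responder_flag(label),
    )


def curves_from_table(growth_table) -> list[GrowthCurve]:
    """GrowthCurves from a long-form table with columns
    ``animal_id, day, volume_mm3`` (extra columns ignored)."""
    curves = []
    for animal_id, grp in growth_table.groupby("animal_id", sort=True):
        grp = grp.sort_values("day")
        curves.append(
            GrowthCurve(
                animal_id=str(animal_id),
                days=tuple(grp["day"].astype(float)),
                volumes_mm3=tuple(grp["volume_mm3"].astype(float)),
            )
        )
    return curves


def classify_table(growth_table, min_day: float = MIN_DAY):
    """Classify every animal in a long-form growth table.

    Returns a DataFrame with columns ``animal_id, best_response,
    best_avg_response, label, responder``. Animals without an eligible
    day get label ``"unclassifiable"`` and NaN statistics; they are
    reported, never dropped.
    """
    import pandas as pd

    rows = []
    for curve in curves_from_table(growth_table):
        try:
            res = classify_curve(curve, min_day)
            rows.append(
                {
                    "animal_id": res.animal_id,
                    "best_response": res.best_response,
                    "best_avg_response": res.best_avg_response,
                    "label": res.label,
                    "responder": res.responder,
                }
            )
        except ClassificationUnavailableError:
            rows.append(
                {
                    "animal_id": curve.animal_id,
                    "best_response": np.nan,
                    "best_avg_response": np.nan,
                    "label": "unclassifiable",
                    "responder": pd.NA,
                }
            )
    return pd.DataFrame(
        rows, columns=["animal_id", "best_response", "best_avg_response", "label", "responder"]
    )
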