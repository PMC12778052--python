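"""Radiotracer quantitation primitives.

Shared by measured (gamma-counter, PET-derived) and simulated data:
radioactive decay correction, percent injected activity per gram (%IA/g),
standardized uptake value (SUV), per-animal tissue ratios,
percent-of-control normalization, and the octanol/PBS partition
coefficient (logD).

Conventions
-----------
* Decay correction references activities back to injection time; negating
  the elapsed time decays forward.
* SUV uses the rodent g/cc convention: SUV = (%IA/cc ÷ 100) × body weight
  in grams, so a uniformly distributed tracer gives SUV ≈ 1 everywhere.
* Tissue ratios are mean-of-per-animal-ratios, not ratio-of-means: the
  ratio is formed within each animal first, then summarized across
  animals.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Literal, Sequence

from petpd.errors import ComputationError, ValidationError

logger = logging.getLogger(__name__)

#: Physical half-life of gallium-68 in minutes.
GA68_HALF_LIFE_MIN = 67.71


@dataclass(frozen=True)
class ActivityMeasurement:
    """One gamma-counter reading: a weighed tissue sample or a standard.

    Parameters
    ----------
    sample_id
        Free-text identifier (animal/tissue or standard label).
    counts
        Counts per minute, non-negative. Assumed dead-time corrected
        upstream.
    count_offset_min
        Minutes elapsed between injection (the decay reference) and the
        count.
    mass_g
        Sample mass in grams; required (and positive) for tissues, absent
        for standards.
    kind
        ``"tissue"`` or ``"standard"``.
    """

    sample_id: str
    counts: float
    count_offset_min: float = 0.0
    mass_g: float | None = None
    kind: Literal["tissue", "standard"] = "tissue"

    def __post_init__(self) -> None:
        if self.counts < 0:
            raise ValidationError(f"{self.sample_id}: counts must be >= 0")
        if self.count_offset_min < 0:
            raise ValidationError(f"{self.sample_id}: count_offset_min must be >= 0")
        if self.kind == "tissue" and (self.mass_g is None or self.mass_g <= 0):
            raise ValidationError(f"{self.sample_id}: tissue mass_g must be > 0")


@dataclass(frozen=True)
class UptakeRecord:
    """Per-animal, per-tissue tracer uptake.

    ``pct_ia_per_g`` comes from ex vivo counting; ``pct_ia_per_cc`` from
    calibrated imaging. Either may be absent depending on provenance.
    """

    animal_id: str
    tissue: str
    pct_ia_per_g: float | None = None
    pct_ia_per_cc: float | None = None
    timepoint_min: float | None = None

    def __post_init__(self) -> None:
        if self.pct_ia_per_g is not None and self.pct_ia_per_g < 0:
            raise ValidationError(f"{self.animal_id}/{self.tissue}: %IA/g must be >= 0")
        if self.pct_ia_per_cc is not None and self.pct_ia_per_cc < 0:
            raise ValidationError(f"{self.animal_id}/{self.tissue}: %IA/cc must be >= 0")


@dataclass(frozen=True)
class RatioSummary:
    """Per-animal tissue-uptake ratios with their mean and sd."""

    numerator_tissue: str
    denominator_tissue: str
    per_animal_ratios: tuple[float, ...] = field(default_factory=tuple)
    mean: float = math.nan
    sd: float = math.nan


def decay_correct(
    activity: float, elapsed_min: float, half_life_min: float = GA68_HALF_LIFE_MIN
) -> float:
    """Back-correct a measured activity to the reference (injection) time.

    Returns ``activity * 2**(elapsed_min / half_life_min)``. Passing a
    negative ``elapsed_min`` decays forward, so the operation is its own
    inverse under sign flip.
    """
    if activity < 0:
        raise ValidationError("activity must be >= 0")
    if half_life_min <= 0:
        raise ValidationError("half_life_min must be > 0")
    return activity * 2.0 ** (elapsed_min / half_life_min)


def percent_ia_per_gram(
    tissue: ActivityMeasurement,
    standards: Sequence[ActivityMeasurement],
    injected_fraction_of_standard: float,
    half_life_min: float = GA68_HALF_LIFE_MIN,
) -> UptakeRecord:
    """Compute %IA and %IA/g for one tissue sample against counting standards.

    Standards are aliquots representing a known fraction of the injected
    dose (``injected_fraction_of_standard``, e.g. 0.01 for a 1% standard).
    All counts are decay-corrected to injection time; the decay-corrected
    mean standard divided by its injected fraction calibrates counts per
    100% of injected activity, and

        %IA   = 100 × tissue_dc / (mean_standard_dc / fraction)
        %IA/g = %IA / mass_g

    The result does not depend on which common reference time is chosen
    for the correction, since the reference factor cancels.
    """
    if not standards:
        raise ValidationError("at least one standard is required")
    if not 0 < injected_fraction_of_standard <= 1:
        raise ValidationError("injected_fraction_of_standard must be in (0, 1]")
    if tissue.kind != "tissue":
        raise ValidationError(f"{tissue.sample_id}: expected a tissue measurement")

    tissue_dc = decay_correct(tissue.counts, tissue.count_offset_min, half_life_min)
    std_dc = [decay_correct(s.counts, s.count_offset_min, half_life_min) for s in standards]
    mean_std = statistics.fmean(std_dc)
    if mean_std <= 0:
        raise ComputationError("standard counts are zero; cannot calibrate injected activity")

    injected_activity = mean_std / injected_fraction_of_standard
    pct_ia = 100.0 * tissue_dc / injected_activity
    assert tissue.mass_g is not None  # guaranteed by ActivityMeasurement invariant
    animal_id, _, tissue_name = tissue.sample_id.partition("/")
    return UptakeRecord(
        animal_id=animal_id,
        tissue=tissue_name or animal_id,
        pct_ia_per_g=pct_ia / tissue.mass_g,
    )


def compute_uptake_table(biodist, standards):
    """%IA/g for every row of a biodistribution table.

    Parameters
    ----------
    biodist : pandas.DataFrame
        Columns ``animal_id, tissue, counts_cpm, count_offset_min, mass_g``.
    standards : pandas.DataFrame
        Columns ``standard_id, counts_cpm, count_offset_min,
        injected_fraction``. All standards must share one injected
        fraction.

    Returns
    -------
    pandas.DataFrame
        Columns ``animal_id, tissue, pct_ia_per_g``.
    """
    import pandas as pd

    fractions = standards["injected_fraction"].unique()
    if len(fractions) != 1:
        raise ValidationError("all standards must share one injected_fraction")
    std_meas = [
        ActivityMeasurement(
            sample_id=str(r.standard_id),
            counts=float(r.counts_cpm),
            count_offset_min=float(r.count_offset_min),
            kind="standard",
        )
        for r in standards.itertuples()
    ]
    rows = []
    for r in biodist.itertuples():
        rec = percent_ia_per_gram(
            ActivityMeasurement(
                sample_id=f"{r.animal_id}/{r.tissue}",
                counts=float(r.counts_cpm),
                count_offset_min=float(r.count_offset_min),
                mass_g=float(r.mass_g),
            ),
            std_meas,
            float(fractions[0]),
        )
        rows.append(
            {"animal_id": rec.animal_id, "tissue": rec.tissue, "pct_ia_per_g": rec.pct_ia_per_g}
        )
    return pd.DataFrame(rows, columns=["animal_id", "tissue", "pct_ia_per_g"])


def suv(concentration_pct_ia_per_cc: float, body_weight_g: float) -> float:
    """Standardized uptake value from a calibrated tracer concentration.

    SUV = (%IA/cc ÷ 100) × body weight (g); dimensionless under the g/cc
    convention.
    """
    if body_weight_g <= 0:
        raise ValidationError("body_weight_g must be > 0")
    if concentration_pct_ia_per_cc < 0:
        raise ValidationError("concentration must be >= 0")
    return concentration_pct_ia_per_cc / 100.0 * body_weight_g


def tissue_ratio_summary(
    pairs: Sequence[tuple[float, float]],
    numerator_tissue: str = "tumor",
    denominator_tissue: str = "blood",
) -> RatioSummary:
    """Summarize per-animal uptake ratios between two tissues.

    Each element of ``pairs`` is one animal's (numerator, denominator)
    uptake. Ratios are formed within animal, then mean/sd taken across
    animals (mean-of-ratios). Animals with a zero denominator are excluded
    with a logged warning; sd is 0 for a single animal.
    """
    if not pairs:
        raise ValidationError("at least one animal pair is required")
    ratios: list[float] = []
    for i, (num, den) in enumerate(pairs):
        if den == 0:
            logger.warning(
                "animal %d: %s uptake is zero; excluded from %s/%s ratio",
                i, denominator_tissue, numerator_tissue, denominator_tissue,
            )
            continue
        ratios.append(num / den)
    if not ratios:
        raise ComputationError("all animals excluded (zero denominators)")
    mean = statistics.fmean(ratios)
    sd = statistics.stdev(ratios) if len(ratios) > 1 else 0.0
    return RatioSummary(
        numerator_tissue=numerator_tissue,
        denominator_tissue=denominator_tissue,
        per_animal_ratios=tuple(ratios),
        mean=mean,
        sd=sd,
    )


def percent_of_control(treated: Sequence[float], control: Sequence[float]) -> list[float]:
    """Express treated-group values as a percentage of the control mean."""
    if not control:
        raise ValidationError("control group must be non-empty")
    control_mean = statistics.fmean(control)
    if control_mean <= 0:
        raise ComputationError("control mean must be positive")
    return [100.0 * t / control_mean for t in treated]


def partition_coefficient(replicates: Sequence[tuple[float, float]]) -> float:
    """logD from paired octanol/PBS gamma counts.

    Mean over replicates of log10(octanol ÷ PBS). Replicates with a zero
    count in either phase are excluded with a warning; if all are
    excluded a :class:`ComputationError` is raised.
    """
    if not replicates:
        raise ValidationError("at least one replicate is required")
    log_ratios: list[float] = []
    for i, (octanol, pbs) in enumerate(replicates):
        if octanol <= 0 or pbs <= 0:
            logger.warning("replicate %d: zero counts in a phase; excluded from logD", i)
            continue
        log_ratios.append(math.log10(octanol / pbs))
    if not log_ratios:
        raise ComputationError("all replicates excluded (zero counts)")
    return statistics.fmean(log_ratios)
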