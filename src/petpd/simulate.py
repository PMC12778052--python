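"""Synthetic two-dose mouse cohort generator.

Emulates the design of a single-dose antibody-drug-conjugate efficacy
study with paired pre/post target-engagement PET: two dose arms of
n = 10 (6 and 15 mg/kg) plus n = 5 saline controls, baseline tumor
volumes ≈ 170 ± 22 mm³, two weeks of caliper follow-up, and noisy
pre/post SUV measurements consistent with each animal's latent (true)
target engagement.

The generative model, per animal:

1. **True TE** — drawn from a dose-specific mixture of uniforms over the
   engagement bins [0,5), [5,25), [25,50), [50,100]; the 15 mg/kg arm is
   weighted toward the upper bins. Saline animals draw from a
   zero-centered normal (sd 5, untruncated), so negative observed TE —
   points above the diagonal of a post-vs-pre plot — occurs.
2. **Responder status** — Bernoulli with a hard step at the engagement
   threshold (default 30%): probability 0 below, 0.875 at or above. A
   smooth logistic alternative is available for sensitivity analyses.
3. **Growth curve** — V(t) = V₀·exp(g·t) with the rate g drawn from a
   responder (−0.02 ± 0.03 /day) or nonresponder (0.09 ± 0.02 /day)
   normal, multiplicative lognormal measurement noise on every day but
   baseline. The growth law is invented plumbing: it exists so the
   mRECIST classifier recovers the intended labels, and is quality-gated
   by a label-consistency property rather than fit to data.
4. **Observed SUVs** — latent SUV_pre lognormal (mean 0.8, CV 20%),
   latent SUV_post = SUV_pre·(1 − TE/100) floored at 1e−6, each observed
   with independent multiplicative lognormal noise (CV 8%).

Reproducibility: one root seed; each animal gets an independent
substream derived by stable hashing of (seed, animal_id), so growing the
cohort never reshuffles existing animals. Identical (config, seed) gives
bit-identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from petpd.errors import ValidationError

SALINE = "saline"

#: Fixed ratio of SUV_max to SUV_mean for the simulated hottest voxel.
SUV_MAX_SCALE = 1.5


@dataclass
class SimConfig:
    """All generator parameters; defaults are the emulated study design."""

    n_per_group: int = 10
    doses: tuple[float, ...] = (6.0, 15.0)
    include_saline: bool = True
    n_saline: int = 5
    te_bin_edges: tuple[float, ...] = (0.0, 5.0, 25.0, 50.0, 100.0)
    te_bin_weights: dict[float, tuple[float, ...]] = field(
        default_factory=lambda: {
            6.0: (0.40, 0.30, 0.20, 0.10),
            15.0: (0.10, 0.20, 0.30, 0.40),
        }
    )
    saline_te_sd: float = 5.0
    threshold_pct: float = 30.0
    p_response_below: float = 0.0
    p_response_at_or_above: float = 0.875
    response_model: str = "step"  # or "logistic"
    logistic_scale_pct: float = 5.0
    baseline_volume_mean_mm3: float = 170.0
    baseline_volume_cv: float = 0.13
    growth_rate_nonresponder_mean: float = 0.09
    growth_rate_nonresponder_sd: float = 0.02
    growth_rate_responder_mean: float = -0.02
    growth_rate_responder_sd: float = 0.03
    measurement_days: tuple[float, ...] = (0.0, 3.0, 7.0, 10.0, 14.0)
    volume_noise_cv: float = 0.08
    suv_pre_mean: float = 0.8
    suv_pre_cv: float = 0.20
    suv_noise_cv: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        self.doses = tuple(float(d) for d in self.doses)
        self.te_bin_edges = tuple(float(e) for e in self.te_bin_edges)
        self.te_bin_weights = {
            float(k): tuple(float(w) for w in v) for k, v in self.te_bin_weights.items()
        }
        self.measurement_days = tuple(float(d) for d in self.measurement_days)
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every offending field."""
        problems: list[str] = []
        if self.n_per_group <= 0:
            problems.append("n_per_group must be > 0")
        if self.include_saline and self.n_saline <= 0:
            problems.append("n_saline must be > 0 when include_saline")
        n_bins = len(self.te_bin_edges) - 1
        if n_bins < 1 or any(np.diff(self.te_bin_edges) <= 0):
            problems.append("te_bin_edges must be strictly increasing with >= 2 edges")
        for dose in self.doses:
            w = self.te_bin_weights.get(dose)
            if w is None:
                problems.append(f"te_bin_weights missing dose {dose}")
            elif len(w) != n_bins or any(x < 0 for x in w) or abs(sum(w) - 1) > 1e-9:
                problems.append(f"te_bin_weights[{dose}] must be {n_bins} non-negative weights summing to 1")
        for name in ("p_response_below", "p_response_at_or_above"):
            if not 0 <= getattr(self, name) <= 1:
                problems.append(f"{name} must be in [0, 1]")
        if self.response_model not in ("step", "logistic"):
            problems.append("response_model must be 'step' or 'logistic'")
        for name in ("baseline_volume_cv", "volume_noise_cv", "suv_pre_cv", "suv_noise_cv"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        days = self.measurement_days
        if not days or days[0] != 0 or not any(d >= 10 for d in days):
            problems.append("measurement_days must start at 0 and include a day >= 10")
        if any(np.diff(days) <= 0):
            problems.append("measurement_days must be strictly increasing")
        if problems:
            raise ValidationError("invalid SimConfig: " + "; ".join(problems))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["doses"] = list(self.doses)
        d["te_bin_edges"] = list(self.te_bin_edges)
        d["measurement_days"] = list(self.measurement_days)
        d["te_bin_weights"] = {str(k): list(v) for k, v in self.te_bin_weights.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "te_bin_weights" in d:
            d["te_bin_weights"] = {float(k): tuple(v) for k, v in d["te_bin_weights"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class CohortTable:
    """The simulated dataset, split into the three analysis-facing tables."""

    truth: pd.DataFrame  # animal_id, group, dose, true_te_pct, responder_true
    growth: pd.DataFrame  # animal_id, group, dose_mg_per_kg, day, volume_mm3
    suv: pd.DataFrame  # animal_id, timepoint, suv_mean, suv_max

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "growth": out / "growth.csv",
            "suv": out / "suv.csv",
            "truth": out / "truth.csv",
        }
        self.growth.to_csv(paths["growth"], index=False)
        self.suv.to_csv(paths["suv"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def animal_rng(seed: int, animal_id: str) -> np.random.Generator:
    """Independent, reproducible substream for one animal.

    The substream key is a SHA-256 hash of the animal id (stable across
    processes, unlike Python's ``hash``) combined with the root seed.
    """
    digest = hashlib.sha256(animal_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """One lognormal draw parameterized by arithmetic mean and CV."""
    if cv == 0:
        return mean
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def sample_te(dose: float | str, config: SimConfig, rng: np.random.Generator) -> float:
    """Draw one animal's true target engagement (%).

    Treated animals: pick an engagement bin by its dose-specific weight,
    then draw uniformly within the bin. Saline: zero-centered normal
    noise (untruncated, so negative TE occurs).
    """
    if dose == SALINE:
        return float(rng.normal(0.0, config.saline_te_sd))
    weights = config.te_bin_weights.get(float(dose))
    if weights is None:
        raise ValidationError(f"no te_bin_weights configured for dose {dose}")
    edges = config.te_bin_edges
    bin_idx = int(rng.choice(len(weights), p=weights))
    return float(rng.uniform(edges[bin_idx], edges[bin_idx + 1]))


def response_probability(true_te: float, config: SimConfig) -> float:
    """P(responder | true TE) under the configured response model."""
    lo, hi = config.p_response_below, config.p_response_at_or_above
    if config.response_model == "step":
        return lo if true_te < config.threshold_pct else hi
    z = (true_te - config.threshold_pct) / config.logistic_scale_pct
    return lo + (hi - lo) / (1.0 + math.exp(-z))


def sample_response(true_te: float, config: SimConfig, rng: np.random.Generator) -> int:
    """Bernoulli responder draw given true engagement."""
    return int(rng.random() < response_probability(true_te, config))


def simulate_growth(
    responder_true: int, config: SimConfig, rng: np.random.Generator, animal_id: str = "animal"
) -> "GrowthCurve":
    """Exponential tumor growth with per-day multiplicative noise.

    Baseline V₀ is lognormal (noise-free at day 0); the growth rate g
    comes from the responder or nonresponder distribution; later days
    get independent lognormal measurement noise.
    """
    from petpd.mrecist import GrowthCurve

    v0 = _lognormal(rng, config.baseline_volume_mean_mm3, config.baseline_volume_cv)
    if responder_true:
        g = rng.normal(config.growth_rate_responder_mean, config.growth_rate_responder_sd)
    else:
        g = rng.normal(config.growth_rate_nonresponder_mean, config.growth_rate_nonresponder_sd)
    volumes = []
    for day in config.measurement_days:
        v = v0 * math.exp(g * day)
        if day > 0:
            v *= _lognormal(rng, 1.0, config.volume_noise_cv)
        volumes.append(v)
    return GrowthCurve(
        animal_id=animal_id, days=config.measurement_days, volumes_mm3=tuple(volumes)
    )


def simulate_suv(
    true_te: float, config: SimConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed (SUV_pre, SUV_post) consistent with the true engagement.

    Latent post-treatment uptake is the pre-treatment latent scaled by
    (1 − TE/100), floored at 1e−6 for complete engagement; both latents
    are observed through independent mean-1 lognormal noise.
    """
    if true_te > 100:
        raise ValidationError("true_te cannot exceed 100%")
    pre_latent = _lognormal(rng, config.suv_pre_mean, config.suv_pre_cv)
    post_latent = max(pre_latent * (1.0 - true_te / 100.0), 1e-6)
    pre_obs = pre_latent * _lognormal(rng, 1.0, config.suv_noise_cv)
    post_obs = post_latent * _lognormal(rng, 1.0, config.suv_noise_cv)
    return pre_obs, post_obs


def _group_plan(config: SimConfig) -> list[tuple[str, float | str, str]]:
    plan = []
    for dose in config.doses:
        for i in range(config.n_per_group):
            plan.append((f"EV{dose:g}-{i + 1:03d}", dose, f"{dose:g} mg/kg"))
    if config.include_saline:
        for i in range(config.n_saline):
            plan.append((f"SAL-{i + 1:03d}", SALINE, SALINE))
    return plan


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> CohortTable:
    """Compose the per-animal samplers into the full cohort dataset.

    ``seed`` overrides ``config.seed``. Deterministic: identical
    (config, seed) produce bit-identical tables.
    """
    config = config if config is not None else SimConfig()
    config.validate()
    root_seed = config.seed if seed is None else int(seed)

    truth_rows, growth_rows, suv_rows = [], [], []
    for animal_id, dose, group in _group_plan(config):
        rng = animal_rng(root_seed, animal_id)
        te = sample_te(dose, config, rng)
        responder = sample_response(te, config, rng)
        curve = simulate_growth(responder, config, rng, animal_id)
        pre_mean, post_mean = simulate_suv(te, config, rng)
        # hottest-voxel statistic: same engagement, scaled latent, own noise
        pre_max = pre_mean * SUV_MAX_SCALE * _lognormal(rng, 1.0, config.suv_noise_cv)
        post_max = post_mean * SUV_MAX_SCALE * _lognormal(rng, 1.0, config.suv_noise_cv)

        dose_num = 0.0 if dose == SALINE else float(dose)
        truth_rows.append(
            {
                "animal_id": animal_id,
                "group": group,
                "dose_mg_per_kg": dose_num,
                "true_te_pct": te,
                "responder_true": responder,
                "suv_pre_obs": pre_mean,
                "suv_post_obs": post_mean,
            }
        )
        for day, vol in zip(curve.days, curve.volumes_mm3):
            growth_rows.append(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "dose_mg_per_kg": dose_num,
                    "day": day,
                    "volume_mm3": vol,
                }
            )
        for timepoint, s_mean, s_max in (("pre", pre_mean, pre_max), ("post", post_mean, post_max)):
            suv_rows.append(
                {
                    "animal_id": animal_id,
                    "timepoint": timepoint,
                    "suv_mean": s_mean,
                    "suv_max": s_max,
                }
            )

    return CohortTable(
        truth=pd.DataFrame(truth_rows),
        growth=pd.DataFrame(growth_rows),
        suv=pd.DataFrame(suv_rows),
    )


def analytic_te_auc(config: SimConfig | None = None, grid_size: int = 200_001) -> float:
    """Numerically exact AUC of true TE against true responder status.

    Integrates P(TE_pos > TE_neg) + ½·P(equal) over the configured TE
    mixture (treated bins + saline normal) and response model, on a fine
    grid. Serves as the independent oracle the simulated AUC must match.
    """
    config = config if config is not None else SimConfig()
    n_total = config.n_per_group * len(config.doses) + (
        config.n_saline if config.include_saline else 0
    )
    lo = min(0.0, -6.0 * config.saline_te_sd) if config.include_saline else 0.0
    grid = np.linspace(lo, 100.0, grid_size)
    dx = grid[1] - grid[0]

    density = np.zeros_like(grid)
    arm_weight = config.n_per_group / n_total
    for dose in config.doses:
        for w, (a, b) in zip(
            config.te_bin_weights[float(dose)],
            zip(config.te_bin_edges[:-1], config.te_bin_edges[1:]),
        ):
            in_bin = (grid >= a) & (grid < b)
            density[in_bin] += arm_weight * w / (b - a)
    if config.include_saline:
        from scipy.stats import norm

        density += (config.n_saline / n_total) * norm.pdf(grid, 0.0, config.saline_te_sd)

    p_resp = np.array([response_probability(t, config) for t in grid])
    f_pos = density * p_resp
    f_neg = density * (1.0 - p_resp)
    w_pos = f_pos.sum() * dx
    w_neg = f_neg.sum() * dx
    cdf_neg = np.cumsum(f_neg) * dx  # P(TE_neg <= t), up to grid resolution
    auc = float((f_pos * (cdf_neg - 0.5 * f_neg * dx)).sum() * dx / (w_pos * w_neg))
    return auc
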