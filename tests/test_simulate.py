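"""Cohort generator: TE mixtures, response model, growth, SUVs, determinism."""

import math

import numpy as np
import pytest

from petpd.errors import ValidationError
from petpd.mrecist import classify_curve, classify_table
from petpd.pdmetrics import target_engagement
from petpd.roc import ScoredCohort, roc_curve
from petpd.simulate import (
    SALINE,
    SimConfig,
    analytic_te_auc,
    animal_rng,
    sample_response,
    sample_te,
    simulate_cohort,
    simulate_growth,
    simulate_suv,
)


class TestSimConfig:
    def test_defaults_are_valid(self):
        SimConfig().validate()

    def test_invalid_config_lists_offending_fields(self):
        with pytest.raises(ValidationError) as exc:
            SimConfig(n_per_group=0, p_response_below=1.5)
        msg = str(exc.value)
        assert "n_per_group" in msg and "p_response_below" in msg

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=7, doses=(6.0,), te_bin_weights={6.0: (0.5, 0.2, 0.2, 0.1)})
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg

    def test_unknown_field_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            SimConfig.from_dict({"n_mice": 10})


class TestSampleTE:
    def test_degenerate_mixture_stays_in_first_bin(self):
        cfg = SimConfig(te_bin_weights={6.0: (1, 0, 0, 0), 15.0: (1, 0, 0, 0)})
        rng = np.random.default_rng(0)
        draws = [sample_te(6.0, cfg, rng) for _ in range(200)]
        assert all(0 <= t < 5 for t in draws)

    def test_bin_frequencies_match_weights(self):
        cfg = SimConfig()
        rng = np.random.default_rng(1)
        n = 10_000
        draws = np.array([sample_te(15.0, cfg, rng) for _ in range(n)])
        counts, _ = np.histogram(draws, bins=cfg.te_bin_edges)
        for obs, p in zip(counts / n, cfg.te_bin_weights[15.0]):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 3 * se + 1e-12

    def test_saline_zero_centered_with_negatives(self):
        cfg = SimConfig()
        rng = np.random.default_rng(2)
        draws = np.array([sample_te(SALINE, cfg, rng) for _ in range(10_000)])
        se = cfg.saline_te_sd / math.sqrt(draws.size)
        assert abs(draws.mean()) < 3 * se
        assert (draws < 0).any() and (draws > 0).any()

    def test_unknown_dose_rejected(self):
        with pytest.raises(ValidationError, match="9.0"):
            sample_te(9.0, SimConfig(), np.random.default_rng(0))


class TestSampleResponse:
    def test_step_extremes(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig()
        assert all(sample_response(10.0, cfg, rng) == 0 for _ in range(100))
        sure = SimConfig(p_response_at_or_above=1.0)
        assert all(sample_response(50.0, sure, rng) == 1 for _ in range(100))

    def test_above_threshold_rate(self):
        cfg = SimConfig()
        rng = np.random.default_rng(3)
        n = 10_000
        frac = np.mean([sample_response(50.0, cfg, rng) for _ in range(n)])
        p = cfg.p_response_at_or_above
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_logistic_model_midpoint(self):
        cfg = SimConfig(response_model="logistic")
        from petpd.simulate import response_probability

        lo, hi = cfg.p_response_below, cfg.p_response_at_or_above
        assert response_probability(cfg.threshold_pct, cfg) == pytest.approx((lo + hi) / 2)
        assert response_probability(200.0, cfg) == pytest.approx(hi, abs=1e-6)


class TestSimulateGrowth:
    def test_flat_noise_free_curve_is_stable_disease(self):
        cfg = SimConfig(
            volume_noise_cv=0.0,
            baseline_volume_cv=0.0,
            growth_rate_responder_mean=0.0,
            growth_rate_responder_sd=0.0,
        )
        res = classify_curve(simulate_growth(1, cfg, np.random.default_rng(0)))
        assert res.label == "mSD" and res.responder == 1

    def test_noise_free_nonresponder_progresses(self):
        cfg = SimConfig(
            volume_noise_cv=0.0,
            baseline_volume_cv=0.0,
            growth_rate_nonresponder_sd=0.0,
        )
        curve = simulate_growth(0, cfg, np.random.default_rng(0))
        # ΔVol at day 14 = 100·(e^{0.09·14} − 1) ≈ +252% → progressive disease
        dv14 = 100 * (math.exp(0.09 * 14) - 1)
        assert curve.volumes_mm3[-1] / curve.volumes_mm3[0] * 100 - 100 == pytest.approx(dv14)
        assert classify_curve(curve).label == "mPD"

    def test_same_substream_reproduces_curve(self):
        cfg = SimConfig()
        c1 = simulate_growth(0, cfg, animal_rng(5, "m1"), "m1")
        c2 = simulate_growth(0, cfg, animal_rng(5, "m1"), "m1")
        assert c1 == c2


class TestSimulateSUV:
    def test_noise_free_inversion(self):
        cfg = SimConfig(suv_noise_cv=0.0)
        for te in (50.0, -30.0, 0.0):
            pre, post = simulate_suv(te, cfg, np.random.default_rng(0))
            assert target_engagement(pre, post) == pytest.approx(te, abs=1e-9)

    def test_observed_te_nearly_unbiased(self):
        """Mean(observed − true) TE stays within the lognormal ratio bias
        bound (exp(σ²) − 1)·(100 − TE) plus 3·SE."""
        cfg = SimConfig()
        rng = np.random.default_rng(4)
        true_te = 40.0
        n = 10_000
        errs = np.empty(n)
        for i in range(n):
            pre, post = simulate_suv(true_te, cfg, rng)
            errs[i] = target_engagement(pre, post) - true_te
        sigma2 = math.log1p(cfg.suv_noise_cv**2)
        bias_bound = (math.exp(sigma2) - 1) * (100 - true_te)
        se = errs.std(ddof=1) / math.sqrt(n)
        assert abs(errs.mean()) < bias_bound + 3 * se

    def test_te_above_100_rejected(self):
        with pytest.raises(ValidationError):
            simulate_suv(101.0, SimConfig(), np.random.default_rng(0))


class TestSimulateCohort:
    def test_bookkeeping(self, default_cohort):
        assert len(default_cohort.truth) == 25  # 10 + 10 + 5
        assert len(default_cohort.growth) == 25 * 5
        assert len(default_cohort.suv) == 25 * 2
        assert (default_cohort.suv[["suv_mean", "suv_max"]] > 0).all().all()

    def test_determinism_bit_identical(self, tmp_path, default_cohort):
        again = simulate_cohort(SimConfig(seed=42))
        p1 = default_cohort.write(tmp_path / "a")
        p2 = again.write(tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_growing_cohort_keeps_existing_animals(self):
        small = simulate_cohort(SimConfig(seed=9, n_per_group=5))
        large = simulate_cohort(SimConfig(seed=9, n_per_group=10))
        merged = small.truth.merge(large.truth, on="animal_id", suffixes=("_s", "_l"))
        assert len(merged) == len(small.truth)
        assert np.allclose(merged["true_te_pct_s"], merged["true_te_pct_l"])

    def test_noise_free_cohort_recovers_labels_exactly(self):
        cfg = SimConfig(
            seed=11,
            p_response_below=0.0,
            p_response_at_or_above=1.0,
            volume_noise_cv=0.0,
            suv_noise_cv=0.0,
            growth_rate_responder_sd=0.0,
            growth_rate_nonresponder_sd=0.0,
        )
        cohort = simulate_cohort(cfg)
        derived = classify_table(cohort.growth).set_index("animal_id")["responder"]
        truth = cohort.truth.set_index("animal_id")["responder_true"].sort_index()
        assert (derived.astype(int).sort_index() == truth).all()

    def test_saline_arm_produces_both_te_signs(self, default_cohort):
        suv_wide = default_cohort.suv.pivot(
            index="animal_id", columns="timepoint", values="suv_mean"
        )
        saline = default_cohort.truth.query("group == 'saline'")["animal_id"]
        te_obs = [
            target_engagement(suv_wide.loc[a, "pre"], suv_wide.loc[a, "post"])
            for a in saline
        ]
        assert any(t < 0 for t in te_obs) and any(t > 0 for t in te_obs)


class TestGeneratorQualityGates:
    def test_label_consistency_at_default_noise(self):
        """mRECIST-derived labels agree with the generative responder label
        for >= 90% of animals, pooled over many simulated cohorts."""
        agree = total = 0
        for seed in range(60):
            cohort = simulate_cohort(SimConfig(seed=seed))
            derived = classify_table(cohort.growth).set_index("animal_id")["responder"]
            truth = cohort.truth.set_index("animal_id")["responder_true"].sort_index()
            agree += int((derived.astype(int).sort_index() == truth).sum())
            total += len(truth)
        assert agree / total >= 0.90

    def test_simulated_auc_matches_analytic_oracle(self):
        """True-TE-vs-true-label AUC at n = 10⁵ matches the numerically
        integrated mixture oracle within 3·SE (Hanley-McNeil)."""
        cfg = SimConfig()
        rng = np.random.default_rng(12)
        n = 100_000
        te = np.empty(n)
        labels = np.empty(n, dtype=int)
        plan = [6.0] * (n * 2 // 5) + [15.0] * (n * 2 // 5) + [SALINE] * (n // 5)
        for i, dose in enumerate(plan):
            te[i] = sample_te(dose, cfg, rng)
            labels[i] = sample_response(te[i], cfg, rng)
        roc = roc_curve(ScoredCohort.from_arrays(te, labels))
        expected = analytic_te_auc(cfg)
        n_pos = labels.sum()
        n_neg = n - n_pos
        a = expected
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        se = math.sqrt(
            (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a))
            / (n_pos * n_neg)
        )
        assert roc.auc == pytest.approx(expected, abs=3 * se)
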