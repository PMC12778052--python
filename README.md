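# petpd — PET target-engagement pharmacodynamics for ADC dosing studies

`petpd` is an analysis pipeline for preclinical studies that use a
receptor-targeted PET tracer to measure how much of its target an
antibody-drug conjugate (ADC) has engaged, and whether that engagement
predicts therapeutic response. The motivating setting is a Nectin-4
tracer imaged before and after a single dose of enfortumab vedotin in
mouse urothelial-carcinoma xenografts, but every stage is generic: any
paired pre/post uptake readout plus longitudinal tumor volumes will do.

The pipeline answers three questions for a dosed cohort:

1. **How much target did the drug engage in each animal?** With tumor
   uptake SUV_pre before and SUV_post after treatment,

   * accessible target (%) = 100 · SUV_post / SUV_pre
   * target engagement TE (%) = 100 · (SUV_pre − SUV_post) / SUV_pre

   The two sum to 100 exactly; TE is negative when uptake rises (a point
   above the diagonal of a post-vs-pre plot — no engagement).

2. **Which animals responded?** Growth curves are classified with
   mouse-adapted mRECIST: ΔVol_t = 100 · (V_t − V_0)/V_0, BestResponse =
   min ΔVol_t over days ≥ 10, BestAvgResponse = the lowest prefix
   average of ΔVol over days ≥ 10. Labels mCR (BestResponse < −95 and
   BestAvgResponse < −40), mPR (< −50 and < −20), mSD (< 35 and < 30),
   else mPD; mPD animals are nonresponders (0), the rest responders (1).

3. **Does engagement predict response, and at what cutoff?** A ROC curve
   of TE against responder labels ("responder if TE ≥ threshold",
   thresholds enumerated at the observed scores), trapezoidal AUC —
   provably equal to Mann-Whitney pairwise concordance with tie credit —
   and the Youden-optimal threshold maximizing J = TPR − FPR, with
   stratified responder rates below vs at-or-above it.

Supporting modules provide radiotracer quantitation primitives (decay
correction, %IA/g from gamma-counter data, SUV, tumor-to-blood ratios,
percent-of-control, logD) and a seeded synthetic cohort generator that
emulates the study design (two dose arms of n = 10 plus 5 saline
controls, baseline volume 170 ± 22 mm³, dose-dependent engagement
mixtures, response probability stepping from 0 to 0.875 at 30% TE).

## Worked example

The numbered scripts under `analysis/` run the whole chain on a
simulated cohort (seed 42) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_target_engagement.py
python analysis/03_response_classification.py
python analysis/04_roc_threshold.py
```

The final script prints:

```
== study-sized cohort (n = 25) ==
AUC = 0.992; Youden threshold = 44.2% TE (J = 0.944)
responders below threshold: 0/17 (0.0%); at/above: 7/8 (87.5%)

== threshold recovery at n = 2,000 ==
AUC = 0.931; Youden threshold = 31.1% TE (J = 0.789)
responders below threshold: 51/1102 (4.6%); at/above: 720/898 (80.2%)
```

Read this as: in a 25-animal cohort TE separates responders from
nonresponders almost perfectly, but the Youden cutoff estimated from 8
responders is noisy (44% here); at n = 2,000 the estimate concentrates
at the generative 30% step. The 0%-vs-87.5% split is the stratified
responder-rate pattern the threshold analysis is designed to expose.

The same chain is available as a CLI:

```bash
petpd simulate --seed 42 --out results/cohort
petpd analyze --growth results/cohort/growth.csv --suv results/cohort/suv.csv \
      --out results/analysis
petpd config-init            # write all generator defaults to sim_config.yaml
```

`analyze` accepts `--stat max` to drive the PD metrics with SUV_max,
and `--score-column`/`--negate` to run the ROC on alternative scores
(e.g. `--score-column suv_post --negate`, since lower post-treatment
uptake predicts response; orientation is never auto-detected).

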