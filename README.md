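# nadopt

Bayesian belief network (BBN) analysis of farmer adoption of nitrogen
best-management practices (BMPs): who adopts practices such as soil testing or
fertigation, which farm and farmer characteristics drive adoption, and how
much engagement-oriented policy interventions (self-certification courses,
information outreach, crop consultants) would raise adoption — overall and for
different types of farms.

The package is aimed at agri-environmental modellers and survey analysts. It
implements the full analysis pipeline as a tested library plus a CLI:

1. **Network model** (`nadopt.bn`, `nadopt.survey_network`) — a discrete BBN
   over nine survey predictors in three blocks (farm characteristics, farmer
   characteristics, engagement), three *latent intermediate nodes* (one per
   block) and one binary adoption target per practice. The intermediates keep
   the target's conditional probability table (CPT) at 3³ = 27 rows instead of
   1152 for nine direct parents. Inference is exact (variable elimination);
   networks read/write losslessly as XMLBIF.
2. **Learning** (`nadopt.em`) — EM estimation of all CPTs from incomplete
   survey tables, including the fully latent intermediates, with Dirichlet
   smoothing and seeded random restarts.
3. **Validation** (`nadopt.validation`) — repeated 70/30 train/test splits
   scoring the Error Rate and the *Prediction Improvement Value*

   PIV = min(AdoptionRate, 1 − AdoptionRate) − ErrorRate,

   the gain over always predicting the majority state. Practices are tiered:
   PIV < 0 *not meaningful*, 0–0.10 *reliable*, > 0.10 *especially reliable*.
4. **Sensitivity** (`nadopt.sensitivity`) — mutual information (bits) between
   each practice and each predictor on the fitted joint, with influence
   directions and cross-practice means.
5. **Policy experiments** (`nadopt.interventions`) — *full* interventions
   (everyone engaged) and *normalized* interventions (+10 percentage points of
   engaged farmers), implemented as do-operations, evaluated per farm type
   (3-letter codes: L/S size, P/A crop, P/N irrigation; "S" pools small and
   medium farms).
6. **Synthetic surveys** (`nadopt.synthetic`) — the original survey is not
   public, so a calibrated generator reproduces its printed margins exactly
   (farm-type composition; engagement by farm size: self-certification 79%
   large vs 47% small/medium, information sources 54% vs 36%, consultant 38%
   vs 42%) and ships scenario fixtures for end-to-end testing.

## Worked example

```bash
nadopt run-all --scenario calibrated --seed 7 --out results/demo \
    --practice soil_testing --practice fertigation --practice variable_rate_gps
```

prints

```
retained (PIV >= 0): ['soil_testing', 'fertigation', 'variable_rate_gps']
especially reliable: ['soil_testing', 'fertigation']
reports under results/demo
```

and `results/demo/validation.csv` contains

```
practice,adoption_rate,mean_error_rate,mean_piv,tier
soil_testing,0.4446742502585315,0.27379310344827584,0.17088114681025562,especially_reliable
fertigation,0.4591520165460186,0.2517241379310345,0.20742787861498413,especially_reliable
variable_rate_gps,0.07652533609100311,0.07310344827586208,0.003421887815141035,reliable
```

Reading: soil testing is adopted by 44% of the synthetic farms; entering each
test farm's characteristics cuts the prediction error from the base-rate 44%
to 27%, a PIV of 0.171 (> 0.10, "especially reliable"), so the practice
qualifies for the policy experiments. Variable-rate GPS adoption is rare
(8%) and its predictors barely beat the base rate (PIV ≈ 0.003). The bundle
also contains the per-predictor mutual-information ranking
(`sensitivity.csv`) and the intervention table (`interventions.csv`); in it,
the full self-certification intervention raises soil-testing adoption by
18.1 pp for small/medium perennial-pressurized (SPP) farms but only 8.1 pp
for their large counterparts (LPP), whose baseline certification rate is
already high. Identical seeds and configurations give byte-identical
reports.

The same pipeline runs on a real survey CSV (`nadopt run-all --csv ...`);
`nadopt.survey_network.discretize_survey` maps raw columns (acres, dollars,
years, counts) onto the model's states (cuts at 50/200 acres, 50k/500k $,
medians 36 years and 4 information sources).

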