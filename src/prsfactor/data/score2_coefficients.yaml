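# SCORE2 10-year CVD risk model: sex-specific log-hazard-ratio weights,
# baseline survivals and low-risk-region recalibration scales, as published
# by the SCORE2 working group and ESC Cardiovascular Risk Collaboration
# (Eur Heart J 2021;42:2439-2454, supplementary methods tables).
# Predictors are transformed as (value - center) / scale before weighting;
# each *_age term multiplies the transformed predictor by transformed age.
provenance: >-
  SCORE2 working group and ESC CVD risk collaboration, Eur Heart J 2021;
  42:2439-2454. Sex-specific coefficients (supplementary table), baseline
  10-year survivals, and low-risk-region recalibration scales.
transformations:
  age: {center: 60.0, scale: 5.0}
  sbp: {center: 120.0, scale: 20.0}
  total_chol: {center: 6.0, scale: 1.0}
  hdl: {center: 1.3, scale: 0.5}
male:
  coefficients:
    age: 0.3742
    smoking: 0.6012
    sbp: 0.2777
    total_chol: 0.1458
    hdl: -0.2698
    smoking_age: -0.0755
    sbp_age: -0.0255
    total_chol_age: -0.0281
    hdl_age: 0.0426
  baseline_survival: 0.9605
  scale1: -0.5699
  scale2: 0.7476
female:
  coefficients:
    age: 0.4648
    smoking: 0.7744
    sbp: 0.3131
    total_chol: 0.1002
    hdl: -0.2606
    smoking_age: -0.1088
    sbp_age: -0.0277
    total_chol_age: -0.0226
    hdl_age: 0.0613
  baseline_survival: 0.9776
  scale1: -0.7380
  scale2: 0.7019
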