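# Sex-specific 10-year coronary heart disease risk equations in the
# Framingham parametric survival form
#
#     risk10 = 1 - S0 ^ exp(LP - LP_mean)
#
# Coefficients transcribed from the published Framingham risk-factor-category
# functions (Wilson et al., Circulation 1998;97:1837-47), total-cholesterol
# variant, "hard + soft CHD" endpoint.  This is the categorical variant:
# age enters continuously (women also carry an age^2 term); total and HDL
# cholesterol and blood pressure enter through category tables.  Blood
# pressure staging uses both systolic and diastolic pressure, taking the
# higher category when they disagree.
#
# The engine works in mmol/l and mmHg; the equations are native to mg/dl,
# so the declared unit conversions are applied to cholesterol covariates
# before binning.  Category bins are right-open: value < upper belongs to
# the bin; .inf closes the last bin.
name: framingham-chd-1998-categorical
sex_specific: true
unit_conversions:
  total_cholesterol: 38.67   # mmol/l -> mg/dl
  hdl_cholesterol: 38.67
guard_ranges:               # outside these a warning is issued, not an error
  age: [30.0, 74.0]
  total_cholesterol: [2.0, 15.0]   # mmol/l
  hdl_cholesterol: [0.3, 4.0]      # mmol/l
  systolic_bp: [70.0, 250.0]
  diastolic_bp: [40.0, 150.0]
equations:
  male:
    baseline_survival: 0.90015
    mean_linear_predictor: 3.0975
    terms:
      - covariate: age
        transform: identity
        coefficient: 0.04826
      - covariate: total_cholesterol
        transform: category_table
        bins: [160.0, 200.0, 240.0, 280.0, .inf]
        coefficients: [-0.65945, 0.0, 0.17692, 0.50539, 0.65713]
      - covariate: hdl_cholesterol
        transform: category_table
        bins: [35.0, 45.0, 50.0, 60.0, .inf]
        coefficients: [0.49744, 0.24310, 0.0, -0.05107, -0.48660]
      - covariate: blood_pressure
        transform: category_table
        bins_systolic: [120.0, 130.0, 140.0, 160.0, .inf]
        bins_diastolic: [80.0, 85.0, 90.0, 100.0, .inf]
        coefficients: [-0.00226, 0.0, 0.28320, 0.52168, 0.61859]
      - covariate: diabetic
        transform: identity
        coefficient: 0.42839
      - covariate: smoker
        transform: identity
        coefficient: 0.52337
  female:
    baseline_survival: 0.96246
    mean_linear_predictor: 9.92545
    terms:
      - covariate: age
        transform: identity
        coefficient: 0.33766
      - covariate: age
        transform: squared
        coefficient: -0.00268
      - covariate: total_cholesterol
        transform: category_table
        bins: [160.0, 200.0, 240.0, 280.0, .inf]
        coefficients: [-0.26138, 0.0, 0.20771, 0.24385, 0.53513]
      - covariate: hdl_cholesterol
        transform: category_table
        bins: [35.0, 45.0, 50.0, 60.0, .inf]
        coefficients: [0.84312, 0.37796, 0.19785, 0.0, -0.42951]
      - covariate: blood_pressure
        transform: category_table
        bins_systolic: [120.0, 130.0, 140.0, 160.0, .inf]
        bins_diastolic: [80.0, 85.0, 90.0, 100.0, .inf]
        coefficients: [-0.53363, 0.0, -0.06773, 0.26288, 0.46573]
      - covariate: diabetic
        transform: identity
        coefficient: 0.59626
      - covariate: smoker
        transform: identity
        coefficient: 0.29246
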