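# Global allometries for predicting per-tree leaf area (LA, m²) and leaf dry
# mass (LM, kg) from a crown-base stem cross-sectional area (m²), in the form
#   Y = CF * elevation * X^slope
# with 95% prediction intervals exp[ln(elevation * X^slope) ± ΔPI] where
#   quadratic form: ΔPI = c0 + c1*u + c2*u²            (u = ln X)
#   ls form:        ΔPI = c0*c1*sqrt(1 + 1/c2 + (u - c3)²/c4)
#
# Coefficients were fitted across 962 trees of 159 species from tropical to
# boreal forests; LA uses a single pooled equation (species as a random
# intercept), LM one equation per plant functional type.  data_range gives
# soft predictor bounds (m²) beyond which predictions warn as extrapolation.
# Site-specific registries may be written in this same schema.
allometries:
  pipe_la_pooled:
    response: LA
    predictor: A_CB
    scope: pooled
    elevation: 2370.0
    slope: 0.940
    cf: 1.065
    n: 768
    data_range: [1.0e-06, 2.0]
    pi: {form: quadratic, c0: 0.71655, c1: 0.00590, c2: 0.00052, residual_se: 0.00002}
  qpipe_la_pooled:
    response: LA
    predictor: A_CB_Est
    scope: pooled
    elevation: 2742.0
    slope: 0.955
    cf: 1.077
    n: 768
    data_range: [1.0e-06, 2.0]
    pi: {form: quadratic, c0: 0.77894, c1: 0.00622, c2: 0.00054, residual_se: 0.00002}
  qpipe_lm_EC:
    response: LM
    predictor: A_CB_Est
    scope: per-PFT
    pft: EC
    elevation: 854.4
    slope: 1.078
    cf: 1.023
    n: 221
    data_range: [1.0e-06, 2.0]
    pi: {form: quadratic, c0: 0.48920, c1: 0.01772, c2: 0.00181, residual_se: 0.00002}
  qpipe_lm_DC:
    response: LM
    predictor: A_CB_Est
    scope: per-PFT
    pft: DC
    elevation: 571.4
    slope: 1.172
    cf: 1.059
    n: 57
    data_range: [1.0e-06, 2.0]
    pi: {form: ls, c0: 2.004, c1: 0.3389, c2: 57.0, c3: -5.206, c4: 62.89}
  qpipe_lm_EB:
    response: LM
    predictor: A_CB_Est
    scope: per-PFT
    pft: EB
    elevation: 293.8
    slope: 0.973
    cf: 1.073
    n: 447
    data_range: [1.0e-06, 2.0]
    pi: {form: quadratic, c0: 0.78223, c1: 0.01286, c2: 0.00112, residual_se: 0.00007}
  qpipe_lm_DB:
    response: LM
    predictor: A_CB_Est
    scope: per-PFT
    pft: DB
    elevation: 180.3
    slope: 1.017
    cf: 1.073
    n: 227
    data_range: [1.0e-06, 2.0]
    pi: {form: quadratic, c0: 0.81205, c1: 0.01924, c2: 0.00159, residual_se: 0.00007}
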