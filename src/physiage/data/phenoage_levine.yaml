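# Phenotypic-age mapping constants, transcribed from an external source
# (Levine et al. 2018, "An epigenetic biomarker of aging for lifespan and
# healthspan", Aging 10:573-591). These values are NOT derived in this
# package; they are shipped as reference data so that cohort tables can be
# scored with the standard published mapping. Units are declared explicitly
# and enforced at compute time.
name: levine-2018-phenoage
intercept: -19.907
weights:
  albumin: -0.0336        # g/L
  creatinine: 0.0095      # umol/L
  glucose: 0.1953         # mmol/L
  crp_ln: 0.0954          # ln(mg/dL)
  lymphocyte_pct: -0.0120 # percent
  mcv: 0.0268             # fL
  rdw: 0.3306             # percent
  alp: 0.00188            # U/L
  wbc: 0.0554             # 10^3 cells/uL
age_weight: 0.0804        # years
gompertz_gamma: 0.0076927
horizon_months: 120
outer_a: 141.50225
outer_b: -0.00553
outer_c: 0.090165
units:
  albumin: g/L
  creatinine: umol/L
  glucose: mmol/L
  crp_ln: ln(mg/dL)
  lymphocyte_pct: percent
  mcv: fL
  rdw: percent
  alp: U/L
  wbc: 10^3 cells/uL
  age: years
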