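# Coefficient tables for the eight GFR estimating equations, transcribed
# from the primary publications so they can be diffed against the sources.
# CKD-EPI family: eGFR = intercept * min(m/kappa,1)^alpha_low
#                                  * max(m/kappa,1)^alpha_high  (per marker)
#                                  * age_base^age * sex_multiplier
#   creatinine in mg/dl, cystatin C in mg/l.  The published Black-race
#   multiplier of the 2009/2012 equations is not part of these tables:
#   the equations are applied in sex+age form only.
# EKFC family: eGFR = 107.3 * (m/Q)^exp * 0.990^(age-40) for age > 40,
#   with exp = -0.322 below m/Q = 1 and -1.132 above; creatinine Q in
#   umol/l (sex-specific adult value, polynomial in age below 25),
#   cystatin C Q in mg/l (sex-free, age-adjusted above 50).

ckdepi_2009_creat:          # Levey et al. 2009, creatinine
  source: CKD-EPI 2009 creatinine equation
  markers: [creatinine]
  intercept: 141.0
  age_base: 0.993
  female_multiplier: 1.018
  creatinine:
    kappa: {female: 0.7, male: 0.9}      # mg/dl
    alpha_low: {female: -0.329, male: -0.411}
    alpha_high: {female: -1.209, male: -1.209}

ckdepi_2012_cys:            # Inker et al. 2012, cystatin C
  source: CKD-EPI 2012 cystatin C equation
  markers: [cystatin_c]
  intercept: 133.0
  age_base: 0.996
  female_multiplier: 0.932
  cystatin_c:
    kappa: {female: 0.8, male: 0.8}      # mg/l
    alpha_low: {female: -0.499, male: -0.499}
    alpha_high: {female: -1.328, male: -1.328}

ckdepi_2012_comb:           # Inker et al. 2012, creatinine + cystatin C
  source: CKD-EPI 2012 creatinine-cystatin C equation
  markers: [creatinine, cystatin_c]
  intercept: 135.0
  age_base: 0.995
  female_multiplier: 0.969
  creatinine:
    kappa: {female: 0.7, male: 0.9}
    alpha_low: {female: -0.248, male: -0.207}
    alpha_high: {female: -0.601, male: -0.601}
  cystatin_c:
    kappa: {female: 0.8, male: 0.8}
    alpha_low: {female: -0.375, male: -0.375}
    alpha_high: {female: -0.711, male: -0.711}

ckdepi_2021_creat:          # Inker et al. 2021, race-free creatinine refit
  source: CKD-EPI 2021 creatinine equation
  markers: [creatinine]
  intercept: 142.0
  age_base: 0.9938
  female_multiplier: 1.012
  creatinine:
    kappa: {female: 0.7, male: 0.9}
    alpha_low: {female: -0.241, male: -0.302}
    alpha_high: {female: -1.200, male: -1.200}

ckdepi_2021_comb:           # Inker et al. 2021, race-free combined refit
  source: CKD-EPI 2021 creatinine-cystatin C equation
  markers: [creatinine, cystatin_c]
  intercept: 135.0
  age_base: 0.9961
  female_multiplier: 0.963
  creatinine:
    kappa: {female: 0.7, male: 0.9}
    alpha_low: {female: -0.219, male: -0.144}
    alpha_high: {female: -0.544, male: -0.544}
  cystatin_c:
    kappa: {female: 0.8, male: 0.8}
    alpha_low: {female: -0.323, male: -0.323}
    alpha_high: {female: -0.778, male: -0.778}

ekfc_creat:                 # Pottel et al. 2021, full-age-spectrum rescaled creatinine
  source: EKFC creatinine equation
  markers: [creatinine]
  intercept: 107.3
  exponent_low: -0.322      # marker/Q < 1
  exponent_high: -1.132     # marker/Q >= 1
  age_base: 0.990
  age_onset: 40.0
  q_adult: {female: 62.0, male: 80.0}    # umol/l, age >= 25
  # ln Q polynomial in age, valid 2 <= age < 25
  q_poly:
    male:   {c0: 3.200, c1: 0.259, clog: -0.543, c2: -0.00763, c3: 0.0000790}
    female: {c0: 3.080, c1: 0.177, clog: -0.223, c2: -0.00596, c3: 0.0000686}

ekfc_cys:                   # Pottel et al. 2023, sex-free rescaled cystatin C
  source: EKFC cystatin C equation
  markers: [cystatin_c]
  intercept: 107.3
  exponent_low: -0.322
  exponent_high: -1.132
  age_base: 0.990
  age_onset: 40.0
  q_base: 0.83              # mg/l, age < 50
  q_age_slope: 0.005        # per year above 50

ekfc_comb:                  # arithmetic mean of the two single-marker EKFC estimates
  source: EKFC combined (mean of creatinine and cystatin C estimates)
  markers: [creatinine, cystatin_c]
  components: [ekfc_creat, ekfc_cys]
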