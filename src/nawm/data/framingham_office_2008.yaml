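# Office-based (non-laboratory) general cardiovascular disease 10-year risk
# profile: weighted sum of log age, log BMI, log SBP (treated/untreated),
# current smoking and diabetes, sex-stratified, transformed through the
# baseline survival s0 as risk% = 100*(1 - s0^exp(lp - lp_mean)).
# Shipped as versioned configuration so the weighting is auditable and
# swappable; the pipeline treats it as opaque coefficients.
name: general-cvd-office-bmi-2008
strata:
  male:
    s0: 0.88431
    lp_mean: 23.9388
    terms:
      log_age: 3.11296
      log_bmi: 0.79277
      log_sbp_untreated: 1.85508
      log_sbp_treated: 1.92672
      smoker: 0.70953
      diabetes: 0.53160
  female:
    s0: 0.94833
    lp_mean: 26.0145
    terms:
      log_age: 2.72107
      log_bmi: 0.51125
      log_sbp_untreated: 2.81291
      log_sbp_treated: 2.88267
      smoker: 0.61868
      diabetes: 0.77763
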