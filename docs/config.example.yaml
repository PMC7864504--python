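# Diagnostic and decision-rule thresholds (mmol/L unless noted).
# Any key may be omitted; defaults shown.
thresholds:
  fpg_gdm: 5.1        # FPG rule-in / GDM band lower edge
  fpg_dip: 7.0        # FPG overt-diabetes threshold
  pg1h_gdm: 10.0      # 1 h GDM criterion (no 1 h DIP criterion exists)
  pg2h_gdm: 8.5       # 2 h GDM band lower edge
  pg2h_dip: 11.1      # 2 h overt-diabetes threshold
  fpg_band_low: 4.7   # lower edge of the OGTT-triggering triage band
  bmi_obesity: 30     # risk factor: BMI strictly above this (kg/m2)
  age_risk: 40        # risk factor: age at or above this (years)
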