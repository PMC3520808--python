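# Synthetic Knudson-style FEV1 prediction equations (illustrative stand-in).
# Structure mirrors the classic sex/age-stratified linear spirometry
# references: predicted_fev1_l = intercept + age_coef*age_years + height_coef*height_cm.
# These coefficients are NOT transcribed from any published table; substitute
# a published reference (e.g. Knudson 1983 or GLI-2012) for clinical use by
# pointing the loader at your own CSV with this schema.
# units: age in years, height in cm, prediction in liters.
sex,age_lo,age_hi,intercept,age_coef,height_coef
M,6,12,-2.80,0.010,0.035
M,12,25,-5.50,0.040,0.050
M,25,85,-4.50,-0.028,0.055
F,6,11,-2.60,0.008,0.033
F,11,20,-3.80,0.030,0.040
F,20,85,-2.60,-0.022,0.037
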