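# Synthetic WHO-2007-style BMI LMS reference (illustrative stand-in for a
# healthy population; NOT transcribed from the WHO tables — substitute the
# published WHO 2007 LMS table with this schema for clinical use).
# z = ((x/M)^L - 1)/(L*S), L=0 -> ln(x/M)/S.  Linear interpolation in age.
# units: age in years, M in kg/m^2, L and S dimensionless.
sex,age_years,L,M,S
M,0,-0.30,13.8,0.085
M,1,-0.40,17.3,0.080
M,3,-0.50,16.2,0.080
M,6,-0.70,15.6,0.085
M,10,-0.90,16.8,0.105
M,14,-1.00,19.2,0.115
M,18,-1.00,21.5,0.115
M,25,-0.95,23.2,0.115
M,30,-0.90,24.0,0.115
M,40,-0.90,24.6,0.115
F,0,-0.25,13.5,0.085
F,1,-0.35,16.9,0.080
F,3,-0.45,15.9,0.080
F,6,-0.65,15.4,0.090
F,10,-0.95,16.9,0.110
F,14,-1.10,19.4,0.120
F,18,-1.10,21.3,0.120
F,25,-1.00,22.5,0.120
F,30,-0.95,23.2,0.120
F,40,-0.95,23.8,0.120
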