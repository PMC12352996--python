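# Age-dependent organ-size factors relative to the weight-proportional
# adult fraction: V_organ(age) = V_adult * (W/W_adult) * factor(age).
# Interpolated linearly in age; organs not listed use factor 1 at all ages.
# Derived from ICRP-style reference organ masses at tabulated ages.
organ,age0,age1,age5,age10,age15,adult
brain,5.2,4.4,3.2,1.9,1.16,1.0
liver,1.55,1.33,1.22,1.02,0.95,1.0
kidney,1.80,1.67,1.40,1.30,1.06,1.0
muscle,0.50,0.55,0.70,0.80,0.95,1.0
adipose,0.65,1.25,0.85,0.85,0.90,1.0
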