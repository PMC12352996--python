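# Hill maturation functions for enzyme expression, fraction of adult:
#   F(age) = PMA^hill / (PMA^hill + tm50^hill),  PMA in weeks (age*52.14 + 40)
# Literature-based defaults standing in for proprietary ontogeny databases;
# all values overridable through the scenario configuration.
enzyme,tm50_pma_weeks,hill
UGT1A9,60,3.0
UGT2B7,50,2.5
UGT1A3,55,3.0
CYP3A4,60,2.0
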