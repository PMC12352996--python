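# Physiological scaling factors by Child-Pugh grade. Flow and volume rows
# are fractions of the healthy value; hematocrit is absolute; enzyme rows
# are reference-concentration multipliers except cyp3a4_conc, which is the
# absolute reference concentration in umol/L liver.
parameter,healthy,cp_a,cp_b,cp_c
portal_flow,1,0.40,0.36,0.04
hepatic_arterial_flow,1,1.30,2.30,3.40
renal_flow,1,0.88,0.65,0.48
brain_flow,1,1,1,1
other_organ_flow,1,1.75,2.25,2.75
liver_volume,1,0.69,0.55,0.28
hematocrit,0.47,0.39,0.37,0.35
albumin,1,0.81,0.68,0.50
agp,1,0.60,0.56,0.30
ugt1a9_conc,1,1,0.48,0.28
ugt2b7_conc,1,1,0.30,0.13
cyp3a4_conc,4.32,4.32,0.86,0.86
gfr,1,1,0.70,0.36
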