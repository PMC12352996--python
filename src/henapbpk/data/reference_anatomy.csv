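# Reference adult male (30 y, East Asian anthropometry: 63 kg, 170 cm).
# Organ volumes (L) and regional blood flows as fractions of cardiac output,
# adapted from ICRP-style reference tables scaled to 63 kg body weight.
# Cardiac output reference: 340 L/h. Splanchnic organs (stomach, small/large
# intestine, spleen, pancreas) drain to the portal vein; the liver receives
# hepatic arterial flow plus the pooled portal flow.
organ,volume_l,flow_fraction_co
lung,0.46,1.0
brain,1.40,0.120
heart,0.29,0.040
kidney,0.27,0.190
muscle,25.0,0.170
adipose,12.6,0.050
skin,2.90,0.050
bone,9.10,0.050
gonads,0.03,0.0005
stomach,0.13,0.010
small_intestine,0.55,0.100
large_intestine,0.32,0.040
spleen,0.13,0.030
pancreas,0.12,0.010
liver,1.60,0.065
rest,2.00,0.0745
arterial_blood,1.10,0
venous_blood,3.55,0
portal_vein,0.25,0
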