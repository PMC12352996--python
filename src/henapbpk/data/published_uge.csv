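# Published 24-h urinary glucose excretion (g, mean and SD) corresponding
# to the exposure operating points in published_exposure.csv, used to verify
# the Emax exposure-response implementation cell-for-cell.
group,dose_mg,uge_cmax,uge_cmax_sd,uge_auc,uge_auc_sd
adult,5,28.64,4.76,30.10,7.44
adult,10,36.10,6.00,37.06,9.16
adolescent,5,29.68,5.36,31.49,8.23
adolescent,10,36.91,6.66,38.09,9.96
child,1.25,21.16,5.77,22.51,7.62
child,2.5,29.52,8.05,30.69,10.39
child,5,36.79,10.03,37.50,12.70
child,10,41.95,11.44,42.18,14.28
infant_toddler,1.25,32.50,16.20,35.18,23.43
infant_toddler,2.5,39.01,19.45,40.67,27.09
infant_toddler,5,43.36,21.62,44.12,29.38
infant_toddler,10,45.92,22.90,46.07,30.68
neonate,1.25,41.11,8.08,43.09,13.21
neonate,2.5,44.63,8.77,45.50,13.95
neonate,5,46.62,9.16,46.82,14.35
neonate,10,47.69,9.37,47.50,14.56
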