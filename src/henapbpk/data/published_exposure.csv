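# Published steady-state exposure operating points (population mean and SD)
# for henagliflozin once-daily regimens, by age group and dose. These serve
# as inputs to the exposure-response and dose-matching worked examples.
group,dose_mg,cmax_ss,cmax_ss_sd,auc_ss,auc_ss_sd
adult,5,88.09,14.64,592.02,146.27
adult,10,176.18,29.28,1184.03,292.54
adolescent,5,96.27,17.37,670.61,175.38
adolescent,10,192.54,34.74,1341.23,350.76
child,1.25,47.47,12.95,311.96,105.63
child,2.5,94.93,25.89,623.92,211.26
child,5,189.87,51.78,1247.84,422.52
child,10,379.73,103.56,2495.68,845.05
infant_toddler,1.25,123.6,61.61,961.6,640.45
infant_toddler,2.5,247.19,123.22,1923.21,1280.91
infant_toddler,5,494.38,246.45,3846.41,2561.81
infant_toddler,10,988.77,492.89,7692.83,5123.63
neonate,1.25,331.47,65.16,2999.04,919.3
neonate,2.5,662.93,130.32,5998.09,1838.6
neonate,5,1325.87,260.64,11996.18,3677.2
neonate,10,2651.73,521.27,23992.33,7354.4
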