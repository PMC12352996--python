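# Age-weight/height growth reference (East Asian), linear interpolation
# between rows; constant after the last pediatric age.
age_years,weight_m_kg,weight_f_kg,height_m_cm,height_f_cm
0.0,3.3,3.2,50,49
0.077,4.5,4.2,54,53
0.25,6.7,6.2,62,60
0.5,8.0,7.4,68,66
1.0,9.8,9.2,75,74
2.0,12.2,11.6,87,86
3.0,14.3,13.9,96,95
5.0,18.4,17.9,110,109
8.0,25.5,25.0,128,127
10.0,31.9,31.5,138,139
12.0,39.5,40.0,149,151
15.0,55.0,50.0,168,157
18.0,61.0,54.0,170,158
30.0,63.0,55.0,170,158
60.0,63.0,55.0,170,158
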