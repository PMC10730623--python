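case,age_years,area_mm2,cc_density_pct,mean_cc_diameter_um,arteriole_density_per_mm2,venule_density_per_mm2
1,88,5.07,74.4,17.2,15.7,30.1
2,67,3.4,73.1,17.7,9.9,23.4
3,88,1.2,71.6,19.1,7.4,12.3
4,>89,2.9,71.8,19.7,7.1,27.2
5,88,1.3,64.9,18.1,6.2,11.6
6,75,5.0,73.0,21.0,5.2,12.6
7,75,4.9,68.1,20.5,6.2,14.0
8,>89,4.4,74.5,19.0,3.6,11.9
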