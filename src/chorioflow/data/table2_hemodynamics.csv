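case,ess_ave_pa,ess_mean_pa,ess_med_pa,vel_ave_mm_s,vel_mean_mm_s,vel_med_mm_s,dp_ave_mmhg,dp_mean_mmhg,dp_med_mmhg
1,1.84,0.91,0.73,1.33,0.61,0.71,6.5,6.5,6.7
2,1.78,0.68,0.41,1.44,0.35,0.37,7,7,7.4
3,1.79,0.73,0.48,0.97,0.45,0.54,7.2,7.2,7.5
4,3.71,2.06,1.31,1.70,0.69,0.89,8.2,8.2,8.7
5,1.26,0.52,0.33,2.00,0.80,0.97,7.5,7.5,7.9
6,1.40,0.55,0.42,1.51,0.61,0.73,7.4,7.4,7.9
7,1.23,0.47,0.38,2.48,1.29,1.50,7.9,7.9,7.8
8,1.06,0.38,0.30,2.00,0.77,0.91,7.4,7.4,8.3
weighted_average,1.69,0.75,0.54,1.73,0.73,0.86,7.4,7.4,7.7
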