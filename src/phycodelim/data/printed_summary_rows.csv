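table,strain,quantity,value,se
table2_percent,VP336,SFA,25.59,0.36
table2_percent,VP336,MUFA,5.07,0.08
table2_percent,VP336,PUFA,69.34,1.35
table2_percent,VP336,Omega-3,62.64,1.23
table2_percent,VP336,Omega-6,6.70,0.12
table2_percent,VP336,Omega-3/omega-6,9.3,
table2_percent,VP339,SFA,14.09,0.29
table2_percent,VP339,MUFA,10.80,0.23
table2_percent,VP339,PUFA,75.11,1.39
table2_percent,VP339,Omega-3,55.61,1.26
table2_percent,VP339,Omega-6,19.50,0.13
table2_percent,VP339,Omega-3/omega-6,2.6,
table2_percent,VP521,SFA,23.21,0.60
table2_percent,VP521,MUFA,8.83,0.17
table2_percent,VP521,PUFA,67.96,1.75
table2_percent,VP521,Omega-3,56.04,1.53
table2_percent,VP521,Omega-6,11.92,0.23
table2_percent,VP521,Omega-3/omega-6,4.7,
table2_percent,VP449,SFA,34.31,1.0
table2_percent,VP449,MUFA,5.11,0.09
table2_percent,VP449,PUFA,60.58,0.81
table2_percent,VP449,Omega-3,34.48,0.74
table2_percent,VP449,Omega-6,26.10,0.29
table2_percent,VP449,Omega-3/omega-6,1.3,
table3_mg_per_l,VP336,SFA,97.69,3.42
table3_mg_per_l,VP336,MUFA,19.36,0.40
table3_mg_per_l,VP336,PUFA,264.60,5.72
table3_mg_per_l,VP336,Omega-3,239.03,5.01
table3_mg_per_l,VP336,Omega-6,25.57,0.72
table3_mg_per_l,VP336,Omega-3/omega-6,9.4,
table3_mg_per_l,VP339,SFA,245.68,6.86
table3_mg_per_l,VP339,MUFA,188.49,2.96
table3_mg_per_l,VP339,PUFA,1311.05,28.72
table3_mg_per_l,VP339,Omega-3,970.54,22.37
table3_mg_per_l,VP339,Omega-6,340.51,6.36
table3_mg_per_l,VP339,Omega-3/omega-6,2.9,
table3_mg_per_l,VP521,SFA,138.16,4.60
table3_mg_per_l,VP521,MUFA,52.57,1.18
table3_mg_per_l,VP521,PUFA,404.54,8.73
table3_mg_per_l,VP521,Omega-3,333.61,7.03
table3_mg_per_l,VP521,Omega-6,70.93,1.71
table3_mg_per_l,VP521,Omega-3/omega-6,4.7,
table3_mg_per_l,VP449,SFA,82.10,1.84
table3_mg_per_l,VP449,MUFA,12.23,0.24
table3_mg_per_l,VP449,PUFA,145.02,2.42
table3_mg_per_l,VP449,Omega-3,82.53,1.27
table3_mg_per_l,VP449,Omega-6,62.49,1.19
table3_mg_per_l,VP449,Omega-3/omega-6,1.3,
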