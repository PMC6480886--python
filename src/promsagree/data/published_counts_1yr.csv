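condition,both,admin_only,patient_only,neither
heart_disease,56736,65460,10689,543543
high_blood_pressure,249608,86350,33177,307293
stroke,2367,4981,8759,660321
leg_pain_poor_circulation,2855,8063,45444,620067
lung_disease,46876,53384,8841,567327
diabetes,68952,9864,7046,590566
kidney_disease,6910,29913,5542,634080
nervous_system_disease,4092,15458,1748,655130
liver_disease,1412,2708,2173,670135
cancer,8740,3970,23644,640074
depression,18263,11660,43326,603179
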