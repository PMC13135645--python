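patient_id,fistula_type,side,outcome,venous_outflow_ml_min,outflow_category,fa_diameter_mm,fa_curvature,dv_diameter_mm,dv_curvature,anastomosis_angle_deg
#71,BCF,left,S,1507,High,6.07,0.013,8.06,0.044,64.7
#69,BCF,left,S,1277,High,4.81,0.028,7.94,0.022,75.8
#60,BCF,left,S,1783,High,6.724,0.014,7.9,0.035,80.4
#40,BCF,left,S,1361,High,5.23,0.018,7.18,0.036,91.4
#77,RCF,left,S,862,Low,3.11,0.045,4.63,0.062,24
#65,RCF,left,S,1753,High,3.84,0.021,8.27,0.036,26.1
#87,RCF,left,S,599,Low,2.64,0.036,5.51,0.036,31.5
#06,RCF,left,S,1033,High,5.00,0.024,4.89,0.038,59.4
#57,RCF,left,S,454,Low,4.64,0.045,3.92,0.026,60.1
#18,RCF,left,S,829,Low,4.80,0.025,6.78,0.042,61.6
#64,RCF,left,S,906,Low,2.92,0.045,4.62,0.036,72.2
#34,RCF,left,S,705,Low,3.72,0.06,6.24,0.055,72.9
#45,BBF,right,S,2864,High,7.73,0.02,8.25,0.029,81.1
#44,BCF,left,U,47,Low,2.75,0.046,2.83,0.075,94.9
#79,RCF,left,U,577,Low,2.23,0.035,5.45,0.054,60
#72,RCF,left,U,1368,High,5.83,0.067,7.23,0.055,80.1
#80,BCF,right,U,694,Low,5.92,0.02,8.64,0.037,68.2
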