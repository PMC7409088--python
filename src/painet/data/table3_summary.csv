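item_id,role,missing_pct,cat1_pct,cat2_pct,cat3_pct,cat4_pct,agreement_pct,weighted_kappa,concordance
PL1,child,33.0,84.4,14.1,1.5,0.0,81.6,0.10,0.48
PL1,parent,8.5,77.9,17.4,3.5,1.2,90.1,0.73,0.48
PL2,child,1.6,73.9,23.9,1.6,0.5,69.6,0.18,0.57
PL2,parent,1.1,53.2,37.1,9.1,0.5,73.3,0.64,0.57
PL3,child,1.0,50.8,36.0,13.2,0.0,60.9,0.49,0.57
PL3,parent,0.5,26.7,54.0,18.7,0.5,70.7,0.65,0.57
SC1,child,0.5,84.7,11.6,3.7,0.0,85.9,0.41,0.67
SC1,parent,0.0,67.0,27.1,5.9,0.0,80.5,0.71,0.67
SC2,child,1.0,84.7,13.8,1.6,0.0,82.6,0.35,0.59
SC2,parent,0.0,60.6,33.5,5.9,0.0,75.0,0.60,0.59
SC3,child,3.7,86.4,12.5,1.1,0.0,85.4,0.34,0.59
SC3,parent,2.7,59.6,30.6,7.7,2.2,72.8,0.60,0.59
SC4,child,6.3,87.2,11.2,1.1,0.6,85.2,0.39,0.62
SC4,parent,1.1,71.5,23.1,4.3,1.1,74.9,0.55,0.62
SC5,child,7.9,92.6,4.5,2.3,0.6,85.9,0.24,0.55
SC5,parent,1.6,72.4,19.5,8.1,0.0,74.6,0.64,0.55
SC6,child,6.3,64.2,31.8,3.9,0.0,73.0,0.45,0.63
SC6,parent,1.6,35.7,42.7,19.5,2.2,66.1,0.66,0.63
MO1,child,4.2,66.7,25.7,2.7,4.9,74.1,0.60,0.75
MO1,parent,1.6,53.0,30.8,11.4,4.9,77.4,0.76,0.75
MO2,child,2.1,71.1,21.9,5.9,1.1,73.4,0.42,0.61
MO2,parent,3.2,36.8,37.9,19.8,5.5,63.9,0.64,0.61
MO3,child,10.5,68.4,19.9,4.7,7.0,69.7,0.53,0.66
MO3,parent,2.7,25.7,43.7,24.0,6.6,70.1,0.73,0.66
MO4,child,4.2,66.7,25.7,7.7,0.0,69.1,0.40,0.60
MO4,parent,3.2,62.6,25.3,10.4,1.6,77.6,0.70,0.60
LT1,child,6.8,64.0,25.8,7.9,2.2,74.9,0.65,0.71
LT1,parent,1.6,40.0,35.7,21.1,3.2,71.7,0.73,0.71
LT2,child,33.5,85.0,13.4,0.8,0.8,83.6,0.48,0.57
LT2,parent,24.5,71.8,19.7,7.7,0.7,80.4,0.75,0.57
LT3,child,4.2,84.7,13.7,1.1,0.5,86.9,0.46,0.65
LT3,parent,1.1,70.4,23.1,6.5,0.0,77.9,0.65,0.65
LT4,child,3.7,82.6,14.7,2.7,0.0,83.8,0.37,0.62
LT4,parent,2.1,60.9,37.0,2.2,0.0,75.3,0.59,0.62
LT5,child,70.2,75.4,7.0,1.8,15.8,82.5,0.45,0.78
LT5,parent,28.2,33.3,33.3,17.0,16.3,73.3,0.77,0.78
LT6,child,22.5,84.5,11.5,3.4,0.7,82.7,0.35,0.56
LT6,parent,11.7,47.6,39.2,12.0,1.2,70.3,0.59,0.56
LT7,child,59.7,67.5,29.9,2.6,0.0,72.6,0.35,0.48
LT7,parent,31.4,62.0,30.2,7.0,0.8,75.9,0.59,0.48
LT8,child,25.1,83.2,14.7,2.1,0.0,89.3,0.49,0.57
LT8,parent,31.9,61.7,32.8,4.7,0.8,76.8,0.57,0.57
CO1,child,0.0,63.4,31.9,3.7,1.0,69.3,0.28,0.60
CO1,parent,0.5,65.8,28.9,5.3,0.0,78.4,0.66,0.60
CO2,child,2.1,78.1,20.9,1.1,0.0,80.7,0.43,0.58
CO2,parent,0.0,72.3,23.4,4.3,0.0,79.9,0.60,0.58
CO3,child,9.4,56.1,31.2,11.0,1.7,65.2,0.43,0.61
CO3,parent,0.5,40.4,45.7,13.3,0.5,71.1,0.66,0.61
CO4,child,4.2,84.7,12.0,2.7,0.5,84.3,0.41,0.63
CO4,parent,0.5,70.1,25.1,4.8,0.0,75.1,0.55,0.63
CO5,child,2.1,81.3,15.0,3.7,0.0,77.3,0.45,0.61
CO5,parent,1.1,81.2,14.5,4.3,0.0,84.9,0.68,0.61
CO6,child,2.6,80.1,17.7,2.2,0.0,79.6,0.19,0.57
CO6,parent,1.1,69.4,25.8,4.8,0.0,76.0,0.53,0.57
CO7,child,12.0,27.4,43.5,23.2,6.0,64.5,0.60,0.63
CO7,parent,3.7,31.5,45.9,21.0,1.7,70.7,0.67,0.63
CO8,child,5.8,61.7,25.6,10.6,2.2,67.8,0.31,0.56
CO8,parent,2.1,41.3,41.3,16.8,0.5,63.7,0.53,0.56
CO9,child,1.6,50.5,31.9,9.0,8.5,64.6,0.47,0.65
CO9,parent,1.6,45.9,35.7,17.3,1.1,74.6,0.77,0.65
CO10,child,1.0,72.0,20.1,6.9,1.1,72.7,0.40,0.56
CO10,parent,3.2,33.5,50.0,15.9,0.5,60.6,0.59,0.56
CO11,child,1.0,79.9,14.8,3.7,1.6,80.2,0.46,0.64
CO11,parent,0.5,49.7,36.9,13.4,0.0,69.9,0.65,0.64
CO12,child,27.2,32.4,28.1,30.2,9.4,55.6,0.48,0.63
CO12,parent,17.6,24.5,47.1,25.8,2.6,69.7,0.63,0.63
SL1,child,0.0,93.7,5.2,1.0,0.0,91.9,0.36,0.64
SL1,parent,3.2,85.2,10.4,2.7,1.6,88.5,0.53,0.64
SL2,child,0.0,85.3,12.6,2.1,0.0,83.8,0.35,0.55
SL2,parent,2.7,47.5,42.1,9.8,0.5,71.2,0.56,0.55
SL3,child,2.1,56.1,30.5,12.3,1.1,65.2,0.52,0.70
SL3,parent,2.7,37.7,42.6,17.5,2.2,71.6,0.74,0.70
SL4,child,5.2,63.0,21.0,9.9,6.1,70.2,0.52,0.63
SL4,parent,9.0,27.5,40.4,24.0,8.2,68.2,0.61,0.63
SL5,child,3.1,73.0,20.0,4.9,2.2,75.6,0.48,0.74
SL5,parent,5.9,33.9,35.0,28.2,2.8,68.1,0.69,0.74
SL6,child,91.1,82.4,17.6,0.0,0.0,,,
SL6,parent,87.8,43.5,34.8,13.0,8.7,,,
SL7,child,28.8,69.9,24.3,4.4,1.5,75.9,0.47,0.53
SL7,parent,13.8,43.8,36.4,15.4,4.3,68.0,0.62,0.53
SL8,child,1.0,68.8,24.9,4.8,1.6,70.7,0.48,0.52
SL8,parent,2.7,47.5,38.8,13.1,0.5,65.1,0.52,0.52
SL9,child,1.6,87.8,10.1,2.1,0.0,83.5,0.36,0.60
SL9,parent,0.0,64.9,31.4,3.7,0.0,79.1,0.63,0.60
SL10,child,0.5,83.2,14.7,2.1,0.0,83.0,0.45,0.51
SL10,parent,1.1,53.2,37.1,8.6,1.1,74.6,0.66,0.51
SL11,child,0.0,68.1,23.0,8.9,0.0,74.7,0.54,0.65
SL11,parent,0.5,47.6,33.7,18.2,0.5,72.8,0.71,0.65
SR1,child,4.7,75.3,18.7,4.4,1.6,79.9,0.56,0.60
SR1,parent,2.7,55.2,36.6,7.1,1.1,75.7,0.64,0.60
SR2,child,6.3,76.0,16.8,5.6,1.7,83.5,0.68,0.71
SR2,parent,1.1,58.6,33.9,7.0,0.5,82.6,0.77,0.71
SR3,child,1.0,85.7,12.2,2.1,0.0,85.1,0.43,0.58
SR3,parent,1.1,77.4,20.4,2.2,0.0,86.0,0.59,0.58
SR4,child,0.5,94.2,4.7,1.1,0.0,95.7,0.51,0.66
SR4,parent,0.5,93.6,5.9,0.5,0.0,93.6,0.57,0.66
SR5,child,4.2,85.2,13.1,1.1,0.5,88.3,0.60,0.63
SR5,parent,1.1,77.4,22.0,0.5,0.0,83.7,0.58,0.63
AC1,child,7.3,60.5,26.0,9.6,4.0,67.8,0.50,0.55
AC1,parent,9.0,43.9,39.2,15.2,1.8,68.2,0.62,0.55
AC2,child,6.3,36.9,45.3,16.2,1.7,60.8,0.44,0.53
AC2,parent,3.7,28.2,47.5,23.8,0.6,63.6,0.58,0.53
AC3,child,2.1,60.4,27.3,11.2,1.1,70.7,0.47,0.60
AC3,parent,0.0,27.7,43.1,29.3,0.0,59.9,0.53,0.60
AC4,child,1.6,61.2,29.8,6.4,2.7,65.6,0.40,0.52
AC4,parent,0.5,51.9,29.4,17.6,1.1,69.8,0.68,0.52
AC5,child,23.6,90.4,9.6,0.0,0.0,87.8,0.32,0.57
AC5,parent,11.7,60.8,33.1,6.0,0.0,72.5,0.59,0.57
FI1,child,1.0,70.9,21.7,6.9,0.5,85.2,0.67,0.69
FI1,parent,6.4,54.5,34.1,10.2,1.1,80.1,0.78,0.69
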