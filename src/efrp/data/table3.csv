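participant,age_group,driving_experience,distraction_count,primed,dynamic_white_space,static_white_space,dynamic_speedometer,static_speedometer,dynamic_billboard,static_billboard,dynamic_speed_sign,static_speed_sign
1,51-55,30,24,1,181.62,167.64,45.16,42.33,56.21,31.09,77.51,105.27
2,41-45,26,21,0,117.10,113.65,86.63,79.82,57.74,43.40,79.39,104.28
3,26-30,<1,25,1,97.97,101.73,143.60,153.17,67.78,70.30,100.89,82.46
4,26-30,7,19,0,285.48,291.37,29.02,42.86,25.71,10.08,2.99,6.55
5,26-30,3,11,0,172.27,152.77,63.90,63.96,29.00,19.43,139.56,149.64
6,26-30,9,15,0,147.88,135.79,85.18,78.48,47.76,39.50,101.48,129.06
7,21-25,6,9,0,201.25,182.38,108.35,105.27,32.28,30.33,48.83,42.94
8,21-25,5,8,0,99.78,87.16,104.08,108.30,38.15,20.58,125.07,151.52
9,21-25,<1,4,0,259.48,263.78,17.80,8.37,19.91,19.13,77.90,79.18
10,26-30,7,2,0,131.48,116.69,65.54,62.35,57.73,49.51,191.84,182.92
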