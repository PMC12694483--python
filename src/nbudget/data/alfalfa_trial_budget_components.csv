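year,pattern,n_rate,initial_soil_n_kg_ha,soil_residue_kg_ha,plant_accumulation_kg_ha,n2o_emission_kg_ha
2023,FP,0,40.03,36.5,91.01,1.21
2023,FP,80,44.96,38.3,96.65,1.54
2023,FP,160,47.6,38.8,113.57,1.81
2023,FP,240,50.13,41.1,104.57,2.21
2023,JM,0,43.17,39.5,84.25,1.38
2023,JM,80,45.97,42.5,93.76,1.74
2023,JM,160,48.3,44.4,121.48,1.89
2023,JM,240,52.87,45.7,94.69,2.39
2023,PM,0,42.8,43.7,91.16,1.56
2023,PM,80,45.67,46.6,110.88,1.99
2023,PM,160,48.6,48.7,148.03,2.14
2023,PM,240,56.03,51.5,116.96,2.63
2024,FP,0,56,55.63,109.72,1.66
2024,FP,80,59.6,58.26,117.05,1.88
2024,FP,160,61.8,59.01,120.66,2.11
2024,FP,240,69.1,62.4,126.01,2.45
2024,JM,0,58.3,58.97,101.74,1.73
2024,JM,80,63.1,62.87,113.51,2.09
2024,JM,160,68.2,66.28,135.74,2.29
2024,JM,240,71.5,68.4,114.48,2.73
2024,PM,0,62.7,65.53,110.32,2.01
2024,PM,80,69.2,69,133.52,2.19
2024,PM,160,77.1,72.3,160.58,2.38
2024,PM,240,79.5,75.27,141.39,3.01
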