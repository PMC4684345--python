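energy_keV,mass_attenuation_cm2_per_g
10,110.7
15,35.87
20,15.85
30,4.972
40,2.214
50,1.213
60,0.7661
80,0.4052
100,0.2721
150,0.1649
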