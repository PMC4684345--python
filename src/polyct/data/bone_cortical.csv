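energy_keV,mass_attenuation_cm2_per_g
10,28.51
15,9.032
20,4.001
30,1.331
40,0.6655
50,0.4242
60,0.3148
80,0.2229
100,0.1855
150,0.1480
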