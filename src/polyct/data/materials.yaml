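# Densities (g/cm^3) and table files for the packaged materials.
# Mass attenuation tables follow the standard sparse NIST grid, 10-150 keV.
water:
  table: water.csv
  density: 1.00
bone_cortical:
  table: bone_cortical.csv
  density: 1.92
titanium:
  table: titanium.csv
  density: 4.54
copper:
  table: copper.csv
  density: 8.96
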