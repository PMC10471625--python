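# Grazing allocation parameters (study-area estimates).
stocking_rate_meadows_forests: 0.2   # LU/ha
stocking_rate_mountain: 1.2          # LU/ha
anpp_fraction: 0.50                  # ANPP / NPP, both areas
consumed_fraction_meadows_forests: 0.65
consumed_fraction_mountain: 0.40
year_length_days: 365.0
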