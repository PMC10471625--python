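# Default climate/soil record for a Pyrenean mid-mountain study area.
insolation_j_m2: 5.0e9          # global radiation, J/m2/yr (~1390 kWh/m2/yr)
albedo: 0.20                    # grassland/forest mosaic
rainfall_m: 1.0                 # m/yr
evapotranspiration_m: 0.55      # m/yr
wind_energy_density_j_m2: 3.0e7 # dissipated near-surface kinetic energy, J/m2/yr
erosion_rate_g_m2: 120.0        # 1.2 t/ha/yr, moderate mountain pasture erosion
soil_organic_fraction: 0.04
soil_energy_content_j_g: 22604.0  # 5.4 kcal per g organic matter
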