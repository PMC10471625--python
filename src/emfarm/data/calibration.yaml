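# Cohort calibration: structural/economic means and SDs per farm type,
# herd decomposition ratios, copula rank correlation between size variables,
# and target emergy shares of each purchased inventory item (fractions of
# the farm's total emergy flow) used by the inventory back-solve.
rank_correlation: 0.6
mountain_day_fraction: 0.3333333333333333  # summer third of the grazing period
herd_ratios:
  bulls_per_cow: 0.02
  heifers_per_cow: 0.20
  calves_per_cow: 0.85
farm_types:
  weaner:
    variables:
      agricultural_area_ha: {mean: 47.3, sd: 31.0}
      herd_lu: {mean: 72.8, sd: 33.8}
      labour_wu: {mean: 1.3, sd: 0.5}
      grazing_days: {mean: 251.5, sd: 49.4}
      total_income_eur: {mean: 41548.0, sd: 28004.0}
      cap_payments_eur: {mean: 32420.0, sd: 16473.0}
      variable_costs_eur: {mean: 23722.0, sd: 13609.0}
    tax_to_cap_ratio: 0.020905923344947737
    emergy_shares:
      machinery_depreciation: 0.025
      buildings_depreciation: 0.047
      small_equipment: 0.011
      veterinary_medicines: 0.021
      electricity: 0.001
      fuel: 0.034
      straw: 0.037
      corn: 0.0
      forage: 0.060
      vitamin_mineral_supplements: 0.002
      concentrates: 0.024
      seeds: 0.0
      fertiliser: 0.049
      phytochemicals: 0.0
  weaner_finisher:
    variables:
      agricultural_area_ha: {mean: 67.6, sd: 52.2}
      herd_lu: {mean: 123.0, sd: 73.1}
      labour_wu: {mean: 1.7, sd: 0.9}
      grazing_days: {mean: 237.5, sd: 24.0}
      total_income_eur: {mean: 82952.0, sd: 45508.0}
      cap_payments_eur: {mean: 56112.0, sd: 37570.0}
      variable_costs_eur: {mean: 56691.0, sd: 45063.0}
    tax_to_cap_ratio: 0.014234875444839857
    emergy_shares:
      machinery_depreciation: 0.029
      buildings_depreciation: 0.034
      small_equipment: 0.012
      veterinary_medicines: 0.021
      electricity: 0.001
      fuel: 0.037
      straw: 0.052
      corn: 0.0
      forage: 0.032
      vitamin_mineral_supplements: 0.003
      concentrates: 0.134
      seeds: 0.0
      fertiliser: 0.037
      phytochemicals: 0.0
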