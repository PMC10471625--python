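resource_name,uev_value,unit_class,source_baseline,renewability_factor,category,origin_tag,reference
sunlight,1.0,energy,1.583e25,1.0,R,solar_derived,transformity of sunlight is 1 by definition
rain_chemical_potential,3.05e4,energy,1.583e25,1.0,R,solar_derived,global rain chemical-potential transformity
evapotranspiration,3.05e4,energy,1.583e25,1.0,R,solar_derived,chemical potential of water actually evapotranspired
wind_kinetic,2.45e3,energy,1.583e25,1.0,R,solar_derived,surface wind kinetic energy transformity
soil_erosion,1.24e5,energy,1.583e25,0.0,N,,soil organic matter transformity
straw,8.0e8,mass,1.583e25,0.35,P,,cereal straw specific emergy
corn,8.5e8,mass,1.583e25,0.30,P,,grain corn specific emergy
forage,9.0e8,mass,1.583e25,0.40,P,,conserved forage specific emergy
concentrates,2.2e9,mass,1.583e25,0.25,P,,compound feed specific emergy
vitamin_mineral_supplements,3.0e9,mass,1.583e25,0.05,P,,mineral premix specific emergy
fuel,1.11e5,energy,1.583e25,0.0,P,,diesel fuel transformity
electricity,2.77e5,energy,1.583e25,0.25,P,,grid electricity transformity; renewable share of national mix
fertiliser,6.38e9,mass,1.583e25,0.01,P,,nitrogen fertiliser specific emergy
seeds,1.5e9,mass,1.583e25,0.30,P,,crop seed specific emergy
phytochemicals,2.49e10,mass,1.583e25,0.01,P,,pesticide specific emergy
veterinary_medicines,1.1e12,money,1.2e25,0.10,P,,em-euro ratio for the national economy
machinery_depreciation,1.1e12,money,1.2e25,0.10,P,,em-euro ratio for the national economy
buildings_depreciation,1.1e12,money,1.2e25,0.10,P,,em-euro ratio for the national economy
small_equipment,1.1e12,money,1.2e25,0.10,P,,em-euro ratio for the national economy
labour,4.0e15,labour,1.2e25,0.10,P,,emergy per full-time work-unit year
cap_payments,1.1e12,money,1.2e25,0.10,S,,em-euro ratio for the national economy
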