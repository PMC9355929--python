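# Default energy and greenhouse-gas conversion coefficients.
#
# Every value here is user-overridable; analysis results are conditional on
# this table.  Sources are literature-standard life-cycle values:
#   - fertilizer / fuel / labor embedded energy: Pimentel (1980),
#     Mittal & Dhawan (1988), Devasenapathy et al. (2009)
#   - grain energy contents: Gopalan et al. (2007) food-composition values
#   - input production GHG intensities: Ecoinvent-style means as used in
#     South Asian cropping-system footprint studies (e.g. Pathak et al. 2010)
#   - fertilizer-N N2O pathway: IPCC 2006 Tier-1 defaults, AR5 GWP100.
energy_per_input:       # MJ per kg nutrient / kg a.i. / L diesel
  n: 60.6
  p2o5: 11.1
  k2o: 6.7
  pesticide: 120.0
  diesel: 47.8
energy_labor: 1.96      # MJ per person-hour of human labor
energy_grain_by_crop:   # MJ per kg of harvested product
  aman_rice: 14.7       # paddy grain
  boro_rice: 14.7
  mungbean: 14.7
  lathyrus: 14.7
  groundnut: 13.0       # unshelled pod basis
  chili: 13.0           # dry-weight basis (food energy of dried chili)
ghg_per_input:          # kg CO2e per kg nutrient / kg a.i. / L diesel
  n: 4.8                # production + transport of fertilizer N
  p2o5: 0.73
  k2o: 0.55
  pesticide: 19.0
  diesel: 3.2           # combustion + upstream production
n2o_factors:
  ef1: 0.01             # direct N2O-N per kg fertilizer N
  ef4: 0.010            # N2O-N per kg NH3-N + NOx-N volatilized
  ef5: 0.0075           # N2O-N per kg N leached/run off
  frac_gasf: 0.10       # fraction of applied N volatilized
  frac_leach: 0.30      # fraction of applied N leached
  gwp_n2o: 265.0        # 100-yr global warming potential of N2O (AR5)
bdt_per_usd: 77.87      # study-year exchange rate
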