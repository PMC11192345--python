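# Scalar economic and accounting parameters for the packaged study configuration.
scc_usd_per_t_co2: 1.47        # annualized social cost of carbon, USD per tonne CO2
coffee:
  production_rate_t_per_ha: 0.84   # tonnes of coffee per hectare per year
  price_usd_per_t: 4685.0          # present market price, USD per tonne (4.685 USD/kg)
  cost_fraction: 0.13              # production cost as a fraction of gross revenue
study_area_ha: 472118.0        # total mapped study area (4721.18 km^2), denominator for shares
report_precision: 2
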