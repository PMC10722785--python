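# Per-country conversion parameters.
# - rho: VOLY:QALY ratio; rho_reciprocal: the VOLY->VOQ multiplier as the
#   sources rounded it (1.087 ~ 1/0.91996, rounded independently per direction).
# - UK: closed-form annuity from discount rate 1.5%, life expectancy 81.1,
#   reference age 40. Other countries: annuity_factor derived from published
#   VSL:VOLY pairs (their underlying inputs are not published); discount_rate
#   0.015 is the fallback used only to rescale the factor in age sensitivity.
# - price_index: implied levels back-derived from published stated/adjusted
#   value pairs, base 2019 = 1.0. Only years that require adjustment appear.
base_year: 2019
countries:
  UK:
    rho: 0.91996
    rho_reciprocal: 1.087
    discount_rate: 0.015
    life_expectancy: 81.1
    reference_age: 40
    price_index:
      2017: 0.9434752884
      2019: 1.0
  NL:
    rho: 0.91996
    rho_reciprocal: 1.087
    annuity_factor: 30.8940520137
    discount_rate: 0.015
    price_index:
      2015: 0.9428371316
      2019: 1.0
  CA:
    rho: 0.91996
    rho_reciprocal: 1.087
    annuity_factor: 30.9669667979
    discount_rate: 0.015
    price_index:
      2004: 0.7562203143
      2019: 1.0
  JP:
    rho: 0.91996
    rho_reciprocal: 1.087
    annuity_factor: 29.1997574702
    discount_rate: 0.015
    price_index:
      2019: 1.0
  AU:
    rho: 0.91996
    rho_reciprocal: 1.087
    annuity_factor: 17.4914399217
    discount_rate: 0.015
    price_index:
      2006: 0.7463626483
      2019: 1.0
  NZ:
    rho: 0.91996
    rho_reciprocal: 1.087
    annuity_factor: 21.6801733667
    discount_rate: 0.015
    price_index:
      2001: 0.705666502
      2018: 0.9656160586
      2019: 1.0
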