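# lifevalues

Governments monetise life and health every day: health-technology agencies
ration against a cost-per-QALY threshold, transport ministries appraise road
schemes with a value of a prevented fatality, environment departments price
life years lost to air pollution. These benchmarks live in different units
(value of a statistical life, value of a life year, value of a QALY), in
different price years, and — strikingly — at very different levels within the
same government. `lifevalues` is a toolkit for putting them on a common
footing and quantifying the gap, aimed at health economists and policy
analysts working on cross-sector resource allocation.

It ships a registry of published benchmarks for six countries (UK, the
Netherlands, Canada, Japan, Australia, New Zealand) with the per-country
parameters needed to convert between measures, and implements:

- **Conversion algebra.** A VSL and a VOLY are linked by the discounted
  annuity over remaining life expectancy,

  a(r, n) = (1 − (1 + r)⁻ⁿ) / r,

  so VOLY = VSL / a(r, n); a VOLY and a value of a QALY (VOQ) are linked by
  the ratio ρ ≤ 1 (a life year in average health is worth ρ of a full-health
  QALY), so VOQ = VOLY / ρ. Default ρ = 0.91996.
- **Price-year adjustment** onto the 2019/2020 base year via per-country
  implied index series.
- **Cross-sector comparison.** Within each country, the health benchmark as
  a percentage of the VOQ implied by each transport and environment
  benchmark — a within-country ratio, so exchange rates and purchasing-power
  parity never enter — plus the headline counts of comparisons in which
  health is valued lower.
- **Sensitivity scans** over the reference age (hence remaining life years)
  and ρ, up to the 1:1 bound.
- **A welfare-allocation model.** Departments turn budget shares m_j into
  health outputs h_j(m_j) and non-health outputs a_j(m_j); with υ the social
  exchange rate between the two attributes, the optimum of
  W = υ·Σh_j + Σa_j subject to Σm_j = M equalises υ·h_j′ + a_j′ across
  departments (pairwise: υ(h_i′ − h_j′) = a_j′ − a_i′). A solver, an
  equilibrium checker and a threshold-inconsistency demo are included.
- **A synthetic-data generator** producing registries and allocation
  problems with known ground truth, so every stage is testable end-to-end.

## Worked example

```python
from lifevalues import (MoneyRange, Measure, RunConfig, convert,
                        default_params, run_pipeline)

params = default_params()

# The UK transport appraisal value of a prevented fatality, on all measures
triple = convert(MoneyRange.point(2_064_189), Measure.VSL, params["UK"])
print("VSL :", triple.vsl)    # VSL : 2,064,189
print("VOLY:", triple.voly)   # VOLY: 67,650
print("VOQ :", triple.voq)    # VOQ : 73,535

# The full six-country comparison
result = run_pipeline(RunConfig(run_sensitivity_scan=False))
print(result.counts)
```

The conversion divides the £2,064,189 VSL by the UK annuity factor
a(0.015, 41.1) ≈ 30.513 to get a £67,650 life year, then scales by the
VOLY:QALY ratio to a £73,535 value per QALY — about 2.5× the upper NICE
threshold of £30,000. The pipeline prints

```
{'comparisons': 15, 'below_100_overall': 13,
 'transport_comparisons': 7, 'below_50_transport': 6,
 'environment_comparisons': 8, 'below_50_environment': 5}
```

i.e. in 13 of the 15 within-country comparisons the health benchmark is
worth less than the transport or environment benchmark, and in 6 of 7
transport and 5 of 8 environment comparisons it is below half.

The same is available from the shell:

```sh
$ lifevalues convert "20,000-30,000" --measure QALY --country UK
{"country": "UK", "source_measure": "VOQ", "vsl": [663351, 995027],
 "voly": [18399, 27599], "voq": [20000, 30000]}

$ lifevalues reproduce --out reports/
```

Other subcommands: `adjust`, `compare`, `sensitivity`, `allocate`,
`threshold-gap`, `simulate` (see `lifevalues --help`).

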