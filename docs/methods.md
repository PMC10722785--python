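# Methods

## The problem

Different departments of the same government attach different monetary
values to the same unit of health. Health ministries and HTA agencies work
in cost per QALY; transport and environment departments publish a value of
a statistical life (VSL, also called a value of a prevented fatality) or a
value of a life year (VOLY) for cost–benefit analysis. To compare them, all
benchmarks must be expressed on one metric — here the value of a QALY
(VOQ) — in one price year, within one country (so currency conversion never
arises: every comparison is a within-country ratio).

## Conversion model

Two parameters map between the three measures.

**Annuity factor.** A statistical life is treated as a stream of remaining
life years discounted at rate r over horizon n = LE − reference age:

    a(r, n) = (1 − (1 + r)^−n) / r,   a(0, n) = n,   0 < a ≤ n.

VSL = VOLY × a(r, n). The packaged UK parameters are r = 1.5 %/year,
LE = 81.1 years, reference age 40 (n = 41.1, a ≈ 30.5128), which reproduce
every UK table cell exactly. For the other five countries the underlying
(r, LE) pairs are not published; the packaged config instead carries
*derived* annuity factors recovered from each country's published VSL:VOLY
column pairs (NL 30.8941, CA 30.9670, JP 29.1998, AU 17.4914, NZ 21.6802).
Each derived factor is the magnitude-weighted mean of the implied ratios
across that country's rows — weighting by the VSL magnitude, because the
precision of an implied ratio grows with the printed value. The run log
records per country whether the factor is closed-form or derived.

**VOLY:QALY ratio.** A life year in average health is worth ρ of a
full-health QALY; ρ ≤ 1 by construction (a year cannot be worth more than a
year in full health). Default ρ = 0.91996, configurable per country.

The source tables this package reproduces applied the ratio with
independently rounded constants per direction: × 0.91996 going VOQ → VOLY
but × 1.087 (≈ 1/0.91996, rounded) going VOLY → VOQ. `CountryParams`
therefore carries both `rho` and an optional `rho_reciprocal`; the shipped
config pins 1.087 so that the large-magnitude yen cells reproduce to the
unit, while sensitivity scans and the synthetic generator use the exact
reciprocal 1/ρ.

**Direction-dependent chain.** Conversions are applied elementwise to range
endpoints, rounding each output to the nearest whole currency unit (half
away from zero):

- from VSL: VOLY = VSL / a; VOQ = VOLY × (1/ρ)
- from VOLY: VSL = VOLY × a; VOQ = VOLY × (1/ρ)
- from VOQ: VOLY = VOQ × ρ; **VSL = VOQ × a / ρ**

The boldface step reproduces the published convention, which is *not* the
VOLY-source chain applied to VOQ×ρ — the two candidate VSLs differ by the
factor 1/ρ² (≈ 1.18). `convert` warns when this convention is exercised and
offers `strict=True` for the internally consistent chain VSL = VOQ × ρ × a;
`voq_vsl_diagnostic` reports both candidates. The default reproduces the
source; the strict mode is the correction, off by default.

Rounded triples are what published tables contain; the unrounded chain
values are kept alongside (`raw_*`) for round-tripping and diagnostics
(rounding an intermediate VOLY before multiplying by a ≈ 30 would otherwise
smear ±15 currency units into a round trip).

## Price-year adjustment

Stated values are brought to the 2019/2020 base year by the ratio of index
levels, rounded to whole units. The packaged series are *implied* indices
back-derived from published stated/adjusted pairs (level = stated/adjusted,
base = 1.0) — the sources do not name their deflator, so the printed pairs
are the only ground truth; no external CPI is fetched. Whether a value is
adjusted at all is an editorial flag on the registry row (`needs_update`):
sources deliberately left many older values nominal, and that choice is
data, not something the package infers.

## Cross-sector comparison

For each country, the health reference benchmark (flagged in the registry)
is expressed as a VOQ range and divided by the VOQ implied by each flagged
transport and environment benchmark; the quotient is reported as an integer
percentage range (rounded half away from zero). Conventions, all fixed by
the published comparison:

- A non-health benchmark stated as a range contributes one comparison per
  endpoint (Japan's transport and environment ranges thus contribute two
  rows each); a health reference range stays one row with a percentage range.
- Two countries pool two point rows into their health reference range
  (Canada's lower/upper agency bounds; Australia's two academic estimates);
  the builder merges flagged rows by (min lower, max upper). Japan's
  reference uses only the lower endpoint of its range row (`hta_ref_bound:
  lower`), matching the published comparison value.
- A comparison counts as "health valued lower" when the *upper* endpoint of
  the health percentage range is strictly below 100 % (and "below half" when
  below 50 %): only if even the most generous health benchmark falls short
  is the gap counted. On the shipped registry this yields 13 of 15
  comparisons below 100 %, 6 of 7 transport and 5 of 8 environment
  comparisons below 50 %; the two exceptions are environment rows (the UK
  acute air-pollution value and the low Japanese academic estimate).

The health-baseline index (health = 100) is the reciprocal view of the same
ratios, used for graphical presentation; no figure values are asserted
anywhere.

## Sensitivity

`run_sensitivity` re-runs the whole pipeline on a grid of reference ages
(default 20–60) and ρ values (default 0.91996/0.95/1.0). For the UK the
annuity is rebuilt from the closed form at n = LE − age. For countries with
derived factors the horizon is inferred by inverting the factor at the
fallback rate 1.5 %/year and the factor is rescaled by the ratio of
closed-form values at the shifted vs baseline horizon; cells using this
fallback are flagged in the output. When a cell's ρ equals a country's
configured ratio the configured reciprocal is kept, so the baseline cell is
identical to a direct pipeline run. The verdict is "robust" when every cell
keeps a majority (default ≥ 8 of 15) of comparisons below 100 %; on the
shipped registry every cell keeps ≥ 13.

## Allocation model

Welfare is linear in the two attributes, W = υH + A, with υ a constant
marginal rate of substitution — sufficient for the pairwise equilibrium
condition and the simplest form consistent with its statement. Production
functions must be non-decreasing and concave on [0, M] (checked by a
marginal-monotonicity probe; violations are rejected with a diagnostic).
The solver searches the common marginal value λ: for each candidate λ the
department-level allocation solves υh′ + a′ = λ by bisection (clamped to
[0, M]), and λ itself is found by root-finding on the budget identity.
Departments whose marginal welfare at zero is below λ receive nothing.
Derivatives use exact forms where the production object supplies them
(the power form does) and central finite differences with step 1e-6·M
otherwise. Equilibrium residuals are reported for every department pair.

The threshold-gap demonstration is an illustrative harness, not an
estimator: departments accept a project iff QALYs × own threshold ≥ cost;
projects accepted under one rule and rejected under another form the
inconsistency set, and welfare is scored against a single reference VOQ
(default the mean threshold) so the loss relative to the consistent rule is
non-negative by construction and zero when thresholds agree. It takes a
project slate and a threshold map directly rather than an allocation
problem, since the inconsistency is a property of the decision rules alone.

## Synthetic data

The generator emulates a registry produced by known conversion parameters:
per synthetic country it draws (r, LE, ρ) and an inflation path, draws
benchmark rows on native measures with realistic magnitudes (QALY values
15–120k, VOLYs 15–300k, VSLs 1–8M currency units, a quarter of rows stated
as ranges, stated years 2000–2019), then fabricates the stated/adjusted
pairs and conversion columns with the same forward chain and rounding the
pipeline uses. Ground truth and the generator's own comparison percentages
are returned separately, so tests can check exact end-to-end agreement and
parameter recovery. One integer seed drives all randomness. The generator
does not mimic document-search pathologies (missing thresholds, ambiguous
sourcing, inconsistent rounding across a row), so passing tests demonstrate
the pipeline's arithmetic, not robustness to messy source documents.
Allocation problems are generated with a shared power exponent so the
Lagrange optimum is analytic (m_j ∝ (υc_j + d_j)^{1/(1−β)}).

## Numerical conventions

- All currency rounding is half away from zero to whole units; percentages
  likewise to integer percent. This matches every reproduced cell; banker's
  rounding does not.
- `annuity_factor` uses the expm1/log1p form for stability near r = 0 and
  returns the n-limit when n·r < 1e-14.
- Reproduction tolerance for monetary cells is ±2 currency units — the
  chained whole-unit rounding in the sources drifts by about one unit per
  step. Percentages and counts must match exactly.
- The discounted-sum oracle for the annuity (Σ (1+r)^−t) agrees with the
  closed form to 1e-9 only at integer horizons; at fractional n the
  fractional-last-year sum is an approximation, so exactness is asserted at
  integer n and continuity/bounds elsewhere.
- Solver tolerances: closed-form recovery to 1e-6 relative (observed
  ~1e-13); equilibrium residuals ≤ 1e-6 × the common marginal value.

## Known limitations

- Two published cells are internally inconsistent with their own rows and
  are excluded from reproduction (documented in the test fixture): the UK
  end-of-life row prints a range VSL for a point input, and the New Zealand
  academic health row's VSL implies an adjusted value contradicting the
  row's own adjusted cell by one unit (its VSL by 24).
- Non-UK (r, LE) pairs are unknown; derived annuity factors are exact for
  reproduction but the age-sensitivity rescaling for those countries rests
  on the fallback rate and is flagged as such.
- ρ = 0.91996 is taken as given (recoverable from every country's printed
  column pairs via `implied_ratio`); its provenance is not re-derived.
- The welfare model is utilitarian and linear in attributes; distributional
  weighting and general W(H, A) are out of scope.
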