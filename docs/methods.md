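# Methods

## The equivalent method

`equicost` estimates what an essential public health service package (such as
China's NEPHSP, delivered free of charge by township health centers) actually
costs, in settings where the only reliable cost figure is the institution's
total operational expense and the only workload data are survey answers of
the form "this service takes *w* workers × *m* minutes per delivery, *q*
deliveries per year".

All activity — primary medical care and the public health programme alike —
is expressed in **standard service equivalents**. One equivalent is the
workload of one health worker delivering one 15-minute consultation, a
convention descended from the WHO's Workload Indicators of Staffing Need
(WISN). A service item's unit equivalent value is

    u = (workers per case × minutes per case) / 15 ,

its annual total is `u × annual cases`, and totals add over items,
institutions, counties and regions. The method then assumes **cost
proportional to workload**:

    cost per equivalent   c = operational cost / total equivalents (all activity)
    programme cost        C = c × programme equivalents
    per-capita estimate   C / registered residents served

The four per-capita measures the package reports are the estimated cost (the
chain above), the actual subsidy (programme revenue / residents), the actual
expenditure (programme spending / residents), and the policy allocation rate
(CNY 74/person in 2020, configurable per dataset).

Assumptions worth stating plainly: only labour enters the cost allocation
(drugs, consumables and diagnostics are excluded, which biases the estimated
cost upward as a total-cost measure); person-minutes are multiplicative in
workers, so two workers × 12 minutes equals 12 workers × 2 minutes; and
equivalents measure quantity of work, not quality.

## Numerical conventions

* **Currency is exact decimal at 2 dp** (CNY fen), with HALF-UP rounding.
  This keeps conservation checks free of binary-float drift and reproduces
  printed ledgers exactly.
* **The cost factor is rounded to the cent before multiplying back out**
  (`rounding="paper"`, the default), matching how published tables of this
  method are computed; `rounding="unrounded"` gives the exact proportional
  allocation. The conservation error of the rounded mode is bounded by
  0.005 CNY × total equivalents.
* Equivalent values are kept at full float precision internally; rounding to
  2 dp happens only at the reporting edge, after summation.
* Group-level costing divides the group's summed cost by the group's summed
  equivalents — never the mean of institution-level ratios.
* `standard_minutes` is a parameter (default 15): the standard is a
  convention, and sensitivity analysis over it is a legitimate use.
* Degenerate scopes (no workload, zero population, zero equivalents) are
  skipped with a logged reason and surfaced in `CostResults.skipped`, never
  silently dropped. A scope with no workload at all reports its programme
  share as undefined (`None`), which is not the same as 0.

## Statistics

* **Spearman's rho** is the Pearson correlation of mid-ranks (average ranks
  for ties). The default p-value is the t-approximation with n − 2 df; an
  exact permutation p-value is available for n ≤ 8.
* **One-way ANOVA** is the classical equal-variance decomposition; a Welch
  heteroscedastic variant is available behind `welch=True`. When all groups
  are identical constants, F is reported as `nan` (undefined), not 0.
* **ANOVA from summaries** uses `ss_between = Σ nᵢ(x̄ᵢ − x̄)²` (nᵢ-weighted
  grand mean) and `ss_within = Σ (nᵢ − 1) sᵢ²`. It is algebraically
  identical to the raw-data ANOVA; when fed 2-dp-rounded printed summaries,
  the reconstructed F carries the input rounding (≈0.03 on the packaged
  category-share table, well within 0.1 of its published value).
* Table 6-style "unit equivalent value" aggregation is defined here as the
  workload-weighted mean across a category's items within the scope
  (Σ u × cases / Σ cases); the choice is stated because survey reports of
  the method do not define it.

## The synthetic-study generator

`generate_study(GeneratorConfig(...))` emulates the study design end to end:
5 regions × 2 counties × 5 townships (one health center each, 50 in total),
a catalogue of 13 programme categories (37 items) plus 5 primary-medical
categories (71 placeholder items), and one finance record per institution.
Defaults, with units and why:

| knob | default | rationale |
|---|---|---|
| residents per institution | log-normal, region medians 17k–55k, σ = 0.45 | right-skewed sizes with SD ≈ mean, largest in the east |
| staff per 1000 residents | N(1.30, 0.35) | ≈ 44 professionals at 34k residents |
| programme equivalents per resident | 6.2 | matches the observed programme workload per registered resident |
| programme share of total workload | N(38 %, 6 %) | the observed regional range ≈ 34–51 % |
| category mix | fixed weights, whole-population services dominant | health education / elderly management / health records carry ≈ 78 % of programme workload; elderly and hypertension weights scale with the configurable demographic fractions (defaults 0.20 and 0.18) |
| item staffing | workers ∈ {1,2,3}, minutes ~ U(2, 60) | plausible ranges; per-item values are assumptions, not calibrated facts |
| true cost per equivalent | region mean N(18, 4), within-region SD 2, floor 5 | centred on the observed CNY 18 |
| cost noise | 5 % relative | survey/ledger noise on operational cost |
| revenue | 74 CNY × allocation population | the allocation rule; allocation population = lag factor (default 1.10) × current residents, a single multiplicative stand-in for the two-year reporting lag under rural population decline |
| expenditure | revenue × (1 + \|N(0.04, 0.05)\|) | spending exceeds current-year revenue via prior-year carryover |

Operational cost is constructed as `true cost per equivalent × realized
equivalents × (1 + noise)` and then quantized to the cent, so with noise off
the pipeline recovers the true cost per equivalent up to that cent
quantization (relative error < 1e−6 at realistic sizes); the recorded ground
truth for the programme share is the share realized after integer rounding
of annual cases (the share actually present in the data), with the drawn
target kept alongside. With 5 % noise the estimate is unbiased, which the
test suite checks across 200 seeds against the Monte-Carlo standard error.

Because revenue follows the allocation rule exactly, generated data do not
reproduce the *observed* pattern that per-capita actual subsidy falls below
the allocation rate — that pattern arises from under-disbursement, which the
study describes only qualitatively and the generator deliberately does not
invent. The packaged regional-aggregate fixture carries the observed
finance pattern instead.

What the generator does **not** emulate: service quality, seasonal or
multi-year dynamics, correlated noise between finance lines, or the true
(unpublished) institution-level microdata distributions. Passing recovery
tests therefore demonstrates the estimator's correctness under the model's
own assumptions, not robustness to real-world misreporting.

## The published-aggregates fixture

`fixture_from_tables()` packages the study's five regional aggregates
(residents, staffing, finance, equivalent totals over 10 health centers
each) as five pseudo-institutions. Each carries exactly two workload
records — one per service class, one annual case at 1 worker ×
(15 × equivalents) minutes — so the fractional regional equivalent totals
pass through the integer `annual_cases` field exactly, and the ordinary
pipeline at `group_by="region"` reproduces every derived cell of the
published tables to the printed cent. Per-institution spread (the published
mean ± SD columns) is not recoverable from aggregates and is reported as
n/a for this fixture.

## Problem sizes

The test suite runs the full 50-institution design once per session plus
small 4–8 institution configurations elsewhere; the bias check uses 200
seeds of a 4-institution design. These sizes keep the whole suite under a
minute while leaving every structural property (5 regions, 10 counties,
catalogue completeness) exercised at full scale.

## Known limitations

* The population denominator is the residents figure recorded by the
  institutions themselves, which can differ from the official budget
  populations; the funding-gap report therefore takes the allocation-basis
  population as an explicit argument rather than inferring it.
* Per-category item counts within the 37-item programme catalogue are an
  assumption (only the 13/37 totals are fixed by the design), and the 71
  primary-medical items are placeholders used only at category granularity.
* The inter-county unit-equivalent ANOVA needs within-county replicates;
  on aggregate fixtures it is reported as undefined.
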