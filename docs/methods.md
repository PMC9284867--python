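# Methods

## Data model

One ledger row is one procurement event: medicine code, purchase month,
purchaser category (ME/MH/MD/OI), procuring-entity id, quantity of
dispensing units, nominal unit price, procurement type
(competitive/waiver/not required) and status (active/inactive). Dates
are handled at month resolution everywhere: deflation needs the month
and aggregation needs the calendar year, so days carry no information
for any quantity the pipeline computes. The medicine master keys each
code to a name, a strength in mg of active ingredient per dispensing
unit, and one or more dosage forms; a drug marketed as both ampoule and
capsule at the same strength is one master row, because every analysis
pools dosage forms of equal strength.

## Filter cascade and inclusion rule

Eligibility keeps exactly the rows with `status = active` and
`procurement_type = competitive`; the filter is idempotent and
order-preserving. The inclusion rule then selects medicines bought by
the inclusion category (default Ministry of Health) in at least
`min_years_purchased` (default 5) *distinct calendar years* of the
window — counting years with at least one qualifying purchase, not
purchase events. The rule is evaluated *after* the eligibility filter;
whether it should run before or after is genuinely ambiguous, so the
inclusion category and threshold are configuration, and the run
manifest records the counts at every stage.

## Deflation

Nominal prices are restated at a reference month (default 2019-07) by
the ratio of index values, `p·idx[ref]/idx[m]`. The index is a file
input (monthly `month,index_value` CSV); when only annual variation
factors are available, `PriceIndexSeries.from_annual_factors` expands
them into a step-wise monthly series constant within each year, which is
how an annual-variation CPI calculator behaves. Adjustment satisfies a
composition law (adjust to ref₁ then ref₂ equals adjusting directly,
to 1e-9 relative) and commutes with aggregation (deflate-then-sum equals
month-group-then-deflate), both enforced by tests. Sources differ on
whether the study reference month is July or December 2019; the package
does not resolve that — the reference month is explicit configuration
echoed into the run manifest.

## Aggregation and shares

Per stratum (medicine × category, optionally × year) the pipeline
accumulates `V = Σ q·s` mg and `E = Σ q·p` currency in ledger order and
derives `WAP/mg = E/V`, the volume-weighted mean of per-mg prices. The
accumulation is a plain in-order summation (ledgers here are thousands
of rows, not millions), which keeps the invariant that a naive
per-record loop reproduces the aggregate bit-for-bit. Percentage shares
are computed on full-precision aggregates and rounded half away from
zero to two decimals only at the display edge, so rounding error never
compounds into derived quantities.

## Avoidable expenditure

Within each medicine × year, the benchmark is the minimum WAP/mg among
categories with positive volume; exact ties are broken by the fixed
category order ME < MH < MD < OI and logged. A plain reading of the
usual verbal description ("spend divided by the lowest price times the
price paid") would produce a *larger* hypothetical spend and hence
non-positive savings; the economically coherent counterfactual is the
transposition `V·w* = E·(w*/w)` — what the same mg volume would have
cost at the benchmark price — and that is what the package implements.
It reproduces the published totals and keeps avoidable expenditure
non-negative by construction. `AE = E − V·w*` is clamped at zero against
1-ulp float noise for a category that pays exactly the benchmark price.
The benchmark category's own entry and zero-volume strata are NA (not
zero): totals sum only non-NA cells, matching the published convention.
Additional quantity is `AE/w*` mg, converted to units by the strength
and rounded half away from zero; whether published unit counts were
rounded or truncated is unstated, so half-away rounding is used and the
±1-unit ambiguity is absorbed by the documented ±2 reconciliation slack.

## Pattern classification

The market-vs-inelastic dichotomy for a medicine × category trajectory
is made operational with the Spearman rank correlation ρ between annual
volume (mg) and annual WAP/mg over years with positive volume: *market*
if ρ ≤ −0.5, *inelastic* if |ρ| < 0.3, otherwise *indeterminate*;
fewer than 4 usable years yields *insufficient data*. The thresholds
and minimum are exposed in configuration: they are the package's
reproducible surrogate for what is otherwise a visual reading of
trajectory plots. Rank correlation makes labels invariant to
positive rescaling of either axis and to year order. A zero-variance
WAP (or volume) series gets ρ = 0 — literal price constancy being the
paradigm case of inelasticity. Note the statistical limits at a 7-year
window: under independence of price and volume the null distribution of
ρ is wide (sd ≈ 0.41 at n = 7), so roughly half of truly unrelated
trajectories land in the |ρ| < 0.3 band; the inelastic label is the
modal outcome under the null, not a near-certain one, and the
Monte-Carlo test asserts exactly that.

## Synthetic generator

The generator emulates the study conditions: a 2013-01 … 2019-12 window,
ten medicines whose per-mg base prices span four orders of magnitude
(0.05/mg for a hormone-therapy tablet up to 24/mg for a monoclonal
antibody), category price multipliers λ = {MH 1.0, ME 1.1, OI 1.25,
MD 1.5} (the defense ministry pays the largest markup, the health
ministry is the benchmark), monthly inflation 0.5% (≈6.2%/year,
CPI-like for Brazil over the period), multiplicative log-normal price
noise with mean 1 and cv 0.1 (prices are positive and right-skewed),
and 15% contamination with inactive or non-competitive rows. Annual
volumes are spread uniformly over months with the remainder to the
earliest months, and all draws come from one seeded generator, so a
seed fixes the ledger byte-for-byte.

Because the emitted index series follows the same drift as prices,
deflated per-mg prices are exactly `base·λ` restated at the reference
month, giving closed-form truth for every downstream quantity:
WAP/mg, expenditure, benchmark category, avoidable spend
`V·base·(λ−λ_min)` and additional mg. Noise-free, the pipeline matches
this truth to 1e-9 relative; with cv 0.1 noise and ~200 purchase events
per stratum, recovered avoidable expenditure is within 3% of truth for
well-separated multipliers (the validation scenario uses λ ∈ {1, 2};
with closely spaced multipliers the *difference* of two noisy WAPs is
relatively much noisier, and only totals over many strata are
recoverable at that tolerance). What the generator does **not** emulate:
demand response to price (volumes are exogenous), entity-level
heterogeneity, seasonal purchasing, or real CPI variability — so
passing recovery tests demonstrates correctness of the pipeline's
arithmetic and filtering, not robustness to every feature of real
registry data.

## Reference tables and reconciliation

The packaged CSVs carry the printed cells of the study's three summary
tables (volumes, spending, avoidable expenditure/additional units).
Reconciliation re-runs the pipeline's own share and additional-quantity
formulas over those cells. Printed integer cells are individually
rounded, so sums reproduce printed totals within ±2 currency units or
units; subtotals of the avoidable table are summed from the printed
per-row *Total* cells, because the per-year unit cells each carry their
own rounding and drift a few units further over 40-cell sums.
Recomputed percentage shares (spending shares, additional-unit shares
of purchased quantities) reproduce the printed two-decimal values
exactly.

## Problem sizes and determinism

The default synthetic scenario is 3,360 eligible events (10 medicines ×
4 categories × 7 years × 12 monthly events) plus contamination; the
noisy-recovery scenario uses 2 medicines × 2 categories × 2 years × 204
events ≈ 1,900 rows. Both run in seconds. All CSV outputs and the run
manifest are byte-deterministic for fixed inputs and configuration; the
CLI aborts with a stage-labelled message (naming the offending month for
index-coverage failures) and non-zero status on any invalid input.
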