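# Methods

## Model structure and assumptions

The simulator is a deterministic annual stock-flow model of a municipal
long-term-care-insurance fund. Time advances in discrete one-year steps with
end-of-year compounding; the base year is 2019 and the horizon runs
inclusively through 2030 (12 simulated years). No sub-annual integration
step is used: all flows are annual rates and all drivers compound
geometrically, so an annual step is exact, not an approximation.

Four exogenous drivers evolve independently: the insured urban-employee pool
(base 2,738,800 persons, +6%/yr), the insured urban/rural-resident pool
(base 1,480,000 persons, +5.9%/yr), per-capita disposable income of urban
residents (base ¥55,870, +8%/yr), and per-capita GDP (base ¥142,739,
+5%/yr). The model assumes stable economic growth, no fund investment
income, and that LTCI benefit eligibility equals severe disability within
the insured population. Retirees are not a separate pool: they are folded
into the employee pool, whose growth rate already reflects total insured
counts.

### Payer structure

Three premium streams fund the pool:

* individuals in **both** pools pay `r_ind` (default 0.06%) of per-capita
  disposable income;
* enterprises pay `r_ent` (default 0.04%) of per-capita GDP for the
  **employee** pool;
* the government subsidises `r_gov` (default 0.04%) of per-capita GDP for
  the **resident** pool.

The source material states the contribution bases but not which pool each
payer covers. The split above is a reconstruction, and it is the unique
simple assignment consistent with both published 2030 revenue deltas at
once: raising `r_ind` from 0.06% to 0.1% must add ≈¥416M, which requires the
individual base to be *both pools* times disposable income
(0.0004 × 7.98M persons × ¥130.3k ≈ ¥415.8M); raising the joint
enterprise/government rate from 0.04% to 0.07% must add ≈¥584M, which
requires the joint base to be *both pools* times GDP
(0.0003 × 7.98M × ¥244.1k ≈ ¥584.4M) — i.e. enterprise and government
together cover everyone exactly once. Splitting that coverage as
employees-to-enterprise / residents-to-government follows how Chinese pilot
schemes assign payers; any other disjoint split of the two pools gives the
same totals, so the headline numbers do not depend on the finer choice.

### Expenditure and the escalation rate

Annual expenditure is
`N_insured · d_sev · (p_inst·c_inst + p_home·c_home) · reimb · (1+esc)^t`,
with defaults: severe disability rate 0.3%, care mix 3% institutional
(¥30,000/yr) / 97% home (¥18,000/yr), reimbursement 70%. The net base-year
cost per beneficiary is ¥12,852, giving 2019 expenditure ≈ ¥162.7M.

Insured-population growth alone (~6%/yr) cannot produce the ≈8.8× expenditure
growth the projection exhibits, so the model carries a single geometric
escalation rate `esc` on the net per-beneficiary cost, absorbing care-cost
inflation and disability-prevalence drift together. No direct observation of
`esc` exists; it is **calibrated** from a scenario anchor whose revenue side
is independent of `esc`: the scenario with individual payment rate 0.1% and
its known 2030 annual balance of +¥381.7M. Since revenue there is fixed, the
required 2030 expenditure is `E* = R(2030) − 381.7M ≈ ¥1,437M`, and because
expenditure is a pure power law in `(1+esc)`,

```
esc = (E* / E(2030; esc=0))^(1/11) − 1 = 0.150412…
```

The calibration is exact (re-simulating reproduces the anchor balance to
floating-point precision) and is re-solved at run time wherever it matters;
the packaged default `DEFAULT_ESC = 0.15041247366147315` is that same value
frozen for convenience. A plausible decomposition — cost growth tied to the
8%/yr income growth plus ≈6.5%/yr residual prevalence escalation, since
1.08 × 1.065 ≈ 1.150 — is offered as interpretation only; the model uses the
single combined rate. The anchor is deliberately a *revenue-side* scenario,
which leaves every expenditure-side published value (reimbursement and
disability batteries) as untouched validation targets; all of them reproduce
to within 0.1%.

### Balance and deficit detection

"Balance" is reported two ways: the annual net flow `R(t) − E(t)` and its
running sum (the fund stock, absent investment income). Published deficit
statements match the **annual** balance, which is therefore the default mode
of `deficit_year`. Under calibrated defaults the annual balance rises to
¥252M around 2023, then declines and first turns negative in 2030 at
−¥34.1M.

## Scenario engine

Four levers are recognised: `r_ind`, `reimb`, `d_sev`, and `r_gov_ent`
(enterprise and government rates moved jointly and equally, as pilot
practice keeps them). The built-in batteries cover the policy-relevant
ranges: r_ind ∈ {0.06, 0.08, 0.1}%, reimb ∈ {50…90}%, joint rate ∈
{0.04…0.07}%, d_sev ∈ {0.3, 0.4, 0.5}%. Scenario application is pure
(the base parameter set is never mutated), and revenue-side levers provably
leave expenditure untouched and vice versa.

The intervention comparison bumps one lever by 10% (relative) and reports
the per-year percent change of the annual balance, using
`100·(B_bumped − B_base)/|B_base|` so the sign of the *effect* rather than
of the baseline determines the sign of the output. Years with a baseline
balance of exactly zero yield NaN and are flagged, not raised. Because
expenditure is exactly linear in both `reimb` and `d_sev`, their 10%-bump
effects are identical to machine precision; the ranking reports the tie in
the documented stable order `d_sev, reimb, r_gov_ent, r_ind`. The full 2030
ordering — disability rate ≥ reimbursement ratio > joint enterprise/
government rate > individual rate — is a structural consequence of the flow
magnitudes (10% of ¥1,437M expenditure vs 10% of ¥779M joint revenue vs 10%
of ¥624M individual revenue). Published per-year percentage tables near the
2027 zero-crossing of the baseline balance are sensitive to an unstated sign
convention and an apparent nonlinearity in the disability effect that a
linear expenditure term cannot produce; only the qualitative ordering is
modelled here.

## Historical validation arithmetic

`percent_error(actual, simulated) = 100·(simulated − actual)/actual`, and
the validation table (insured-employee counts and per-capita disposable
income, 2012–2018, fourteen pairs) ships as a checksummed CSV fixture. The
published income-series error rates carry the opposite sign — they equal
`100·(actual − simulated)/actual` — while the population-series rates match
the convention above; the published 0.67% "average error" is the signed mean
of the rates *as printed*. A `HistoricalPair` therefore records the reported
rate alongside the raw pair and prefers it when averaging, so `mean_error`
over the packaged table reproduces 0.67% while `percent_error` itself stays
a single consistent formula. The absolute mean of the printed rates is
1.94%, also computed (`mean_absolute_error`) as the more honest typical-
deviation summary. The simulated historical columns themselves come from the
original study's undisclosed fit and are treated as given data, not
regenerated.

## Sensitivity analysis

The Monte-Carlo analysis draws each lever independently from a uniform
distribution over its scenario range (r_ind ∈ [0.06, 0.1]%, reimb ∈
[50, 90]%, joint rate ∈ [0.04, 0.07]%, d_sev ∈ [0.3, 0.5]%) — no
correlation structure is imposed, as none is stated for the original
verification design. The default draw count is 200, matching that design;
the default seed is 2019 (no seed is published; the value is fixed and
recorded inside every `Envelope` so results are reproducible and
self-describing). Per-year summaries are min, 5th/95th percentile, median,
and max of the annual balance. With 200 draws the envelope is a
verification-style spread, not a precise quantile estimate; variance-based
indices (e.g. Sobol) are out of scope.

## Synthetic yearbook series

`generate_yearbook_series` emulates the statistical shape of municipal
yearbook series: `x0·(1+g)^t·exp(ε_t)` with `ε_t ~ N(0, σ²)`. Noise is
multiplicative lognormal because yearbook-scale quantities are positive and
grow geometrically; σ ≈ 0.02 matches the 1–2% deviations seen in the real
validation table. What the generator does **not** emulate: serial
correlation of deviations, structural breaks (policy changes, boundary
redefinitions), and reporting revisions. Tests passing on synthetic series
therefore demonstrate the arithmetic and recovery machinery, not robustness
to those real-data features.

## Numerical choices, degenerate inputs, limitations

* Internal units are yuan and persons; helpers convert to millions/billions
  of yuan and 万 (10⁴ persons) only for reporting. CSV output keeps full
  double precision (`%.17g`); read-back is bit-exact with a correctly
  rounding parser (`pandas.read_csv(..., float_precision="round_trip")`).
* Comparisons against published values use 0.2% relative tolerance — the
  published figures carry 3–4 significant figures.
* Parameter validation: populations/costs/bases strictly positive; payment
  and benefit shares in [0, 1]; growth and escalation rates in (−1, 1); the
  care-mix shares must sum to 1 within 1e-12; the horizon must contain at
  least one year. Calibration rejects anchors whose implied expenditure is
  non-positive, and anchors at the base year (no growth interval to solve).
* The closed-form driver projection and the year-stepped recurrence are two
  independent code paths to the same quantities; their agreement to 1e-12
  relative is enforced by the test suite.
* Problem sizes are the study's own: a 12-year horizon, 4-lever scenario
  grids of 3–5 points, 200 sensitivity draws. Everything runs in well under
  a second.
* Main limitations: the escalation rate conflates cost inflation with
  prevalence drift and is anchored to a single scenario figure; disability
  dynamics are static (no disability-stock accumulation, which the source
  projections appear to contain implicitly); no fund investment income; no
  retiree-specific premium stream.
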