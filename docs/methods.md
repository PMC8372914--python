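# Methods

## Model structure

The model is a cohort decision tree: three structurally identical trees
(one per device strategy — condom-UBT, ESM-UBT, Bakri-UBT), each
evaluated on the full annual cohort of women whose atonic PPH is
refractory to uterotonics. The eligible cohort is derived as
`deliveries in public facilities (20,785,669) × PPH incidence (0.03606)
× atonic share (0.80) × uterotonic-failure share (0.10) = 59,962`.
UBT treatment is a discrete short event without recurrence or state
transitions, so no Markov structure is used; costs are one-time and
undiscounted, while health outcomes extend over the lifetime horizon
and are discountable.

Structural assumptions, each carried as an explicit `PathwayPolicies`
switch or documented constant:

- All eligible women receive the same device system-wide (hence one
  tree per strategy rather than a decision node inside the engine).
- Primary-level facilities stabilize, insert the balloon at
  primary-level prices, and refer every case to secondary care
  (one referral cost); no re-insertion downstream.
- Surgery (pooled "devascularization" = B-Lynch/stepwise
  devascularization, and obstetric hysterectomy) is available at
  secondary and tertiary levels with level- and device-specific unit
  costs.
- ICU exists at tertiary level only; a secondary-care case needing ICU
  pays one additional referral. ICU cost is charged on top of the
  inpatient (IPD) cost, not instead of it, since both are separate
  per-event unit costs.
- Hysterectomy is definitive for bleeding control (no
  post-hysterectomy failure branch).
- Provider training (INR 375) is charged once per patient as a
  health-system item; household out-of-pocket expenditure (INR 2,755)
  is charged once per patient at every terminal.

Branch probabilities stay symbolic (parameter references, with a
structural complement branch on every chance node) and resolve at
evaluation time, so sensitivity analyses re-evaluate the same
structure. An exhaustive path-enumeration oracle cross-checks the
rollback evaluation to 1e-12 in the test suite.

### Mortality

The published death counts (214/214/216) cannot be derived from the
stated mortality inputs under any single assignment rule we could
construct (all-cause maternal mortality 0.00308 over the cohort gives
184.7; the differences between strategies imply contradictory excess
rates). The package therefore makes the death rule explicit and
configurable: the default applies background all-cause maternal
mortality uniformly across terminals (`background_only`), and an
optional excess probability on the mass left uncontrolled after the
balloon (`background_plus_excess`, default excess 0) is available for
scenario analysis. Deaths and death-driven DALY levels are consequently
reported but not treated as reproduction targets; orderings across
strategies are invariant to this choice.

## Costs and perspectives

The societal perspective sums health-system and household payers; the
health-system perspective drops the household items. All costs are in
2017-18 INR (USD at 64.5 INR). Incremental per-patient costs are
perspective-invariant here because the household component is identical
across arms. The model's absolute health-system level sits ~INR 379
per patient above the published per-patient figure, which is the
per-patient training cost: the published tables appear to exclude
training from the health-system panel while keeping it in the societal
total. Incremental results — which drive every cost-effectiveness
quantity — are unaffected, and the package keeps training as a
health-system item.

## DALYs

`DALY = YLL + YLD`, no age weighting. Disability assignment per
terminal: control by the balloon alone → mild maternal haemorrhage
(0.114) for the 6-week postpartum period (0.11 y); any
devascularization, hysterectomy or ICU admission → severe maternal
haemorrhage (0.324) applied once per patient (weights describe a health
state, not a count of events); hysterectomy additionally → secondary
infertility (0.005, proxied by puerperal-sepsis infertility) over the
remaining reproductive span (46 − 21 = 25 y). Decedents accrue YLL
only (remaining life expectancy 53.79 y), never YLD, to avoid double
counting. ICU-admitted but balloon-controlled cases take the severe
weight, following the grouping of ICU admission with the severe state.

Discounting of future life-years is configurable because the published
convention is not stated: `annual_annuity` (default,
`(1−(1+r)^−L)/r`, the Indian reference-case convention), `continuous`
(`(1−e^{−rL})/r`), or `none`. The default rate is 3% (0–5% range).
The cross-strategy DALY ordering (ESM < condom < Bakri) holds under
every method and rate in range, and is what the tests assert; absolute
per-patient DALY levels additionally depend on the death rule above
and are not asserted.

## Cost-effectiveness arithmetic

ICER = Δcost / ΔDALYs averted, reported as undefined when the effect
difference is below 1e-12. NMB = ΔDALYs averted × WTP − Δcost at
WTP = INR 24,211/DALY. Because a negative ICER is ambiguous between
the dominant (cheaper, better) and dominated (costlier, worse)
quadrants, every ICER is accompanied by a dominance label and the NMB.
The exact origin (no difference in either dimension) is labelled as a
zero-magnitude trade-off rather than dominance. Comparisons are
pairwise against condom-UBT only; no three-way efficiency frontier is
computed.

## Sampling distributions

Each parameter carries `(value, low, high)`. For probabilistic
analysis, Beta distributions are assigned to probabilities, proportions
and disability weights, Gamma to costs, counts, rates and durations,
parameterized by **method of moments** with mean = value and
sd = (high − low)/3.92, i.e. the interval is treated as a symmetric
95% CI (the divisor is a convention; the source tables do not state
whether limits are CIs or absolute bounds). Degenerate intervals yield
fixed parameters; a Beta whose implied variance is infeasible falls
back to fixed with a logged warning.

Device-effectiveness parameters carry a ceiling of 0.983 (the highest
effectiveness reported in the literature); draws above it are rejected
and redrawn. Plain rejection would shift the sampled mean well below
the point estimate (for ESM, 0.953 → 0.926, i.e. tens of Monte-Carlo
standard errors), de-centring the whole probabilistic analysis, so the
Beta hyperparameters are re-fit such that the **truncated**
distribution has the point estimate as its mean: the precision
α+β is kept at its method-of-moments value where possible and raised
(narrowing the spread) only when no mean-preserving truncated Beta
exists at that precision — which is the case for ESM, whose
method-of-moments spread is wider than any distribution bounded at
0.983 with mean 0.953 can support. Sampled means then recover the base
values to Monte-Carlo error, which the tests assert for every
parameter.

## Sensitivity and value-of-information analysis

**OWSA** sets each parameter to its low and high limit in turn (others
at base), re-evaluates both strategies, and ranks by the swing in
incremental NMB. NMB rather than ICER is the tornado scale because the
ICER is unbounded near a zero effect difference; the ICER is recorded
alongside and the ranking agrees in regular regions.

**PSA** draws all non-fixed parameters jointly and independently per
iteration (no correlation structure is imposed; none is stated in the
sources) and re-evaluates both arms of a comparison on the shared draw
(common random numbers for shared parameters; device-specific
parameters are separate parameters and so are sampled separately).
Cohort size and delivery counts are held at base inside the PSA:
per-patient incremental results are cohort-invariant, and resampling
them would only inject noise into totals. The discount rate and
disability weights are sampled like any other parameter. Results are
deterministic given the seed.

**CEAC**: fraction of draws with positive incremental NMB over a WTP
grid (default 0–400,000 INR in 1,000-INR steps, always including
24,211, 1× GDP per capita 127,816, and 3× GDP 383,448). At WTP = 0 the
curve equals the cost-saving fraction by construction.

**EVPI**: with two strategies the comparator's incremental NMB is
identically zero, so per-person EVPI = E[max(0, NMB)] − max(0, E[NMB]),
scaled by an undiscounted one-time annual cohort (59,962) for the
population figure. At reference settings the package computes a
population EVPI of ≈ INR 12 million for the ESM-vs-condom decision,
the same order as published (the exact figure depends on the unstated
hyperparameterization above).

### Reproduction status of published uncertainty results

The base-case incrementals reproduce the published values closely
(−73 / +10,222–10,224 INR per patient; surgery and ICU counts within
0.1%). The published probability that ESM-UBT is cost-effective
(63.5%) is **not** recovered: the package obtains ≈ 50% at n = 10,000.
The discrepancy is structural, not stochastic: the published base-case
NMB of 809 INR is dominated by a DALYs-averted term (0.030/patient)
that is itself driven by the irreproducible death assignment discussed
above, whereas this model's DALY difference at the default death rule
contributes only ≈ 37 INR. With a base-case NMB of ≈ 110 INR and a
left-skewed condom-effectiveness distribution (mean 0.923 against a
0.983 ceiling puts the median near 0.945), the positive-NMB fraction
sits near one half. All truncation variants considered give 43–50%.
The Bakri-vs-condom probability (published 0.1%) reproduces at 0.0%.

## Synthetic data and what the tests show

The synthetic module generates (a) reduced single-facility micro-models
whose expected counts, costs and DALYs are computed by independent
closed-form arithmetic embedded in the generator, and (b) randomized
parameter files that keep the reference registry's names and
statistical shape (bounded proportions, positively skewed log-normal
cost jitter with ±40% limits, facility shares drawn jointly to sum
below one) while drawing fresh values. Tests against (a) verify the
engine and reducers to 1e-9 relative; tests against (b) verify that
the pipeline is total over valid inputs. Neither emulates real-world
features such as correlated costs across facility levels, within-level
facility heterogeneity, or non-Beta effectiveness evidence, so passing
tests certify the computational machinery and the published-table
reproduction, not external validity of the inputs.

## Numerical choices

- Sibling branch probabilities must sum to 1 within 1e-9; complement
  branches make this structural for binary nodes.
- Rollback vs path-enumeration agreement: 1e-12 per terminal.
- ICER undefined below an effect difference of 1e-12.
- Reports round INR to whole rupees, DALYs to 4 decimals,
  probabilities to 3; USD is converted from unrounded INR, then
  rounded. Internal computation is never rounded.
- Zero cohorts yield zero totals and NaN per-patient values.
- Default problem sizes: full cohort 59,962 for deterministic runs;
  n = 10,000 PSA draws (the published simulation count), seeded.

## Known limitations

- The death-assignment rule, the published absolute DALY levels, and
  the PSA hyperparameterization are under-specified in the sources;
  the package exposes them as explicit conventions rather than guessing
  silently, and the corresponding published figures are treated as
  orders of magnitude, not targets.
- No anemia comorbidity, blood-transfusion itemization, wage or
  productivity losses (excluded from scope); no correlation structure
  in the PSA; no EVPPI; no efficiency frontier across all three
  devices.
- Costs are from a single-state costing exercise at 2017-18 prices
  with a fixed USD rate; no inflation adjustment across years.
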