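# ubtcea

Decision-analytic cost-effectiveness model for **uterine balloon
tamponade (UBT)** devices in the management of **atonic post-partum
hemorrhage (PPH)** at Indian public health facilities.

Atonic PPH — bleeding from a uterus that fails to contract after
delivery — is the leading direct cause of maternal death in India.
When uterotonic drugs fail, national guidelines recommend inserting a
balloon tamponade device; three devices are in use: the improvised
**condom-UBT** (standard of care), the low-cost **ESM-UBT** kit, and
the commercial **Bakri-UBT**. This package evaluates each device
strategy on an annual cohort of UBT-eligible women with a decision-tree
cohort model and answers, for analysts and health-technology-assessment
teams: which device offers the best value, and how certain can a
decision-maker be?

## The model

A decision tree pushes the eligible cohort (59,962 women/year) through:

1. **facility level** accessed (primary 18.6%, secondary 32.9%,
   tertiary 48.5%); primary-level cases are stabilized, receive the
   balloon at primary prices, and are referred to secondary care;
2. **bleeding control** by the device (effectiveness 0.923 condom,
   0.953 ESM, 0.843 Bakri) versus a **surgical cascade**: immediate
   obstetric hysterectomy (14.6%) or uterus-preserving
   devascularization, itself followed by hysterectomy in 22.0% of
   cases;
3. **ICU admission** (2.5% of controlled, 76.9% of uncontrolled cases),
   available at tertiary level only — secondary-level cases needing ICU
   incur an extra referral.

Each terminal accrues health-system costs (insertion, inpatient stay,
surgery, ICU, referral, provider training) and the household
out-of-pocket expenditure (societal perspective = both payers).
Outcomes are **DALYs**: `DALY = YLL + YLD`, with
`YLL = deaths × life expectancy at death` (53.79 remaining years,
discountable at 3%/yr) and
`YLD = cases × disability weight × duration` (mild haemorrhage 0.114
for control by balloon alone, severe 0.324 for any surgical/ICU
pathway, plus secondary infertility 0.005 over the remaining 25
reproductive years after hysterectomy).

Strategies are compared pairwise against condom-UBT via the ICER
(incremental cost per DALY averted) and the **net monetary benefit**
`NMB = ΔDALYs averted × WTP − Δcost` at the Indian willingness-to-pay
threshold of INR 24,211 per DALY averted. Uncertainty is handled by
one-way sensitivity analysis (tornado on incremental NMB),
10,000-draw probabilistic sensitivity analysis (Beta distributions for
probabilities/proportions/weights, Gamma for costs and resources,
parameterized by method of moments from the interval limits),
cost-effectiveness acceptability curves, and the expected value of
perfect information.

## Worked example

```sh
ubtcea run --out reports
```

writes `strategy_results.csv`:

```
strategy,...,per_patient_societal_cost_inr,per_patient_health_system_cost_inr,per_patient_daly,deaths,patients_operated,icu_admissions,...
condom_ubt,...,6341,3586,0.0985,185,4617,4934,...
esm_ubt,...,6268,3513,0.0970,185,2818,3596,...
bakri_ubt,...,16563,13808,0.1026,185,9414,8503,...
```

Managing the cohort with condom-UBT costs INR 6,341 per patient from
the societal perspective and leads to an expected 4,617 surgical
patients and 4,934 ICU admissions per year; ESM-UBT roughly halves the
surgical load (2,818), while Bakri-UBT doubles it (9,414) at more than
twice the per-patient cost. `cea_results.csv` gives the pairwise
comparison:

```
intervention,comparator,perspective,incremental_cost_inr,...,dalys_averted,icer_inr_per_daly,nmb_inr,dominance
esm_ubt,condom_ubt,societal,-73,...,0.0015,-47700,110,dominant
bakri_ubt,condom_ubt,societal,10222,...,-0.0041,-2502647,-10320,dominated
```

ESM-UBT saves INR 73 per patient while averting DALYs (dominant:
cost-saving and more effective; positive NMB of 110); Bakri-UBT costs
INR 10,222 more per patient and loses health (dominated, NMB −10,320).
Note that a negative ICER means opposite things in the two rows, which
is why every ICER is reported with its dominance label and NMB.

The full published analysis — base case, tornado diagrams for both
device pairs, two 10,000-draw PSAs, acceptability curves and EVPI —
is one command:

```sh
ubtcea reproduce-paper --out reports --n 10000 --seed 42
```

`ubtcea owsa`, `ubtcea psa`, `ubtcea ceac`, `ubtcea evpi` and
`ubtcea dump-fixture` run the individual stages; every run writes a
manifest with content hashes, the seed and the package version.

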