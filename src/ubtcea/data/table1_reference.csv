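name,group,value,low,high,family,units,description
age_onset,duration,21,16.8,25.2,gamma,years,Median age at first childbirth of the modelled cohort
deliveries_public,count,20785669,16628535,24942803,gamma,deliveries/year,Annual deliveries in Indian public health facilities (includes home deliveries)
p_mort_all_cause,probability,0.00308,0.00246,0.00369,beta,,Probability of all-cause maternal mortality in India
p_mort_pph,probability,0.00108,0.00086,0.00130,beta,,Probability of maternal mortality due to PPH in India
p_primary,proportion,0.18610,0.14888,0.22332,beta,,Proportion of deliveries at primary healthcare level
p_secondary,proportion,0.32930,0.26344,0.39516,beta,,Proportion of deliveries at secondary healthcare level
p_tertiary,proportion,0.48460,0.38768,0.58152,beta,,Proportion of deliveries at tertiary healthcare level
p_pph_incidence,probability,0.03606,0.02885,0.04327,beta,,Incidence of post-partum haemorrhage among deliveries in India
p_atonic_share,proportion,0.80,0.64,0.96,beta,,Share of PPH cases that are atonic
p_uterotonic_failure,proportion,0.10,0.08,0.12,beta,,Share of atonic PPH cases not controlled by uterotonic drugs (eligible for UBT)
cohort_ubt_eligible,count,59962,47970,71955,gamma,women/year,Annual cohort of women eligible for UBT insertion after atonic PPH
p_eff_condom,probability,0.923,0.738,0.983,beta,,Proportion of atonic PPH cases controlled after condom-UBT insertion
p_eff_bakri,probability,0.843,0.674,0.983,beta,,Proportion of atonic PPH cases controlled after Bakri-UBT insertion
p_eff_esm,probability,0.953,0.762,0.983,beta,,Proportion of atonic PPH cases controlled after ESM-UBT insertion
p_hyst_immediate,proportion,0.14634,0.11707,0.17561,beta,,Proportion of uncontrolled cases undergoing obstetric hysterectomy immediately after UBT
p_hyst_after_devasc,proportion,0.21951,0.17561,0.26341,beta,,Proportion of uncontrolled cases undergoing hysterectomy after devascularization surgery
p_icu_controlled,probability,0.025,0.020,0.030,beta,,Probability of ICU admission when bleeding is controlled with UBT alone
p_icu_uncontrolled,probability,0.769,0.61520,0.92280,beta,,Probability of ICU admission when bleeding is uncontrolled after UBT
cost_insert_condom_primary,cost,161,97,226,gamma,INR,Condom-UBT insertion cost at primary level (includes device cost INR 128)
cost_insert_condom_secondary,cost,341,264,419,gamma,INR,Condom-UBT insertion cost at secondary level
cost_insert_condom_tertiary,cost,419,342,510,gamma,INR,Condom-UBT insertion cost at tertiary level
cost_insert_esm_primary,cost,432,232,639,gamma,INR,ESM-UBT insertion cost at primary level (includes device cost INR 397)
cost_insert_esm_secondary,cost,567,381,748,gamma,INR,ESM-UBT insertion cost at secondary level
cost_insert_esm_tertiary,cost,671,548,806,gamma,INR,ESM-UBT insertion cost at tertiary level
cost_insert_bakri_primary,cost,9585,4792,14125,gamma,INR,Bakri-UBT insertion cost at primary level (includes device cost INR 9554)
cost_insert_bakri_secondary,cost,9746,5676,13855,gamma,INR,Bakri-UBT insertion cost at secondary level
cost_insert_bakri_tertiary,cost,9874,7288,12371,gamma,INR,Bakri-UBT insertion cost at tertiary level
cost_devasc_esm_secondary,cost,3671,2393,5095,gamma,INR,Devascularization surgery cost at secondary level after ESM-UBT
cost_hyst_esm_secondary,cost,7734,5114,10494,gamma,INR,Obstetric hysterectomy cost at secondary level after ESM-UBT
cost_devasc_esm_tertiary,cost,3335,2618,4108,gamma,INR,Devascularization surgery cost at tertiary level after ESM-UBT
cost_hyst_esm_tertiary,cost,5579,4386,6908,gamma,INR,Obstetric hysterectomy cost at tertiary level after ESM-UBT
cost_devasc_condom_secondary,cost,4864,3186,6733,gamma,INR,Devascularization surgery cost at secondary level after condom-UBT
cost_hyst_condom_secondary,cost,7788,5025,10849,gamma,INR,Obstetric hysterectomy cost at secondary level after condom-UBT
cost_devasc_condom_tertiary,cost,3418,2703,4154,gamma,INR,Devascularization surgery cost at tertiary level after condom-UBT
cost_hyst_condom_tertiary,cost,5470,4276,6734,gamma,INR,Obstetric hysterectomy cost at tertiary level after condom-UBT
cost_devasc_bakri_secondary,cost,4954,3302,6701,gamma,INR,Devascularization surgery cost at secondary level after Bakri-UBT
cost_hyst_bakri_secondary,cost,7721,5166,10668,gamma,INR,Obstetric hysterectomy cost at secondary level after Bakri-UBT
cost_devasc_bakri_tertiary,cost,3418,2683,4173,gamma,INR,Devascularization surgery cost at tertiary level after Bakri-UBT
cost_hyst_bakri_tertiary,cost,5470,4334,6688,gamma,INR,Obstetric hysterectomy cost at tertiary level after Bakri-UBT
cost_icu_tertiary,cost,4896,3244,6746,gamma,INR,ICU admission cost at tertiary level for atonic PPH
cost_ipd_secondary,cost,1774,1083,2548,gamma,INR,Inpatient admission cost at secondary level for atonic PPH
cost_ipd_tertiary,cost,1806,1335,2315,gamma,INR,Inpatient admission cost at tertiary level for atonic PPH
cost_referral,cost,1001,801,1201,gamma,INR,Health system cost for referral of a patient
cost_training,cost,375,300,450,gamma,INR,Healthcare provider training cost per patient
cost_oope,cost,2755,2204,3306,gamma,INR,Out-of-pocket expenditure for childbirth (household)
discount_rate,rate,0.030,0.000,0.050,gamma,/year,Annual discount rate for health outcomes
dw_mild_haem,weight,0.114,0.078,0.159,beta,,Disability weight for maternal haemorrhage with less than 1 liter blood loss
dw_severe_haem,weight,0.324,0.220,0.442,beta,,Disability weight for maternal haemorrhage with greater than 1 liter blood loss
dw_infertility,weight,0.005,0.002,0.011,beta,,Disability weight for secondary infertility (proxy: infertility due to puerperal sepsis)
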