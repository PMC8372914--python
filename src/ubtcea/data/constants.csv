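name,group,value,low,high,family,units,description
wtp_per_daly,cost,24211,24211,24211,fixed,INR/DALY,India-specific willingness-to-pay threshold per DALY averted (2017)
gdp_per_capita,cost,127816,127816,127816,fixed,INR,Indian GDP per capita used for threshold multiples
usd_rate,rate,64.5,64.5,64.5,fixed,INR/USD,Currency conversion rate for 2017-18
life_expectancy_remaining,duration,53.79,53.79,53.79,fixed,years,Remaining age-specific life expectancy at age 21 (Indian female abridged life tables)
duration_haemorrhage,duration,0.11,0.11,0.11,fixed,years,Duration of haemorrhage-related disability (six-week postpartum period)
cohort_age,duration,21,21,21,fixed,years,Age of the cohort at childbirth
infertility_end_age,duration,46,46,46,fixed,years,End of reproductive life-span for infertility disability
duration_infertility,duration,25,25,25,fixed,years,Secondary infertility disability duration (infertility_end_age minus cohort_age)
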