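parameter,value,unit,source
insured_urban_employees,273.88,wan_persons,yearbook_2020
insured_urban_rural_residents,148,wan_persons,yearbook_2020
per_capita_disposable_income,55870,yuan,yearbook_2020
per_capita_gdp,142739,yuan,yearbook_2020
growth_insured_employees,0.06,fraction_per_year,yearbook_2011_2020
growth_insured_residents,0.059,fraction_per_year,yearbook_2011_2020
growth_disposable_income,0.08,fraction_per_year,yearbook_2015_2020
growth_per_capita_gdp,0.05,fraction_per_year,yearbook_2000_2020
individual_payment_rate,0.0006,fraction,assumed
enterprise_contribution_rate,0.0004,fraction,assumed
government_subsidy_rate,0.0004,fraction,assumed
severe_disability_rate,0.003,fraction,literature_survey
share_institutional_care,0.03,fraction,literature
share_home_care,0.97,fraction,literature
cost_institutional_care,30000,yuan_per_year,survey
cost_home_care,18000,yuan_per_year,survey
reimbursement_ratio,0.70,fraction,assumed
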