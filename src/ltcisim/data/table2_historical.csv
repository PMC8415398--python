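year,series,actual,simulated,reported_error
2012,insured_employees,182.15,180.7244,-0.78265
2013,insured_employees,192.26,191.4216,-0.43608
2014,insured_employees,203.64,199.4962,-2.03487
2015,insured_employees,212.23,209.7704,-1.15893
2016,insured_employees,223.16,228.185,2.251748
2017,insured_employees,242.75,241.956,-0.32709
2018,insured_employees,257.4,257.4472,0.018337
2012,disposable_income,37576,38382.08,-2.1452
2013,disposable_income,41360,36772,11.09284
2014,disposable_income,39625,39539.296,0.216288
2015,disposable_income,42607,42923.712,-0.74333
2016,disposable_income,46254,46417.632,-0.35377
2017,disposable_income,50019,50484.128,-0.9299
2018,disposable_income,54401,51847.36,4.694105
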