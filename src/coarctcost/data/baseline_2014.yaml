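# Baseline parameter set for the CoA stenting cost model.
# Event probabilities (beta family) and unit costs (gamma family, GBP 2014).
# Complementary shares are stored once (e.g. the surgery share after a failed
# stent is derived as 1 - p_repeat_stent). The mid-term AWI reintervention
# share is 0.05, the complement of the 0.95 re-coarctation share.
schema_version: 1
p_success: {mean: 0.967, sd: 0.0128}
p_repeat_stent: {mean: 0.5, sd: 0.1}
p_awi: {mean: 0.008, sd: 0.0026}
p_awi_percutaneous: {mean: 0.9, sd: 0.02}
p_imaging_short: {mean: 1.0, sd: 0.01}
p_imaging_mid: {mean: 1.0, sd: 0.01}
p_htn_short: {mean: 0.43, sd: 0.0301}
p_htn_mid: {mean: 0.389, sd: 0.1051}
p_reint_short: {mean: 0.091, sd: 0.0286}
p_reint_mid: {mean: 0.185, sd: 0.0413}
p_reint_awi_short: {mean: 0.1, sd: 0.02}
p_reint_awi_mid: {mean: 0.05, sd: 0.02}
c_stent: {mean: 4507.72, sd: 2612.84}
c_surgery: {mean: 7497.61, sd: 5600.01}
c_awi_interventional: {mean: 10913.59, sd: 5790.90}
c_awi_surgical: {mean: 8545.20, sd: 2305.29}
c_imaging: {mean: 5660.04, sd: 1698.01}
c_htn_annual: {mean: 67.53, sd: 20.26}
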