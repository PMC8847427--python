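# Default dosimetry configuration: threshold-based risk characterization
# for subchronic inhalation of TiO2 under an intensive mask-use scenario.
# NOAEC for lung inflammation from a repeated-dose rat inhalation study;
# 2 masks worn over an 8-h period (change every 4 h).  The acceptable
# exposure level per mask is carried as a documented override; supply
# inhaled_volume_per_period (m^3) and assessment_factor instead (and set
# ael_mask_override to null) to evaluate the explicit derivation chain.
noaec: 0.5                 # mg/m^3
exposure_period_h: 8
masks_per_period: 2
ael_mask_override: 3.6     # µg per mask
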