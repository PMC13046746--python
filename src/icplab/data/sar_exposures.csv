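model_name,psar_continuous_wkg,absorbed_power_w,measurement_s,body_mass_kg
adult,3.61,1.63,120,
child_3.5y,3.59,1.14,120,
child_29mo,3.67,1.28,120,
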