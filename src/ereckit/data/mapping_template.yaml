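acuity_dialect: metric_6
acuity_dialects: {}
age_years: age
bcva_left: bcva_left
bcva_right: bcva_right
cluster_id: cluster
correction_definition: spectacles or contact lenses
cva_left: cva_left
cva_right: cva_right
person_id: person_id
pinhole_left: pinhole_left
pinhole_right: pinhole_right
sex: sex
sex_values: {}
strata:
  residence: residence
strata_values: {}
ucva_left: ucva_left
ucva_right: ucva_right
wears_distance_correction: wears_correction
weight: weight
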