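# Default layered structure: nine observed predictors feed three latent
# intermediate nodes (one per variable block); only the intermediates point at
# the binary adoption target.  Cross-edges between predictors are explicit and
# may be edited freely; the target is re-pointable to any practice.
target: cover_crops
n_latent_states: 3
grouping:
  farm_size: farm_characteristics
  irrigation_system: farm_characteristics
  crop_type: farm_characteristics
  income: farmer_characteristics
  education: farmer_characteristics
  years_in_farming: farmer_characteristics
  self_certification: engagement
  info_sources: engagement
  consultant: engagement
cross_edges:
- [farm_size, income]
- [farm_size, self_certification]
- [farm_size, info_sources]
- [farm_size, consultant]
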