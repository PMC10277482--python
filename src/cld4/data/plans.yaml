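# Built-in feature extraction plans.
#
# "ranking"  — the features consumed by the 20 default selection criteria.
# "analytics" — the 24-feature set used for PCA / correlation risk analysis
#               (productivity, growth, process-parameter and quality
#               summaries including windowed pH averages).
ranking:
  - Titre:max
  - Titre:min
  - Titre:avg
  - Titre:end_point
  - q_antibody:max
  - q_antibody:min
  - q_antibody:end_point
  - VCD:max
  - VCD:avg
  - VCD:end_point
  - Viability:max
  - Viability:min
  - Viability:end_point
  - Lactate:max
  - Lactate:avg
  - Lactate:end_point
  - Monomer:end_point
  - Aggregate:end_point
  - Fragment:end_point
  - TSB:end_point

analytics:
  - Titre:end_point
  - Titre:max
  - q_antibody:avg
  - VCD:max
  - VCD:end_point
  - Viability:min
  - Viability:end_point
  - Lactate:end_point
  - Lactate:max
  - Glucose:end_point
  - Glucose:max
  - pH:avg
  - pH:std
  - pH:time_above_sp
  - pH:time_below_sp
  - pH:avg:d0-7
  - pH:avg:d7-14
  - DO2:avg
  - DO2:std
  - Flow_O2:end_point
  - Flow_O2:cumulative
  - Flow_CO2:cumulative
  - Base:cumulative
  - TSB:end_point
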