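# Default selection criteria for the cell line manufacturability index.
#
# 20 criteria spanning productivity, growth and product quality.  Ratings
# are linear between the campaign's worst (0) and best (1) value of each
# feature; "min_is_best" reverses which end counts as best (lactate,
# aggregate, fragment and trisulfide bond are reverse-rated).  The
# trisulfide-bond end point carries raw weight 3 — enough to keep clones
# with any measurable TSB out of the top ranks — and all other criteria
# carry weight 1.  Edit freely per project.
criteria:
  - {name: "Titre (Max)",      feature: "Titre:max",           direction: max_is_best, weight: 1}
  - {name: "Titre (Min)",      feature: "Titre:min",           direction: max_is_best, weight: 1}
  - {name: "Titre (Mean)",     feature: "Titre:avg",           direction: max_is_best, weight: 1}
  - {name: "Titre (EP)",       feature: "Titre:end_point",     direction: max_is_best, weight: 1}
  - {name: "qp (Max)",         feature: "q_antibody:max",      direction: max_is_best, weight: 1}
  - {name: "qp (Min)",         feature: "q_antibody:min",      direction: max_is_best, weight: 1}
  - {name: "qp (EP)",          feature: "q_antibody:end_point", direction: max_is_best, weight: 1}
  - {name: "VCD (Max)",        feature: "VCD:max",             direction: max_is_best, weight: 1}
  - {name: "VCD (Mean)",       feature: "VCD:avg",             direction: max_is_best, weight: 1}
  - {name: "VCD (EP)",         feature: "VCD:end_point",       direction: max_is_best, weight: 1}
  - {name: "Viab (Max)",       feature: "Viability:max",       direction: max_is_best, weight: 1}
  - {name: "Viab (Min)",       feature: "Viability:min",       direction: max_is_best, weight: 1}
  - {name: "Viab (EP)",        feature: "Viability:end_point", direction: max_is_best, weight: 1}
  - {name: "Lact (Max)",       feature: "Lactate:max",         direction: min_is_best, weight: 1}
  - {name: "Lact (Mean)",      feature: "Lactate:avg",         direction: min_is_best, weight: 1}
  - {name: "Lact (EP)",        feature: "Lactate:end_point",   direction: min_is_best, weight: 1}
  - {name: "Monomer (EP)",     feature: "Monomer:end_point",   direction: max_is_best, weight: 1}
  - {name: "Aggregate (EP)",   feature: "Aggregate:end_point", direction: min_is_best, weight: 1}
  - {name: "Fragment (EP)",    feature: "Fragment:end_point",  direction: min_is_best, weight: 1}
  - {name: "TSB (EP)",         feature: "TSB:end_point",       direction: min_is_best, weight: 3}
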