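# Variable registry: classification into the five data categories,
# units, source instrument and accepted synonyms.  Edit or extend this
# file to map real instrument exports without code changes.
categories:
  process_parameters:
    pH:        {unit: "-",        source: "ambr15",  synonyms: [ph]}
    DO2:       {unit: "%",        source: "ambr15",  synonyms: [do2, dissolved oxygen, do]}
    Temperature: {unit: "degC",   source: "ambr15",  synonyms: [temp, t]}
    Stirrer:   {unit: "rpm",      source: "ambr15",  synonyms: [rpm, agitation, stirrer speed]}
    Flow_O2:   {unit: "mL/min",   source: "ambr15",  synonyms: [f_o2, flow o2, o2 flow]}
    Flow_CO2:  {unit: "mL/min",   source: "ambr15",  synonyms: [f_co2, flow co2, co2 flow]}
    Base:      {unit: "mL",       source: "ambr15",  synonyms: [base addition, base volume, cumul base], cumulative: true}
    Station_Temperature: {unit: "degC", source: "ambr15-station", synonyms: [station temperature]}
    Gas_Supply: {unit: "bar",     source: "ambr15-station", synonyms: [gas supply, supply pressure]}
  growth:
    VCD:       {unit: "1e6 cells/mL", source: "vi-cell",  synonyms: [viable cell density, xv]}
    Viability: {unit: "%",        source: "vi-cell",  synonyms: [viab]}
    Glucose:   {unit: "g/L",      source: "ysi2900",  synonyms: [gluc, glc]}
    Lactate:   {unit: "g/L",      source: "ysi2900",  synonyms: [lact, lac]}
    Spec_Growth_Rate: {unit: "1/day", source: "derived", synonyms: [spec growth rate, mu, growth rate]}
  productivity:
    Titre:     {unit: "mg/L",     source: "hplc-protein-a", synonyms: [titer, mab, product concentration]}
    q_antibody: {unit: "pg/cell/day", source: "derived", synonyms: [qp, q_p, specific productivity, q antibody]}
  product_quality:
    Monomer:   {unit: "%",        source: "hp-sec",   synonyms: [mono, monomer purity]}
    Aggregate: {unit: "%",        source: "hp-sec",   synonyms: [agg, aggregates]}
    Fragment:  {unit: "%",        source: "hp-sec",   synonyms: [frag, fragments]}
    TSB:       {unit: "%",        source: "tqs-ms",   synonyms: [trisulfide bond, trisulfide]}
  metadata:
    Feed:      {unit: "",         source: "ambr15",   synonyms: [feed event]}
    Antifoam:  {unit: "",         source: "ambr15",   synonyms: [antifoam event]}
    Alarm:     {unit: "",         source: "ambr15",   synonyms: [alarms]}
    Station_Log: {unit: "",       source: "ambr15-station", synonyms: [station log]}
    Calibration: {unit: "",       source: "ambr15-station", synonyms: []}
    Observation: {unit: "",       source: "eln",      synonyms: [observations, note]}
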