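# Clone screening campaign report

Project {{user.project_id}} — molecule {{user.molecule_reference}}.
Prepared for {{user.scientist}} on {{gen.report_date}}.

## Campaign summary

{{gen.campaign_summary}}

## Clone ranking (manufacturability index)

{{gen.top_clone_table}}

{{gen.lead_clone_sentence}}

## Risk findings

{{gen.risk_findings}}

## Capacity recommendation

{{gen.capacity_recommendation}}

## Metadata and observations

Inoculation date: {{user.inoculation_date}}.
Scientist observations: {{user.observations}}
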