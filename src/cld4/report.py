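"""Rule-based data-to-text report generation.

The final pipeline stage assembles a ReportContext from the earlier
stages (warehouse counts, MI_CL ranking, risk findings, capacity plan,
metadata) and realizes a Markdown report from a template containing three
token classes:

* static text — copied verbatim;
* ``{{user.slot}}`` — values supplied by the scientist as metadata;
* ``{{gen.slot}}`` — text produced by deterministic functions of the
  context (tables, summary sentences, capacity numbers).

An optional ``|format`` suffix applies a printf-style float format, e.g.
``{{gen.batch_volume|.1f}}``.  Realization is pure (no data access) and
deterministic: identical contexts — including the injected report date —
render byte-identical documents.  Document plan, in order: campaign
summary, top-clone table, risk findings, capacity recommendation,
metadata/observations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .analytics import RiskFinding, band_tsb
from .capacity import CapacityInputs, CapacityPlan, plan_capacity
from .etl import Warehouse
from .features import FeatureTable
from .micl import MICLResult

_TOKEN = re.compile(r"\{\{\s*(user|gen)\.([A-Za-z0-9_]+)(?:\|([^}]+))?\s*\}\}")


class UnresolvedSlotError(KeyError):
    def __init__(self, slots: list[str]):
        super().__init__(f"unresolved template slots: {', '.join(slots)}")
        self.slots = slots


@dataclass
class ReportContext:
    """Everything the template may reference, re-derived from the pipeline
    stages (counts come from the warehouse, never from caches)."""

    n_clones: int
    n_records: int
    category_counts: dict[str, int]
    top_clones: pd.DataFrame          # index clone id; MI_CL + key features
    findings: list[RiskFinding]
    capacity: CapacityPlan | None
    metadata: dict
    report_date: str = "1970-01-01"
    risk_threshold: float = 0.7

    # -- generated-text functions -------------------------------------------

    def campaign_summary(self) -> str:
        counts = ", ".join(f"{v:,} {k.replace('_', ' ')}"
                           for k, v in self.category_counts.items())
        return (f"{self.n_clones} clones were screened; the data warehouse "
                f"holds {self.n_records:,} records ({counts}).")

    def top_clone_table(self) -> str:
        cols = ["MI_CL", "Titre:end_point", "Viability:end_point",
                "Monomer:end_point", "TSB:end_point"]
        header = ("| Clone | MI_CL | Titre EP (mg/L) | Viability EP (%) "
                  "| Monomer (%) | TSB (%) |")
        sep = "|---" * 6 + "|"
        lines = [header, sep]
        for cid, row in self.top_clones.iterrows():
            cells = [cid] + [
                f"{row[c]:.3f}" if c == "MI_CL" else f"{row[c]:.1f}"
                for c in cols if c in row.index]
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)

    def lead_clone_sentence(self) -> str:
        lead = self.top_clones.index[0]
        row = self.top_clones.iloc[0]
        band = band_tsb(float(row["TSB:end_point"]))
        return (f"Clone {lead} is recommended as lead with MI_CL = "
                f"{row['MI_CL']:.2f}, end-point titre "
                f"{row['Titre:end_point'] / 1000:.1f} g/L and a {band} "
                f"trisulfide-bond level of {row['TSB:end_point']:.1f} %.")

    def risk_findings_text(self) -> str:
        if not self.findings:
            return (f"No process/quality correlations exceeded |r| >= "
                    f"{self.risk_threshold:g}.")
        lines = [f.message() for f in self.findings]
        return "\n".join(f"- {line}" for line in lines)

    def capacity_recommendation(self) -> str:
        if self.capacity is None:
            return ("Capacity requirements were not computed: patient count "
                    "or dose metadata is missing.")
        return (f"Annual product demand is {self.capacity.demand_g_per_year:,.0f} g; "
                f"meeting it requires a bioreactor working volume of "
                f"{self.capacity.batch_volume_L:,.1f} L per batch.")

    def generated_slots(self) -> dict[str, object]:
        slots: dict[str, object] = {
            "report_date": self.report_date,
            "campaign_summary": self.campaign_summary(),
            "top_clone_table": self.top_clone_table(),
            "lead_clone_sentence": self.lead_clone_sentence(),
            "risk_findings": self.risk_findings_text(),
            "capacity_recommendation": self.capacity_recommendation(),
            "n_clones": self.n_clones,
            "n_records": self.n_records,
            "lead_clone": self.top_clones.index[0],
            "lead_micl": float(self.top_clones["MI_CL"].iloc[0]),
        }
        if self.capacity is not None:
            slots["annual_demand"] = self.capacity.demand_g_per_year
            slots["batch_volume"] = self.capacity.batch_volume_L
        return slots


def build_context(warehouse: Warehouse, micl: MICLResult,
                  findings: list[RiskFinding], table: FeatureTable,
                  metadata: dict | None = None, top_n: int = 5,
                  report_date: str = "1970-01-01",
                  risk_threshold: float = 0.7) -> ReportContext:
    """Assemble the report context; capacity degrades gracefully to "not
    computed" when dose/patient metadata is absent."""
    meta = dict(warehouse.metadata())
    meta.update(metadata or {})
    top_ids = micl.ranking[:top_n]
    top = pd.DataFrame({"MI_CL": micl.scores[top_ids]})
    for col in ("Titre:end_point", "Viability:end_point",
                "Monomer:end_point", "TSB:end_point"):
        if col in table.values.columns:
            top[col] = table.values.loc[top_ids, col]

    capacity = None
    if meta.get("target_patients") and meta.get("dose_g_per_patient_year"):
        titre = meta.get("titre_estimate_g_per_L")
        if titre is None and "Titre:end_point" in top.columns:
            titre = float(top["Titre:end_point"].iloc[0]) / 1000.0  # mg/L -> g/L
        try:
            capacity = plan_capacity(CapacityInputs(
                n_patients=int(meta["target_patients"]),
                dose_g_per_patient_year=float(meta["dose_g_per_patient_year"]),
                titre_g_per_L=titre,
                n_batches_per_year=meta.get("n_batches_per_year"),
                dsp_yield=meta.get("dsp_yield"),
                batch_success_rate=meta.get("batch_success_rate")))
        except (ValueError, TypeError):
            capacity = None

    return ReportContext(
        n_clones=len(warehouse.vessel_ids),
        n_records=len(warehouse),
        category_counts=warehouse.counts_by_category(),
        top_clones=top, findings=findings, capacity=capacity,
        metadata=meta, report_date=report_date,
        risk_threshold=risk_threshold)


def default_template() -> str:
    return resources.files("cld4.data").joinpath("report_template.md").read_text()


def realize(template: str, context: ReportContext) -> str:
    """Render the template against the context.

    Pure function of its arguments; unresolved slots raise with the full
    list of missing slot names.
    """
    gen = context.generated_slots()
    user = context.metadata
    missing: list[str] = []

    def _sub(match: re.Match) -> str:
        kind, slot, fmt = match.group(1), match.group(2), match.group(3)
        source = gen if kind == "gen" else user
        if slot not in source:
            missing.append(f"{kind}.{slot}")
            return match.group(0)
        value = source[slot]
        if fmt:
            return format(float(value), fmt)
        return str(value)

    rendered = _TOKEN.sub(_sub, template)
    if missing:
        raise UnresolvedSlotError(sorted(set(missing)))
    return rendered
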