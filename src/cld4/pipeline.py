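"""End-to-end pipeline: simulate -> ingest -> features -> rank -> analyze
-> report, with a single global seed and a hashed artifact manifest.

Stage outputs are pure functions of the configuration and seed, so two
runs with identical inputs produce byte-identical artifacts (verified by
the manifest's content hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from . import analytics, micl, report
from .config import CampaignConfig
from .etl import Warehouse, ingest_raw
from .features import FeatureTable, build_feature_table, load_plan
from .micl import CriteriaConfig, compute_micl, default_criteria, select_top
from .simulate import generate_campaign, write_raw_files

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


class PipelineConfig(BaseModel):
    out_dir: str = "cld4_run"
    seed: int = 0
    campaign: CampaignConfig = Field(default_factory=CampaignConfig)
    ranking_plan: str = "ranking"
    analytics_plan: str = "analytics"
    criteria_path: str | None = None
    top_n: int = 5
    risk_threshold: float = 0.7
    template_path: str | None = None
    report_date: str = "1970-01-01"
    metadata_overrides: dict = Field(default_factory=dict)

    def stage_seed(self, stage_index: int) -> int:
        """Derived per-stage seed: child of the global seed via SeedSequence."""
        child = np.random.SeedSequence(self.seed).spawn(stage_index + 1)[-1]
        return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            result = fn()
            log.info("stage %s complete", name)
            return result
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    def _simulate():
        campaign = config.campaign.model_copy(update={"seed": config.seed})
        bundle = generate_campaign(campaign)
        write_raw_files(bundle, out / "raw")
        return bundle

    stage("simulate", _simulate)

    def _ingest() -> Warehouse:
        wh = ingest_raw(out / "raw")
        wh.to_jsonl(out / "warehouse.jsonl")
        artifacts["warehouse"] = out / "warehouse.jsonl"
        return wh

    warehouse = stage("ingest", _ingest)

    def _features() -> tuple[FeatureTable, FeatureTable]:
        rank_tbl = build_feature_table(warehouse, load_plan(config.ranking_plan))
        ana_tbl = build_feature_table(warehouse, load_plan(config.analytics_plan))
        rank_tbl.to_csv(out / "features_ranking.csv")
        ana_tbl.to_csv(out / "features_analytics.csv")
        artifacts["features_ranking"] = out / "features_ranking.csv"
        artifacts["features_analytics"] = out / "features_analytics.csv"
        return rank_tbl, ana_tbl

    rank_table, ana_table = stage("features", _features)

    def _rank():
        if config.criteria_path is not None:
            criteria = CriteriaConfig.from_yaml(config.criteria_path)
        else:
            criteria = default_criteria()
        result = compute_micl(rank_table, criteria)
        result.to_frame().to_csv(out / "micl.csv", float_format="%.8g")
        artifacts["micl"] = out / "micl.csv"
        return result

    micl_result = stage("rank", _rank)

    def _analyze():
        std, _ = analytics.standardize(ana_table)
        pca_res = analytics.pca(std)
        corr = analytics.correlation_matrix(ana_table)
        findings = analytics.flag_risks(
            corr, analytics.DEFAULT_PROCESS_FEATURES,
            analytics.DEFAULT_QUALITY_FEATURES, config.risk_threshold)
        pca_res.scores.to_csv(out / "pca_scores.csv", float_format="%.8g")
        pca_res.loadings.to_csv(out / "pca_loadings.csv", float_format="%.8g")
        corr.matrix.to_csv(out / "correlation.csv", float_format="%.8g")
        (out / "findings.json").write_text(json.dumps(
            [vars(f) for f in findings], indent=2, sort_keys=True) + "\n")
        for key in ("pca_scores", "pca_loadings", "correlation", "findings"):
            suffix = ".json" if key == "findings" else ".csv"
            artifacts[key] = out / f"{key}{suffix}"
        return findings

    findings = stage("analyze", _analyze)

    def _report() -> Path:
        ctx = report.build_context(
            warehouse, micl_result, findings, rank_table,
            metadata=config.metadata_overrides, top_n=config.top_n,
            report_date=config.report_date,
            risk_threshold=config.risk_threshold)
        template = (Path(config.template_path).read_text()
                    if config.template_path else report.default_template())
        text = report.realize(template, ctx)
        path = out / "report.md"
        path.write_text(text)
        artifacts["report"] = path
        return path

    stage("report", _report)

    manifest = {
        "seed": config.seed,
        "top_clones": select_top(micl_result, config.top_n),
        "artifacts": {name: {"path": str(p), "sha256": _sha256(p)}
                      for name, p in sorted(artifacts.items())},
    }
    (out / "pipeline_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
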