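"""Extract-Transform-Load: raw campaign files to a queryable warehouse.

Every raw CSV row becomes one warehouse record keyed by vessel/station ID,
timestamp (seconds from inoculation) and source instrument, tagged with
one of the five data categories.  The warehouse persists as JSON Lines
(one record per line): streamable, diff-able and human-readable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import SensorSeries
from .variables import (CATEGORIES, UnclassifiedVariableError, canonical_name,
                        variable_info)

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["vessel_id", "timestamp_s", "source", "category",
                  "variable", "value", "unit"]

#: vessel_id used for campaign-level metadata records
CAMPAIGN_ID = "CAMPAIGN"


class IngestError(ValueError):
    pass


@dataclass
class Warehouse:
    """Category-tagged record store with (vessel, variable, time) access.

    ``numeric`` holds measurement records (float values); ``text`` holds
    event/log/metadata records (string values).  Both are kept sorted by
    (vessel_id, variable, timestamp_s, source) with duplicate keys dropped.
    """

    numeric: pd.DataFrame
    text: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("numeric", "text"):
            df = getattr(self, name)
            if list(df.columns) != RECORD_COLUMNS:
                raise ValueError(f"{name} frame must have columns {RECORD_COLUMNS}")
        self.numeric = self._canonical(self.numeric)
        # text (event/log/metadata) records are legitimate with a shared
        # timestamp; only full-row duplicates are dropped
        self.text = self._canonical(self.text, key=RECORD_COLUMNS)
        self._index: dict | None = None

    @staticmethod
    def _canonical(df: pd.DataFrame, key: list[str] | None = None
                   ) -> pd.DataFrame:
        df = df.drop_duplicates(
            subset=key or ["vessel_id", "variable", "timestamp_s", "source"])
        df = df.sort_values(["vessel_id", "variable", "timestamp_s", "source"],
                            kind="mergesort")
        return df.reset_index(drop=True)

    # -- access ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.numeric) + len(self.text)

    @property
    def vessel_ids(self) -> list[str]:
        ids = self.numeric.loc[self.numeric["category"].isin(
            ["growth", "productivity"]), "vessel_id"].unique()
        return sorted(ids)

    def counts_by_category(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for df in (self.numeric, self.text):
            for cat, n in df["category"].value_counts().items():
                counts[cat] += int(n)
        return counts

    def _positions(self, vessel_id: str, variable: str) -> np.ndarray:
        if self._index is None:
            self._index = self.numeric.groupby(
                ["vessel_id", "variable"], sort=False).indices
        return self._index.get((vessel_id, variable), np.array([], dtype=int))

    def query(self, vessel_id: str, variable: str,
              time_window: tuple[float, float] | None = None) -> SensorSeries:
        """Time-sorted numeric records for one vessel and variable.

        ``time_window`` is an inclusive (start, end) in seconds from
        inoculation; an empty selection is valid and returns an empty series.
        """
        variable = canonical_name(variable)
        pos = self._positions(vessel_id, variable)
        sub = self.numeric.iloc[pos]
        t = sub["timestamp_s"].to_numpy(dtype=float)
        v = sub["value"].to_numpy(dtype=float)
        if time_window is not None:
            lo, hi = time_window
            m = (t >= lo) & (t <= hi)
            t, v = t[m], v[m]
        unit = sub["unit"].iloc[0] if len(sub) else ""
        source = sub["source"].iloc[0] if len(sub) else ""
        return SensorSeries(vessel_id, variable, t, v, unit=unit, source=source)

    def metadata(self) -> dict:
        """Campaign-level metadata re-assembled from text records."""
        sub = self.text[(self.text["vessel_id"] == CAMPAIGN_ID)
                        & (self.text["variable"] == "Observation")]
        meta: dict = {}
        for _, row in sub.iterrows():
            key, _, value = str(row["value"]).partition("=")
            try:
                meta[key] = json.loads(value)
            except (json.JSONDecodeError, ValueError):
                meta[key] = value
        return meta

    # -- persistence ---------------------------------------------------------

    def to_jsonl(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for df in (self.numeric, self.text):
                for rec in df.itertuples(index=False):
                    fh.write(json.dumps(rec._asdict(), sort_keys=True,
                                        default=float) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "Warehouse":
        rows = [json.loads(line) for line in open(path)
                if line.strip()]
        df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
        if df.empty:
            return cls(df, df.copy())
        is_num = df["value"].map(lambda v: isinstance(v, (int, float)))
        numeric = df[is_num].astype({"value": float})
        return cls(numeric.reset_index(drop=True),
                   df[~is_num].reset_index(drop=True))


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=RECORD_COLUMNS)


def _records_from_raw(df: pd.DataFrame, owner_id: str
                      ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Transform one raw CSV table into (numeric, text, skipped) records."""
    required = {"timestamp_s", "variable", "value", "unit"}
    if not required.issubset(df.columns):
        raise IngestError(f"raw table missing columns {required - set(df.columns)}")
    skipped = int(df["variable"].isna().sum() + df["timestamp_s"].isna().sum())
    df = df.dropna(subset=["variable", "timestamp_s"]).copy()

    cats, sources, names = [], [], []
    for name in df["variable"].astype(str):
        info = variable_info(name)  # raises UnclassifiedVariableError
        cats.append(info.category)
        sources.append(info.source)
        names.append(info.name)
    out = pd.DataFrame({
        "vessel_id": owner_id,
        "timestamp_s": pd.to_numeric(df["timestamp_s"], errors="coerce"),
        "source": sources, "category": cats, "variable": names,
        "value": df["value"], "unit": df["unit"].fillna(""),
    })
    bad_t = out["timestamp_s"].isna() | (out["timestamp_s"] < 0)
    skipped += int(bad_t.sum())
    out = out[~bad_t]
    as_num = pd.to_numeric(out["value"], errors="coerce")
    numeric = out[as_num.notna()].assign(value=as_num[as_num.notna()])
    text = out[as_num.isna()].assign(value=out.loc[as_num.isna(), "value"].astype(str))
    return (numeric[RECORD_COLUMNS].reset_index(drop=True),
            text[RECORD_COLUMNS].reset_index(drop=True), skipped)


def _metadata_records(meta: dict) -> pd.DataFrame:
    rows = [(CAMPAIGN_ID, 0.0, "eln", "metadata", "Observation",
             f"{k}={json.dumps(v, sort_keys=True)}", "")
            for k, v in sorted(meta.items())]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def ingest_raw(directory: str | Path) -> Warehouse:
    """Ingest a raw campaign directory (reference CSV dialect) into a
    warehouse.  Malformed rows are skipped and counted; building the
    warehouse from the same directory twice yields identical results.
    """
    directory = Path(directory)
    csv_paths = sorted(directory.glob("vessels/*/*.csv")) + \
        sorted(directory.glob("stations/*/*.csv"))
    numeric_parts, text_parts = [], []
    skipped = 0
    for path in csv_paths:
        owner = path.parent.name
        if not owner:
            raise IngestError(f"cannot determine vessel/station ID for {path}")
        raw = pd.read_csv(path, dtype={"variable": str, "value": str,
                                       "unit": str}, on_bad_lines="skip")
        num, txt, skip = _records_from_raw(raw, owner)
        numeric_parts.append(num)
        text_parts.append(txt)
        skipped += skip

    meta_path = directory / "metadata.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if meta:
        text_parts.append(_metadata_records(meta))

    numeric = (pd.concat(numeric_parts, ignore_index=True)
               if numeric_parts else _empty_frame())
    text = (pd.concat(text_parts, ignore_index=True)
            if text_parts else _empty_frame())
    wh = Warehouse(numeric, text)
    wh.summary = {
        "n_files": len(csv_paths), "n_records": len(wh),
        "n_skipped_rows": skipped, "counts": wh.counts_by_category(),
    }
    log.info("ingested %d files: %d records (%d rows skipped)",
             len(csv_paths), len(wh), skipped)
    return wh


def warehouse_from_bundle(bundle) -> Warehouse:
    """Build a warehouse directly from an in-memory campaign bundle.

    Equivalent to ``write_raw_files`` + ``ingest_raw`` without the disk
    round trip; used for fast repeated-campaign statistics.
    """
    from .simulate import SENSOR_STREAMS, STATION_STREAMS, VESSEL_STREAMS

    numeric_parts, text_parts = [], []
    for vid in bundle.vessel_ids:
        for stream in VESSEL_STREAMS:
            if stream in SENSOR_STREAMS:
                s = bundle.sensors[vid][SENSOR_STREAMS[stream]]
                info = variable_info(s.variable)
                numeric_parts.append(pd.DataFrame({
                    "vessel_id": vid, "timestamp_s": s.time_s,
                    "source": info.source, "category": info.category,
                    "variable": info.name, "value": np.round(s.values, 6),
                    "unit": s.unit}))
            else:
                num, txt, _ = _records_from_raw(bundle.vessel_tables[vid][stream], vid)
                numeric_parts.append(num)
                text_parts.append(txt)
    for sid, tables in bundle.station_tables.items():
        for stream in STATION_STREAMS:
            num, txt, _ = _records_from_raw(tables[stream], sid)
            numeric_parts.append(num)
            text_parts.append(txt)
    text_parts.append(_metadata_records(bundle.metadata))
    wh = Warehouse(pd.concat(numeric_parts, ignore_index=True),
                   pd.concat(text_parts, ignore_index=True))
    wh.summary = {"n_files": None, "n_records": len(wh), "n_skipped_rows": 0,
                  "counts": wh.counts_by_category()}
    return wh
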