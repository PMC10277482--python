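"""Synthetic fed-batch screening campaign generator.

Produces a complete raw campaign — per-vessel sensor traces, daily
off-line assays, periodic titre samples, harvest product-quality records
and campaign metadata — with the statistical structure of a 48-clone
micro-bioreactor screen:

* two metabolic phenotypes: lactate *consumers* (back-metabolise lactate
  late in the run) and lactate *producers* (no back-metabolism, high
  peak and end-point lactate, depressed viability and productivity);
* a small elite subset (consumers with high specific productivity, a
  position low in the pH dead-band, zero trisulfide bond and high
  monomer purity) that a sound ranking should recover;
* a dead-band pH controller whose realized trace sits at
  ``setpoint + drift_bias * deadband`` plus autocorrelated control error;
* trisulfide bond formation as an increasing (hinge) function of the
  realized mean pH over days 0-7;
* lactate overflow coupled to viability decline, and viability decline
  coupled to specific productivity, at documented target correlations.

All dynamics are phenomenological (logistic growth with a death phase,
bolus feeds, trapezoidal titre accumulation); they are not a mechanistic
metabolic model.  Every random draw derives from ``config.seed``, so the
same configuration yields byte-identical raw output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import CampaignConfig, ClonePhenotype, QualityProfile
from .series import SensorSeries
from .variables import unit_of

#: The fixed per-vessel raw file layout (12 streams per cell culture run).
VESSEL_STREAMS = (
    "pH", "DO2", "temperature", "stirrer", "flow_O2", "flow_CO2",
    "base_volume", "antifoam_events", "feed_events", "alarms",
    "titre_samples", "offline_samples",
)

#: The fixed per-station raw file layout (4 streams per culture station).
STATION_STREAMS = (
    "station_temperature", "station_log", "calibration", "gas_supply",
)

#: Streams that are continuous sensor traces (one variable per file).
SENSOR_STREAMS = {
    "pH": "pH", "DO2": "DO2", "temperature": "Temperature",
    "stirrer": "Stirrer", "flow_O2": "Flow_O2", "flow_CO2": "Flow_CO2",
    "base_volume": "Base",
}

RAW_COLUMNS = ["timestamp_s", "variable", "value", "unit"]


@dataclass
class CampaignBundle:
    """In-memory representation of one complete raw campaign."""

    config: CampaignConfig
    phenotypes: list[ClonePhenotype]
    sensors: dict[str, dict[str, SensorSeries]]          # vessel -> variable
    vessel_tables: dict[str, dict[str, pd.DataFrame]]    # vessel -> stream
    station_tables: dict[str, dict[str, pd.DataFrame]]   # station -> stream
    metadata: dict = field(default_factory=dict)

    @property
    def vessel_ids(self) -> list[str]:
        return list(self.sensors)

    def quality_endpoints(self) -> pd.DataFrame:
        """Harvest product-quality records, one row per vessel."""
        rows = []
        for vid, tables in self.vessel_tables.items():
            off = tables["offline_samples"]
            q = off[off["variable"].isin(["Monomer", "Aggregate", "Fragment", "TSB"])]
            rec = {"vessel_id": vid}
            for _, r in q.iterrows():
                rec[r["variable"]] = r["value"]
            rows.append(rec)
        return pd.DataFrame(rows).set_index("vessel_id")


def sample_phenotypes(config: CampaignConfig) -> list[ClonePhenotype]:
    """Draw the clone phenotype panel for a campaign.

    A fixed number of clones (``config.n_elite``, default 5 of 48) are
    elite: lactate consumers with high specific productivity, low pH
    drift bias (hence zero expected trisulfide bond), minimum viability
    at or above ~89 % and monomer purity above ~96.8 %.  The remaining
    clones are mostly lactate producers whose peak lactate, minimum
    viability and productivity are coupled through a single latent
    health axis.
    """
    if config.n_clones <= 0:
        raise ValueError("n_clones must be positive")
    rng = np.random.default_rng(config.seed)
    cpl = config.coupling
    noise = config.noise
    elite_idx = set(rng.choice(config.n_clones, size=config.n_elite,
                               replace=False).tolist())
    phenotypes: list[ClonePhenotype] = []
    for i, cid in enumerate(config.clone_ids()):
        elite = i in elite_idx
        if elite:
            mode = "consumer"
            health = rng.uniform(0.86, 0.95)
            qp = rng.uniform(11.5, 14.5)
            growth = rng.uniform(1.0, 1.2)
            bias = rng.uniform(-0.85, -0.55)
            viab_min = rng.uniform(89.2, 92.0)
            lact_max = (cpl.lact_base + cpl.lact_span * (1 - health)
                        + rng.normal(0.0, 0.4 * noise.lactate))
            ep_frac = rng.uniform(0.08, 0.20)
            agg = rng.uniform(0.7, 1.5)
            frag = rng.uniform(0.5, 1.2)
        else:
            mode = "producer" if rng.random() < 0.72 else "consumer"
            health = (rng.uniform(0.05, 0.55) if mode == "producer"
                      else rng.uniform(0.35, 0.80))
            qp = rng.uniform(5.5, 11.0)
            growth = rng.uniform(0.7, 1.15)
            bias = rng.uniform(-1.0, 1.0)
            viab_min = (cpl.viab_base + cpl.viab_span * health
                        + rng.normal(0.0, noise.viability))
            viab_min = float(np.clip(viab_min, 15.0, 96.0))
            lact_max = (cpl.lact_base + cpl.lact_span * (1 - health)
                        + rng.normal(0.0, noise.lactate))
            ep_frac = (rng.uniform(0.88, 1.0) if mode == "producer"
                       else rng.uniform(0.08, 0.25))
            agg = 0.8 + 2.2 * (1 - health) + rng.uniform(0.0, 0.7)
            frag = 0.6 + 1.2 * (1 - health) + rng.uniform(0.0, 0.5)
        lact_max = float(np.clip(lact_max, 0.3, None))
        expected_tsb = expected_tsb_from_bias(bias, config)
        phenotypes.append(ClonePhenotype(
            clone_id=cid,
            station_id=config.station_of(i),
            lactate_mode=mode,
            elite=elite,
            health=float(health),
            growth_rate_scale=float(growth),
            qp_scale=float(qp),
            pH_drift_bias=float(bias),
            viab_min_pct=float(viab_min),
            lact_max_gL=lact_max,
            lact_ep_frac=float(ep_frac),
            quality=QualityProfile(
                monomer_pct=float(100.0 - agg - frag),
                aggregate_pct=float(agg),
                fragment_pct=float(frag),
                tsb_pct=float(expected_tsb),
            ),
        ))
    return phenotypes


def expected_tsb_from_bias(bias: float, config: CampaignConfig) -> float:
    """Noise-free trisulfide bond end-point implied by a dead-band position.

    Hinge mapping: no TSB forms while the mean pH stays below the
    formation threshold; above it TSB grows linearly.  Monotone
    non-decreasing in ``bias`` by construction.
    """
    mean_ph = config.pH_setpoint + bias * config.pH_deadband
    return tsb_from_mean_ph(mean_ph, config)


def tsb_from_mean_ph(mean_ph: float, config: CampaignConfig) -> float:
    cpl = config.coupling
    return float(cpl.tsb_slope * max(0.0, mean_ph - cpl.tsb_ph_threshold))


# ---------------------------------------------------------------------------
# dynamics


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def _daily_profiles(ph: ClonePhenotype, config: CampaignConfig,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Daily off-line trajectories for one clone (noise-free biology core
    plus assay noise)."""
    cpl = config.coupling
    noise = config.noise
    days = np.arange(config.duration_days + 1, dtype=float)

    # viability: sigmoidal decline from ~98.5 % toward the clone's floor,
    # later and shallower for healthy clones
    d50 = 8.5 + 4.0 * ph.health
    viab = ph.viab_min_pct + (98.5 - ph.viab_min_pct) / (
        1.0 + np.exp((days - d50) / 1.4))
    viab = np.clip(viab, 0.0, 100.0)

    # logistic total cell density with carrying capacity set by health
    k = (18.0 + 32.0 * ph.health) * ph.growth_rate_scale
    v0 = 0.45
    mu = 0.85 * ph.growth_rate_scale
    vcd_total = k / (1.0 + (k / v0 - 1.0) * np.exp(-mu * days))
    vcd = vcd_total * viab / 100.0  # viable cell density, 1e6 cells/mL

    # glucose: consumption proportional to viable biomass, bolus feeds
    gluc = np.empty_like(days)
    gluc[0] = 6.0
    feed_days = set(config.feed_days)
    for d in range(1, len(days)):
        g = gluc[d - 1] - 0.055 * vcd[d - 1]
        if d in feed_days:
            g += config.feed_bolus_g_per_L
        gluc[d] = max(0.15, g)

    # lactate: smooth rise to the clone's peak, then either back-metabolism
    # (consumers) or persistence (producers) toward the end-point fraction
    frac = 0.375 if ph.lactate_mode == "consumer" else 0.69
    d_peak = frac * config.duration_days
    rise = _smoothstep(days / d_peak)
    tail = _smoothstep((days - d_peak) / (config.duration_days - d_peak))
    lact = ph.lact_max_gL * (rise - (1.0 - ph.lact_ep_frac) * tail)
    lact = np.clip(lact, 0.0, None)

    # titre: accumulation of qp * VCD with productivity depressed at low
    # viability (mg/L per day with VCD in 1e6 cells/mL and qp in pg/cell/day)
    qp_eff = ph.qp_scale * (viab / 100.0) ** cpl.qp_viab_gamma
    rate = qp_eff * vcd
    titre = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]))])

    # assay noise (multiplicative, non-negative), titre kept non-decreasing
    if noise.offline_rel > 0:
        vcd = vcd * (1 + rng.normal(0, noise.offline_rel, vcd.shape))
        gluc = gluc * (1 + rng.normal(0, noise.offline_rel, gluc.shape))
        lact = lact * (1 + rng.normal(0, noise.offline_rel, lact.shape))
        viab = np.clip(
            viab * (1 + rng.normal(0, 0.3 * noise.offline_rel, viab.shape)),
            0.0, 100.0)
    if noise.titre_rel > 0:
        titre = titre * (1 + rng.normal(0, noise.titre_rel, titre.shape))
    titre = np.maximum.accumulate(np.clip(titre, 0.0, None))

    # cumulative base addition tracks cumulative lactate *production*
    produced = np.cumsum(np.clip(np.diff(lact, prepend=0.0), 0.0, None))
    base = cpl.base_per_lactate * produced

    return {"days": days, "VCD": np.clip(vcd, 0.0, None),
            "Viability": viab, "Glucose": np.clip(gluc, 0.0, None),
            "Lactate": np.clip(lact, 0.0, None), "Titre": titre,
            "Base": base}


def _ar1(rng: np.random.Generator, n: int, sd: float, tau_s: float,
         interval_s: float) -> np.ndarray:
    """Stationary AR(1) noise with sd ``sd`` and correlation time ``tau_s``."""
    if sd <= 0:
        return np.zeros(n)
    rho = float(np.exp(-interval_s / tau_s))
    burn = 200
    white = rng.normal(0.0, sd * np.sqrt(1 - rho * rho), n + burn)
    return lfilter([1.0], [1.0, -rho], white)[burn:]


def _sensor_traces(ph: ClonePhenotype, daily: dict[str, np.ndarray],
                   config: CampaignConfig,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    noise = config.noise
    t = config.sensor_times_s
    n = t.size
    dt = float(config.sensor_interval_s)
    t_days = t / 86400.0

    sp, db = config.pH_setpoint, config.pH_deadband
    target = sp + ph.pH_drift_bias * db
    ctrl = _ar1(rng, n, noise.pH_ar, tau_s=10800.0, interval_s=dt)
    ph_trace = np.clip(target + ctrl, sp - db, sp + db)
    if noise.pH_meas > 0:
        ph_trace = ph_trace + rng.normal(0.0, noise.pH_meas, n)

    do2 = np.clip(config.do2_setpoint
                  + _ar1(rng, n, noise.do2, tau_s=7200.0, interval_s=dt),
                  10.0, 100.0)
    temp = config.temperature_setpoint + _ar1(rng, n, noise.temperature,
                                              tau_s=3600.0, interval_s=dt)

    vcd = np.interp(t_days, daily["days"], daily["VCD"])
    vcd_frac = vcd / max(vcd.max(), 1e-9)
    stirrer = 600.0 + 600.0 * np.sqrt(vcd_frac)

    flow_o2 = np.clip(0.02 + 0.012 * vcd
                      + _ar1(rng, n, 0.002 * (1 if noise.do2 > 0 else 0),
                             tau_s=3600.0, interval_s=dt), 0.0, None)
    flow_co2 = np.clip(0.05 + 0.45 * np.clip(ph_trace - sp, 0.0, None) / db,
                       0.0, None)
    base = np.interp(t_days, daily["days"], daily["Base"])
    return {"pH": ph_trace, "DO2": do2, "Temperature": temp,
            "Stirrer": stirrer, "Flow_O2": flow_o2, "Flow_CO2": flow_co2,
            "Base": base}


def default_metadata(config: CampaignConfig) -> dict:
    """Campaign metadata record: project identifiers, dose/market
    assumptions for capacity planning, and controller setpoints."""
    return {
        "project_id": "CLD-SYN-001",
        "scientist": "synthetic",
        "molecule_reference": "antibody-peptide fusion (synthetic)",
        "inoculation_date": "2026-01-05",
        "observations": "No contamination observed; routine antifoam additions.",
        "target_patients": 40000,
        "dose_g_per_patient_year": 0.5,
        "n_batches_per_year": 20,
        "dsp_yield": 0.75,
        "batch_success_rate": 0.9,
        "setpoints": {
            "pH": config.pH_setpoint,
            "DO2": config.do2_setpoint,
            "Temperature": config.temperature_setpoint,
            "Glucose": config.glucose_setpoint,
        },
        "pH_deadband": config.pH_deadband,
        "n_clones": config.n_clones,
        "n_stations": config.n_stations,
        "duration_days": config.duration_days,
        "seed": config.seed,
    }


def generate_campaign(config: CampaignConfig | None = None) -> CampaignBundle:
    """Simulate a complete raw campaign from a configuration."""
    config = config or CampaignConfig()
    phenotypes = sample_phenotypes(config)
    sensors: dict[str, dict[str, SensorSeries]] = {}
    vessel_tables: dict[str, dict[str, pd.DataFrame]] = {}
    t = config.sensor_times_s
    end_s = float(config.duration_days * 86400)

    for i, ph in enumerate(phenotypes):
        rng = np.random.default_rng((config.seed, 101, i))
        daily = _daily_profiles(ph, config, rng)
        traces = _sensor_traces(ph, daily, config, rng)
        vid = ph.clone_id
        sensors[vid] = {
            var: SensorSeries(vid, var, t, vals, unit=unit_of(var),
                              source="ambr15")
            for var, vals in traces.items()
        }

        # trisulfide bond from the realized mean pH over days 0-7
        mask = t < 7 * 86400
        mean_ph_0_7 = float(traces["pH"][mask].mean())
        tsb = tsb_from_mean_ph(mean_ph_0_7, config)
        if config.noise.tsb_rel > 0:
            tsb *= 1.0 + float(rng.normal(0.0, config.noise.tsb_rel))
        tsb = float(np.clip(tsb, 0.0, 100.0))

        off_rows = []
        for var in ("VCD", "Viability", "Glucose", "Lactate"):
            for d, v in zip(daily["days"], daily[var]):
                off_rows.append((d * 86400.0, var, round(float(v), 6),
                                 unit_of(var)))
        q = ph.quality
        for var, val in (("Monomer", q.monomer_pct),
                         ("Aggregate", q.aggregate_pct),
                         ("Fragment", q.fragment_pct), ("TSB", tsb)):
            off_rows.append((end_s, var, round(float(val), 6), unit_of(var)))
        offline = pd.DataFrame(off_rows, columns=RAW_COLUMNS)

        titre_rows = [(d * 86400.0, "Titre",
                       round(float(np.interp(d, daily["days"], daily["Titre"])), 4),
                       unit_of("Titre"))
                      for d in config.titre_sample_days]
        titre = pd.DataFrame(titre_rows, columns=RAW_COLUMNS)

        feed_rows = [(d * 86400.0, "Feed",
                      f"bolus feed {config.feed_bolus_g_per_L:g} g/L glucose", "")
                     for d in config.feed_days]
        feeds = pd.DataFrame(feed_rows, columns=RAW_COLUMNS)

        n_af = int(rng.integers(2, 5))
        af_times = np.sort(rng.uniform(86400.0, end_s, n_af)).round(0)
        antifoam = pd.DataFrame(
            [(s, "Antifoam", "antifoam 50 uL added", "") for s in af_times],
            columns=RAW_COLUMNS)

        alarm_rows = []
        if rng.random() < 0.3:
            alarm_rows.append((round(float(rng.uniform(0, end_s))), "Alarm",
                               "DO2 excursion below alarm limit", ""))
        alarms = pd.DataFrame(alarm_rows, columns=RAW_COLUMNS)

        vessel_tables[vid] = {
            "titre_samples": titre, "offline_samples": offline,
            "feed_events": feeds, "antifoam_events": antifoam,
            "alarms": alarms,
        }

    station_tables: dict[str, dict[str, pd.DataFrame]] = {}
    hourly = np.arange(0.0, end_s + 1, 3600.0)
    for s_i, sid in enumerate(config.station_ids()):
        rng = np.random.default_rng((config.seed, 202, s_i))
        st_temp = config.temperature_setpoint + _ar1(
            rng, t.size, config.noise.temperature, 7200.0,
            float(config.sensor_interval_s))
        gas = 1.8 + _ar1(rng, hourly.size, 0.02 * (1 if config.noise.do2 > 0 else 0),
                         7200.0, 3600.0)
        station_tables[sid] = {
            "station_temperature": pd.DataFrame({
                "timestamp_s": t, "variable": "Station_Temperature",
                "value": st_temp.round(4), "unit": unit_of("Station_Temperature")}),
            "gas_supply": pd.DataFrame({
                "timestamp_s": hourly, "variable": "Gas_Supply",
                "value": gas.round(4), "unit": unit_of("Gas_Supply")}),
            "station_log": pd.DataFrame(
                [(0.0, "Station_Log", f"station {sid} started", ""),
                 (end_s, "Station_Log", f"station {sid} run complete", "")],
                columns=RAW_COLUMNS),
            "calibration": pd.DataFrame(
                [(0.0, "Calibration", "pH probe 2-point calibration passed", ""),
                 (0.0, "Calibration", "DO2 probe calibration passed", "")],
                columns=RAW_COLUMNS),
        }

    return CampaignBundle(config=config, phenotypes=phenotypes,
                          sensors=sensors, vessel_tables=vessel_tables,
                          station_tables=station_tables,
                          metadata=default_metadata(config))


def _sensor_frame(series: SensorSeries) -> pd.DataFrame:
    return pd.DataFrame({
        "timestamp_s": series.time_s, "variable": series.variable,
        "value": np.round(series.values, 6), "unit": series.unit})


def write_raw_files(bundle: CampaignBundle, directory: str | Path) -> dict:
    """Write the campaign to the open reference CSV dialect.

    Layout: ``vessels/<id>/<stream>.csv`` (12 streams per vessel) and
    ``stations/<id>/<stream>.csv`` (4 streams per station), each CSV with
    the header ``timestamp_s,variable,value,unit``, plus ``metadata.json``
    and a ``manifest.json`` listing every file.  Returns the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []

    def _write(df: pd.DataFrame, path: Path, kind: str, owner: str,
               stream: str) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False, float_format="%.6f")
        entries.append({"path": str(path.relative_to(directory)),
                        "kind": kind, "id": owner, "stream": stream,
                        "rows": int(len(df))})

    for vid in bundle.vessel_ids:
        vdir = directory / "vessels" / vid
        for stream in VESSEL_STREAMS:
            if stream in SENSOR_STREAMS:
                df = _sensor_frame(bundle.sensors[vid][SENSOR_STREAMS[stream]])
            else:
                df = bundle.vessel_tables[vid][stream]
            _write(df, vdir / f"{stream}.csv", "vessel", vid, stream)

    for sid, tables in bundle.station_tables.items():
        sdir = directory / "stations" / sid
        for stream in STATION_STREAMS:
            _write(tables[stream], sdir / f"{stream}.csv", "station", sid, stream)

    (directory / "metadata.json").write_text(
        json.dumps(bundle.metadata, indent=2, sort_keys=True) + "\n")
    manifest = {"n_vessels": len(bundle.vessel_ids),
                "n_stations": len(bundle.station_tables),
                "n_csv_files": len(entries), "files": entries}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
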