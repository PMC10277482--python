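"""Campaign configuration and clone phenotype definitions.

A campaign models a fed-batch CHO clone screen on a 48-vessel automated
micro-bioreactor system (four culture stations of 12 vessels, ~11-15 mL
working volume, 16 day runs).  The defaults reproduce the standard
operating conditions of such a screen: pH controlled to 7.0 with a 0.1
dead-band, dissolved oxygen to 50 %, temperature to 33 degC, sensors
logged every 90 s, titre assayed on days 8/10/12/14 and five equally
spaced bolus feeds after the first feed day.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator


class NoiseScales(BaseModel):
    """Magnitudes of the stochastic terms in the campaign simulator.

    Setting every field to 0 gives a fully deterministic campaign whose
    pH traces sit exactly at ``pH_setpoint + drift_bias * deadband``.
    """

    pH_ar: float = 0.018          # AR(1) stationary sd of the pH control error
    pH_meas: float = 0.003        # white measurement noise on the pH probe
    do2: float = 3.0              # % dissolved-oxygen control error
    temperature: float = 0.05     # degC probe noise
    lactate: float = 0.75         # g/L clone-to-clone residual on peak lactate
    viability: float = 1.3        # % residual on minimum viability (non-elite)
    titre_rel: float = 0.02       # relative noise on titre assay points
    tsb_rel: float = 0.12         # relative (proportional) noise on TSB assay
    offline_rel: float = 0.015    # relative noise on daily offline assays

    def zeroed(self) -> "NoiseScales":
        return NoiseScales(**{k: 0.0 for k in self.model_dump()})


class CouplingConstants(BaseModel):
    """Phenomenological couplings between clone health, metabolism,
    productivity and product quality.

    These are generator parameters, not measured outputs: the calibration
    tests verify that the campaign statistics they induce (for example the
    lactate-viability correlation) recover the documented targets.
    """

    # documented calibration targets, recovered by the analytics stage
    target_r_lactate_viability: float = 0.9    # |r|(Lact max, Viab min)
    target_r_viabdrop_qp: float = -0.5         # r(viability drop, mean q_p)

    lact_base: float = 1.2        # g/L peak lactate of a perfectly healthy clone
    lact_span: float = 6.5        # g/L extra peak lactate at health = 0
    viab_base: float = 40.0       # % minimum viability at health = 0
    viab_span: float = 60.0       # % additional minimum viability at health = 1
    qp_viab_gamma: float = 0.12   # exponent coupling q_p to instantaneous viability
    tsb_slope: float = 150.0      # % TSB per pH unit above the formation threshold
    tsb_ph_threshold: float = 6.96  # mean pH (days 0-7) below which no TSB forms
    base_per_lactate: float = 0.55  # mL base added per g/L of lactate produced


class CampaignConfig(BaseModel):
    """Full specification of one synthetic screening campaign."""

    n_clones: int = 48
    n_stations: int = 4
    duration_days: int = 16
    sensor_interval_s: int = 90
    pH_setpoint: float = 7.0
    pH_deadband: float = 0.1
    do2_setpoint: float = 50.0
    temperature_setpoint: float = 33.0
    glucose_setpoint: float = 4.0
    titre_sample_days: list[int] = Field(default_factory=lambda: [8, 10, 12, 14])
    first_feed_day: int = 3
    n_feeds: int = 5
    feed_spacing_days: int = 2
    feed_bolus_g_per_L: float = 3.0
    n_elite: int = 5
    seed: int = 0
    noise: NoiseScales = Field(default_factory=NoiseScales)
    coupling: CouplingConstants = Field(default_factory=CouplingConstants)

    @model_validator(mode="after")
    def _check(self) -> "CampaignConfig":
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        if self.n_stations <= 0 or self.n_clones % self.n_stations:
            raise ValueError("n_clones must be divisible by n_stations")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        if self.sensor_interval_s <= 0:
            raise ValueError("sensor_interval must be positive")
        if self.pH_deadband <= 0:
            raise ValueError("pH deadband must be positive")
        if self.n_elite < 0 or self.n_elite > self.n_clones:
            raise ValueError("n_elite must lie in [0, n_clones]")
        if any(d > self.duration_days for d in self.titre_sample_days):
            raise ValueError("titre sample days must fall within the run")
        return self

    @property
    def feed_days(self) -> list[int]:
        days = [self.first_feed_day + i * self.feed_spacing_days
                for i in range(self.n_feeds)]
        return [d for d in days if d <= self.duration_days]

    @property
    def sensor_times_s(self) -> np.ndarray:
        """Sensor sampling grid in seconds from inoculation (inclusive ends)."""
        return np.arange(0, self.duration_days * 86400 + 1, self.sensor_interval_s,
                         dtype=float)

    def clone_ids(self) -> list[str]:
        width = max(2, len(str(self.n_clones)))
        return [f"C{i + 1:0{width}d}" for i in range(self.n_clones)]

    def station_ids(self) -> list[str]:
        return [f"ST{i + 1}" for i in range(self.n_stations)]

    def station_of(self, clone_index: int) -> str:
        per_station = self.n_clones // self.n_stations
        return self.station_ids()[clone_index // per_station]


class QualityProfile(BaseModel):
    """End-point product-quality parameters of one clone."""

    monomer_pct: float
    aggregate_pct: float
    fragment_pct: float
    tsb_pct: float  # expected TSB before the realized-pH mapping and noise


class ClonePhenotype(BaseModel):
    """Latent biological parameters of one clone.

    ``health`` is the single latent axis coupling lactate overflow,
    viability decline and productivity loss; lactate producers (no late
    back-metabolism of lactate) occupy its lower range.  ``pH_drift_bias``
    is the clone/vessel position within the controller dead-band in
    [-1, +1]; sustained operation near the upper band drives trisulfide
    bond formation.
    """

    clone_id: str
    station_id: str
    lactate_mode: Literal["consumer", "producer"]
    elite: bool
    health: float
    growth_rate_scale: float
    qp_scale: float  # base specific productivity, pg cell^-1 day^-1
    pH_drift_bias: float
    viab_min_pct: float
    lact_max_gL: float
    lact_ep_frac: float
    quality: QualityProfile

    @model_validator(mode="after")
    def _check(self) -> "ClonePhenotype":
        if self.growth_rate_scale <= 0 or self.qp_scale <= 0:
            raise ValueError("scales must be positive")
        if not -1.0 <= self.pH_drift_bias <= 1.0:
            raise ValueError("pH_drift_bias must lie in [-1, 1]")
        return self
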