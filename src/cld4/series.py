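"""Time-series container shared by the simulator, warehouse and features."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SensorSeries:
    """One vessel's time-stamped trace of one variable.

    Times are seconds from inoculation and must be strictly increasing.
    """

    vessel_id: str
    variable: str
    time_s: np.ndarray
    values: np.ndarray
    unit: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.shape != self.values.shape:
            raise ValueError("time and value arrays must have equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time_s.size)

    @property
    def time_days(self) -> np.ndarray:
        return self.time_s / 86400.0

    def window(self, start_day: float, end_day: float,
               closed_end: bool = False) -> "SensorSeries":
        """Samples with day in [start, end) (or [start, end] if closed)."""
        d = self.time_days
        mask = (d >= start_day) & ((d <= end_day) if closed_end else (d < end_day))
        return SensorSeries(self.vessel_id, self.variable,
                            self.time_s[mask], self.values[mask],
                            self.unit, self.source)
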