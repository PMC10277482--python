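"""Capacity planning: annual demand and required batch working volume.

    D_product = N_patients * d_patient_year                      (g / year)
    V_batch   = D_product / (T_est * N_batches * Y_DSP * P_s)    (L / batch)

where T_est is the estimated titre of the lead clone (g/L), N_batches the
number of batches per year, Y_DSP the overall downstream yield fraction
and P_s the batch success rate.  The full product sits in the denominator:
better yield and higher success rate reduce the required volume.
Dimensions: g / (g L^-1) = L.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator


class CapacityInputs(BaseModel):
    n_patients: int = Field(ge=0)
    dose_g_per_patient_year: float = Field(ge=0)
    titre_g_per_L: float | None = None         # estimated lead-clone titre
    n_batches_per_year: int | None = None
    dsp_yield: float | None = None             # fraction in (0, 1]
    batch_success_rate: float | None = None    # fraction in (0, 1]

    @model_validator(mode="after")
    def _check(self) -> "CapacityInputs":
        for name in ("dsp_yield", "batch_success_rate"):
            v = getattr(self, name)
            if v is not None and not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        return self


class CapacityPlan(BaseModel):
    demand_g_per_year: float
    batch_volume_L: float


def annual_demand(inputs: CapacityInputs) -> float:
    """Annual product demand in grams."""
    return inputs.n_patients * inputs.dose_g_per_patient_year


def batch_volume(inputs: CapacityInputs) -> float:
    """Required bioreactor working volume per batch, in litres."""
    factors = {"titre_g_per_L": inputs.titre_g_per_L,
               "n_batches_per_year": inputs.n_batches_per_year,
               "dsp_yield": inputs.dsp_yield,
               "batch_success_rate": inputs.batch_success_rate}
    for name, v in factors.items():
        if v is None or v <= 0:
            raise ValueError(f"{name} must be positive for volume calculation")
    return annual_demand(inputs) / (
        inputs.titre_g_per_L * inputs.n_batches_per_year
        * inputs.dsp_yield * inputs.batch_success_rate)


def plan_capacity(inputs: CapacityInputs) -> CapacityPlan:
    return CapacityPlan(demand_g_per_year=annual_demand(inputs),
                        batch_volume_L=batch_volume(inputs))
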