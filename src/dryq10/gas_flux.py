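"""Closed-jar headspace accumulation: raw gas measurements to emission rates.

The jar is sealed and flushed with CO2-free air at the start of each
temperature step; CO2 accumulates in the headspace over the step duration.
The emission rate follows from the concentration change, the headspace
volume, the ideal-gas molar volume at jar temperature (1 atm convention),
and the dry soil mass:

    rate = dC * 1e-6 * V_head / V_m(T) * M_C * 1e6 / (m_soil * dt)

in ug C per g dry soil per hour.  The delta13C of the emitted CO2 equals the
final headspace delta13C when the jar was flushed (initial CO2 ~ 0); with a
non-zero initial concentration a two-point isotope mass balance is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MOLAR_MASS_C, MOLAR_VOLUME_STP, IncubationProtocol

#: Measured rates more negative than this (ug C g-1 h-1) are flagged as
#: physically implausible rather than ordinary noise excursions.
NEGATIVE_RATE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class EmissionRate:
    sample_id: str
    temperature: float  # degC
    rate_total: float  # ug C g-1 h-1; may be negative, never silently NaN
    delta13c_emitted: float  # permil VPDB
    flagged_negative: bool = False


def headspace_volume(protocol: IncubationProtocol) -> float:
    """Headspace volume in litres: jar volume minus the soil solid volume.

    The soil volume is soil mass over an assumed bulk density; raises if the
    soil fills the jar.
    """
    if protocol.bulk_density_g_cm3 <= 0:
        raise ValueError("bulk density must be positive")
    soil_ml = protocol.soil_mass_g / protocol.bulk_density_g_cm3
    head_ml = protocol.jar_volume_ml - soil_ml
    if head_ml <= 0:
        raise ValueError(
            f"soil volume {soil_ml:.1f} mL fills the {protocol.jar_volume_ml:.0f} mL jar"
        )
    return head_ml / 1000.0


def molar_volume(temperature_c, pressure_atm: float = 1.0):
    """Ideal-gas molar volume (L mol-1) at jar temperature and pressure."""
    return MOLAR_VOLUME_STP * (np.asarray(temperature_c) + 273.15) / 273.15 / pressure_atm


def emission_rate(
    sample_id: str,
    temperature: float,
    duration: float,
    co2_initial: float,
    co2_final: float,
    delta13c_headspace: float,
    protocol: IncubationProtocol,
    delta13c_initial: float | None = None,
) -> EmissionRate:
    """Convert one incubation step's measurements into an emission rate.

    ``delta13c_headspace`` is the final headspace value.  If the jar was not
    flushed (``co2_initial`` > 0) an initial delta13C is required for the
    two-point mass balance; with flushing the emitted delta13C is the
    headspace delta13C itself.
    """
    if duration <= 0:
        raise ValueError("step duration must be positive")
    if co2_initial < 0 or co2_final < 0:
        raise ValueError("CO2 concentrations must be non-negative")
    v_head = headspace_volume(protocol)
    v_m = float(molar_volume(temperature, protocol.pressure_atm))
    d_ppm = co2_final - co2_initial
    rate = (
        d_ppm * 1e-6 * v_head / v_m * MOLAR_MASS_C * 1e6
        / (protocol.soil_mass_g * duration)
    )
    if co2_initial == 0 or delta13c_initial is None:
        delta_emitted = delta13c_headspace
    else:
        if d_ppm == 0:
            delta_emitted = float("nan")
        else:
            delta_emitted = (
                co2_final * delta13c_headspace - co2_initial * delta13c_initial
            ) / d_ppm
    return EmissionRate(
        sample_id=sample_id,
        temperature=temperature,
        rate_total=rate,
        delta13c_emitted=delta_emitted,
        flagged_negative=rate < -NEGATIVE_RATE_TOLERANCE,
    )


def emission_rates(incubation: pd.DataFrame, protocol: IncubationProtocol) -> pd.DataFrame:
    """Vectorised rate computation for an incubation table.

    Expects columns sample_id, temperature_C, duration_h, co2_initial_ppm,
    co2_final_ppm, delta13c_headspace_permil; returns one row per step with
    rate_total, delta13c_emitted and a negative-rate flag.
    """
    if (incubation["duration_h"] <= 0).any():
        raise ValueError("all step durations must be positive")
    v_head = headspace_volume(protocol)
    t = incubation["temperature_C"].to_numpy(float)
    v_m = molar_volume(t, protocol.pressure_atm)
    d_ppm = (incubation["co2_final_ppm"] - incubation["co2_initial_ppm"]).to_numpy(float)
    rate = (
        d_ppm * 1e-6 * v_head / v_m * MOLAR_MASS_C * 1e6
        / (protocol.soil_mass_g * incubation["duration_h"].to_numpy(float))
    )
    out = incubation[["sample_id", "temperature_C"]].copy()
    out["rate_total"] = rate
    # flushed-jar convention: emitted delta13C is the final headspace value
    out["delta13c_emitted"] = incubation["delta13c_headspace_permil"].to_numpy(float)
    out["flagged_negative"] = rate < -NEGATIVE_RATE_TOLERANCE
    return out
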