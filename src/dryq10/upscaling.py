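"""Dryland carbon bookkeeping: heterotrophic flux, warming scenarios, offsets.

Dryland heterotrophic respiration is global soil respiration times the
dryland share times the heterotrophic fraction; its carbonate-derived part
is the SIC share of that.  A warming of dT degC multiplies a base flux F by
Q10^(dT/10), so the warming-induced increment above baseline is

    dF = F * (Q10^(dT/10) - 1).

The aridity-offset calculation re-evaluates the SOC and SIC increments after
shifting each Q10 by its per-0.1-aridity-index change (SOC down, SIC up for
a 0.1 AI decrease): the drop in SOC-derived emissions is partly offset by
the gain in SIC-derived emissions.  In "printed" rounding mode the two
components are rounded to one decimal before the offset ratio, matching how
such budget numbers are typically chained from rounded intermediates; "full"
mode keeps full precision (and yields a somewhat smaller offset).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import UpscalingConstants


@dataclass(frozen=True)
class UpscalingResult:
    dryland_het_resp: float  # Pg C yr-1
    f_sic_base: float
    f_soc_base: float
    warming_flux_soc_q10: float  # SIC warming increment using the SOC Q10
    warming_flux_sic_q10: float  # SIC warming increment using the SIC Q10
    underestimate_pct: float
    soc_reduction: float
    sic_gain: float
    offset_pct: float
    offset_pct_full: float
    rounding: str


def dryland_heterotrophic_respiration(c: UpscalingConstants) -> float:
    """Dryland heterotrophic soil respiration in Pg C yr-1."""
    return c.rs_global * c.dryland_share * c.heterotrophic_fraction


def warming_induced_flux(base_flux: float, q10: float, delta_t: float) -> float:
    """Warming-induced flux increment above baseline: F (Q10^(dT/10) - 1)."""
    if base_flux < 0:
        raise ValueError("base flux must be non-negative")
    if q10 <= 0:
        raise ValueError("Q10 must be positive")
    return base_flux * (q10 ** (delta_t / 10.0) - 1.0)


def underestimate_percent(flux_low: float, flux_high: float) -> float:
    """Percent by which flux_low underestimates flux_high."""
    if flux_high <= 0:
        raise ValueError("reference flux must be positive")
    return 100.0 * (1.0 - flux_low / flux_high)


def aridity_offset(c: UpscalingConstants, rounding: str = "printed"):
    """SOC-flux reduction, SIC-flux gain and offset percent per 0.1 AI decrease.

    SOC's Q10 falls by ``q10_soc_change_per_0p1_ai`` and SIC's rises by
    ``q10_sic_change_per_0p1_ai``; the warming increments are recomputed and
    differenced.  Returns ``(soc_reduction, sic_gain, offset_pct)`` with the
    ratio taken on 1-decimal-rounded components in "printed" mode.
    """
    het = dryland_heterotrophic_respiration(c)
    f_sic = het * c.sic_share
    f_soc = het * (1.0 - c.sic_share)
    soc_old = warming_induced_flux(f_soc, c.mean_q10_soc, c.delta_t)
    soc_new = warming_induced_flux(
        f_soc, c.mean_q10_soc - c.q10_soc_change_per_0p1_ai, c.delta_t)
    sic_old = warming_induced_flux(f_sic, c.mean_q10_sic, c.delta_t)
    sic_new = warming_induced_flux(
        f_sic, c.mean_q10_sic + c.q10_sic_change_per_0p1_ai, c.delta_t)
    soc_reduction = soc_old - soc_new
    sic_gain = sic_new - sic_old
    if soc_reduction <= 0:
        raise ValueError("SOC reduction is non-positive; offset undefined")
    if rounding == "printed":
        num, den = round(sic_gain, 1), round(soc_reduction, 1)
        if den <= 0:
            raise ValueError("rounded SOC reduction is zero; offset undefined")
        offset_pct = 100.0 * num / den
    elif rounding == "full":
        offset_pct = 100.0 * sic_gain / soc_reduction
    else:
        raise ValueError("rounding must be 'printed' or 'full'")
    return soc_reduction, sic_gain, offset_pct


def run_upscaling(c: UpscalingConstants, rounding: str = "printed") -> UpscalingResult:
    """Full bookkeeping chain with every intermediate value."""
    c.validate()
    het = dryland_heterotrophic_respiration(c)
    f_sic = het * c.sic_share
    f_soc = het * (1.0 - c.sic_share)
    w_soc_q10 = warming_induced_flux(f_sic, c.mean_q10_soc, c.delta_t)
    w_sic_q10 = warming_induced_flux(f_sic, c.mean_q10_sic, c.delta_t)
    under = underestimate_percent(w_soc_q10, w_sic_q10)
    soc_red, sic_gain, offset = aridity_offset(c, rounding)
    _, _, offset_full = aridity_offset(c, "full")
    return UpscalingResult(
        dryland_het_resp=het,
        f_sic_base=f_sic,
        f_soc_base=f_soc,
        warming_flux_soc_q10=w_soc_q10,
        warming_flux_sic_q10=w_sic_q10,
        underestimate_pct=under,
        soc_reduction=soc_red,
        sic_gain=sic_gain,
        offset_pct=offset,
        offset_pct_full=offset_full,
        rounding=rounding,
    )
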