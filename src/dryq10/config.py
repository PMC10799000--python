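"""Configuration blocks for the whole pipeline.

Every tunable constant lives in one of the frozen dataclasses below; nothing
numeric is hard-coded inside the operations. All blocks round-trip losslessly
through plain dicts / YAML, and unknown keys are rejected so a typo in a
config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

DEPTHS = ("topsoil", "subsoil")
MOISTURE_LEVELS = ("field", "WHC20", "WHC40", "WHC60")
#: WHC treatment index used for the linear moisture effect (centred on WHC40).
WHC_INDEX = {"WHC20": 0, "WHC40": 1, "WHC60": 2}

MOLAR_MASS_C = 12.011  # g mol-1
MOLAR_VOLUME_STP = 22.414  # L mol-1 at 0 degC, 1 atm


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


def _from_dict(cls, d: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def _to_dict(obj) -> dict:
    out = {}
    for f in fields(obj):
        v = getattr(obj, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


@dataclass(frozen=True)
class IncubationProtocol:
    """Closed-jar incubation geometry and the temperature ramp.

    50 g of dry-weight soil in a 250 mL jar, sealed and flushed with CO2-free
    air at each temperature step; headspace gas is sampled at the start
    (15 mL, replaced with CO2-free air) and again after the step duration.
    The ramp runs 5-30 degC in 5 degC increments, with shorter accumulation
    times at warmer temperatures so headspace CO2 stays in a comparable range.
    """

    jar_volume_ml: float = 250.0
    soil_mass_g: float = 50.0
    bulk_density_g_cm3: float = 1.3  # used only to derive headspace volume
    sample_volume_ml: float = 15.0
    flush_to_zero: bool = True
    pressure_atm: float = 1.0
    temperatures_c: tuple = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    step_durations_h: tuple = (48.0, 36.0, 24.0, 18.0, 12.0, 8.0)

    def validate(self) -> "IncubationProtocol":
        if self.bulk_density_g_cm3 <= 0:
            raise ConfigError("bulk density must be positive")
        if self.soil_mass_g < 0 or self.jar_volume_ml <= 0:
            raise ConfigError("jar volume must be positive, soil mass non-negative")
        if self.jar_volume_ml - self.soil_mass_g / self.bulk_density_g_cm3 <= 0:
            raise ConfigError("soil volume fills or exceeds the jar")
        if len(self.temperatures_c) != len(self.step_durations_h):
            raise ConfigError("temperatures and step durations differ in length")
        if list(self.temperatures_c) != sorted(self.temperatures_c):
            raise ConfigError("protocol temperatures must be ascending")
        for d in self.step_durations_h:
            if not (4.0 <= d <= 72.0):
                raise ConfigError(f"step duration {d} h outside [4, 72] h")
        if self.pressure_atm <= 0:
            raise ConfigError("pressure must be positive")
        return self


@dataclass(frozen=True)
class EndMembers:
    """Isotopic end members and corrections for the two-source mixing model.

    ``diffusion_offset`` is the per-mil enrichment applied to the emitted
    delta13C to recover soil CO2 (molecular diffusion leaves emitted CO2
    4.4 permil lighter than soil CO2). ``temp_frac_a/b`` are a linear hook
    (a + b*T) for temperature-dependent fractionation of the end members;
    the default (0, 0) assumes source and source-derived CO2 share one
    delta13C value.
    """

    delta13c_soc_end: float = -24.0
    delta13c_sic_end: float = -2.0
    diffusion_offset: float = 4.4
    temp_frac_a: float = 0.0
    temp_frac_b: float = 0.0
    min_separation: float = 5.0

    def validate(self) -> "EndMembers":
        if self.min_separation <= 0:
            raise ConfigError("min_separation must be positive")
        if abs(self.delta13c_sic_end - self.delta13c_soc_end) < self.min_separation:
            raise ConfigError(
                "end members closer than the minimum separation "
                f"({self.min_separation} permil): mixing is ill-conditioned"
            )
        return self


@dataclass(frozen=True)
class QCThresholds:
    """Goodness-of-fit gates for the exponential temperature-response fits."""

    r2_soc: float = 0.95
    r2_sic: float = 0.85
    min_points: int = 4

    def validate(self) -> "QCThresholds":
        if not (0 <= self.r2_soc <= 1 and 0 <= self.r2_sic <= 1):
            raise ConfigError("R2 thresholds must lie in [0, 1]")
        if self.min_points < 3:
            raise ConfigError("need at least 3 points for a meaningful fit")
        return self


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic dryland cohort.

    The defaults emulate a 30-site transect across northern-China-like
    drylands: aridity index (AI) 0.04-0.59, MAT -1.2-10.0 degC independent of
    AI, two depths, field moisture plus three water-holding-capacity (WHC)
    treatments.  Ground-truth Q10s are linear in AI (opposite slopes for the
    organic and carbonate sources) plus a linear WHC effect and Gaussian
    site noise.
    """

    n_sites: int = 30
    ai_range: tuple = (0.04, 0.59)
    mat_range: tuple = (-1.2, 10.0)
    map_range: tuple = (46.0, 486.0)
    depths: tuple = DEPTHS
    moisture_levels: tuple = MOISTURE_LEVELS
    q10_soc_slope: float = 4.7  # Q10 per unit AI (= 0.47 per 0.1 AI)
    q10_sic_slope: float = -3.9
    q10_soc_mean: float = 3.14  # cohort mean at field moisture
    q10_sic_mean: float = 4.23
    q10_noise_sd: float = 0.25
    q10_floor: float = 1.02
    sic_contribution_20c: tuple = (0.072, 0.111)  # (topsoil, subsoil) f_SIC at 20 degC
    r_soc_20c_topsoil: float = 1.0  # ug C g-1 h-1
    r_soc_20c_subsoil: float = 0.3
    rate_lognorm_sd: float = 0.5  # per-sample spread of the 20 degC SOC rate
    delta13c_soc_mean: float = -24.0
    delta13c_soc_sd: float = 1.0
    delta13c_sic_mean: float = -2.0
    delta13c_sic_sd: float = 1.0
    whc_effect_soc: float = 0.4  # Q10 increment per WHC step (20->40->60)
    whc_effect_sic: float = -0.4
    co2_noise_sd_ppm: float = 5.0
    delta13c_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        lo, hi = self.ai_range
        if not (0 <= lo < hi <= 1):
            raise ConfigError("ai_range must be an increasing interval within [0, 1]")
        if self.n_sites < 3:
            raise ConfigError("need at least 3 sites for the regression stages")
        if not self.moisture_levels:
            raise ConfigError("moisture_levels may not be empty")
        for m in self.moisture_levels:
            if m != "field" and m not in WHC_INDEX:
                raise ConfigError(f"unknown moisture level {m!r}")
        for d in self.depths:
            if d not in DEPTHS:
                raise ConfigError(f"unknown depth {d!r}")
        if self.r_soc_20c_topsoil <= 0 or self.r_soc_20c_subsoil <= 0:
            raise ConfigError("20 degC SOC rates must be positive")
        for c in self.sic_contribution_20c:
            if not (0 < c < 1):
                raise ConfigError("sic_contribution_20c must lie in (0, 1)")
        for s in (self.q10_soc_slope, self.q10_sic_slope):
            if not abs(s) < 1e6:
                raise ConfigError("Q10 slopes must be finite")
        if min(self.q10_noise_sd, self.co2_noise_sd_ppm, self.delta13c_noise_sd) < 0:
            raise ConfigError("noise SDs must be non-negative")
        return self

    def noiseless(self) -> "GeneratorConfig":
        """Copy with all measurement noise switched off (round-trip checks)."""
        return dataclasses.replace(
            self, co2_noise_sd_ppm=0.0, delta13c_noise_sd=0.0
        )


@dataclass(frozen=True)
class UpscalingConstants:
    """Bookkeeping constants for the dryland carbon upscaling arithmetic.

    ``rs_global`` is global soil respiration; drylands contribute
    ``dryland_share`` of it, of which ``heterotrophic_fraction`` is microbial.
    ``sic_share`` is the carbonate-derived share of dryland heterotrophic CO2.
    Mean Q10s and their per-0.1-AI changes parameterise the warming and
    aridity scenarios.
    """

    rs_global: float = 88.0  # Pg C yr-1
    dryland_share: float = 0.386
    heterotrophic_fraction: float = 0.60
    sic_share: float = 0.27
    delta_t: float = 4.0  # degC of warming
    mean_q10_soc: float = 3.14
    mean_q10_sic: float = 4.23
    q10_soc_change_per_0p1_ai: float = 0.47
    q10_sic_change_per_0p1_ai: float = 0.39

    def validate(self) -> "UpscalingConstants":
        for name in ("dryland_share", "heterotrophic_fraction", "sic_share"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.mean_q10_soc <= 1 or self.mean_q10_sic <= 1:
            raise ConfigError("mean Q10s must exceed 1")
        if self.rs_global < 0:
            raise ConfigError("rs_global must be non-negative")
        return self


#: Default path-model composites; the first listed member fixes the PC1 sign.
#: The physical group is oriented toward mineral-protected fractions
#: (MAOM first) so the composite reads as "physicochemical protection".
DEFAULT_COMPOSITES = {
    "climate": ("mat", "aridity_index"),
    "physical": ("oc_maom", "oc_fe", "oc_ca", "oc_pom"),
    "chemical": ("ph", "cec", "ca", "mg"),
    "substrate": ("soc", "sic", "cai", "d_soc"),
}

#: Default recursive DAG: climate drives each soil group; all four composites
#: feed the response.  Edges are (from, to) with "response" as a placeholder.
DEFAULT_DAG = (
    ("climate", "physical"),
    ("climate", "chemical"),
    ("climate", "substrate"),
    ("climate", "response"),
    ("physical", "response"),
    ("chemical", "response"),
    ("substrate", "response"),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs, in one round-trippable block."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    protocol: IncubationProtocol = field(default_factory=IncubationProtocol)
    end_members: EndMembers = field(default_factory=EndMembers)
    qc: QCThresholds = field(default_factory=QCThresholds)
    upscaling: UpscalingConstants = field(default_factory=UpscalingConstants)
    holm_correction: bool = True
    rounding: str = "printed"  # "printed" | "full" for the upscaling offset
    dag: tuple = DEFAULT_DAG
    composites: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITES))
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.generator.validate()
        self.protocol.validate()
        self.end_members.validate()
        self.qc.validate()
        self.upscaling.validate()
        if self.rounding not in ("printed", "full"):
            raise ConfigError("rounding must be 'printed' or 'full'")
        return self

    def to_dict(self) -> dict:
        return {
            "generator": _to_dict(self.generator),
            "protocol": _to_dict(self.protocol),
            "end_members": _to_dict(self.end_members),
            "qc": _to_dict(self.qc),
            "upscaling": _to_dict(self.upscaling),
            "holm_correction": self.holm_correction,
            "rounding": self.rounding,
            "dag": [list(e) for e in self.dag],
            "composites": {k: list(v) for k, v in self.composites.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "generator": GeneratorConfig,
            "protocol": IncubationProtocol,
            "end_members": EndMembers,
            "qc": QCThresholds,
            "upscaling": UpscalingConstants,
        }
        kwargs = {}
        for key, klass in sub.items():
            if key in d:
                kwargs[key] = _from_dict(klass, d.pop(key))
        if "dag" in d:
            kwargs["dag"] = tuple(tuple(e) for e in d.pop("dag"))
        if "composites" in d:
            kwargs["composites"] = {
                k: tuple(v) for k, v in d.pop("composites").items()
            }
        for key in ("holm_correction", "rounding", "seed"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ConfigError(f"RunConfig: unknown keys {sorted(d)}")
        return cls(**kwargs).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
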