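"""Configuration: schema-validated acquisition/threshold/statistics settings.

Every constant that appears in any diagnostic rule or fitting routine is
present here, loaded from a packaged TOML file and overridable by a user
TOML; unknown keys are rejected.  Outputs record a SHA-256 hash of the
effective configuration so every report is traceable to its settings.
"""

from __future__ import annotations

import hashlib
import tomllib
from importlib import resources

from pydantic import BaseModel, ConfigDict, Field

from .signal_model import AcquisitionProtocol, FatSpectrum
from .synthetic_cohort import CohortConfig

__all__ = [
    "AnalysisConfig",
    "load_config",
    "default_config",
    "default_fat_spectrum",
    "default_protocol",
]


class SpectrumSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    field_strength_t: float = 1.5
    ppm_offsets: list[float]
    relative_amplitudes: list[float]

    def build(self) -> FatSpectrum:
        return FatSpectrum.from_ppm(
            self.ppm_offsets, self.relative_amplitudes, self.field_strength_t
        )


class ProtocolSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    first_te_ms: float
    delta_te_ms: float
    n_echoes: int = Field(ge=4)

    def build(self, organ: str) -> AcquisitionProtocol:
        return AcquisitionProtocol.uniform(
            self.first_te_ms, self.delta_te_ms, self.n_echoes, organ=organ
        )


class FitSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t2star_min_ms: float = 0.1
    t2star_max_ms: float = 1000.0
    ff_starts: list[float] = [0.05, 0.25, 0.45, 0.65]
    truncation_snr_factor: float = 2.0
    with_offset: bool = False

    @property
    def t2s_bounds(self) -> tuple[float, float]:
        return (self.t2star_min_ms, self.t2star_max_ms)


class ThresholdSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pancreas_t2s_normal_ms: float = 26.0
    ff_upper_limit_pct: float = 6.6
    lic_significant_mg_g: float = 3.0
    heart_t2s_normal_ms: float = 20.0
    jet_velocity_ph_m_s: float = 3.2
    fpg_ifg_mg_dl: float = 100.0
    fpg_dm_mg_dl: float = 126.0
    glucose2h_igt_mg_dl: float = 140.0
    glucose2h_dm_mg_dl: float = 200.0


class LicCalibrationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    slope_mg_g_per_hz: float = 0.0254
    intercept_mg_g: float = 0.202


class StatsSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    stepwise_entry_p: float = 0.05
    stepwise_removal_p: float = 0.10
    vif_max: float = 5.0
    tolerance_min: float = 0.20
    normative_epsilon_pct: float = 0.1


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    spectrum: SpectrumSettings
    protocols: dict[str, ProtocolSettings]
    fit: FitSettings = FitSettings()
    thresholds: ThresholdSettings = ThresholdSettings()
    lic_calibration: LicCalibrationSettings = LicCalibrationSettings()
    stats: StatsSettings = StatsSettings()
    generator: CohortConfig | None = None

    def sha256(self) -> str:
        return hashlib.sha256(
            self.model_dump_json(exclude_none=True).encode()
        ).hexdigest()


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _default_raw() -> dict:
    text = resources.files("ferrofat.data").joinpath("default_config.toml").read_text()
    return tomllib.loads(text)


def default_config() -> AnalysisConfig:
    return AnalysisConfig.model_validate(_default_raw())


def load_config(path=None) -> AnalysisConfig:
    """Packaged defaults, deep-merged with an optional user TOML file."""
    raw = _default_raw()
    if path is not None:
        with open(path, "rb") as fh:
            raw = _deep_merge(raw, tomllib.load(fh))
    return AnalysisConfig.model_validate(raw)


def default_fat_spectrum(field_strength_t: float | None = None) -> FatSpectrum:
    """The packaged six-peak fat spectrum, optionally rescaled to another field."""
    settings = default_config().spectrum
    if field_strength_t is not None:
        settings = settings.model_copy(update={"field_strength_t": field_strength_t})
    return settings.build()


def default_protocol(organ: str) -> AcquisitionProtocol:
    protocols = default_config().protocols
    if organ not in protocols:
        raise KeyError(f"no default protocol for organ {organ!r}")
    return protocols[organ].build(organ)
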