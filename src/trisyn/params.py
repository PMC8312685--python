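"""Model parameters, unit handling, configuration loading and validation.

The configuration is authored in the units the source tables use
(mS/cm^2, uA/cm^2, mV, M^-1 ms^-1 ...) and normalised once into a canonical
SI-based system before any computation:

* potentials in V, time in s
* current densities in A m^-2, conductances in S m^-2, capacitance in F m^-2
* concentrations in mM (the one deliberate departure from strict SI: every
  current law uses concentration *ratios*, and the Faraday flux conversion
  carries the mM <-> mol/L factor explicitly)
* receptor binding rates in mM^-1 s^-1, unbinding rates in s^-1.

Exact identities used at the boundary: 1 uA/cm^2 = 0.01 A/m^2,
1 mS/cm^2 = 10 S/m^2, 1 uF/cm^2 = 0.01 F/m^2, 1 M^-1 ms^-1 = 1 mM^-1 s^-1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "ConfigError",
    "Constants",
    "GeometryParams",
    "NeuronParams",
    "ReleaseParams",
    "AstroParams",
    "InitialConcentrations",
    "ModelConfig",
    "default_config",
    "load_config",
    "normalize_units",
    "config_to_dict",
    "config_from_dict",
    "config_hash",
]

# exact unit identities (table unit -> canonical)
UA_PER_CM2_TO_A_PER_M2 = 0.01
MS_PER_CM2_TO_S_PER_M2 = 10.0
UF_PER_CM2_TO_F_PER_M2 = 0.01
MV_TO_V = 1e-3
PER_MS_TO_PER_S = 1e3


class ConfigError(ValueError):
    """Invalid configuration value or key."""


@dataclass(frozen=True)
class Constants:
    """Physical constants (values as used throughout the model)."""

    faraday: float = 96480.0        # C mol^-1
    gas_constant: float = 8.3145    # J K^-1 mol^-1
    temperature: float = 310.0      # K

    @property
    def thermal_voltage(self) -> float:
        """RT/F in volts; always recomputed from F, R, T."""
        return self.gas_constant * self.temperature / self.faraday


@dataclass(frozen=True)
class GeometryParams:
    """Compartment geometry. Volumes in litres, area in m^2."""

    vol_syn: float = 8.5883e-16   # synaptic compartment volume (L)
    vol_ast: float = 1.885e-17    # astrocytic compartment volume (L)
    area_ast: float = 1.4137e-13  # perisynaptic astrocytic membrane area (m^2)

    def validate(self) -> None:
        for name in ("vol_syn", "vol_ast", "area_ast"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"geometry.{name} must be positive")


@dataclass(frozen=True)
class NeuronParams:
    """Hodgkin-Huxley and ionotropic-receptor parameters for one neuron.

    Both neurons share this parameter set.  In table units conductances are
    mS/cm^2, capacitance uF/cm^2, potentials mV, binding rates M^-1 ms^-1 and
    unbinding rates ms^-1.
    """

    c_m: float = 1.0          # membrane capacitance
    g_na: float = 35.0        # voltage-gated Na+ conductance
    g_k: float = 6.0          # delayed-rectifier K+ conductance
    g_leak: float = 0.0112    # leak conductance
    e_leak: float = -74.6     # leak reversal
    g_nmda: float = 0.026
    g_ampa: float = 0.0145
    g_gabaa: float = 0.0145
    e_nmda: float = 0.0
    e_ampa: float = 0.0
    e_gabaa: float = -85.0
    alpha_nmda: float = 72.0
    alpha_ampa: float = 1.1e3
    alpha_gabaa: float = 5.0e2
    beta_nmda: float = 6.6e-3
    beta_ampa: float = 0.190
    beta_gabaa: float = 0.72
    na_internal: float = 15.0   # fixed neuron-internal Na+ (mM)
    k_internal: float = 130.0   # fixed neuron-internal K+ (mM)
    mg: float = 1.0             # Mg2+ level in the NMDA block term (mM)
    v_rest_target: float = -71.0  # postsynaptic resting potential (calibration target)

    def to_canonical(self) -> "NeuronParams":
        return replace(
            self,
            c_m=self.c_m * UF_PER_CM2_TO_F_PER_M2,
            g_na=self.g_na * MS_PER_CM2_TO_S_PER_M2,
            g_k=self.g_k * MS_PER_CM2_TO_S_PER_M2,
            g_leak=self.g_leak * MS_PER_CM2_TO_S_PER_M2,
            e_leak=self.e_leak * MV_TO_V,
            g_nmda=self.g_nmda * MS_PER_CM2_TO_S_PER_M2,
            g_ampa=self.g_ampa * MS_PER_CM2_TO_S_PER_M2,
            g_gabaa=self.g_gabaa * MS_PER_CM2_TO_S_PER_M2,
            e_nmda=self.e_nmda * MV_TO_V,
            e_ampa=self.e_ampa * MV_TO_V,
            e_gabaa=self.e_gabaa * MV_TO_V,
            # M^-1 ms^-1 == mM^-1 s^-1 (numerically identical)
            beta_nmda=self.beta_nmda * PER_MS_TO_PER_S,
            beta_ampa=self.beta_ampa * PER_MS_TO_PER_S,
            beta_gabaa=self.beta_gabaa * PER_MS_TO_PER_S,
            v_rest_target=self.v_rest_target * MV_TO_V,
        )

    def validate(self) -> None:
        for name in ("c_m", "g_na", "g_k", "g_leak", "g_nmda", "g_ampa", "g_gabaa"):
            if getattr(self, name) < 0:
                raise ConfigError(f"neuron.{name} must be non-negative")
        for name in (
            "alpha_nmda", "alpha_ampa", "alpha_gabaa",
            "beta_nmda", "beta_ampa", "beta_gabaa",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"neuron.{name} must be positive")
        for name in ("na_internal", "k_internal"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"neuron.{name} must be positive")
        if self.mg < 0:
            raise ConfigError("neuron.mg must be non-negative")


@dataclass(frozen=True)
class ReleaseParams:
    """Three-pool vesicle-resource model and per-spike release amounts."""

    u: float = 0.5          # utilisation fraction per spike
    tau_r: float = 0.800    # recovery time constant (s)
    tau_i: float = 0.003    # inactivation time constant (s)
    glu_scale: float = 0.1  # Glu released per unit released fraction (mM)
    k_release: float = 0.05  # K+ added to the cleft per spike (mM)

    def to_canonical(self) -> "ReleaseParams":
        return self  # already in canonical units

    def validate(self) -> None:
        if not 0 < self.u <= 1:
            raise ConfigError("release.u must be in (0, 1]")
        if self.tau_r <= 0 or self.tau_i <= 0:
            raise ConfigError("release time constants must be positive")
        if self.glu_scale < 0 or self.k_release < 0:
            raise ConfigError("release amounts must be non-negative")


@dataclass(frozen=True)
class AstroParams:
    """Astrocytic transporter/channel parameters (already SI in the tables)."""

    i_nka_max: float = 0.1081   # maximal Na+/K+-ATPase current (A m^-2)
    k_nai: float = 1.5          # NKA affinity for astrocytic Na+ (mM)
    k_ke: float = 10.0          # NKA affinity for synaptic K+ (mM)
    i_ncx_max: float = 0.01     # maximal Na+/Ca2+ exchanger current (A m^-2)
    gamma: float = 0.5          # NCX energy-barrier partition parameter
    alpha_eaat: float = 2e-4    # EAAT-2 current scale (A m^-2)
    beta_eaat: float = 29.2     # EAAT-2 voltage sensitivity (V^-1)
    g_kir: float = 1440.0       # Kir4.1 conductance scale (S m^-2 per mM K+)
    g_gat: float = 2.1e2        # GAT-3 conductance (S m^-2)
    e_kir_offset: float = 0.0   # optional additive offset on the Kir driving force (V)
    i_nkcc_max: float = 0.0     # NKCC current scale (A m^-2); optional component
    z_na: int = 1
    z_k: int = 1
    z_ca: int = 2
    z_glu: int = -1
    z_gaba: int = 1  # one GABA per net elementary charge through GAT-3

    def to_canonical(self) -> "AstroParams":
        return self  # table values are already in the canonical system

    def validate(self) -> None:
        for name in ("i_nka_max", "k_nai", "k_ke", "i_ncx_max", "alpha_eaat",
                     "beta_eaat", "g_kir", "g_gat"):
            if getattr(self, name) < 0:
                raise ConfigError(f"astro.{name} must be non-negative")
        for name in ("z_na", "z_k", "z_ca", "z_glu", "z_gaba"):
            if getattr(self, name) == 0:
                raise ConfigError(f"astro.{name} must be non-zero")


@dataclass(frozen=True)
class InitialConcentrations:
    """Initial/basal concentrations (mM) and the fixed H+/Cl- ratios.

    ``glu_syn`` and ``gaba_syn`` default to ``None`` meaning *derive them*:
    the ambient synaptic Glu is calibrated so the unstimulated postsynaptic
    neuron settles at the target resting potential, and the basal synaptic
    GABA is the value that puts the GAT-3 reversal potential exactly at the
    astrocytic membrane potential.  Chloride is not a dynamic species; only
    the fixed ratio Cl_syn/Cl_ast enters (through the GAT-3 and NKCC laws).
    """

    na_syn: float = 140.0
    na_ast: float = 15.0
    k_syn: float = 4.0
    k_ast: float = 130.0
    ca_syn: float = 2.0
    ca_ast: float = 1e-4
    gaba_ast: float = 2.0
    glu_syn: float | None = None   # mM; None -> calibrated (tonic ambient Glu)
    gaba_syn: float | None = None  # mM; None -> solved from E_GAT = V_a
    h_ratio: float = 10.0 ** (-7.3) / 10.0 ** (-7.2)  # pH 7.3 (syn) / 7.2 (ast)
    cl_syn: float = 130.0
    cl_ast: float = 40.0

    @property
    def cl_ratio(self) -> float:
        return self.cl_syn / self.cl_ast

    def to_canonical(self) -> "InitialConcentrations":
        return self  # mM everywhere

    def validate(self) -> None:
        for name in ("na_syn", "na_ast", "k_syn", "k_ast", "ca_syn", "ca_ast",
                     "gaba_ast", "h_ratio", "cl_syn", "cl_ast"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"init.{name} must be positive")
        for name in ("glu_syn", "gaba_syn"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigError(f"init.{name} must be positive when given")


GABAA_PLACEMENTS = ("both", "post_only", "none")
RELEASE_MODES = ("impulse", "continuous")


@dataclass(frozen=True)
class ModelConfig:
    """Complete model configuration.

    ``units`` records whether the numeric fields are still in table units
    (``"table"``) or have been normalised (``"canonical"``).  All computation
    entry points normalise first; :func:`normalize_units` is idempotent.
    """

    constants: Constants = field(default_factory=Constants)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    release: ReleaseParams = field(default_factory=ReleaseParams)
    astro: AstroParams = field(default_factory=AstroParams)
    init: InitialConcentrations = field(default_factory=InitialConcentrations)
    v_ast: float = -80.0          # constant astrocytic membrane potential (mV / V)
    glu_ast_basal: float = 1.5    # basal astrocytic Glu (mM): 1.5, 5 or 10 in the study
    gat3_enabled: bool = True
    gabaa_placement: str = "both"  # "both" | "post_only" | "none"
    nkcc_enabled: bool = False
    nka_k_sign: float = -1.0      # sign of the NKA term in the K+ composition
    release_mode: str = "impulse"  # "impulse" | "continuous"
    dt: float = 1e-5              # integration step (s); 0.01 ms
    duration: float = 90.0        # simulated time (s)
    record_dt: float = 1e-3       # trace decimation interval (s)
    units: str = "table"

    def validate(self) -> None:
        self.geometry.validate()
        self.neuron.validate()
        self.release.validate()
        self.astro.validate()
        self.init.validate()
        if self.glu_ast_basal <= 0:
            raise ConfigError("glu_ast_basal must be positive")
        if self.gabaa_placement not in GABAA_PLACEMENTS:
            raise ConfigError(
                f"gabaa_placement must be one of {GABAA_PLACEMENTS}, "
                f"got {self.gabaa_placement!r}"
            )
        if self.release_mode not in RELEASE_MODES:
            raise ConfigError(f"release_mode must be one of {RELEASE_MODES}")
        if not self.gat3_enabled and self.gabaa_placement != "none":
            raise ConfigError(
                "gabaa_placement must be 'none' when gat3_enabled is False "
                "(no GABA source without GAT-3)"
            )
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.duration < 0:
            raise ConfigError("duration must be non-negative")
        if self.record_dt <= 0:
            raise ConfigError("record_dt must be positive")
        if self.nka_k_sign not in (-1.0, 1.0):
            raise ConfigError("nka_k_sign must be +1 or -1")
        if self.units not in ("table", "canonical"):
            raise ConfigError("units must be 'table' or 'canonical'")

    @property
    def thermal_voltage(self) -> float:
        return self.constants.thermal_voltage


def normalize_units(config: ModelConfig) -> ModelConfig:
    """Convert a table-unit configuration to the canonical system (idempotent)."""
    if config.units == "canonical":
        return config
    return replace(
        config,
        neuron=config.neuron.to_canonical(),
        release=config.release.to_canonical(),
        astro=config.astro.to_canonical(),
        init=config.init.to_canonical(),
        v_ast=config.v_ast * MV_TO_V,
        units="canonical",
    )


def default_config(**overrides: Any) -> ModelConfig:
    """The study's default configuration, in table units.

    Keyword overrides address top-level fields (e.g. ``glu_ast_basal=10``)
    or nested ones with dotted flat keys via :func:`load_config`.
    """
    cfg = ModelConfig(**overrides) if overrides else ModelConfig()
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# flat-key schema: structured-text configs and key=value overrides
# ---------------------------------------------------------------------------

_SECTIONS = {
    "constants": Constants,
    "geometry": GeometryParams,
    "neuron": NeuronParams,
    "release": ReleaseParams,
    "astro": AstroParams,
    "init": InitialConcentrations,
}

_TOP_LEVEL = (
    "v_ast", "glu_ast_basal", "gat3_enabled", "gabaa_placement",
    "nkcc_enabled", "nka_k_sign", "release_mode", "dt", "duration",
    "record_dt",
)


def _flat_schema() -> dict[str, tuple[str | None, str]]:
    """Map flat config keys to (section, field).  Section fields win their
    bare name; ambiguities would need the dotted form (none exist today)."""
    schema: dict[str, tuple[str | None, str]] = {}
    for name in _TOP_LEVEL:
        schema[name] = (None, name)
    for sec, cls in _SECTIONS.items():
        for f in dataclasses.fields(cls):
            schema[f"{sec}.{f.name}"] = (sec, f.name)
            schema.setdefault(f.name, (sec, f.name))
    return schema


_SCHEMA = _flat_schema()


def _coerce(value: Any, current: Any) -> Any:
    if isinstance(value, str) and not isinstance(current, str):
        if isinstance(current, bool):
            if value.lower() in ("true", "1", "yes", "on"):
                return True
            if value.lower() in ("false", "0", "no", "off"):
                return False
            raise ConfigError(f"cannot parse boolean from {value!r}")
        if current is None or isinstance(current, float):
            return float(value)
        if isinstance(current, int):
            return int(value)
    if isinstance(current, bool) and isinstance(value, (int, float)):
        return bool(value)
    if isinstance(current, float) and isinstance(value, int):
        return float(value)
    return value


def _apply_flat(cfg: ModelConfig, items: Mapping[str, Any]) -> ModelConfig:
    for key, value in items.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown configuration key: {key!r}")
        sec, name = _SCHEMA[key]
        if sec is None:
            cfg = replace(cfg, **{name: _coerce(value, getattr(cfg, name))})
        else:
            sub = getattr(cfg, sec)
            sub = replace(sub, **{name: _coerce(value, getattr(sub, name))})
            cfg = replace(cfg, **{sec: sub})
    return cfg


def _parse_overrides(overrides: Mapping[str, Any] | Iterable[str] | None) -> dict:
    if overrides is None:
        return {}
    if isinstance(overrides, Mapping):
        return dict(overrides)
    parsed = {}
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        key, _, value = item.partition("=")
        parsed[key.strip()] = value.strip()
    return parsed


def load_config(path: str | None = None,
                overrides: Mapping[str, Any] | Iterable[str] | None = None,
                ) -> ModelConfig:
    """Load a flat-key YAML configuration (table units) and apply overrides.

    An empty or absent file yields the table defaults.  Unknown keys and
    invalid values raise :class:`ConfigError`; overrides may be a mapping or
    an iterable of ``key=value`` strings.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            try:
                loaded = yaml.safe_load(fh)
            except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
                raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config file must contain a flat key/value mapping")
            data.update(loaded)
    cfg = ModelConfig()
    cfg = _apply_flat(cfg, data)
    cfg = _apply_flat(cfg, _parse_overrides(overrides))
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)


def _build(cls, data: Mapping[str, Any]):
    return cls(**{k: v for k, v in data.items() if k != "cl_ratio"})


def config_from_dict(data: Mapping[str, Any]) -> ModelConfig:
    kwargs = dict(data)
    for sec, cls in _SECTIONS.items():
        if sec in kwargs and isinstance(kwargs[sec], Mapping):
            kwargs[sec] = _build(cls, kwargs[sec])
    cfg = ModelConfig(**kwargs)
    cfg.validate()
    return cfg


def config_hash(config: ModelConfig) -> str:
    """SHA-256 of the canonical JSON serialization; changes when any field does."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
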