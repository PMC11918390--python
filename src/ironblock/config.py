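"""Configuration loading and unit normalisation.

The model is configured from a YAML file in which every dimensional quantity
is a string ``"<value> <unit>"``.  All quantities are normalised to an internal
SI-based system: concentrations in mol/L, membrane densities in mol/cm^2,
volumes in L, areas in cm^2, times in seconds.  Amounts are always mol.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "UnitError",
    "ConfigError",
    "parse_quantity",
    "format_quantity",
    "ModelConfig",
    "load_config",
    "default_config",
]


class UnitError(ValueError):
    """Raised when a unit string cannot be interpreted."""


class ConfigError(ValueError):
    """Raised when a configuration file is structurally invalid."""


# Multiplicative factors to the internal unit system.  Each entry maps a unit
# spelling to (factor, dimension tag).  The dimension tag is only used for
# error messages and round-tripping.
_UNIT_FACTORS: dict[str, tuple[float, str]] = {
    # concentration -> M
    "M": (1.0, "concentration"),
    "mM": (1e-3, "concentration"),
    "uM": (1e-6, "concentration"),
    "µM": (1e-6, "concentration"),
    "nM": (1e-9, "concentration"),
    "pM": (1e-12, "concentration"),
    # surface density -> mol/cm^2
    "mol/cm^2": (1.0, "density"),
    "pmol/cm^2": (1e-12, "density"),
    "fmol/cm^2": (1e-15, "density"),
    # volume -> L
    "L": (1.0, "volume"),
    "mL": (1e-3, "volume"),
    "uL": (1e-6, "volume"),
    "pL": (1e-12, "volume"),
    # area -> cm^2
    "cm^2": (1.0, "area"),
    "um^2": (1e-8, "area"),
    # time -> s
    "s": (1.0, "time"),
    "min": (60.0, "time"),
    "h": (3600.0, "time"),
    # rates
    "1/s": (1.0, "first-order rate"),
    "1/(M s)": (1.0, "second-order rate"),
    "1/(M^2 s)": (1.0, "third-order rate"),
    "M/s": (1.0, "zeroth-order rate"),
    "mM/s": (1e-3, "zeroth-order rate"),
    "uM/s": (1e-6, "zeroth-order rate"),
    "nM/s": (1e-9, "zeroth-order rate"),
    "pM/s": (1e-12, "zeroth-order rate"),
    # amounts -> mol
    "mol": (1.0, "amount"),
    "pmol": (1e-12, "amount"),
    "fmol": (1e-15, "amount"),
}


def parse_quantity(value: Any) -> float:
    """Parse ``"2.31 uM"`` (or a bare number) into internal units.

    Bare numbers are taken as dimensionless.  Raises :class:`UnitError` for
    unrecognised unit spellings.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise UnitError(f"cannot parse quantity from {value!r}")
    parts = value.split(None, 1)
    try:
        mag = float(parts[0])
    except ValueError as exc:
        raise UnitError(f"malformed quantity {value!r}") from exc
    if len(parts) == 1:
        return mag
    unit = parts[1].strip()
    if unit not in _UNIT_FACTORS:
        raise UnitError(f"unrecognised unit {unit!r} in {value!r}")
    return mag * _UNIT_FACTORS[unit][0]


def format_quantity(value: float, unit: str) -> str:
    """Render an internal value back into the given unit (round-trip aid)."""
    if unit not in _UNIT_FACTORS:
        raise UnitError(f"unrecognised unit {unit!r}")
    return f"{value / _UNIT_FACTORS[unit][0]:.12g} {unit}"


_REQUIRED_SECTIONS = ("compartments", "initial", "reactions")

# reaction -> allowed parameter keys
_REACTION_PARAMS: dict[str, tuple[str, ...]] = {
    "dmt1_endocytosis_free": ("k_cat",),
    "dmt1_endocytosis_lip": ("k_cat", "K_m", "n"),
    "dmt1_fusion": ("k_cat",),
    "dmt1_iron_transport": ("k_cat", "K_m"),
    "oxidation": ("k_cat", "K_m", "n", "rO", "H"),
    "reduction": ("k_deg",),
    "nucleation": ("k_cat", "K_i", "n", "rN", "L"),
    "mineralization": ("k_cat", "K_m", "K_i", "n", "m", "capacity"),
    "ft_core_release": ("k_deg",),
    "ft_degradation": ("k_deg",),
    "fpn_inactivation": ("k_cat", "K_m", "n"),
    "fpn_activation": ("k_cat",),
    "fpn_iron_transport": ("k_cat", "K_m"),
    "irps_inactivation": ("k_cat",),
    "irps_activation": ("k_cat",),
    "ft_expression": ("k_cat", "K_m", "n"),
    "body_sequestration": ("k_cat",),
    "basal_uptake": ("k_cat",),
    "paracellular": ("k_for", "k_rev"),
}

_COMPARTMENTS = ("lumen", "cytoplasm", "blood", "apical_membrane", "basal_membrane")

_SPECIES = (
    "Fe_lumen", "LIP", "DFP", "core", "FT",
    "DMT1_active", "DMT1_cytoplasm", "FPN_active", "FPN_inactive",
    "IRPs_active", "IRPs_inactive", "Fe_blood", "Fe_body",
)


@dataclass
class ModelConfig:
    """Unit-normalised model definition.

    Attributes
    ----------
    compartments : mapping of compartment name to size (L or cm^2).
    initial : mapping of species name to intensive initial value.
    rates : mapping ``reaction -> parameter -> float`` in internal units.
    protocols : free-form protocol defaults (normalised where dimensional).
    """

    compartments: dict[str, float]
    initial: dict[str, float]
    rates: dict[str, dict[str, float]]
    protocols: dict[str, Any] = field(default_factory=dict)

    def copy(self) -> "ModelConfig":
        return ModelConfig(
            compartments=dict(self.compartments),
            initial=dict(self.initial),
            rates={k: dict(v) for k, v in self.rates.items()},
            protocols=copy.deepcopy(self.protocols),
        )

    def get_rate(self, key: str) -> float:
        """Look up ``"reaction.parameter"`` (used by scans and fitting)."""
        reaction, _, param = key.partition(".")
        try:
            return self.rates[reaction][param]
        except KeyError as exc:
            raise ConfigError(f"unknown rate parameter {key!r}") from exc

    def set_rate(self, key: str, value: float) -> None:
        reaction, _, param = key.partition(".")
        if reaction not in self.rates or param not in self.rates[reaction]:
            raise ConfigError(f"unknown rate parameter {key!r}")
        self.rates[reaction][param] = float(value)


def _normalise(raw: Mapping[str, Any]) -> ModelConfig:
    for section in _REQUIRED_SECTIONS:
        if section not in raw:
            raise ConfigError(f"missing required section {section!r}")

    comps: dict[str, float] = {}
    for name, spec in raw["compartments"].items():
        if name not in _COMPARTMENTS:
            raise ConfigError(f"unknown compartment {name!r}")
        size = parse_quantity(spec["size"] if isinstance(spec, Mapping) else spec)
        if not size > 0:
            raise ConfigError(f"compartment {name!r} must have positive size")
        comps[name] = size
    missing = set(_COMPARTMENTS) - set(comps)
    if missing:
        raise ConfigError(f"missing compartments: {sorted(missing)}")

    init: dict[str, float] = {}
    for name, value in raw["initial"].items():
        if name not in _SPECIES:
            raise ConfigError(f"unknown species {name!r}")
        v = parse_quantity(value)
        if v < 0:
            raise ConfigError(f"negative initial value for {name!r}")
        init[name] = v
    missing = set(_SPECIES) - set(init)
    if missing:
        raise ConfigError(f"missing initial values: {sorted(missing)}")

    rates: dict[str, dict[str, float]] = {}
    for reaction, params in raw["reactions"].items():
        if reaction not in _REACTION_PARAMS:
            raise ConfigError(f"unknown reaction {reaction!r}")
        allowed = _REACTION_PARAMS[reaction]
        rates[reaction] = {}
        for pname, pval in params.items():
            if pname not in allowed:
                raise ConfigError(f"unknown parameter {reaction}.{pname}")
            val = parse_quantity(pval)
            if val < 0:
                raise ConfigError(f"negative rate constant {reaction}.{pname}")
            rates[reaction][pname] = val
    missing = set(_REACTION_PARAMS) - set(rates)
    if missing:
        raise ConfigError(f"missing reactions: {sorted(missing)}")

    protocols = copy.deepcopy(raw.get("protocols", {}))
    return ModelConfig(compartments=comps, initial=init, rates=rates,
                       protocols=protocols)


def load_config(path) -> ModelConfig:
    """Load and normalise a model configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _normalise(raw)


def default_config() -> ModelConfig:
    """The packaged default model (reproduces the published parameter tables)."""
    ref = importlib.resources.files("ironblock.data").joinpath("defaults.yaml")
    raw = yaml.safe_load(ref.read_text())
    return _normalise(raw)
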