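"""Model constants and configuration loading.

Every tunable constant of the model lives here with its built-in default.
A YAML or JSON file may override any subset using dotted sections, e.g.::

    consanguinity:
      e_nocare: 25
    folate:
      k_dose: 1.5

Precedence: CLI flag > config file > built-in default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InputError


@dataclass
class AccessConfig:
    """Smooth IMR→access curve calibration window and anchors.

    ``m_lo``/``m_hi`` are the infant mortality rates (per 1000 livebirths)
    at which access clamps to 1 and 0; anchors are (IMR, access) points at
    the midpoints of the interior stepped bands.
    """

    m_lo: float = 9.0
    m_hi: float = 100.0
    anchors: list = field(
        default_factory=lambda: [(17.0, 0.50), (39.5, 0.15), (77.0, 0.05)]
    )
    anchor_tol: float = 0.05


@dataclass
class ConsanguinityConfig:
    """Excess infant mortality attributable to consanguinity.

    ``e_nocare`` is the excess infant deaths per 1000 livebirths at the
    first-cousin reference coefficient (0.0625) with no access to care;
    ``rho`` the fraction of those deaths avertable under optimal care.
    """

    f_ref: float = 0.0625
    e_nocare: float = 30.0
    rho: float = 0.8
    n_iter: int = 2
    imr_floor: float = 1.0


@dataclass
class FolateConfig:
    """Folic-acid fortification constants (rates per 1000 births)."""

    sb_anenc_floor: float = 0.7
    enceph_share: float = 0.115
    total_floor: float = 0.77
    k_dose: float = 1.65
    ofc_max_effect: float = 0.05
    chd_max_effect: float = 0.05
    #: optional list of (ppm, residual-ratio) pairs; piecewise-linear when set
    dose_response_table: list | None = None


@dataclass
class ReproductiveConfig:
    p_affected: float = 0.25
    healthy_target: int = 2  # prospective couples stop at this many healthy children


@dataclass
class TopConfig:
    restricted_multiplier: float = 0.5
    restricted_conditions: list = field(
        default_factory=lambda: ["down_syndrome", "spina_bifida"]
    )


@dataclass
class AntiDConfig:
    efficacy: float = 1.0


@dataclass
class ModelConfig:
    access: AccessConfig = field(default_factory=AccessConfig)
    consanguinity: ConsanguinityConfig = field(default_factory=ConsanguinityConfig)
    folate: FolateConfig = field(default_factory=FolateConfig)
    reproductive: ReproductiveConfig = field(default_factory=ReproductiveConfig)
    top: TopConfig = field(default_factory=TopConfig)
    antid: AntiDConfig = field(default_factory=AntiDConfig)


def _apply_overrides(cfg: ModelConfig, data: dict) -> ModelConfig:
    for section, values in data.items():
        if not hasattr(cfg, section):
            raise InputError(f"unknown config section: {section!r}")
        sub = getattr(cfg, section)
        if not isinstance(values, dict):
            raise InputError(f"config section {section!r} must be a mapping")
        for key, val in values.items():
            if not any(f.name == key for f in dataclasses.fields(sub)):
                raise InputError(f"unknown config key: {section}.{key}")
            setattr(sub, key, val)
    return cfg


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Return the built-in defaults, overlaid with a YAML/JSON file if given."""
    cfg = ModelConfig()
    if path is None:
        return cfg
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return cfg
    if not isinstance(data, dict):
        raise InputError(f"config file {path} must contain a mapping")
    return _apply_overrides(cfg, data)
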