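"""Scenario configuration: YAML loading, unit handling, validation.

Human-authored configs use YAML with explicit unit suffixes at the boundary
(µm, kΩ, pF, ...); everything is converted to SI on load.  Machine outputs
are JSON.  A scenario bundles the coupling network, the recording setup, the
probe geometry, the stage list and the simulation parameters; anything
omitted falls back to the packaged reference-experiment fixture.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import yaml

from . import constants as C
from .coupling import CouplingNetwork, ShieldCoupling
from .impedance import ComplexImpedance, impedance_from_spec
from .interference import MatchingScheme, shared_cm_impedance
from .signal_path import RecordingSetup
from .simulate import (
    MAINS_HZ,
    SpikeUnit,
    StageConfig,
    default_coupling_network,
    default_spike_units,
    default_stage_fixture,
)
from .volume_conductor import ElectrodeSite

__all__ = ["ScenarioConfig", "load_scenario", "load_probe_geometry", "parse_quantity", "config_hash"]

_UNIT_SCALE = {
    "": 1.0,
    "ohm": 1.0, "kohm": 1e3, "mohm": 1e6, "gohm": 1e9,
    "f": 1.0, "pf": 1e-12, "nf": 1e-9, "uf": 1e-6,
    "v": 1.0, "mv": 1e-3, "uv": 1e-6,
    "a": 1.0, "ma": 1e-3, "ua": 1e-6, "na": 1e-9,
    "m": 1.0, "mm": 1e-3, "um": 1e-6,
    "hz": 1.0, "khz": 1e3,
    "s": 1.0, "ms": 1e-3,
}
_QUANT_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµμ]*)\s*$")


def parse_quantity(value: Any) -> float:
    """Parse ``6.95e5``, ``"695 kohm"``, ``"21 pF"``, ``"30 um"`` ... to SI floats."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _QUANT_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num, unit = m.groups()
    unit = unit.replace("µ", "u").replace("μ", "u").lower()
    unit = {"ω": "ohm"}.get(unit, unit)
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return float(num) * _UNIT_SCALE[unit]


@dataclass
class ScenarioConfig:
    """Everything needed to run a simulation or a stage sweep."""

    coupling: CouplingNetwork
    stages: list[StageConfig]
    units: list[SpikeUnit]
    sites: Optional[list[ElectrodeSite]]
    duration_s: float = 8.0
    fs: float = 32_000.0
    seed: int = 0
    lfp_rms_v: float = 100e-6
    n_channels: int = 1
    calibrate_to_stage1: bool = True
    raw: dict = field(default_factory=dict)


def load_probe_geometry(path_or_dict) -> list[ElectrodeSite]:
    """Probe geometry from YAML/JSON: sites with id, role, x/y/z in µm."""
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
    else:
        with open(path_or_dict) as fh:
            doc = yaml.safe_load(fh)
    sites = []
    for entry in doc["sites"]:
        pos = tuple(parse_quantity(entry[k]) * (1e-6 if isinstance(entry[k], (int, float)) else 1.0)
                    for k in ("x", "y", "z"))
        sites.append(ElectrodeSite(str(entry["id"]), pos, entry["role"]))
    return sites


def _coupling_from_dict(d: dict) -> CouplingNetwork:
    shield = None
    if "shield" in d:
        s = d["shield"]
        shield = ShieldCoupling(
            C_IS=parse_quantity(s["C_IS"]),
            C_SB=parse_quantity(s["C_SB"]),
            Z_SE=complex(parse_quantity(s["Z_SE"])),
        )
    return CouplingNetwork(
        V_IE=complex(parse_quantity(d.get("V_IE", 230.0))),
        frequency=parse_quantity(d.get("frequency", MAINS_HZ)),
        Z_IE=complex(parse_quantity(d.get("Z_IE", 1e6))),
        Z_B=complex(parse_quantity(d.get("Z_B", 500.0))),
        C_BE=parse_quantity(d.get("C_BE", 100e-12)),
        C_IB=parse_quantity(d.get("C_IB", 1e-12)),
        C_HE=parse_quantity(d.get("C_HE", 10e-12)),
        Z_IG_star=complex(parse_quantity(d.get("Z_IG_star", 10e3))),
        shield=shield,
    )


def _stage_from_dict(d: dict) -> StageConfig:
    def imp_pair(key: str) -> dict[float, ComplexImpedance]:
        spec = d[key]
        return {
            MAINS_HZ: impedance_from_spec({**spec["50"], "freq": MAINS_HZ}),
            1000.0: impedance_from_spec({**spec["1000"], "freq": 1000.0}),
        }

    return StageConfig(
        stage=int(d["stage"]),
        description=str(d.get("description", "")),
        n_reference=int(d.get("n_reference", 0)),
        n_ground=int(d.get("n_ground", 0)),
        Z_ref_parallel=imp_pair("Z_ref_parallel"),
        Z_gnd_parallel=imp_pair("Z_gnd_parallel"),
        Z_SG_eff=imp_pair("Z_SG_eff"),
        Z_RG_eff=imp_pair("Z_RG_eff"),
        f_SG=float(d.get("f_SG", 0.25)),
        f_RG=float(d.get("f_RG", 0.20)),
    )


def load_scenario(path: Optional[str] = None, *, seed: Optional[int] = None) -> ScenarioConfig:
    """Load a scenario YAML; with no path, the packaged reference fixture.

    ``seed`` overrides the file's seed when given.
    """
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}

    coupling = _coupling_from_dict(doc.get("coupling", {}))
    if "stages" in doc:
        stages = [_stage_from_dict(s) for s in doc["stages"]]
    else:
        stages = default_stage_fixture()
    if "spike_units" in doc:
        units = [
            SpikeUnit(
                name=str(u["name"]),
                pp_mean_v=parse_quantity(u["pp_mean"]),
                pp_sd_v=parse_quantity(u.get("pp_sd", 0.0)),
                rate_hz=parse_quantity(u.get("rate", 5.0)),
            )
            for u in doc["spike_units"]
        ]
    else:
        units = list(default_spike_units())
    sites = load_probe_geometry(doc["probe"]) if "probe" in doc else None
    sim = doc.get("simulation", {})
    cfg = ScenarioConfig(
        coupling=coupling,
        stages=stages,
        units=units,
        sites=sites,
        duration_s=parse_quantity(sim.get("duration", 8.0)),
        fs=parse_quantity(sim.get("fs", 32_000.0)),
        seed=int(sim.get("seed", 0)),
        lfp_rms_v=parse_quantity(sim.get("lfp_rms", 100e-6)),
        n_channels=int(sim.get("n_channels", 1)),
        calibrate_to_stage1=bool(sim.get("calibrate_to_stage1", True)),
        raw=doc,
    )
    if seed is not None:
        cfg.seed = seed
    return cfg


def config_hash(cfg: ScenarioConfig) -> str:
    """Short stable hash of the raw config document plus the effective seed."""
    payload = json.dumps({"raw": cfg.raw, "seed": cfg.seed}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
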