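"""YAML run configuration: schema validation, defaults, hashing.

A run config bundles the design(s), material/loading protocol, fluid,
surrogate and stimulus constants, and the sweep block.  Unknown keys are
rejected so typos fail loudly; a seed is mandatory whenever a stochastic
stage (field generation, sweep) is configured.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .geometry import ScaffoldSpec
from .mechanics import LoadingProtocol, OgdenParams
from .mechanoreg import StimulusConstants
from .synthetic_fields import FluidProperties, SurrogateParams

__all__ = ["RunConfig", "ConfigError", "read_config", "write_config", "spec_from_dict"]


class ConfigError(ValueError):
    pass


_DESIGN_KEYS = {
    "name", "D_scaffold_mm", "H_scaffold_mm", "D_strand_um",
    "N_H", "N_V", "Y_mm", "h_mm",
}
_MATERIAL_KEYS = {"mu_kpa", "alpha", "d"}
_PROTOCOL_KEYS = {"frequency_hz", "amplitude_fraction", "timestep_s"}
_FLUID_KEYS = {"density_kg_m3", "dynamic_viscosity_pa_s"}
_SURROGATE_KEYS = {
    "strain_transfer", "junction_amplification", "wss_gain_mpa",
    "vel_exponent", "pore_exponent", "atten_scale_mm", "sigma", "n_nodes",
}
_STIMULUS_KEYS = {"a", "b_mpa"}
_SWEEP_KEYS = {
    "base", "nh_range", "nv_set", "reference", "criterion", "stop_threshold",
}
_TOP_KEYS = {
    "designs", "material", "protocol", "fluid", "surrogate", "stimulus",
    "sweep", "seed", "output_dir", "voxel_resolution_mm",
}


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def spec_from_dict(block: dict) -> ScaffoldSpec:
    _reject_unknown(block, _DESIGN_KEYS, f"design {block.get('name', '?')!r}")
    if "name" not in block:
        raise ConfigError("every design needs a name")
    return ScaffoldSpec(
        name=block["name"],
        D_scaffold=float(block.get("D_scaffold_mm", 10.0)),
        H_scaffold=float(block.get("H_scaffold_mm", 4.8)),
        D_strand=float(block.get("D_strand_um", 700.0)) / 1000.0,
        N_H=int(block.get("N_H", 7)),
        N_V=int(block.get("N_V", 9)),
        Y=float(block["Y_mm"]) if "Y_mm" in block else None,
        h=float(block["h_mm"]) if "h_mm" in block else None,
    )


@dataclass(frozen=True)
class RunConfig:
    designs: tuple[ScaffoldSpec, ...]
    material: OgdenParams = OgdenParams()
    protocol: LoadingProtocol = LoadingProtocol()
    fluid: FluidProperties = FluidProperties()
    surrogate: SurrogateParams = SurrogateParams()
    stimulus: StimulusConstants = StimulusConstants()
    n_nodes: int = 10_000
    voxel_resolution_mm: float = 0.025
    seed: int = 0
    output_dir: str = "."
    sweep: dict = field(default_factory=dict)

    def digest(self) -> str:
        """Stable hash of the full configuration, embedded in outputs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "designs": [
                {
                    "name": d.name,
                    "D_scaffold_mm": d.D_scaffold,
                    "H_scaffold_mm": d.H_scaffold,
                    "D_strand_um": d.D_strand * 1000.0,
                    "N_H": d.N_H,
                    "N_V": d.N_V,
                    "Y_mm": d.Y,
                    "h_mm": d.h,
                }
                for d in self.designs
            ],
            "material": {
                "mu_kpa": [t[0] for t in self.material.terms],
                "alpha": [t[1] for t in self.material.terms],
                "d": [t[2] for t in self.material.terms],
            },
            "protocol": {
                "frequency_hz": self.protocol.frequency,
                "amplitude_fraction": self.protocol.amplitude_fraction,
                "timestep_s": self.protocol.timestep,
            },
            "fluid": {
                "density_kg_m3": self.fluid.density,
                "dynamic_viscosity_pa_s": self.fluid.dynamic_viscosity,
            },
            "surrogate": {
                "strain_transfer": self.surrogate.strain_transfer,
                "junction_amplification": self.surrogate.junction_amplification,
                "wss_gain_mpa": self.surrogate.wss_gain_mpa,
                "vel_exponent": self.surrogate.vel_exponent,
                "pore_exponent": self.surrogate.pore_exponent,
                "atten_scale_mm": self.surrogate.atten_scale_mm,
                "sigma": self.surrogate.sigma,
                "n_nodes": self.n_nodes,
            },
            "stimulus": {"a": self.stimulus.a, "b_mpa": self.stimulus.b},
            "sweep": self.sweep,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "voxel_resolution_mm": self.voxel_resolution_mm,
        }


def read_config(path: str) -> RunConfig:
    """Load and validate a YAML run configuration, filling defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config root")
    designs_raw = raw.get("designs")
    if not designs_raw:
        raise ConfigError("config must list at least one design")
    designs = tuple(spec_from_dict(d) for d in designs_raw)

    mat = raw.get("material", {})
    _reject_unknown(mat, _MATERIAL_KEYS, "material")
    mus = mat.get("mu_kpa", [-5.8])
    alphas = mat.get("alpha", [-1.3])
    ds = mat.get("d", [0.0] * len(mus))
    if not (len(mus) == len(alphas) == len(ds)):
        raise ConfigError("material term lists must have equal length")
    material = OgdenParams(terms=tuple(zip(map(float, mus),
                                           map(float, alphas),
                                           map(float, ds))))

    proto = raw.get("protocol", {})
    _reject_unknown(proto, _PROTOCOL_KEYS, "protocol")
    protocol = LoadingProtocol(
        frequency=float(proto.get("frequency_hz", 1.0)),
        amplitude_fraction=float(proto.get("amplitude_fraction", 0.05)),
        scaffold_height=designs[0].H_scaffold,
        timestep=float(proto.get("timestep_s", 0.01)),
    )

    fl = raw.get("fluid", {})
    _reject_unknown(fl, _FLUID_KEYS, "fluid")
    fluid = FluidProperties(
        density=float(fl.get("density_kg_m3", 1000.0)),
        dynamic_viscosity=float(fl.get("dynamic_viscosity_pa_s", 1.45e-3)),
    )

    sur = dict(raw.get("surrogate", {}))
    _reject_unknown(sur, _SURROGATE_KEYS, "surrogate")
    n_nodes = int(sur.pop("n_nodes", 10_000))
    seed = raw.get("seed")
    if seed is None and (raw.get("surrogate") is not None or raw.get("sweep")):
        raise ConfigError("a seed is mandatory for stochastic stages")
    seed = int(seed or 0)
    surrogate = SurrogateParams(**{k: float(v) for k, v in sur.items()}, seed=seed)

    stim = raw.get("stimulus", {})
    _reject_unknown(stim, _STIMULUS_KEYS, "stimulus")
    constants = StimulusConstants(
        a=float(stim.get("a", 0.0375)), b=float(stim.get("b_mpa", 10.0))
    )

    sweep = raw.get("sweep", {}) or {}
    _reject_unknown(sweep, _SWEEP_KEYS, "sweep")

    return RunConfig(
        designs=designs,
        material=material,
        protocol=protocol,
        fluid=fluid,
        surrogate=surrogate,
        stimulus=constants,
        n_nodes=n_nodes,
        voxel_resolution_mm=float(raw.get("voxel_resolution_mm", 0.025)),
        seed=seed,
        output_dir=str(raw.get("output_dir", ".")),
        sweep=sweep,
    )


def write_config(config: RunConfig, path: str) -> str:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return str(path)
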