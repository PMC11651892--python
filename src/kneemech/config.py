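"""Structured run configuration (YAML) binding the pipeline together.

The configuration mirrors the model blocks: geometry, elastic-foundation
law, ligaments, muscles, solver, gait and experiment.  Keys carry explicit
units in their names; unknown keys are rejected before any computation;
omitted blocks fall back to the documented defaults (the shipped knee
model and the default walking cycle).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .contact import EfLaw
from .gait import GaitParams
from .geometry import (
    InlaySpec,
    make_femoral_component,
    make_patellar_button,
    make_tibial_inlay,
)
from .ligaments import CONFORMITIES, PRESTRAIN_DELTAS, LigamentBundle
from .model import KneeModel, SolverSettings
from .muscles import MuscleActuator, default_muscles
from .pathgeom import WrapCylinder


class ConfigError(ValueError):
    pass


@dataclass
class GeometryConfig:
    mesh_resolution_mm: float = 1.5
    inlay: dict = field(default_factory=dict)          # InlaySpec overrides
    femoral: dict = field(default_factory=dict)        # make_femoral_component kwargs
    button_radius_mm: float = 13.0
    button_thickness_mm: float = 8.0


@dataclass
class ExperimentConfig:
    deltas: list = field(default_factory=lambda: list(PRESTRAIN_DELTAS))
    conformities: list = field(default_factory=lambda: list(CONFORMITIES))
    reference_medial_share: float = 0.6
    reference_noise_bw: float = 0.02


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    ef_law: EfLaw = field(default_factory=EfLaw)
    solver: SolverSettings = field(default_factory=SolverSettings)
    gait: GaitParams = field(default_factory=GaitParams)
    seed: int = 0
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    ligaments: list | None = None   # full bundle dicts; None -> defaults
    muscles: list | None = None     # full actuator dicts; None -> defaults
    output_dir: str = "kneemech_out"

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "geometry": asdict(self.geometry),
            "ef_law": asdict(self.ef_law),
            "solver": asdict(self.solver),
            "gait": asdict(self.gait),
            "seed": self.seed,
            "experiment": asdict(self.experiment),
            "ligaments": self.ligaments,
            "muscles": self.muscles,
            "output_dir": self.output_dir,
        }
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build_dataclass(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults when omitted)."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    cfg = RunConfig()
    if "geometry" in raw:
        cfg.geometry = _build_dataclass(GeometryConfig, raw["geometry"], "geometry")
        if cfg.geometry.inlay:
            _build_dataclass(InlaySpec, dict(cfg.geometry.inlay), "geometry.inlay")
    if "ef_law" in raw:
        cfg.ef_law = _build_dataclass(EfLaw, raw["ef_law"], "ef_law")
    if "solver" in raw:
        cfg.solver = _build_dataclass(SolverSettings, raw["solver"], "solver")
    if "gait" in raw:
        cfg.gait = _build_dataclass(GaitParams, raw["gait"], "gait")
    if "experiment" in raw:
        cfg.experiment = _build_dataclass(
            ExperimentConfig, raw["experiment"], "experiment"
        )
    cfg.seed = int(raw.get("seed", 0))
    cfg.ligaments = raw.get("ligaments")
    cfg.muscles = raw.get("muscles")
    cfg.output_dir = raw.get("output_dir", "kneemech_out")
    return cfg


def _ligaments_from_config(entries: list) -> list[LigamentBundle]:
    out = []
    for e in entries:
        out.append(
            LigamentBundle(
                name=e["name"],
                proximal_points=np.asarray(e["proximal_points_mm"]),
                distal_points=np.asarray(e["distal_points_mm"]),
                stiffness_n_per_mm=float(e["stiffness_n_per_mm"]),
                reference_strain=float(e["reference_strain"]),
                transition_strain=float(e.get("transition_strain", 0.03)),
                proximal_body=e.get("proximal_body", "femur"),
                distal_body=e.get("distal_body", "tibia"),
            )
        )
    return out


def _muscles_from_config(entries: list) -> list[MuscleActuator]:
    out = []
    wrap_cache: dict = {}
    for e in entries:
        wrap = None
        if e.get("wrap"):
            key = json.dumps(e["wrap"], sort_keys=True)
            if key not in wrap_cache:
                w = e["wrap"]
                wrap_cache[key] = WrapCylinder(
                    point=np.asarray(w["point_mm"]),
                    axis=np.asarray(w["axis"]),
                    radius=float(w["radius_mm"]),
                    body=w.get("body", "femur"),
                )
            wrap = wrap_cache[key]
        out.append(
            MuscleActuator(
                e["name"],
                [(b, np.asarray(p)) for b, p in e["path"]],
                float(e["max_isometric_force_n"]),
                wrap=wrap,
            )
        )
    return out


def build_model(cfg: RunConfig, conformity: str = "standard") -> KneeModel:
    """Assemble (and reference-calibrate) a knee model from a configuration."""
    from .ligaments import default_ligaments

    g = cfg.geometry
    inlay_kwargs = dict(g.inlay)
    inlay_kwargs.setdefault("mesh_resolution_mm", g.mesh_resolution_mm)
    spec = InlaySpec(**inlay_kwargs)
    if conformity == "low":
        spec = spec.low_conformity()
    elif conformity != "standard":
        raise ConfigError("conformity must be 'standard' or 'low'")
    femoral_kwargs = dict(g.femoral)
    femoral_kwargs.setdefault("resolution", g.mesh_resolution_mm)
    ligaments = (
        _ligaments_from_config(cfg.ligaments)
        if cfg.ligaments is not None
        else default_ligaments()
    )
    muscles = (
        _muscles_from_config(cfg.muscles)
        if cfg.muscles is not None
        else default_muscles()
    )
    model = KneeModel(
        femur=make_femoral_component(**femoral_kwargs),
        inlay=make_tibial_inlay(spec),
        button=make_patellar_button(
            g.button_radius_mm, g.button_thickness_mm, g.mesh_resolution_mm
        ),
        ligaments=ligaments,
        muscles=muscles,
        ef_law=cfg.ef_law,
        settings=cfg.solver,
        inlay_spec=spec,
        conformity=conformity,
    )
    model.assemble_reference()
    return model
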