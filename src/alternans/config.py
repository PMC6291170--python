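"""Experiment configuration: one round-trippable mapping with dotted-key
overrides and a content hash that stamps every output artifact."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import yaml

from .errors import ConfigError
from .ionic_models import CellModel, luo_rudy_1991
from .protocols import StimulusTrain, supra_threshold_amplitude
from .tissue_solver import Geometry, assign_dead_cells, build_geometry

__all__ = ["ExperimentConfig", "config_hash", "build_model", "build_geom",
           "build_train"]


def _default_model() -> dict:
    return {"name": "lr91", "s_gna": 1.0, "delta_tau_h_ms": 30.0,
            "v_mod_threshold_mv": -70.0}


def _default_geometry() -> dict:
    return {"kind": "strand", "n_nodes": 800, "shape": [800, 800],
            "dx_mm": 0.15, "d_par": 0.15, "d_perp": None,
            "anisotropic": False, "fibers": "uniform",
            "dead_fraction": 0.0}


def _default_protocol() -> dict:
    return {"name": "steady_state", "pcl_ms": 800.0, "n_beats": 20,
            "s1_pcl_ms": 800.0, "di_list_ms": None, "resolution_ms": 1.0,
            "stimulus_extent_nodes": 5, "pulse_duration_ms": 2.0,
            "amplitude": None}


def _default_numerics() -> dict:
    return {"dt_ms": 0.005, "dt_save_ms": 5.0}


def _default_analysis() -> dict:
    return {"epsilon_ms": 1.0, "dvdt_threshold": 10.0, "cv_nodes": [25, 75],
            "transient_beats": 5, "distal_margin_nodes": 25}


@dataclass
class ExperimentConfig:
    """Serialisable description of one simulation + analysis run."""

    model: dict = field(default_factory=_default_model)
    geometry: dict = field(default_factory=_default_geometry)
    protocol: dict = field(default_factory=_default_protocol)
    numerics: dict = field(default_factory=_default_numerics)
    analysis: dict = field(default_factory=_default_analysis)
    seed: int = 0
    outdir: str = "out"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        base = cls()
        for block in ("model", "geometry", "protocol", "numerics", "analysis"):
            if block in d:
                unknown = set(d[block]) - set(getattr(base, block))
                if unknown:
                    raise ConfigError(f"unknown {block} keys: {sorted(unknown)}")
                getattr(base, block).update(d[block])
        base.seed = int(d.get("seed", base.seed))
        base.outdir = str(d.get("outdir", base.outdir))
        return base

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def apply_overrides(self, overrides: Sequence[str]) -> "ExperimentConfig":
        """Apply 'block.key=value' strings (values parsed as YAML)."""
        for item in overrides:
            if "=" not in item:
                raise ConfigError(f"override '{item}' is not key=value")
            key, raw = item.split("=", 1)
            parts = key.strip().split(".")
            target = self.to_dict()
            node = target
            for p in parts[:-1]:
                if p not in node or not isinstance(node[p], dict):
                    raise ConfigError(f"unknown config path '{key}'")
                node = node[p]
            if parts[-1] not in node:
                raise ConfigError(f"unknown config key '{key}'")
            node[parts[-1]] = yaml.safe_load(raw)
            new = ExperimentConfig.from_dict(target)
            self.__dict__.update(new.__dict__)
        return self

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(d: dict) -> str:
    """Short stable content hash of a configuration mapping."""
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_model(cfg: ExperimentConfig) -> CellModel:
    m = cfg.model
    if m["name"] == "lr91":
        return luo_rudy_1991(
            s_gna=float(m.get("s_gna", 1.0)),
            delta_tau_h=float(m.get("delta_tau_h_ms", 30.0)),
            v_mod_threshold=float(m.get("v_mod_threshold_mv", -70.0)),
        )
    if m["name"].startswith("minimal3v"):
        from .synthetic_data import minimal_pde_cell

        preset = m["name"].split("_", 1)[1] if "_" in m["name"] else "steep"
        return minimal_pde_cell(
            preset,
            s_gna=float(m.get("s_gna", 1.0)),
            delta_tau_v=float(m.get("delta_tau_h_ms", 0.0)),
            v_mod_threshold=float(m.get("v_mod_threshold_mv", -70.0)),
        )
    raise ConfigError(f"unknown model '{m['name']}'")


def build_geom(cfg: ExperimentConfig) -> Geometry:
    gset = cfg.geometry
    g = build_geometry(
        kind=gset["kind"],
        n_nodes=int(gset.get("n_nodes", 800)),
        shape=tuple(gset.get("shape", (800, 800))),
        dx=float(gset.get("dx_mm", 0.15)),
        d_par=float(gset.get("d_par", 0.15)),
        d_perp=gset.get("d_perp"),
        anisotropic=bool(gset.get("anisotropic", False)),
        fibers=gset.get("fibers", "uniform"),
    )
    frac = float(gset.get("dead_fraction", 0.0) or 0.0)
    if frac > 0:
        g = assign_dead_cells(g, frac, cfg.seed)
    return g


def build_train(cfg: ExperimentConfig, model: CellModel,
                geometry: Optional[Geometry] = None) -> StimulusTrain:
    p = cfg.protocol
    amp = p.get("amplitude")
    if amp is None:
        amp = supra_threshold_amplitude(model, dt=float(cfg.numerics["dt_ms"]))
    site = None
    if geometry is not None and geometry.ndim == 2:
        from .protocols import place_stimulus

        site = place_stimulus(geometry, "sheet_corner",
                              int(p["stimulus_extent_nodes"]))
    return StimulusTrain(
        amplitude=float(amp),
        pulse_duration=float(p["pulse_duration_ms"]),
        pcl=float(p["pcl_ms"]),
        count=int(p["n_beats"]),
        extent=int(p["stimulus_extent_nodes"]),
        site=site,
    )
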