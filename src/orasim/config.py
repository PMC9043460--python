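"""Run configuration: one YAML file with a block per pipeline stage.

Unknown keys are rejected so that every physical default stays auditable;
a loaded configuration round-trips through ``dump_config`` byte-for-byte
at the dataclass level.  ``config_hash`` fingerprints the canonical dump
for run logging.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field

import yaml

from .mechanics import AirPuff, MaterialModel
from .optics import OpticalConfig
from .pipeline import SimulationConfig

__all__ = ["GeometryBlock", "SweepBlock", "IOBlock", "RunConfig",
           "load_config", "dump_config", "config_hash", "setup_logging"]


@dataclass(frozen=True)
class GeometryBlock:
    R_mm: float = 7.0
    CCT_um: float = 550.0
    p: float = 1.0
    x_limbus_mm: float = 5.5
    pct_offset_um: float = 100.0


@dataclass(frozen=True)
class MaterialBlock:
    E_MPa: float = 0.4
    nu: float = 0.49
    a1: float = 0.4
    a2: float = 0.1
    a3: float = 0.1
    tau1_s: float = 0.0031623     # lg(tau1/1 ms) = -2.5, the sweep midpoint
    tau2_s: float = 1.0e-4
    tau3_s: float = 1.0e-4
    rho_kg_m3: float = 1062.0

    def to_material(self) -> MaterialModel:
        return MaterialModel(**dataclasses.asdict(self))


@dataclass(frozen=True)
class SolverBlock:
    n_radial: int = 40
    n_thickness: int = 4
    output_frames: int = 251
    dt_safety: float = 0.8
    hourglass: float = 0.05
    static_tol: float = 1.0e-6
    unloaded_tol_mm: float = 1.0e-3
    unloaded_max_iter: int = 20
    width_scale_per_ms: float = 16.0


@dataclass(frozen=True)
class SweepBlock:
    R_mm: tuple = (6.0, 8.0)
    CCT_um: tuple = (450.0, 650.0)
    IOP_mmHg: tuple = (10.0, 30.0)
    E_MPa: tuple = (0.2, 0.6)
    a1: tuple = (0.25, 0.6)
    tau1_s: tuple = (0.001, 0.1)
    n_samples: int = 2000
    split: float = 0.7


@dataclass(frozen=True)
class IOBlock:
    outdir: str = "orasim_out"
    log_file: str = "orasim_run.log"


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometryBlock = field(default_factory=GeometryBlock)
    material: MaterialBlock = field(default_factory=MaterialBlock)
    puff: AirPuff = field(default_factory=AirPuff)
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    solver: SolverBlock = field(default_factory=SolverBlock)
    sweep: SweepBlock = field(default_factory=SweepBlock)
    io: IOBlock = field(default_factory=IOBlock)
    iop_mmHg: float = 20.0
    seed: int = 1
    verbosity: int = 1

    def simulation_config(self) -> SimulationConfig:
        s, g, m = self.solver, self.geometry, self.material
        return SimulationConfig(
            p=g.p, x_limbus_mm=g.x_limbus_mm, pct_offset_um=g.pct_offset_um,
            n_radial=s.n_radial, n_thickness=s.n_thickness,
            nu=m.nu, a2=m.a2, a3=m.a3, tau2_s=m.tau2_s, tau3_s=m.tau3_s,
            rho_kg_m3=m.rho_kg_m3, puff=self.puff, optics=self.optics,
            output_frames=s.output_frames, dt_safety=s.dt_safety,
            hourglass=s.hourglass, static_tol=s.static_tol,
            unloaded_tol_mm=s.unloaded_tol_mm,
            unloaded_max_iter=s.unloaded_max_iter,
            width_scale_per_ms=s.width_scale_per_ms)


_BLOCK_TYPES = {
    "geometry": GeometryBlock,
    "material": MaterialBlock,
    "puff": AirPuff,
    "optics": OpticalConfig,
    "solver": SolverBlock,
    "sweep": SweepBlock,
    "io": IOBlock,
}


def _build(cls, data: dict, where: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config block {where!r}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    top_scalars = {"iop_mmHg", "seed", "verbosity"}
    unknown = set(raw) - set(_BLOCK_TYPES) - top_scalars
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _BLOCK_TYPES.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    for name in top_scalars:
        if name in raw:
            kwargs[name] = raw[name]
    return RunConfig(**kwargs)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig, path=None) -> str:
    text = yaml.safe_dump(_as_plain(cfg), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:16]


def setup_logging(cfg: RunConfig, log_path=None) -> logging.Logger:
    """Per-run logger recording seed and config hash (no wall-clock stamps,
    so demo outputs stay byte-reproducible)."""
    logger = logging.getLogger("orasim")
    logger.setLevel(logging.DEBUG if cfg.verbosity > 1 else logging.INFO)
    for handler in list(logger.handlers):
        logger.removeHandler(handler)
        handler.close()
    if log_path is not None:
        handler = logging.FileHandler(log_path, mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.info("config_hash=%s seed=%d", config_hash(cfg), cfg.seed)
    return logger
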