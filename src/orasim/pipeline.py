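"""End-to-end forward simulation of one ORA measurement.

Chains geometry construction, the stress-free pull-back, the explicit
air-puff transient, ray tracing and feature extraction for a single set of
clinical inputs.  ``SimulationConfig`` bundles every numerical knob so
sweeps can be scaled down (coarser mesh, fewer frames/rays) for desk use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .features import DEFAULT_WIDTH_SCALE_PER_MS, OraFeatures, extract_features
from .geometry import CorneaGeometry, build_mesh, solve_unloaded_config
from .mechanics import AirPuff, MaterialModel, simulate_airpuff
from .optics import OpticalConfig, applanation_curve

__all__ = ["SimulationConfig", "simulate_ora"]


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical configuration of the forward pipeline."""

    p: float = 1.0
    x_limbus_mm: float = 5.5
    pct_offset_um: float = 100.0
    n_radial: int = 40
    n_thickness: int = 4
    nu: float = 0.49
    a2: float = 0.1
    a3: float = 0.1
    tau2_s: float = 1.0e-4
    tau3_s: float = 1.0e-4
    rho_kg_m3: float = 1062.0
    puff: AirPuff = field(default_factory=AirPuff)
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    output_frames: int = 251
    dt_safety: float = 0.8
    hourglass: float = 0.05
    static_tol: float = 1e-6
    unloaded_tol_mm: float = 1e-3
    unloaded_max_iter: int = 20
    width_scale_per_ms: float = DEFAULT_WIDTH_SCALE_PER_MS

    def coarse(self, n_radial: int = 24, n_thickness: int = 3,
               output_frames: int = 151, n_rays: int = 1200) -> "SimulationConfig":
        """A scaled-down copy for sweeps and smoke runs."""
        return replace(self, n_radial=n_radial, n_thickness=n_thickness,
                       output_frames=output_frames,
                       optics=replace(self.optics, n_rays=n_rays))


def simulate_ora(
    R_mm: float,
    CCT_um: float,
    IOP_mmHg: float,
    E_MPa: float,
    a1: float,
    tau1_s: float,
    config: SimulationConfig | None = None,
    return_intermediates: bool = False,
):
    """ORA output parameters for one set of clinical/biomechanical inputs.

    Returns the :class:`~orasim.features.OraFeatures`; with
    ``return_intermediates`` also the deformation history and applanation
    curve.
    """
    cfg = config or SimulationConfig()
    geom = CorneaGeometry(R_mm=R_mm, CCT_um=CCT_um, p=cfg.p,
                          x_limbus_mm=cfg.x_limbus_mm,
                          pct_offset_um=cfg.pct_offset_um)
    mesh = build_mesh(geom, cfg.n_radial, cfg.n_thickness)
    material = MaterialModel(E_MPa=E_MPa, nu=cfg.nu,
                             a1=a1, a2=cfg.a2, a3=cfg.a3,
                             tau1_s=tau1_s, tau2_s=cfg.tau2_s,
                             tau3_s=cfg.tau3_s, rho_kg_m3=cfg.rho_kg_m3)
    unloaded = solve_unloaded_config(
        mesh, material, IOP_mmHg,
        tol_mm=cfg.unloaded_tol_mm, max_iter=cfg.unloaded_max_iter,
        tol=cfg.static_tol, dt_safety=cfg.dt_safety, hourglass=cfg.hourglass)
    history = simulate_airpuff(
        unloaded, material, IOP_mmHg, cfg.puff,
        output_frames=cfg.output_frames, dt_safety=cfg.dt_safety,
        hourglass=cfg.hourglass, static_tol=cfg.static_tol)
    curve = applanation_curve(history, cfg.optics)
    feats: OraFeatures = extract_features(
        curve, history=history, puff=cfg.puff,
        width_scale_per_ms=cfg.width_scale_per_ms)
    if return_intermediates:
        return feats, history, curve
    return feats
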