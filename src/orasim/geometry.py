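"""Axisymmetric corneal geometry: elliptic surfaces, meshing, stress-free state.

The cornea is modelled as an axisymmetric solid bounded by two ellipses.
The anterior surface is

    x^2 / (R^2/p) + y^2 / (R^2/p^2) = 1,

where ``R`` is the central (apical) radius of curvature and ``p`` the ellipse
shape factor; for any ``p`` the apical curvature radius equals ``R``.  The
posterior surface is an ellipse with vertical semi-axis ``R/p - CCT`` whose
horizontal semi-axis is solved so that the surface passes through the point
``(x_limbus, y0 - PCT)``, i.e. so that the peripheral thickness at the limbus
equals ``PCT = CCT + 100 um``.

Because corneal topography is imaged at the in-vivo IOP, the meshed solid is
the *loaded* configuration.  :func:`solve_unloaded_config` recovers the
stress-free geometry by fixed-point inverse inflation ("pull-back").
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConvergenceError, GeometryError
from .units import um_to_mm

__all__ = [
    "CorneaGeometry",
    "Mesh",
    "anterior_surface",
    "posterior_surface",
    "limbus_point",
    "solve_posterior_axis",
    "build_mesh",
    "solve_unloaded_config",
]


@dataclass(frozen=True)
class CorneaGeometry:
    """Parametric description of the axisymmetric corneal solid.

    Parameters
    ----------
    R_mm : float
        Central anterior curvature radius (mm).
    CCT_um : float
        Central corneal thickness (um).
    p : float
        Ellipse shape factor of the anterior surface (1.0 = spherical cap).
    x_limbus_mm : float
        Radial (x) coordinate of the limbus (mm).  11 mm corneal diameter
        by default.
    pct_offset_um : float
        Peripheral-minus-central thickness offset (um); the peripheral
        thickness is ``PCT = CCT + pct_offset``.
    """

    R_mm: float
    CCT_um: float
    p: float = 1.0
    x_limbus_mm: float = 5.5
    pct_offset_um: float = 100.0

    def __post_init__(self):
        if self.R_mm <= 0:
            raise GeometryError("central radius R must be positive")
        if self.CCT_um <= 0:
            raise GeometryError("central thickness CCT must be positive")
        if self.p <= 0:
            raise GeometryError("shape factor p must be positive")
        if self.x_limbus_mm < 0:
            raise GeometryError("limbus coordinate must be nonnegative")
        if self.x_limbus_mm >= self.a_anterior_mm:
            raise GeometryError(
                "limbus lies beyond the horizontal extent of the anterior ellipse"
            )

    # -- derived quantities (clinical units) --------------------------------
    @property
    def CCT_mm(self) -> float:
        return um_to_mm(self.CCT_um)

    @property
    def PCT_um(self) -> float:
        """Peripheral corneal thickness (um)."""
        return self.CCT_um + self.pct_offset_um

    @property
    def PCT_mm(self) -> float:
        return um_to_mm(self.PCT_um)

    @property
    def a_anterior_mm(self) -> float:
        """Horizontal semi-axis of the anterior ellipse (mm)."""
        return self.R_mm / math.sqrt(self.p)

    @property
    def b_anterior_mm(self) -> float:
        """Vertical semi-axis of the anterior ellipse (mm): apex height."""
        return self.R_mm / self.p

    @property
    def b_posterior_mm(self) -> float:
        """Vertical semi-axis of the posterior ellipse (mm)."""
        return self.R_mm / self.p - self.CCT_mm

    @property
    def a_posterior_mm(self) -> float:
        """Horizontal semi-axis of the posterior ellipse (mm)."""
        return solve_posterior_axis(self)


def anterior_surface(geom: CorneaGeometry, x_mm):
    """Height y (mm) of the anterior surface at radial coordinate ``x_mm``.

    Accepts scalars or arrays.  Raises for points beyond the limbus.
    """
    x = np.asarray(x_mm, dtype=float)
    if np.any(np.abs(x) > geom.x_limbus_mm * (1 + 1e-12)):
        raise GeometryError("x beyond the limbus / anterior ellipse extent")
    a, b = geom.a_anterior_mm, geom.b_anterior_mm
    y = b * np.sqrt(np.maximum(1.0 - (x / a) ** 2, 0.0))
    return float(y) if np.isscalar(x_mm) else y


def posterior_surface(geom: CorneaGeometry, x_mm):
    """Height y (mm) of the posterior surface at radial coordinate ``x_mm``."""
    x = np.asarray(x_mm, dtype=float)
    a, b = geom.a_posterior_mm, geom.b_posterior_mm
    if np.any(np.abs(x) > a * (1 + 1e-12)):
        raise GeometryError("x beyond the posterior ellipse extent")
    y = b * np.sqrt(np.maximum(1.0 - (x / a) ** 2, 0.0))
    return float(y) if np.isscalar(x_mm) else y


def limbus_point(geom: CorneaGeometry) -> tuple[float, float]:
    """Anterior limbus coordinates ``(x_limbus, y0)`` in mm."""
    return geom.x_limbus_mm, anterior_surface(geom, geom.x_limbus_mm)


def solve_posterior_axis(geom: CorneaGeometry) -> float:
    """Horizontal semi-axis of the posterior ellipse (mm).

    Solved from the membership of the peripheral point
    ``(x_limbus, y0 - PCT)`` on the posterior ellipse with vertical semi-axis
    ``R/p - CCT``.
    """
    xl, y0 = limbus_point(geom)
    b = geom.b_posterior_mm
    if b <= 0:
        raise GeometryError("posterior vertical semi-axis is nonpositive")
    ylp = y0 - geom.PCT_mm
    denom = 1.0 - (ylp / b) ** 2
    if denom <= 0:
        raise GeometryError(
            "posterior ellipse infeasible: limbus point outside vertical semi-axis"
        )
    if xl == 0.0:
        # degenerate: posterior similar to anterior, zero-thickness limit
        return geom.R_mm / math.sqrt(geom.p)
    return xl / math.sqrt(denom)


@dataclass
class Mesh:
    """Structured quadrilateral mesh of the axisymmetric corneal half-section.

    Node numbering is a tensor grid: index ``j * (n_radial + 1) + i`` with
    ``i`` the radial station (0 on the symmetry axis) and ``j`` the
    through-thickness layer (0 on the posterior surface).  Elements are
    counter-clockwise quads, so Jacobians are positive for any valid
    geometry.
    """

    nodes_mm: np.ndarray          # (N, 2) radial/axial coordinates, mm
    elems: np.ndarray             # (Ne, 4) int connectivity, CCW
    anterior_nodes: np.ndarray    # node ids on the anterior surface, x ascending
    posterior_nodes: np.ndarray
    limbus_nodes: np.ndarray      # fully constrained edge
    axis_nodes: np.ndarray        # symmetry axis, radial displacement = 0
    anterior_edges: np.ndarray    # (k, 2) node pairs, x ascending
    posterior_edges: np.ndarray
    n_radial: int
    n_thickness: int

    @property
    def n_nodes(self) -> int:
        return self.nodes_mm.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elems.shape[0]

    @property
    def apex_index(self) -> int:
        """Node id of the anterior apex (on the symmetry axis)."""
        return int(self.anterior_nodes[0])

    def copy(self) -> "Mesh":
        return self.with_nodes(self.nodes_mm)

    def with_nodes(self, nodes_mm: np.ndarray) -> "Mesh":
        """Same topology with replaced coordinates."""
        return dataclasses.replace(self, nodes_mm=np.array(nodes_mm, dtype=float))

    def element_areas_mm2(self) -> np.ndarray:
        q = self.nodes_mm[self.elems]  # (Ne, 4, 2)
        x, y = q[..., 0], q[..., 1]
        return 0.5 * (
            (x[:, 2] - x[:, 0]) * (y[:, 3] - y[:, 1])
            - (x[:, 3] - x[:, 1]) * (y[:, 2] - y[:, 0])
        )

    # -- plain-text export / import ----------------------------------------
    def to_csv(self, prefix: str) -> tuple[str, str]:
        """Write ``<prefix>_nodes.csv`` and ``<prefix>_elements.csv``."""
        npath, epath = f"{prefix}_nodes.csv", f"{prefix}_elements.csv"
        hdr = "x_mm,y_mm"
        np.savetxt(npath, self.nodes_mm, delimiter=",", header=hdr, comments="")
        np.savetxt(
            epath, self.elems, delimiter=",", fmt="%d",
            header="n0,n1,n2,n3", comments="",
        )
        return npath, epath

    @classmethod
    def from_csv(cls, prefix: str, n_radial: int, n_thickness: int) -> "Mesh":
        """Rebuild a structured mesh written by :meth:`to_csv`.

        The tensor-grid numbering is implied by ``n_radial``/``n_thickness``.
        """
        nodes = np.loadtxt(f"{prefix}_nodes.csv", delimiter=",", skiprows=1)
        elems = np.loadtxt(f"{prefix}_elements.csv", delimiter=",",
                           skiprows=1, dtype=np.int64, ndmin=2)
        if nodes.shape[0] != (n_radial + 1) * (n_thickness + 1):
            raise ValueError("node count does not match the stated resolution")
        template = build_mesh(CorneaGeometry(7.0, 550.0), n_radial, n_thickness)
        if not np.array_equal(template.elems, elems):
            raise ValueError("connectivity is not the expected tensor grid")
        return template.with_nodes(nodes)


def build_mesh(geom: CorneaGeometry, n_radial: int = 40, n_thickness: int = 4) -> Mesh:
    """Structured quad mesh between the posterior and anterior ellipses.

    Radial stations are uniform in x; each station's node column is linear
    between the posterior and anterior surface heights, so the apex column
    height equals CCT and the limbus column height equals PCT exactly.
    """
    if n_radial < 8:
        raise ValueError("n_radial must be >= 8")
    if n_thickness < 2:
        raise ValueError("n_thickness must be >= 2")
    xs = np.linspace(0.0, geom.x_limbus_mm, n_radial + 1)
    ya = anterior_surface(geom, xs)
    yp = posterior_surface(geom, xs)   # raises GeometryError if infeasible
    frac = np.linspace(0.0, 1.0, n_thickness + 1)
    nodes = np.empty(((n_radial + 1) * (n_thickness + 1), 2))
    for j, f in enumerate(frac):
        rows = slice(j * (n_radial + 1), (j + 1) * (n_radial + 1))
        nodes[rows, 0] = xs
        nodes[rows, 1] = yp + f * (ya - yp)

    def nid(i, j):
        return j * (n_radial + 1) + i

    elems = np.empty((n_radial * n_thickness, 4), dtype=np.int64)
    k = 0
    for j in range(n_thickness):
        for i in range(n_radial):
            elems[k] = (nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1))
            k += 1

    ii = np.arange(n_radial + 1)
    jj = np.arange(n_thickness + 1)
    anterior_nodes = nid(ii, n_thickness)
    posterior_nodes = nid(ii, 0)
    limbus_nodes = nid(n_radial, jj)
    axis_nodes = nid(0, jj)
    anterior_edges = np.column_stack([anterior_nodes[:-1], anterior_nodes[1:]])
    posterior_edges = np.column_stack([posterior_nodes[:-1], posterior_nodes[1:]])
    return Mesh(
        nodes_mm=nodes,
        elems=elems,
        anterior_nodes=anterior_nodes,
        posterior_nodes=posterior_nodes,
        limbus_nodes=limbus_nodes,
        axis_nodes=axis_nodes,
        anterior_edges=anterior_edges.astype(np.int64),
        posterior_edges=posterior_edges.astype(np.int64),
        n_radial=n_radial,
        n_thickness=n_thickness,
    )


def solve_unloaded_config(
    mesh: Mesh,
    material,
    iop_mmHg: float,
    tol_mm: float = 1e-3,
    max_iter: int = 40,
    **static_kwargs,
) -> Mesh:
    """Stress-free configuration consistent with the imaged geometry at IOP.

    Fixed-point "pull-back": starting from the imaged coordinates, each
    iteration statically inflates the current unloaded candidate to ``iop``
    and subtracts the (relaxed) mismatch to the imaged target.  The
    relaxation factor adapts by Aitken's Delta-squared rule, which keeps the
    iteration contractive for soft corneas whose inflation gain exceeds one.
    Converged when the re-inflated apex lands within ``tol_mm`` of the
    target apex.

    Raises :class:`ConvergenceError` (carrying the last residual) if the
    apex error does not fall below ``tol_mm`` within ``max_iter`` rounds.
    """
    from .mechanics import static_inflate  # local import: avoids module cycle

    if iop_mmHg < 0:
        raise ValueError("iop must be nonnegative")
    if iop_mmHg == 0.0:
        return mesh.copy()
    # the pre-inflation is solved with the instantaneous modulus (see
    # static_inflate); the dynamic prestate is built consistently from it
    static_kwargs.setdefault("modulus", "instantaneous")

    target = mesh.nodes_mm.copy()
    unloaded = target.copy()
    apex = mesh.apex_index
    history = []
    err_prev = None
    last_step = None
    beta = 0.75
    for _ in range(max_iter):
        # backtrack the last correction if it produced a mesh the static
        # solver cannot handle (large pull-backs can fold thin elements)
        step_scale = 1.0
        while True:
            candidate = mesh.with_nodes(unloaded)
            try:
                inflated = static_inflate(candidate, material, iop_mmHg,
                                          **static_kwargs)
                break
            except (ValueError, RuntimeError):
                if last_step is None or step_scale < 0.1:
                    raise
                step_scale *= 0.5
                unloaded = unloaded + step_scale * last_step
        err = inflated.nodes_mm - target
        apex_err = float(np.linalg.norm(err[apex]))
        history.append(apex_err)
        if apex_err < tol_mm:
            return mesh.with_nodes(unloaded)
        if err_prev is not None:
            diff = err_prev - err
            denom = float(np.sum(diff * diff))
            if denom > 0:
                beta = float(np.clip(beta * np.sum(err_prev * diff) / denom,
                                     0.05, 1.0))
        err_prev = err
        last_step = beta * err
        unloaded = unloaded - last_step
    raise ConvergenceError(
        f"unloaded-state iteration did not reach {tol_mm} mm in {max_iter} rounds "
        f"(last apex residual {history[-1]:.3e} mm)",
        residual=history[-1],
        history=history,
    )
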