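"""Reduced biomechanical lip model (hexahedral finite elements).

The perioral soft tissue is modelled as two curved slabs (upper and lower
lip) of trilinear hexahedra in three layers (inner / centre / outer).
Nodes on the inner surface are fixed, standing in for attachment to the
mandible and maxilla; all other nodes are dynamic.  The ground matrix is
a two-term Mooney–Rivlin material on the distortional invariant,

    W = C10 (I1~ - 3) + C20 (I1~ - 3)^2 + kappa/2 (ln J)^2,

with I1~ = trace(F~ F~^T), F~ = J^(-1/3) F, plus a quadratic bulk
penalty (kb/2)(J - 1)^2 enforcing soft incompressibility at quadrature
level.  Muscles are fibre polylines; every element whose centroid lies
within a radius (default 5 mm) of the polyline becomes a muscle element
with fibre direction given by the nearest segment tangent.  Along the
fibre a transversely isotropic stress acts,

    sigma_fibre = sigma_max * (f_passive(lam~) + a * f_active(lam~)),

where lam~ is fibre stretch over optimal fibre stretch, f_passive is an
exponential toe region that becomes linear (value- and slope-matched)
beyond lam* and f_active is a parabolic force–length curve peaking at 1.
Time stepping is implicit: each backward-Euler step minimises the
incremental potential (strain energy + gravity + inertia + viscous
dissipation) over the free nodal positions.

Unit system: mm, kg, s — hence forces in mN and stresses in kPa; user
inputs keep the conventional units (kPa, kg/m^3, m/s^2) and are converted
on entry.  Coordinates: x lateral (left positive), y vertical (gravity
acts in -y), z anterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "MaterialParams",
    "MeshConfig",
    "MuscleDef",
    "LipModel",
    "TrajectorySet",
    "InvertedElementError",
    "SimulationError",
    "AdaptResult",
    "build_lip_mesh",
    "default_muscles",
    "default_lip_model",
    "assign_muscle_elements",
    "attach_muscles",
    "mooney_rivlin_energy",
    "mr_first_piola",
    "muscle_fibre_stress",
    "fibre_energy",
    "simulate",
    "adapt_sigma_max",
]

_J_GUARD = 0.05  # below this volume ratio ln J is extended quadratically


class InvertedElementError(RuntimeError):
    """An element's deformation Jacobian became non-positive."""

    def __init__(self, element: int, step: int | None = None):
        self.element = int(element)
        self.step = step
        where = f" at step {step}" if step is not None else ""
        super().__init__(f"inverted element {element}{where}")


class SimulationError(RuntimeError):
    """A time step failed to converge (carries the step index)."""

    def __init__(self, message: str, step: int | None = None):
        self.step = step
        super().__init__(message)


# ---------------------------------------------------------------------------
# model definition
# ---------------------------------------------------------------------------

@dataclass
class MaterialParams:
    """Passive tissue parameters (kPa, kg/m^3, m/s^2)."""

    c10: float = 2.5
    c20: float = 1.175
    kappa: float = 25.0
    bulk_modulus: float = 25.0
    density: float = 1040.0
    gravity: tuple[float, float, float] = (0.0, -9.8, 0.0)

    def __post_init__(self) -> None:
        if min(self.c10, self.c20, self.kappa, self.bulk_modulus) <= 0:
            raise ValueError("all stiffness parameters must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass
class MeshConfig:
    """Geometry of the reduced two-slab lip mesh (mm / degrees)."""

    nu: int = 16           # circumferential elements per lip
    nv: int = 4            # vertical elements per lip
    nw: int = 3            # radial (layer) elements per lip
    r_inner: float = 30.0  # inner (skeletal) surface radius
    thickness: float = 7.5
    arc_deg: float = 120.0
    lip_height: float = 10.0
    gap: float = 2.0       # initial opening between the lips

    @property
    def r_outer(self) -> float:
        return self.r_inner + self.thickness

    @property
    def half_arc(self) -> float:
        return np.deg2rad(self.arc_deg) / 2.0

    def analytic_volume(self) -> float:
        """Closed-form volume of the two annular-sector slabs."""
        arc = np.deg2rad(self.arc_deg)
        ring = 0.5 * (self.r_outer**2 - self.r_inner**2)
        return 2.0 * arc * ring * self.lip_height


@dataclass
class MuscleDef:
    """One model muscle: a fibre polyline plus its force-law parameters."""

    name: str
    polyline: np.ndarray            # (P, 3) points, mm
    lam_star: float = 1.4           # stretch where the passive law turns linear
    p1: float = 0.05                # exponential stress coefficient
    p2: float = 6.6                 # uncrimping factor
    lam_ofl: float = 1.0            # optimal fibre stretch
    elements: np.ndarray | None = None  # manual element override (ids)

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2:
            raise ValueError(
                f"muscle {self.name}: polyline needs at least 2 points"
            )
        if self.lam_star <= 1.0:
            raise ValueError(f"muscle {self.name}: lam_star must exceed 1")


@dataclass
class LipModel:
    """Mesh + material + muscles + boundary sets + marker map."""

    nodes: np.ndarray               # (N, 3) reference positions, mm
    elems: np.ndarray               # (E, 8) hex connectivity
    layers: np.ndarray              # (E,) layer label per element
    fixed: np.ndarray               # fixed node ids (inner surface)
    marker_nodes: np.ndarray        # (10,) node ids of the lip markers
    marker_names: list[str]
    material: MaterialParams
    muscles: list[MuscleDef] = field(default_factory=list)
    muscle_elems: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    sigma_max: float = 300.0        # kPa, shared by all muscle elements
    mesh_config: MeshConfig | None = None
    _assembly: "_Assembly | None" = field(
        default=None, repr=False, compare=False
    )
    _fibre_cache: dict | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elems.shape[0]

    def assembly(self) -> "_Assembly":
        if self._assembly is None:
            self._assembly = _Assembly(self)
        return self._assembly

    def rotated(self, R: np.ndarray) -> "LipModel":
        """The same model with reference state (and gravity) rotated."""
        R = np.asarray(R, dtype=float)
        mat = replace(
            self.material,
            gravity=tuple(R @ np.asarray(self.material.gravity)),
        )
        muscles = [
            replace(m, polyline=m.polyline @ R.T) for m in self.muscles
        ]
        melems = {
            name: (ids.copy(), dirs @ R.T)
            for name, (ids, dirs) in self.muscle_elems.items()
        }
        return replace(
            self,
            nodes=self.nodes @ R.T,
            material=mat,
            muscles=muscles,
            muscle_elems=melems,
            _assembly=None,
            _fibre_cache=None,
        )


@dataclass
class TrajectorySet:
    """3-D trajectories of the ten lip markers (mm)."""

    positions: np.ndarray           # (markers, frames, 3)
    frame_rate: float
    source: str = "simulated"       # "simulated" | "measured"
    instruction: str = ""
    repetition: int = 0
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (markers x frames x 3)")
        if self.positions.shape[1] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if np.isnan(self.positions).any():
            raise ValueError("trajectory contains NaNs")

    @property
    def n_markers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def build_lip_mesh(
    config: MeshConfig | None = None,
    material: MaterialParams | None = None,
) -> LipModel:
    """Build the structured two-slab all-hex lip mesh.

    Each lip is an annular sector: ``nu`` elements along the arc, ``nv``
    vertically, ``nw`` radially.  The innermost node shell is fixed.  Ten
    marker nodes sit on the outer surface: five on the upper lip (mouth
    corners at the free edge, cupid-bow pair and philtrum at the top
    edge) and five along the free edge of the lower lip.
    """
    cfg = config or MeshConfig()
    mat = material or MaterialParams()
    nu, nv, nw = cfg.nu, cfg.nv, cfg.nw
    if min(nu, nv, nw) < 1 or nu % 4 != 0:
        raise ValueError("need nu divisible by 4 and nv, nw >= 1")

    theta = np.linspace(-cfg.half_arc, cfg.half_arc, nu + 1)
    radii = np.linspace(cfg.r_inner, cfg.r_outer, nw + 1)
    y_upper = cfg.gap / 2 + cfg.lip_height * np.arange(nv + 1) / nv
    y_lower = -cfg.gap / 2 - cfg.lip_height + \
        cfg.lip_height * np.arange(nv + 1) / nv

    nodes: list[np.ndarray] = []
    index = np.empty((2, nu + 1, nv + 1, nw + 1), dtype=int)
    for lip, ys in enumerate((y_upper, y_lower)):
        for i, th in enumerate(theta):
            for j, y in enumerate(ys):
                for k, r in enumerate(radii):
                    index[lip, i, j, k] = len(nodes)
                    nodes.append(
                        np.array([r * np.sin(th), y, r * np.cos(th)])
                    )
    nodes_arr = np.array(nodes)

    elems: list[list[int]] = []
    layers: list[str] = []
    layer_names = ("inner", "centre", "outer")
    for lip in range(2):
        for i in range(nu):
            for j in range(nv):
                for k in range(nw):
                    elems.append([
                        index[lip, i, j, k],
                        index[lip, i + 1, j, k],
                        index[lip, i + 1, j + 1, k],
                        index[lip, i, j + 1, k],
                        index[lip, i, j, k + 1],
                        index[lip, i + 1, j, k + 1],
                        index[lip, i + 1, j + 1, k + 1],
                        index[lip, i, j + 1, k + 1],
                    ])
                    layers.append(layer_names[min(2, (3 * k) // nw)])
    elems_arr = np.array(elems, dtype=int)

    fixed = np.unique(index[:, :, :, 0].ravel())

    quarter = nu // 4
    iq = [0, quarter, 2 * quarter, 3 * quarter, nu]
    marker_nodes = [
        index[0, iq[0], 0, nw],        # corner_R (free edge, upper lip)
        index[0, iq[1], nv, nw],       # cupid_R (top edge)
        index[0, iq[2], nv, nw],       # philtrum
        index[0, iq[3], nv, nw],       # cupid_L
        index[0, iq[4], 0, nw],        # corner_L
        index[1, iq[0], nv, nw],       # lower_corner_R (free edge)
        index[1, iq[1], nv, nw],       # lower_mid_R
        index[1, iq[2], nv, nw],       # lower_centre
        index[1, iq[3], nv, nw],       # lower_mid_L
        index[1, iq[4], nv, nw],       # lower_corner_L
    ]
    marker_names = [
        "corner_R", "cupid_R", "philtrum", "cupid_L", "corner_L",
        "lower_corner_R", "lower_mid_R", "lower_centre", "lower_mid_L",
        "lower_corner_L",
    ]

    model = LipModel(
        nodes=nodes_arr,
        elems=elems_arr,
        layers=np.array(layers),
        fixed=fixed,
        marker_nodes=np.array(marker_nodes, dtype=int),
        marker_names=marker_names,
        material=mat,
        mesh_config=cfg,
    )
    # reject degenerate reference elements up front
    asm = model.assembly()
    if np.any(asm.w <= 0):
        bad = int(np.argwhere(np.any(asm.w <= 0, axis=1))[0, 0])
        raise InvertedElementError(bad)
    return model


def _arc_pts(r, y, t0, t1, n=9):
    th = np.linspace(t0, t1, n)
    return np.column_stack([r * np.sin(th), np.full(n, float(y)),
                            r * np.cos(th)])


def _line_pts(p0, p1, n=5):
    return np.linspace(np.asarray(p0, float), np.asarray(p1, float), n)


def default_muscles(cfg: MeshConfig | None = None) -> list[MuscleDef]:
    """Schematic fibre polylines for the 20 model muscle groups.

    Geometry is approximate — left-side polylines placed relative to the
    mesh arc, mirrored in x for the right side.  Users can supply their
    own polylines or explicit element lists instead.
    """
    cfg = cfg or MeshConfig()
    tm = cfg.half_arc
    rm = cfg.r_inner + 0.5 * cfg.thickness
    g, h = cfg.gap, cfg.lip_height
    yut, yub = g / 2 + h, g / 2               # upper lip top / bottom edge
    ylt, ylb = -g / 2, -g / 2 - h             # lower lip top / bottom edge

    def at(frac, r=rm):
        th = frac * tm
        return np.array([r * np.sin(th), 0.0, r * np.cos(th)])

    left: dict[str, np.ndarray] = {}
    # orbicularis oris: loop around the mouth (upper arc, corner, lower arc)
    left["OOP"] = np.vstack([
        _arc_pts(rm, yub + 0.45 * h, 0.0, 0.92 * tm, 8),
        at(0.97)[None, :],
        _arc_pts(rm, ylt - 0.45 * h, 0.92 * tm, 0.0, 8),
    ])
    left["OOM"] = np.vstack([
        _arc_pts(rm, yub + 0.12 * h, 0.0, 0.85 * tm, 8),
        at(0.95)[None, :],
        _arc_pts(rm, ylt - 0.12 * h, 0.85 * tm, 0.0, 8),
    ])
    left["BUC"] = _arc_pts(rm, 0.0, 0.65 * tm, 1.0 * tm, 6)
    p = at(0.85)
    left["RIS"] = _line_pts(p, p + [7.0, 0.0, -5.0])
    p = at(0.90) + [0.0, yub, 0.0]
    left["ZYG"] = _line_pts(p, p + [5.0, 9.0, -5.0])
    left["LAO"] = _line_pts(at(0.80) + [0.0, yub + 0.1 * h, 0.0],
                            at(0.75) + [0.0, yut + 2.0, -1.0])
    p = at(0.30)
    left["LLSAN"] = _line_pts(p + [0.0, yub, 0.0], p + [0.0, yut + 2.0, 0.0])
    p = at(0.75)
    left["DAO"] = _line_pts(p + [0.0, ylt, 0.0], p + [0.0, ylb - 2.0, 0.0])
    p = at(0.35)
    left["DLI"] = _line_pts(p + [0.0, ylt, 0.0], p + [0.0, ylb - 1.0, 0.0])
    p = at(0.12)
    left["MEN"] = _line_pts(p + [0.0, ylb - 1.0, 0.0],
                            p + [0.0, ylt - 0.45 * h, 0.0])

    muscles = []
    for name, pts in left.items():
        muscles.append(MuscleDef(name=f"{name}_L", polyline=pts))
        muscles.append(MuscleDef(name=f"{name}_R",
                                 polyline=pts * np.array([-1.0, 1.0, 1.0])))
    return muscles


def _point_segment_distance(points: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> np.ndarray:
    """Distance from each point (n,3) to segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def assign_muscle_elements(
    model: LipModel,
    muscle: MuscleDef,
    radius: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Elements within ``radius`` of the fibre polyline, with directions.

    Returns (element ids, unit fibre direction per element).  The fibre
    direction is the tangent of the nearest polyline segment.  An
    explicit ``muscle.elements`` list overrides the radius rule (the
    manual-assignment hook); directions still come from the nearest
    segment.  An empty result triggers a warning (inactive muscle).
    """
    centroids = model.nodes[model.elems].mean(axis=1)
    pts = muscle.polyline
    nseg = pts.shape[0] - 1
    dists = np.empty((model.n_elements, nseg))
    for s in range(nseg):
        dists[:, s] = _point_segment_distance(centroids, pts[s], pts[s + 1])
    nearest = np.argmin(dists, axis=1)
    if muscle.elements is not None:
        ids = np.asarray(muscle.elements, dtype=int)
    else:
        ids = np.nonzero(dists[np.arange(model.n_elements), nearest]
                         <= radius)[0]
    if ids.size == 0:
        warnings.warn(
            f"muscle {muscle.name}: no elements within {radius} mm of the "
            "fibre polyline (muscle inactive)",
            stacklevel=2,
        )
        return ids, np.empty((0, 3))
    tangents = pts[nearest[ids] + 1] - pts[nearest[ids]]
    dirs = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    return ids, dirs


def attach_muscles(
    model: LipModel,
    muscles: list[MuscleDef] | None = None,
    radius: float = 5.0,
) -> LipModel:
    """Attach muscle definitions to the model (in place) and return it."""
    model.muscles = muscles if muscles is not None else default_muscles(
        model.mesh_config
    )
    model.muscle_elems = {}
    model._fibre_cache = None
    for m in model.muscles:
        model.muscle_elems[m.name] = assign_muscle_elements(model, m, radius)
    return model


def default_lip_model(
    config: MeshConfig | None = None,
    material: MaterialParams | None = None,
    sigma_max: float = 300.0,
    muscle_radius: float = 5.0,
) -> LipModel:
    """Default mesh with the default muscle set attached."""
    model = build_lip_mesh(config, material)
    attach_muscles(model, radius=muscle_radius)
    model.sigma_max = sigma_max
    return model


# ---------------------------------------------------------------------------
# constitutive laws
# ---------------------------------------------------------------------------

def _cofactor(F: np.ndarray) -> np.ndarray:
    """Cofactor matrix, cof(F) = dJ/dF = J F^-T (vectorised)."""
    C = np.empty_like(F)
    C[..., 0, 0] = F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1]
    C[..., 0, 1] = F[..., 1, 2] * F[..., 2, 0] - F[..., 1, 0] * F[..., 2, 2]
    C[..., 0, 2] = F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0]
    C[..., 1, 0] = F[..., 0, 2] * F[..., 2, 1] - F[..., 0, 1] * F[..., 2, 2]
    C[..., 1, 1] = F[..., 0, 0] * F[..., 2, 2] - F[..., 0, 2] * F[..., 2, 0]
    C[..., 1, 2] = F[..., 0, 1] * F[..., 2, 0] - F[..., 0, 0] * F[..., 2, 1]
    C[..., 2, 0] = F[..., 0, 1] * F[..., 1, 2] - F[..., 0, 2] * F[..., 1, 1]
    C[..., 2, 1] = F[..., 0, 2] * F[..., 1, 0] - F[..., 0, 0] * F[..., 1, 2]
    C[..., 2, 2] = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    return C


def _det3(F: np.ndarray, C: np.ndarray) -> np.ndarray:
    return (F[..., 0, 0] * C[..., 0, 0] + F[..., 0, 1] * C[..., 0, 1]
            + F[..., 0, 2] * C[..., 0, 2])


def _guarded_log(J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ln J with a C1 quadratic extension below the guard threshold.

    Keeps the volumetric energy finite (and strongly restoring) when a
    line-search probe passes through a nearly inverted state.
    """
    J0 = _J_GUARD
    Jc = np.maximum(J, J0)
    phi = np.where(J >= J0, np.log(Jc),
                   np.log(J0) + (J - J0) / J0 - (J - J0) ** 2 / (2 * J0**2))
    dphi = np.where(J >= J0, 1.0 / Jc, 1.0 / J0 - (J - J0) / J0**2)
    return phi, dphi


def _mr_energy_piola(
    F: np.ndarray, mat: MaterialParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mooney–Rivlin + volumetric energy density W (kPa) and P = dW/dF.

    Vectorised over leading axes of F.  Returns (W, P, J).
    """
    C = _cofactor(F)
    J = _det3(F, C)
    Jc = np.maximum(J, _J_GUARD)
    Jm23 = Jc ** (-2.0 / 3.0)
    I1 = np.sum(F * F, axis=(-2, -1))
    x = Jm23 * I1 - 3.0
    W_dev = mat.c10 * x + mat.c20 * x * x
    dWdx = mat.c10 + 2.0 * mat.c20 * x
    # dI1~/dF = J^-2/3 (2F - (2/3) I1 F^-T);  F^-T = C / J
    P = dWdx[..., None, None] * (
        2.0 * Jm23[..., None, None] * F
        - (2.0 / 3.0) * (Jm23 * I1 / Jc)[..., None, None] * C
    )
    phi, dphi = _guarded_log(J)
    W_vol = 0.5 * mat.kappa * phi**2 + 0.5 * mat.bulk_modulus * (J - 1.0)**2
    P += (mat.kappa * phi * dphi
          + mat.bulk_modulus * (J - 1.0))[..., None, None] * C
    return W_dev + W_vol, P, J


def mr_first_piola(F: np.ndarray,
                   mat: MaterialParams | None = None) -> np.ndarray:
    """First Piola–Kirchhoff stress dW/dF (kPa) of the ground matrix."""
    _, P, _ = _mr_energy_piola(np.asarray(F, float), mat or MaterialParams())
    return P


def mooney_rivlin_energy(
    F: np.ndarray, mat: MaterialParams | None = None
) -> tuple[float, np.ndarray]:
    """Strain energy density W (kPa) and Cauchy stress for one F.

    Raises :class:`InvertedElementError` if det F <= 0.
    """
    mat = mat or MaterialParams()
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError("F must be a single 3x3 deformation gradient")
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvertedElementError(0)
    W, P, _ = _mr_energy_piola(F, mat)
    sigma = P @ F.T / J
    return float(W), sigma


def _fibre_passive(lam_bar: np.ndarray, p1, p2, ls
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Normalised passive force f_p and its antiderivative from lam~=1.

    Exponential toe for 1 < lam~ < lam*, then linear with matched value
    and slope (C1 at lam*); zero in compression.  The parameters may be
    scalars or arrays broadcast against ``lam_bar``.
    """
    lb = np.asarray(lam_bar, dtype=float)
    f_star = p1 * (np.exp(p2 * (ls - 1.0)) - 1.0)
    slope = p1 * p2 * np.exp(p2 * (ls - 1.0))
    F_star = p1 * ((np.exp(p2 * (ls - 1.0)) - 1.0) / p2 - (ls - 1.0))

    toe = np.clip(lb, 1.0, ls)
    f = np.where(
        lb <= 1.0, 0.0,
        np.where(lb < ls,
                 p1 * (np.exp(p2 * (toe - 1.0)) - 1.0),
                 f_star + slope * (lb - ls)),
    )
    Fint = np.where(
        lb <= 1.0, 0.0,
        np.where(
            lb < ls,
            p1 * ((np.exp(p2 * (toe - 1.0)) - 1.0) / p2 - (toe - 1.0)),
            F_star + f_star * (lb - ls) + 0.5 * slope * (lb - ls) ** 2,
        ),
    )
    return f, Fint


def _fibre_active(lam_bar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parabolic force–length curve and its antiderivative from lam~=1.

    f_a = 1 - 4 (lam~ - 1)^2 clamped to [0, 1]; zero outside [0.5, 1.5].
    """
    lb = np.asarray(lam_bar, dtype=float)
    f = np.clip(1.0 - 4.0 * (lb - 1.0) ** 2, 0.0, 1.0)

    def anti(u):
        return u - (4.0 / 3.0) * (u - 1.0) ** 3

    uc = np.clip(lb, 0.5, 1.5)
    Fint = anti(uc) - anti(1.0)
    return f, Fint


def muscle_fibre_stress(
    lam: float | np.ndarray,
    a: float | np.ndarray,
    m: MuscleDef,
    sigma_max: float = 300.0,
) -> np.ndarray:
    """Along-fibre nominal stress sigma_max (f_p + a f_a), kPa."""
    lam = np.asarray(lam, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("fibre stretch must be positive")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    lb = lam / m.lam_ofl
    fp, _ = _fibre_passive(lb, m.p1, m.p2, m.lam_star)
    fa, _ = _fibre_active(lb)
    return sigma_max * (fp + a * fa)


def fibre_energy(
    lam: np.ndarray, a, m: MuscleDef, sigma_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fibre strain energy density and its lam-derivative (the stress).

    Defined so that dW/dlam equals :func:`muscle_fibre_stress`; the
    energy is the analytic integral of the force law from rest length.
    """
    lb = np.asarray(lam, dtype=float) / m.lam_ofl
    fp, Fp = _fibre_passive(lb, m.p1, m.p2, m.lam_star)
    fa, Fa = _fibre_active(lb)
    W = sigma_max * m.lam_ofl * (Fp + a * Fa)
    dW = sigma_max * (fp + a * fa)
    return W, dW


# ---------------------------------------------------------------------------
# assembly and time stepping
# ---------------------------------------------------------------------------

_GAUSS = np.array([[i, j, k] for k in (-1, 1) for j in (-1, 1)
                   for i in (-1, 1)]) / np.sqrt(3.0)
_LOCAL = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)


def _shape_gradients() -> np.ndarray:
    """dN_a/dxi at the 8 Gauss points: (gauss, node, 3)."""
    out = np.empty((8, 8, 3))
    for g, xi in enumerate(_GAUSS):
        for a, la in enumerate(_LOCAL):
            t = (1.0 + la * xi)  # per-axis factors
            out[g, a, 0] = 0.125 * la[0] * t[1] * t[2]
            out[g, a, 1] = 0.125 * la[1] * t[0] * t[2]
            out[g, a, 2] = 0.125 * la[2] * t[0] * t[1]
    return out


class _Assembly:
    """Precomputed quadrature data for fast vectorised assembly."""

    def __init__(self, model: LipModel):
        dndxi = _shape_gradients()                      # (G, 8, 3)
        X = model.nodes[model.elems]                    # (E, 8, 3)
        # Jacobian dX/dxi per element and gauss point
        Jref = np.einsum("eaj,gak->egjk", X, dndxi)
        detJ = np.linalg.det(Jref)
        self.w = detJ                                   # gauss weights are 1
        Jinv = np.linalg.inv(np.where(
            detJ[..., None, None] == 0, np.eye(3), Jref))
        self.gradN = np.einsum("gak,egkj->egaj", dndxi, Jinv)  # (E,G,8,3)
        self.gradN_w = self.gradN * self.w[..., None, None]
        self.conn = model.elems
        vol_e = self.w.sum(axis=1)
        mass = np.zeros(model.n_nodes)
        np.add.at(mass, model.elems,
                  (model.material.density * 1e-9 * vol_e / 8.0)[:, None])
        self.node_mass = mass                           # kg
        self.free = np.setdiff1d(np.arange(model.n_nodes), model.fixed)


def _fibre_arrays(model: LipModel) -> dict | None:
    """Concatenated per-muscle-element data for batched fibre assembly.

    Cached on the model; rebuilt whenever muscles are (re)attached.
    Entries with the same element id (overlapping muscles) are kept
    separate and accumulate additively.
    """
    if model._fibre_cache is not None:
        return model._fibre_cache or None
    ids, dirs, midx, p1, p2, ls, lofl = [], [], [], [], [], [], []
    for mi, m in enumerate(model.muscles):
        eids, edirs = model.muscle_elems.get(
            m.name, (np.empty(0, int), None)
        )
        if eids.size == 0:
            continue
        ids.append(eids)
        dirs.append(edirs)
        midx.append(np.full(eids.size, mi))
        p1.append(np.full(eids.size, m.p1))
        p2.append(np.full(eids.size, m.p2))
        ls.append(np.full(eids.size, m.lam_star))
        lofl.append(np.full(eids.size, m.lam_ofl))
    if not ids:
        model._fibre_cache = {}
        return None
    col = np.concatenate
    model._fibre_cache = {
        "ids": col(ids),
        "dirs": col(dirs),
        "muscle": col(midx),
        "p1": col(p1)[:, None],
        "p2": col(p2)[:, None],
        "ls": col(ls)[:, None],
        "lofl": col(lofl)[:, None],
    }
    return model._fibre_cache


def _total_energy_grad(
    model: LipModel,
    x: np.ndarray,
    act: np.ndarray,
    E_prev: np.ndarray | None = None,
    kv_coef: float = 0.0,
    with_gravity: bool = True,
) -> tuple[float, np.ndarray, dict]:
    """Potential energy (muscle work included) and its nodal gradient.

    ``act`` holds one activation scalar per entry of ``model.muscles``.
    Returns (energy, gradient (N,3), info) where info carries the Green
    strains, min det F and its element for reuse by the stepper.
    """
    asm = model.assembly()
    x_el = x[asm.conn]                                   # (E, 8, 3)
    xT = x_el.transpose(0, 2, 1)[:, None]                # (E, 1, 3, 8)
    F = xT @ asm.gradN                                   # (E, G, 3, 3)

    W, P, J = _mr_energy_piola(F, model.material)

    Egr = 0.5 * (F.transpose(0, 1, 3, 2) @ F - np.eye(3))
    if kv_coef > 0.0 and E_prev is not None:
        dE = Egr - E_prev
        W = W + 0.5 * kv_coef * np.sum(dE * dE, axis=(-2, -1))
        P = P + kv_coef * (F @ dE)

    energy = float(np.sum(asm.w * W))
    # grad_el[e,a,i] = sum_g w * gradN[e,g,a,j] P[e,g,i,j]
    g_el = (asm.gradN_w @ P.transpose(0, 1, 3, 2)).sum(axis=1)
    grad = np.zeros_like(x)
    flat = asm.conn.ravel()
    for c in range(3):
        grad[:, c] = np.bincount(flat, weights=g_el[..., c].ravel(),
                                 minlength=model.n_nodes)

    fb = _fibre_arrays(model)
    if fb is not None:
        ids = fb["ids"]
        dirs = fb["dirs"]
        Fm = F[ids]                                       # (M, G, 3, 3)
        t = Fm @ dirs[:, None, :, None]                   # (M, G, 3, 1)
        lam = np.maximum(np.linalg.norm(t[..., 0], axis=-1), 1e-9)
        lb = lam / fb["lofl"]
        a_m = act[fb["muscle"]][:, None]
        fp, Fp = _fibre_passive(lb, fb["p1"], fb["p2"], fb["ls"])
        fa, Fa = _fibre_active(lb)
        Wf = model.sigma_max * fb["lofl"] * (Fp + a_m * Fa)
        dWf = model.sigma_max * (fp + a_m * fa)
        energy += float(np.sum(asm.w[ids] * Wf))
        P_f = (dWf / lam)[..., None, None] * (t * dirs[:, None, None, :])
        g_f = (asm.gradN_w[ids] @ P_f.transpose(0, 1, 3, 2)).sum(axis=1)
        flat_f = asm.conn[ids].ravel()
        for c in range(3):
            grad[:, c] += np.bincount(flat_f, weights=g_f[..., c].ravel(),
                                      minlength=model.n_nodes)

    if with_gravity:
        gvec = np.asarray(model.material.gravity) * 1e3   # mm/s^2
        energy -= float(np.sum(asm.node_mass[:, None] * gvec * x))
        grad -= asm.node_mass[:, None] * gvec

    j_elem = J.min(axis=1)
    e_min = int(np.argmin(j_elem))
    info = {"green": Egr, "min_J": float(j_elem[e_min]),
            "max_J": float(J.max()), "min_J_elem": e_min}
    return energy, grad, info


def internal_energy_and_forces(
    model: LipModel,
    x: np.ndarray,
    act: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Total strain energy and internal nodal forces (-gradient), no gravity.

    Exposed for verification: forces must equal the negative gradient of
    the strain energy for any nodal configuration.
    """
    if act is None:
        act = np.zeros(len(model.muscles))
    e, g, _ = _total_energy_grad(model, np.asarray(x, float), act,
                                 with_gravity=False)
    return e, -g


def simulate(
    model: LipModel,
    act,
    duration: float | None = None,
    kv_damping: float = 0.5,
    mass_damping: float = 0.0,
    pgtol: float = 1e-4,
    maxiter: int = 400,
    check_inversion: bool = True,
    j_monitor: list | None = None,
) -> TrajectorySet:
    """Forward dynamics driven by an ActivationSet.

    One implicit (backward-Euler) step per activation frame: the step
    solves ``min_x  W(x) + inertia + viscous dissipation`` over the free
    nodes, warm-started from the inertial prediction.  ``kv_damping`` is
    the Kelvin–Voigt viscosity (kPa*s) on the Green-strain rate;
    ``mass_damping`` an optional mass-proportional coefficient (1/s).
    If ``j_monitor`` is a list it receives the (min, max) element volume
    ratio of every accepted step.  Returns the marker trajectories at
    the model frame rate.

    Raises :class:`InvertedElementError` (with element and step) if an
    accepted step contains det F <= 0, and :class:`SimulationError` if a
    step fails to converge.
    """
    n_m = len(model.muscles)
    act_mat = np.zeros((n_m, act.n_frames))
    for mi, m in enumerate(model.muscles):
        if m.name in act.labels:
            act_mat[mi] = act.values[act.labels.index(m.name)]
    steps = act.n_frames
    if duration is None:
        span = float(act.times[-1] - act.times[0]) if act.times.size else 0.0
        duration = span if span > 0 else 2.0
    dt = duration / steps

    asm = model.assembly()
    free = asm.free
    x = model.nodes.copy()
    v = np.zeros_like(x)
    kv_coef = kv_damping / dt
    m_free = asm.node_mass[free][:, None]
    inert_c = m_free / dt**2 + mass_damping * m_free / dt

    # Green strain of the previous accepted state (for the viscous term)
    _, _, info = _total_energy_grad(model, x, act_mat[:, 0] * 0.0)
    E_prev = info["green"]

    markers = np.empty((model.marker_nodes.size, steps, 3))
    for k in range(steps):
        a_k = act_mat[:, k]
        x_prev = x
        x_pred = x.copy()
        x_pred[free] += dt * v[free]

        def objective(u, a_k=a_k, x_prev=x_prev, x_pred=x_pred,
                      E_prev=E_prev):
            xs = x_prev.copy()
            xs[free] = u.reshape(-1, 3)
            e, g, _ = _total_energy_grad(model, xs, a_k, E_prev, kv_coef)
            d_pred = xs[free] - x_pred[free]
            e += 0.5 * float(np.sum(inert_c * d_pred * d_pred))
            gf = g[free] + inert_c * d_pred
            return e, gf.ravel()

        u0 = x_pred[free].ravel()
        for attempt in range(3):
            res = minimize(
                objective,
                u0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": pgtol,
                         "maxcor": 20},
            )
            gnorm = (float(np.max(np.abs(res.jac)))
                     if res.jac is not None else 0.0)
            if res.success or gnorm <= 50 * max(pgtol, 1e-5):
                break
            u0 = res.x  # restart with fresh curvature memory
        # a line-search abort with an already-tiny gradient is acceptable
        if not res.success and gnorm > 50 * max(pgtol, 1e-5):
            raise SimulationError(
                f"step {k}: solver did not converge ({res.message}, "
                f"|g|={gnorm:.2e})",
                step=k,
            )
        x = x_prev.copy()
        x[free] = res.x.reshape(-1, 3)
        _, _, info = _total_energy_grad(model, x, a_k, E_prev, kv_coef)
        if check_inversion and info["min_J"] <= 0.0:
            raise InvertedElementError(info["min_J_elem"], step=k)
        if j_monitor is not None:
            j_monitor.append((info["min_J"], info["max_J"]))
        E_prev = info["green"]
        v = np.zeros_like(x)
        v[free] = (x[free] - x_prev[free]) / dt
        markers[:, k, :] = x[model.marker_nodes]

    return TrajectorySet(
        positions=markers,
        frame_rate=steps / duration,
        source="simulated",
        instruction=act.instruction,
        repetition=act.repetition,
        marker_names=list(model.marker_names),
    )


@dataclass
class AdaptResult:
    """Outcome of the maximum-stress adaptation loop."""

    sigma_max: float
    attempts: list[float]
    trajectories: TrajectorySet | None = None


def adapt_sigma_max(
    model: LipModel,
    act,
    start: float = 300.0,
    factor: float = 0.9,
    floor: float = 1.0,
    simulate_fn=None,
    **sim_kwargs,
) -> AdaptResult:
    """Decrease sigma_max by 10% whenever the run inverts an element.

    Starting at ``start`` (kPa), the activation sequence is simulated;
    on an :class:`InvertedElementError` sigma_max is multiplied by
    ``factor`` and the run restarted.  The first clean value is returned
    (with its trajectories) and left set on the model.  Falling below
    ``floor`` raises :class:`SimulationError` ("cannot stabilise").
    """
    sim = simulate_fn if simulate_fn is not None else simulate
    sigma = float(start)
    attempts: list[float] = []
    while sigma >= floor:
        attempts.append(sigma)
        model.sigma_max = sigma
        try:
            traj = sim(model, act, **sim_kwargs)
        except InvertedElementError:
            sigma *= factor
            continue
        return AdaptResult(sigma_max=sigma, attempts=attempts,
                           trajectories=traj)
    raise SimulationError(
        f"cannot stabilise: sigma_max fell below {floor} kPa"
    )
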