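"""Parametric solids for the femur surrogate, fixtures and implant proxies.

The bench model is a machined proximal-femur surrogate: a cylinder of
10 PCF polyurethane foam capped by a spherical head, enclosed (except for a
distal exposure band that permits varus collapse) in a polished steel shell,
seated on a steel base block whose top surface is inclined 28 degrees above
horizontal so that the implant axis sits 62 degrees from vertical.  The
commercial implants are proprietary CAD; here they are replaced by
parametric proxies (threaded screw = solid of revolution with annular
ridges, helical blade = shaft plus swept fins) that preserve the contrasts
that matter for cut-out: engagement length, outer diameter and thread/fin
character.

All solids carry an exact analytic point-containment function alongside
their triangulated boundary, which makes centroid carving and rigid
discretization fast and independent of ray-casting backends.  Units are
mm throughout; the global frame has z vertical with loading in -z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import shapely
import trimesh
from shapely.geometry import Polygon
from trimesh.creation import revolve

__all__ = [
    "SolidModel",
    "ImplantSpec",
    "AssemblySpec",
    "DiscretizedSolid",
    "build_femur_surrogate",
    "build_implant_proxy",
    "build_fixtures",
    "position_implant",
    "discretize_rigid",
    "points_in_mesh",
    "implant_preset",
    "rotation_about_y",
]

ContainsFn = Callable[[np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# solid model wrapper
# ---------------------------------------------------------------------------


@dataclass
class SolidModel:
    """A watertight triangulated solid with a pose and fast containment.

    The mesh lives in the solid's local frame; ``transform`` (4x4,
    rotation + translation, mm) poses it in the world.  ``contains``
    evaluates point membership through exact analytic component tests
    (profile polygons for solids of revolution, half-spaces for blocks)
    rather than ray casting.
    """

    mesh: trimesh.Trimesh
    label: str = ""
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))
    _contains_fns: Sequence[ContainsFn] = ()
    _component_volumes: tuple[float, ...] = ()

    @property
    def volume(self) -> float:
        if self._component_volumes:
            return float(sum(self._component_volumes))
        return float(self.mesh.volume)

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    def posed_mesh(self) -> trimesh.Trimesh:
        m = self.mesh.copy()
        m.apply_transform(self.transform)
        return m

    def with_transform(self, transform: np.ndarray) -> "SolidModel":
        return replace(self, transform=np.asarray(transform, dtype=float))

    def apply_transform(self, transform: np.ndarray) -> "SolidModel":
        """Compose an additional world-frame transform onto the pose."""
        return self.with_transform(np.asarray(transform, dtype=float) @ self.transform)

    def to_local(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.transform)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of world-frame points in the solid."""
        local = self.to_local(points)
        if self._contains_fns:
            inside = np.zeros(len(local), dtype=bool)
            for fn in self._contains_fns:
                inside |= fn(local)
            return inside
        return points_in_mesh(self.mesh, local)

    def export_stl(self, path) -> None:
        self.posed_mesh().export(path)

    # convenience anchors -------------------------------------------------
    @property
    def axis_world(self) -> np.ndarray:
        """Local +z axis expressed in the world frame (unit vector)."""
        return self.transform[:3, 2] / np.linalg.norm(self.transform[:3, 2])

    def point_world(self, local_point) -> np.ndarray:
        p = np.asarray(local_point, dtype=float)
        return self.transform[:3, :3] @ p + self.transform[:3, 3]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImplantSpec:
    """Parametric description of an implant proxy.

    ``kind`` selects the head-element style.  ``thread_outer_diameter``
    doubles as the blade width for fin-type devices; ``pitch_mm`` is the
    thread pitch for screws and ``helix_angle_deg`` the fin twist for
    blades.  The 135-degree neck-shaft angle is bookkeeping for the
    loading-frame construction, not part of the proxy geometry itself.
    """

    kind: str = "screw"  # screw | blade | nail-with-screw | nail-with-blade
    shaft_diameter: float = 8.0
    thread_length: float = 20.0
    thread_outer_diameter: float = 12.0
    pitch_mm: float = 3.0
    helix_angle_deg: float = 0.0
    neck_shaft_angle_deg: float = 135.0
    overall_length: float = 80.0
    fin_thickness: float = 2.0

    def __post_init__(self):
        if self.kind not in ("screw", "blade", "nail-with-screw", "nail-with-blade"):
            raise ValueError(f"unsupported implant kind {self.kind!r}")
        for name in (
            "shaft_diameter",
            "thread_length",
            "thread_outer_diameter",
            "pitch_mm",
            "overall_length",
            "fin_thickness",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"implant dimension {name} must be positive")
        if self.thread_length > self.overall_length:
            raise ValueError("thread/blade region cannot exceed overall length")
        if self.thread_outer_diameter < self.shaft_diameter:
            raise ValueError("thread outer diameter must be >= shaft diameter")

    @property
    def head_element(self) -> str:
        return "blade" if "blade" in self.kind else "screw"


#: representative proxy dimensions per device style; approximations, not
#: vendor geometry (exact commercial diameters are not published here).
_PRESETS = {
    "screw": dict(kind="screw", shaft_diameter=8.0, thread_length=22.0,
                  thread_outer_diameter=12.7, pitch_mm=3.0, overall_length=80.0),
    "blade": dict(kind="blade", shaft_diameter=9.0, thread_length=45.0,
                  thread_outer_diameter=16.0, helix_angle_deg=8.0,
                  fin_thickness=2.5, overall_length=80.0),
    "nail-with-screw": dict(kind="nail-with-screw", shaft_diameter=10.5,
                            thread_length=28.0, thread_outer_diameter=14.0,
                            pitch_mm=4.0, overall_length=80.0),
    "nail-with-blade": dict(kind="nail-with-blade", shaft_diameter=10.0,
                            thread_length=45.0, thread_outer_diameter=16.5,
                            helix_angle_deg=8.0, fin_thickness=2.5,
                            overall_length=80.0),
}


def implant_preset(kind: str, **overrides) -> ImplantSpec:
    """Default proxy dimensions for a device style, with overrides."""
    if kind not in _PRESETS:
        raise ValueError(f"unsupported implant kind {kind!r}")
    params = dict(_PRESETS[kind])
    params.update(overrides)
    return ImplantSpec(**params)


@dataclass(frozen=True)
class AssemblySpec:
    """Dimensions of the femur surrogate and loading-frame fixtures."""

    femur_length: float = 70.0
    head_diameter: float = 40.0
    shell_exposure: float = 7.5
    base_angle_deg: float = 28.0
    tip_to_joint: float = 15.0
    shell_thickness: float = 1.5
    shell_apex_hole_radius: float = 2.0
    cup_clearance: float = 0.3

    def __post_init__(self):
        if self.femur_length <= 0 or self.head_diameter <= 0:
            raise ValueError("femur dimensions must be positive")
        if self.head_diameter / 2.0 >= self.femur_length:
            raise ValueError("head radius must be smaller than overall length")
        if not 0.0 < self.base_angle_deg < 90.0:
            raise ValueError("base angle must lie in (0, 90) degrees")
        if self.shell_exposure >= self.femur_length:
            raise ValueError("shell exposure must be smaller than femur length")
        if self.tip_to_joint < 0 or self.tip_to_joint > self.femur_length:
            raise ValueError("tip-to-joint distance outside femur")

    @property
    def implant_axis_from_vertical_deg(self) -> float:
        """Complementary construction: base at 28 deg -> axis 62 deg."""
        return 90.0 - self.base_angle_deg


# ---------------------------------------------------------------------------
# profile / revolve helpers
# ---------------------------------------------------------------------------


def _revolve_solid(profile_rz: np.ndarray, label: str, sections: int = 96) -> SolidModel:
    """Revolve an (r, z) polyline about the z axis into a SolidModel.

    The profile either starts and ends on the axis (r = 0), producing a
    simply-connected solid, or forms a closed ring off the axis, producing
    an annular solid.  Containment is the 2D point-in-profile test in
    (radius, z) coordinates.
    """
    prof = np.asarray(profile_rz, dtype=float)
    mesh = revolve(prof, sections=sections)
    if mesh.volume < 0:
        mesh.invert()

    ring = prof if np.allclose(prof[0], prof[-1]) else np.vstack([prof, prof[:1]])
    poly = Polygon(ring)
    if not poly.is_valid:
        poly = poly.buffer(0)

    def contains(points: np.ndarray, poly=poly) -> np.ndarray:
        r = np.hypot(points[:, 0], points[:, 1])
        return shapely.contains_xy(poly, r, points[:, 2])

    return SolidModel(
        mesh=mesh,
        label=label,
        _contains_fns=(contains,),
        _component_volumes=(float(mesh.volume),),
    )


def _arc(center_rz, radius, a0, a1, n=48) -> np.ndarray:
    """Sampled arc in the (r, z) half-plane; angle measured from +z."""
    t = np.linspace(a0, a1, n)
    return np.column_stack(
        [center_rz[0] + radius * np.sin(t), center_rz[1] + radius * np.cos(t)]
    )


def _merge_profile(points: list[np.ndarray]) -> np.ndarray:
    prof = np.vstack(points)
    keep = np.ones(len(prof), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(prof, axis=0), axis=1) > 1e-9
    return prof[keep]


# ---------------------------------------------------------------------------
# femur surrogate
# ---------------------------------------------------------------------------


def build_femur_surrogate(spec: AssemblySpec, sections: int = 96) -> SolidModel:
    """Cylinder-neck body capped by a spherical head; flat distal face.

    Local frame: +z is the neck/head axis, the distal face lies in z = 0,
    the head apex at z = femur_length.  The cylinder diameter equals the
    head diameter, matching a lathe-turned surrogate.
    """
    R = spec.head_diameter / 2.0
    L = spec.femur_length
    cap_center = np.array([0.0, L - R])
    prof = _merge_profile(
        [
            np.array([[0.0, 0.0], [R, 0.0], [R, L - R]]),
            _arc(cap_center, R, math.pi / 2.0, 0.0),
        ]
    )
    solid = _revolve_solid(prof, label="femur-surrogate", sections=sections)
    return solid


def femur_analytic_volume(spec: AssemblySpec) -> float:
    """Closed-form volume of the capped-cylinder surrogate (mm^3)."""
    R = spec.head_diameter / 2.0
    L = spec.femur_length
    return math.pi * R * R * (L - R) + 2.0 / 3.0 * math.pi * R**3


# ---------------------------------------------------------------------------
# implant proxies
# ---------------------------------------------------------------------------


def _screw_profile(spec: ImplantSpec) -> np.ndarray:
    rs = spec.shaft_diameter / 2.0
    rt = spec.thread_outer_diameter / 2.0
    L = spec.overall_length
    z0 = L - spec.thread_length
    pts: list[np.ndarray] = [np.array([[0.0, 0.0], [rs, 0.0], [rs, z0]])]
    n_teeth = int(spec.thread_length // spec.pitch_mm)
    z = z0
    for _ in range(n_teeth):
        pts.append(np.array([[rt, z + spec.pitch_mm / 2.0], [rs, z + spec.pitch_mm]]))
        z += spec.pitch_mm
    pts.append(np.array([[rs, L], [0.0, L]]))
    return _merge_profile(pts)


def _twisted_fin(
    r_in: float,
    r_out: float,
    thickness: float,
    z0: float,
    z1: float,
    twist_per_mm: float,
    phase: float,
    n_slices: int = 40,
) -> tuple[trimesh.Trimesh, ContainsFn]:
    """A rectangular fin swept along z with a rotation about the z axis.

    Cross-section at z spans x in [r_in, r_out], y in [-t/2, t/2], rotated
    by ``phase + twist_per_mm * (z - z0)``.  Watertight by construction;
    containment un-twists the query point and tests the 2D rectangle.
    """
    half_t = thickness / 2.0
    corners = np.array(
        [[r_in, -half_t], [r_out, -half_t], [r_out, half_t], [r_in, half_t]]
    )
    zs = np.linspace(z0, z1, n_slices)
    verts = []
    for z in zs:
        ang = phase + twist_per_mm * (z - z0)
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        xy = corners @ rot.T
        verts.append(np.column_stack([xy, np.full(4, z)]))
    V = np.vstack(verts)

    faces = []
    for k in range(n_slices - 1):
        a = 4 * k
        b = 4 * (k + 1)
        for e in range(4):
            i0, i1 = a + e, a + (e + 1) % 4
            j0, j1 = b + e, b + (e + 1) % 4
            faces.append([i0, i1, j1])
            faces.append([i0, j1, j0])
    faces.append([0, 2, 1])  # bottom cap
    faces.append([0, 3, 2])
    top = 4 * (n_slices - 1)
    faces.append([top, top + 1, top + 2])
    faces.append([top, top + 2, top + 3])

    mesh = trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()

    def contains(points: np.ndarray) -> np.ndarray:
        z = points[:, 2]
        ok = (z > z0) & (z < z1)
        ang = phase + twist_per_mm * (z - z0)
        c, s = np.cos(ang), np.sin(ang)
        # rotate by -ang
        x = c * points[:, 0] + s * points[:, 1]
        y = -s * points[:, 0] + c * points[:, 1]
        ok &= (x > r_in) & (x < r_out) & (np.abs(y) < half_t)
        return ok

    return mesh, contains


def build_implant_proxy(spec: ImplantSpec, sections: int = 96) -> SolidModel:
    """Parametric implant proxy: threaded screw or helical-fin blade.

    Local frame: axis +z, insertion tip at z = overall_length (so the
    proxy shares the femur's axis orientation when positioned).  Screws
    approximate the helical thread with stacked annular ridges; blades
    carry two opposed fins attached tangentially to the shaft.  The
    nail-with-* kinds reuse the respective head element (the nail body
    lies outside the head surrogate and plays no role in cut-out).
    """
    if spec.head_element == "screw":
        return replace(
            _revolve_solid(_screw_profile(spec), label=f"implant-{spec.kind}",
                           sections=sections),
            label=f"implant-{spec.kind}",
        )

    rs = spec.shaft_diameter / 2.0
    shaft_prof = np.array(
        [[0.0, 0.0], [rs, 0.0], [rs, spec.overall_length], [0.0, spec.overall_length]]
    )
    shaft = _revolve_solid(shaft_prof, label="shaft", sections=sections)

    r_out = spec.thread_outer_diameter / 2.0
    z1 = spec.overall_length
    z0 = z1 - spec.thread_length
    twist = math.tan(math.radians(spec.helix_angle_deg)) / max(r_out, 1e-9)
    fins = [
        _twisted_fin(rs, r_out, spec.fin_thickness, z0, z1, twist, phase)
        for phase in (0.0, math.pi)
    ]
    meshes = [shaft.mesh] + [m for m, _ in fins]
    fns = list(shaft._contains_fns) + [fn for _, fn in fins]
    vols = tuple(float(m.volume) for m in meshes)
    mesh = trimesh.util.concatenate(meshes)
    return SolidModel(
        mesh=mesh,
        label=f"implant-{spec.kind}",
        _contains_fns=tuple(fns),
        _component_volumes=vols,
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _box_solid(extents, label: str) -> SolidModel:
    mesh = trimesh.creation.box(extents=extents)
    half = np.asarray(extents, dtype=float) / 2.0

    def contains(points: np.ndarray, half=half) -> np.ndarray:
        return np.all(np.abs(points) < half, axis=1)

    return SolidModel(mesh=mesh, label=label, _contains_fns=(contains,),
                      _component_volumes=(float(mesh.volume),))


def _wedge_solid(spec: AssemblySpec, half_x=60.0, half_y=40.0, depth=50.0) -> SolidModel:
    """Base block whose top face passes through the origin with outward
    normal (sin(beta), 0, cos(beta)); the surface descends toward +x."""
    beta = math.radians(spec.base_angle_deg)
    slope = math.tan(beta)
    z_top = lambda x: -slope * x
    zb = -depth - slope * half_x
    quad_top = [
        (-half_x, -half_y, z_top(-half_x)),
        (half_x, -half_y, z_top(half_x)),
        (half_x, half_y, z_top(half_x)),
        (-half_x, half_y, z_top(-half_x)),
    ]
    quad_bot = [(x, y, zb) for x, y, _ in quad_top]
    V = np.array(quad_bot + quad_top, dtype=float)
    faces = np.array(
        [
            [0, 2, 1], [0, 3, 2],          # bottom
            [4, 5, 6], [4, 6, 7],          # top
            [0, 1, 5], [0, 5, 4],          # y = -half_y
            [3, 7, 6], [3, 6, 2],          # y = +half_y
            [1, 2, 6], [1, 6, 5],          # x = +half_x
            [0, 4, 7], [0, 7, 3],          # x = -half_x
        ]
    )
    mesh = trimesh.Trimesh(vertices=V, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    n = np.array([math.sin(beta), 0.0, math.cos(beta)])

    def contains(points: np.ndarray) -> np.ndarray:
        ok = points @ n < 0.0
        ok &= points[:, 2] > zb
        ok &= np.abs(points[:, 0]) < half_x
        ok &= np.abs(points[:, 1]) < half_y
        return ok

    solid = SolidModel(mesh=mesh, label="base", _contains_fns=(contains,),
                       _component_volumes=(float(mesh.volume),))
    return solid


def base_top_normal(spec: AssemblySpec) -> np.ndarray:
    beta = math.radians(spec.base_angle_deg)
    return np.array([math.sin(beta), 0.0, math.cos(beta)])


def build_shell(spec: AssemblySpec, exposure_start: float | None = None,
                sections: int = 96) -> SolidModel:
    """Steel cortical shell: offset of the femur surface leaving the distal
    exposure band uncovered, with a small apex vent hole so the annular
    profile stays off-axis."""
    R = spec.head_diameter / 2.0
    t = spec.shell_thickness
    a = spec.shell_apex_hole_radius
    e = spec.shell_exposure if exposure_start is None else exposure_start
    L = spec.femur_length
    cap = np.array([0.0, L - R])

    phi_in = math.pi / 2.0 - math.asin(a / R)
    phi_out = math.pi / 2.0 - math.asin(a / (R + t))
    inner = _merge_profile(
        [np.array([[R, e]]), _arc(cap, R, math.pi / 2.0, math.pi / 2.0 - phi_in)]
    )
    outer = _merge_profile(
        [_arc(cap, R + t, math.pi / 2.0 - phi_out, math.pi / 2.0),
         np.array([[R + t, e]])]
    )
    ring = np.vstack([inner, outer, inner[:1]])
    return replace(_revolve_solid(ring, label="shell", sections=sections),
                   label="shell")


def build_acetabulum(spec: AssemblySpec, sections: int = 96) -> SolidModel:
    """Sliding acetabulum: a disc with a spherical recess matching the
    shell-covered head, flat on top for the loading plate.  Local frame:
    the recess sphere center is the origin, axis +z vertical."""
    Rc = spec.head_diameter / 2.0 + spec.shell_thickness + spec.cup_clearance
    rim = math.radians(50.0)
    r_rim = Rc * math.sin(rim)
    z_rim = -Rc * math.cos(rim)
    r_outer = r_rim + 4.0
    z_top = z_rim + 18.0
    prof = _merge_profile(
        [
            np.array([[0.0, -Rc]]),
            _arc((0.0, 0.0), Rc, 0.0, rim)[1:],
            np.array([[r_outer, z_rim], [r_outer, z_top], [0.0, z_top]]),
        ]
    )
    return replace(_revolve_solid(prof, label="acetabulum", sections=sections),
                   label="acetabulum")


def build_fixtures(spec: AssemblySpec, exposure_start: float | None = None
                   ) -> list[SolidModel]:
    """Shell, acetabulum cap, flat loading plate and angled base block,
    each in its own local frame (posing happens at assembly)."""
    shell = build_shell(spec, exposure_start=exposure_start)
    acetabulum = build_acetabulum(spec)
    plate = _box_solid((90.0, 90.0, 12.0), "plate")
    base = _wedge_solid(spec)
    return [shell, acetabulum, plate, base]


# ---------------------------------------------------------------------------
# positioning
# ---------------------------------------------------------------------------


def rotation_about_y(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    T = np.eye(4)
    T[:3, :3] = np.array(
        [[math.cos(a), 0.0, math.sin(a)], [0.0, 1.0, 0.0],
         [-math.sin(a), 0.0, math.cos(a)]]
    )
    return T


def position_implant(
    implant: SolidModel, femur: SolidModel, spec: AssemblySpec,
    implant_length: float | None = None, femur_length: float | None = None,
) -> np.ndarray:
    """World transform that makes the implant axis collinear with the femur
    neck axis with its tip ``tip_to_joint`` short of the head apex.

    Both solids keep their tips/apex on their local +z axis (implant tip at
    z = overall length, femur apex at z = femur length), so the delta is
    computed from the current poses; if the implant is already positioned
    the returned transform is the identity (idempotence).
    """
    if implant_length is None:
        implant_length = float(implant.mesh.bounds[1, 2])
    if femur_length is None:
        femur_length = spec.femur_length
    if spec.tip_to_joint > femur_length:
        raise ValueError("tip-to-joint distance exceeds femur length")

    target_tip_local_z = femur_length - spec.tip_to_joint
    # desired implant pose: femur pose composed with an axial shift placing
    # the tip at the target station on the shared axis
    shift = np.eye(4)
    shift[2, 3] = target_tip_local_z - implant_length
    desired = femur.transform @ shift
    return desired @ np.linalg.inv(implant.transform)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


@dataclass
class DiscretizedSolid:
    """Volumetric particle fill of a rigid solid (world frame)."""

    points: np.ndarray      # (n, 3) centroids, mm
    radius: np.ndarray      # (n,) half-spacing of each particle's level, mm
    surface: np.ndarray     # (n,) bool, True for the refined surface band
    label: str = ""


def _lattice(bounds: np.ndarray, spacing: float) -> np.ndarray:
    lo, hi = bounds
    axes = [np.arange(lo[d] + spacing / 2.0, hi[d], spacing) for d in range(3)]
    if any(len(a) == 0 for a in axes):
        return np.empty((0, 3))
    g = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([x.ravel() for x in g])


def discretize_rigid(
    solid: SolidModel, resolution_range: tuple[float, float]
) -> DiscretizedSolid:
    """Fill a solid with particles: coarse interior, refined surface band.

    ``resolution_range`` is (min_um, max_um).  The interior is a regular
    lattice at the coarse spacing; every coarse cell whose probe stencil
    touches the exterior is replaced by fine-lattice particles, yielding a
    one-band surface refinement toward the minimum resolution.  All
    centroids lie strictly inside the solid.
    """
    min_um, max_um = resolution_range
    if min_um <= 0 or max_um < min_um:
        raise ValueError("need 0 < min resolution <= max resolution")
    fine = min_um * 1e-3
    coarse = max_um * 1e-3
    mesh_world = solid.posed_mesh()
    bounds = np.array(mesh_world.bounds)
    extent = float(np.min(bounds[1] - bounds[0]))
    if coarse > extent:
        import warnings

        warnings.warn(
            f"coarse resolution {coarse:.3f} mm exceeds smallest feature "
            f"{extent:.3f} mm of {solid.label!r}",
            stacklevel=2,
        )

    coarse_pts = _lattice(bounds, coarse)
    inside_c = solid.contains(coarse_pts)
    coarse_pts = coarse_pts[inside_c]

    if fine == coarse:
        return DiscretizedSolid(
            points=coarse_pts,
            radius=np.full(len(coarse_pts), coarse / 2.0),
            surface=np.zeros(len(coarse_pts), dtype=bool),
            label=solid.label,
        )

    # probe stencil: a coarse particle is interior if the six face-neighbor
    # probes at one coarse spacing are all inside
    offsets = coarse * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    interior = np.ones(len(coarse_pts), dtype=bool)
    for off in offsets:
        interior &= solid.contains(coarse_pts + off)

    kept_coarse = coarse_pts[interior]

    # fine particles fill every coarse cell not claimed by an interior point
    fine_pts = _lattice(bounds, fine)
    inside_f = solid.contains(fine_pts)
    fine_pts = fine_pts[inside_f]
    cell_f = np.floor((fine_pts - bounds[0]) / coarse).astype(np.int64)
    cell_c = np.floor((kept_coarse - bounds[0]) / coarse).astype(np.int64)
    dims = np.ceil((bounds[1] - bounds[0]) / coarse).astype(np.int64) + 1
    key_f = (cell_f[:, 0] * dims[1] + cell_f[:, 1]) * dims[2] + cell_f[:, 2]
    key_c = (cell_c[:, 0] * dims[1] + cell_c[:, 1]) * dims[2] + cell_c[:, 2]
    claimed = np.isin(key_f, key_c)
    kept_fine = fine_pts[~claimed]

    points = np.vstack([kept_coarse, kept_fine])
    radius = np.concatenate(
        [np.full(len(kept_coarse), coarse / 2.0), np.full(len(kept_fine), fine / 2.0)]
    )
    surface = np.concatenate(
        [np.zeros(len(kept_coarse), dtype=bool), np.ones(len(kept_fine), dtype=bool)]
    )
    return DiscretizedSolid(points=points, radius=radius, surface=surface,
                            label=solid.label)


def surface_points(
    solid: SolidModel, spacing_mm: float, seed: int = 0
) -> np.ndarray:
    """Deterministic quasi-even surface sample of a posed solid.

    Returns roughly area / spacing^2 points on the boundary (world frame);
    used as smooth contact point sets for rigid bodies.
    """
    mesh = solid.posed_mesh()
    count = max(int(math.ceil(mesh.area / spacing_mm**2)), 32)
    pts, _ = trimesh.sample.sample_surface(mesh, count, seed=seed)
    return np.asarray(pts, dtype=float)


# ---------------------------------------------------------------------------
# generic containment (fallback + oracle)
# ---------------------------------------------------------------------------


def points_in_mesh(
    mesh: trimesh.Trimesh, points: np.ndarray, chunk: int = 2048
) -> np.ndarray:
    """Ray-parity membership test against a closed triangulated surface.

    Vectorized Moller-Trumbore along a fixed, slightly tilted direction so
    rays avoid edge-on hits for lattice-aligned points.  Quadratic in
    (points x triangles) per chunk; intended for moderate meshes and as an
    independent cross-check of the analytic containment functions.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles  # (m, 3, 3)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    d = np.array([0.577350269, 0.211324865, 0.788675134])
    d /= np.linalg.norm(d)

    pvec = np.cross(d, e2)  # (m, 3)
    det = np.einsum("mj,mj->m", e1, pvec)
    ok_tri = np.abs(det) > 1e-12
    inv_det = np.where(ok_tri, 1.0 / np.where(ok_tri, det, 1.0), 0.0)

    inside = np.zeros(len(pts), dtype=bool)
    for s in range(0, len(pts), chunk):
        p = pts[s : s + chunk]
        tvec = p[:, None, :] - v0[None, :, :]  # (c, m, 3)
        u = np.einsum("cmj,mj->cm", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("cmj,j->cm", qvec, d) * inv_det
        t = np.einsum("cmj,mj->cm", qvec, e2) * inv_det
        hit = (
            ok_tri[None, :]
            & (u >= 0.0)
            & (v >= 0.0)
            & (u + v <= 1.0)
            & (t > 1e-9)
        )
        inside[s : s + chunk] = (hit.sum(axis=1) % 2).astype(bool)
    return inside
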