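"""Assembly of the full cut-out bench model from parametric parts.

Global frame: z vertical, loading in -z.  The base block's top surface
passes through the origin with its normal tilted ``base_angle`` (28 deg)
from vertical toward +x, so the femur/implant axis — which lies in the
x-z plane at the complementary 62 deg from vertical — enters the base
obliquely, mirroring the bench rig where the 135-degree sliding-hip-screw
construct sees a clinically representative walking force direction.

Assembly steps: build the femur surrogate, carve the implant cavity by
centroid membership in the femur's local frame, pose everything at the
62-degree inclination, seat the foam on the base plane (particles below
the seat are trimmed — the machined oblique distal face), wrap the foam in
the steel shell (distal exposure band uncovered), stack acetabulum and
loading plate above the head, and wire the six-interface contact graph:
plate-acetabulum, acetabulum-shell, shell-foam, implant-foam,
implant-base (prismatic anti-rotation joint) and foam-base.

A single ``scale`` factor coarsens every particle resolution (foam nominal
400 um, rigid surfaces nominally 160-640 um) so that reduced desk-scale
runs stay around 10^3-10^4 particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .foam import FoamCloud, carve_implant, generate_porous_cloud
from .materials import MaterialModel, foam_material, lookup_material
from .mechanics import (
    ContactPair,
    RigidBody,
    SimulationState,
    assemble_simulation,
    initialize_contact_allowances as mech_init_allowances,
)

__all__ = ["AssemblyModel", "build_assembly", "default_contact_pairs"]

#: simulated plate rate, mm/ms
PLATE_RATE = 2.0
#: smooth-start interval of the prescribed plate velocity, ms (numerical
#: conditioning only; < 2% of the total travel time)
PLATE_RAMP_MS = 0.25


def _plate_motion(t: float) -> np.ndarray:
    rate = PLATE_RATE * min(t / PLATE_RAMP_MS, 1.0)
    return np.array([0.0, 0.0, -rate])


@dataclass
class AssemblyModel:
    """A posed, discretized, contact-wired simulation of one device."""

    state: SimulationState
    spec: geo.AssemblySpec
    implant_spec: geo.ImplantSpec
    solids: dict[str, geo.SolidModel]
    foam_cloud: FoamCloud
    seed: int
    scale: float
    materials_mode: str

    @property
    def implant_axis(self) -> np.ndarray:
        return self.solids["implant"].axis_world


def default_contact_pairs(
    foam_resolution_mm: float,
    mat: MaterialModel,
    sample_spacing_mm: float,
    rigid_point_mass_g: float = 0.02,
) -> list[ContactPair]:
    """The six interfaces of the bench rig.

    Penalty stiffnesses are area-consistent: foam-side contacts carry one
    force per foam particle (stiffness E r), while rigid-rigid interfaces
    carry one force per surface sample whose patch stiffness is the
    penalty modulus E / r times the patch area s^2 — interface stiffness
    then scales with contact area regardless of sampling density.
    Dashpots are near-critical for the mass each contact point carries.
    """
    r = foam_resolution_mm
    k_foam = mat.E * r                         # N/mm per foam particle
    m_foam = mat.density * r**3
    c_foam = math.sqrt(k_foam * m_foam)
    k_rigid = (mat.E / r) * sample_spacing_mm**2
    c_rigid = 0.7 * math.sqrt(k_rigid * rigid_point_mass_g)
    off = r / 2.0
    return [
        ContactPair("plate", "acetabulum", stiffness=k_rigid, friction=0.1,
                    damping=c_rigid),
        ContactPair("acetabulum", "shell", stiffness=k_rigid, friction=0.1,
                    damping=c_rigid),
        ContactPair("foam", "shell", stiffness=k_foam, friction=0.3,
                    gap_offset=off, damping=c_foam),
        ContactPair("foam", "implant", stiffness=k_foam, friction=0.3,
                    gap_offset=off, damping=c_foam),
        ContactPair("implant", "base", kind="joint"),
        ContactPair("foam", "base", stiffness=k_foam, friction=0.3,
                    kind="plane", damping=c_foam),
    ]


def build_assembly(
    implant_kind: str = "screw",
    scale: float = 4.0,
    seed: int = 7,
    materials_mode: str = "static",
    spec: geo.AssemblySpec | None = None,
    implant_spec: geo.ImplantSpec | None = None,
    vf: float | None = None,
    damping_ratio: float = 0.01,
    support_factor: float = 2.4,
) -> AssemblyModel:
    """Build the full cut-out model for one implant proxy.

    ``materials_mode`` selects static or dynamic (10%-derated) foam
    strengths; ``scale`` multiplies all particle resolutions (1.0 is the
    nominal 400 um foam cloud, 4.0 the coarse desk scale).
    """
    spec = spec or geo.AssemblySpec()
    implant_spec = implant_spec or geo.implant_preset(implant_kind)
    fm = foam_material()
    mat = fm.particles(materials_mode)
    if vf is None:
        vf = fm.volume_fraction

    # scale particle properties so the porous network reproduces the
    # overall foam stiffness at this discretization (see benchmarks)
    from dataclasses import replace as _replace

    from .benchmarks import network_compensation

    kappa = network_compensation(400.0 * scale, vf, support_factor)
    mat = _replace(
        mat,
        E=kappa * mat.E,
        yield_stress=kappa * mat.yield_stress,
        ultimate_stress=kappa * mat.ultimate_stress,
    )

    # ---- geometry in the femur's local frame --------------------------
    femur = geo.build_femur_surrogate(spec)
    implant = geo.build_implant_proxy(implant_spec)
    T_impl_local = geo.position_implant(
        implant, femur, spec, implant_length=implant_spec.overall_length
    )
    implant_local = implant.apply_transform(T_impl_local)

    foam_res_um = 400.0 * scale
    cloud = generate_porous_cloud(femur, foam_res_um, vf, seed=seed, material=mat)
    cloud = carve_implant(cloud, implant_local)

    # ---- pose at the 62-degree inclination on the 28-degree seat ------
    axis_deg = spec.implant_axis_from_vertical_deg
    n_seat = geo.base_top_normal(spec)
    a_axis = np.array(
        [math.sin(math.radians(axis_deg)), 0.0, math.cos(math.radians(axis_deg))]
    )
    R_head = spec.head_diameter / 2.0
    tilt = math.degrees(
        math.acos(np.clip(abs(float(a_axis @ n_seat)), 0.0, 1.0))
    )  # angle between axis and seat normal
    sink = R_head * math.sin(math.radians(tilt)) + 0.5
    T_pose = geo.rotation_about_y(axis_deg)
    T_pose[:3, 3] = -sink * n_seat

    femur_w = femur.apply_transform(T_pose)
    implant_w = implant_local.apply_transform(T_pose)
    cloud = cloud.transformed(T_pose)

    # trim the oblique distal seat: particles resting on/above the plane
    r_mm = cloud.resolution_mm
    gap = cloud.centroids @ n_seat
    cloud = cloud.select(gap >= 0.5 * r_mm)

    # shell exposure measured along the axis from the seat-plane crossing
    s0 = sink / float(a_axis @ n_seat)
    shell = geo.build_shell(spec, exposure_start=s0 + spec.shell_exposure)
    shell_w = shell.apply_transform(T_pose)

    acet = geo.build_acetabulum(spec)
    head_center_w = femur_w.point_world([0.0, 0.0, spec.femur_length - R_head])
    T_acet = np.eye(4)
    T_acet[:3, 3] = head_center_w - np.array([0.0, 0.0, 0.9 * spec.cup_clearance])
    acet_w = acet.apply_transform(T_acet)

    plate = geo._box_solid((70.0, 70.0, 10.0), "plate")
    acet_top_z = float(acet_w.posed_mesh().bounds[1, 2])
    T_plate = np.eye(4)
    T_plate[:3, 3] = np.array([head_center_w[0], 0.0, acet_top_z + 5.0 + 0.05])
    plate_w = plate.apply_transform(T_plate)

    base = geo._wedge_solid(spec)

    # ---- rigid contact surfaces ---------------------------------------
    # dense deterministic surface samples give smooth bearing surfaces at
    # a contact radius of half the sample spacing
    steel = lookup_material("steel-316L")
    titanium = lookup_material("titanium-Ti6Al4V")
    sample_spacing = 0.6 * r_mm

    def rigid(sol, mat_r, name, constraint="free", spacing=None, **kw) -> RigidBody:
        s = spacing or sample_spacing
        pts = geo.surface_points(sol, s)
        return RigidBody(
            name=name,
            points=pts,
            radius=np.full(len(pts), s / 2.0),
            mass=sol.volume * mat_r.density,
            constraint=constraint,
            **kw,
        )

    implant_metal = steel if implant_spec.head_element == "screw" else titanium
    bodies = [
        rigid(shell_w, steel, "shell"),
        rigid(acet_w, steel, "acetabulum"),
        rigid(plate_w, steel, "plate", constraint="prescribed",
              motion=_plate_motion, spacing=1.5 * r_mm),
        rigid(implant_w, implant_metal, "implant", constraint="prismatic",
              axis=a_axis),
    ]
    base_disc_pts = _seat_patch(spec, r_mm)
    base_body = RigidBody(
        name="base",
        points=base_disc_pts,
        radius=np.full(len(base_disc_pts), r_mm / 2.0),
        mass=base.volume * steel.density,
        constraint="fixed",
        plane=(np.zeros(3), n_seat),
    )
    bodies.append(base_body)

    n_rigid_pts = sum(len(b.points) for b in bodies[:2])
    point_mass = min(b.mass for b in bodies[:2]) / max(n_rigid_pts, 1)
    pairs = default_contact_pairs(r_mm, mat, sample_spacing,
                                  rigid_point_mass_g=point_mass)
    state = assemble_simulation(
        cloud,
        bodies,
        mat,
        pairs,
        support_factor=support_factor,
        damping_ratio=damping_ratio,
        check_overlap=False,  # stacked near-touch fixtures are intentional
    )
    state.contact_ramp_ms = PLATE_RAMP_MS
    mech_init_allowances(state)

    solids = {
        "femur": femur_w,
        "implant": implant_w,
        "shell": shell_w,
        "acetabulum": acet_w,
        "plate": plate_w,
        "base": base,
    }
    return AssemblyModel(
        state=state,
        spec=spec,
        implant_spec=implant_spec,
        solids=solids,
        foam_cloud=cloud,
        seed=seed,
        scale=scale,
        materials_mode=materials_mode,
    )


def _seat_patch(spec: geo.AssemblySpec, r_mm: float, half: float = 45.0) -> np.ndarray:
    """Point grid on the base top plane (visualization / bookkeeping)."""
    n = geo.base_top_normal(spec)
    beta = math.radians(spec.base_angle_deg)
    t1 = np.array([math.cos(beta), 0.0, -math.sin(beta)])  # downhill tangent
    t2 = np.array([0.0, 1.0, 0.0])
    u = np.arange(-half, half + 1e-9, 4.0 * r_mm)
    U, V = np.meshgrid(u, u, indexing="ij")
    pts = U.ravel()[:, None] * t1 + V.ravel()[:, None] * t2
    return pts - (r_mm / 2.0) * n
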