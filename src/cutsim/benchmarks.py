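"""Canonical solver validation problems.

Small self-contained set-ups used by the test-suite and the acceptance
script: confined uniaxial crush of a particle block between rigid platens
(against the closed-form neo-Hookean stress-stretch curve), effective
modulus of porous blocks as a function of volume fraction, and a bonded
two-particle oscillator.

The crush comparison pairs the *transmitted force* with the *measured bulk
stretch* (mean F_zz over the mid-slab): nodal-integration mesh-free
discretizations carry a stiffened boundary row about one particle deep, so
the nominal platen strain overstates the bulk strain by a resolution-
dependent margin while the stress-stretch relation itself is reproduced
closely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from . import mechanics as mech
from .foam import generate_porous_cloud
from .geometry import _box_solid
from .materials import MaterialModel, lame_parameters

__all__ = [
    "CrushSample",
    "confined_crush",
    "closed_form_confined_stress",
    "effective_modulus",
]


def closed_form_confined_stress(stretch: float, mat: MaterialModel) -> float:
    """Axial Cauchy stress under uniaxial strain F = diag(1, 1, stretch).

    sigma_zz = (mu (stretch^2 - 1) + lambda ln stretch) / stretch  [MPa]
    """
    mu, lam = lame_parameters(mat)
    return (mu * (stretch**2 - 1.0) + lam * math.log(stretch)) / stretch


@dataclass
class CrushSample:
    nominal_strain: float
    bulk_stretch: float
    force_N: float
    closed_form_N: float

    @property
    def relative_error(self) -> float:
        return abs(self.force_N / self.closed_form_N - 1.0)


def _block_state(
    edge_mm: float,
    resolution_um: float,
    vf: float,
    mat: MaterialModel,
    seed: int,
    damping_ratio: float = 1.0,
    support_factor: float = 2.0,
):
    cube = _box_solid((edge_mm, edge_mm, edge_mm), "block")
    cloud = generate_porous_cloud(cube, resolution_um, vf, seed=seed)
    st = mech.assemble_simulation(
        cloud, [], mat, [],
        damping_ratio=damping_ratio, support_factor=support_factor,
    )
    X = st.X
    zmin, zmax = X[:, 2].min(), X[:, 2].max()
    bottom = X[:, 2] < zmin + 1e-6
    top = X[:, 2] > zmax - 1e-6
    fix = np.zeros((st.n, 3), dtype=bool)
    fix[:, 0] = fix[:, 1] = True      # lateral confinement (uniaxial strain)
    fix[bottom, 2] = True
    st.fix_mask = fix
    st.prescribed_mask = top
    return st, bottom, top, zmax - zmin


def confined_crush(
    edge_mm: float = 6.0,
    resolution_um: float = 1000.0,
    mat: MaterialModel | None = None,
    nominal_strains: tuple[float, ...] = (0.02, 0.035, 0.05),
    vf: float = 1.0,
    seed: int = 0,
    rate_mm_ms: float = 0.3,
    settle_steps: int = 2500,
    suppress_damage: bool = True,
) -> list[CrushSample]:
    """Quasi-static confined compression of a particle block.

    The top node layer is driven downward at ``rate_mm_ms`` with strong
    damping; at each target nominal strain the platen holds, the block
    relaxes, and the transmitted force at the fixed bottom layer is
    compared with the closed-form confined neo-Hookean stress evaluated at
    the measured bulk stretch.
    """
    if mat is None:
        from .materials import lookup_material

        mat = lookup_material("foam-10PCF-compact-static")
    if suppress_damage:
        mat = replace(mat, yield_stress=None, ultimate_stress=None)
        mat = replace(mat, yield_stress=1e9, ultimate_stress=1e9)

    st, bottom, top, H = _block_state(edge_mm, resolution_um, vf, mat, seed)
    X = st.X
    vel = [-rate_mm_ms]
    st.prescribed_velocity = lambda t: np.array([0.0, 0.0, vel[0]])
    dt = mech.stable_dt(st)
    area = edge_mm * edge_mm

    mid = (X[:, 2] > X[:, 2].min() + 0.25 * H) & (X[:, 2] < X[:, 2].max() - 0.25 * H)
    samples = []
    for target in nominal_strains:
        vel[0] = -rate_mm_ms
        guard = 0
        while True:
            mech.advance(st, dt)
            guard += 1
            eps = -(st.x[top][:, 2].mean() - X[top][:, 2].mean()) / H
            if eps >= target or guard > 500_000:
                break
        vel[0] = 0.0
        for _ in range(settle_steps):
            mech.advance(st, dt)
        force = -st.last_forces[bottom][:, 2].sum()
        F = mech.deformation_gradients(st)
        stretch = float(F[mid][:, 2, 2].mean())
        exact = -closed_form_confined_stress(stretch, mat) * area * (
            1.0 if vf >= 1.0 else vf
        )
        samples.append(CrushSample(target, stretch, float(force), float(exact)))
    return samples


@lru_cache(maxsize=32)
def network_compensation(
    resolution_um: float,
    vf: float = 0.14,
    support_factor: float = 2.4,
    seed: int = 3,
) -> float:
    """Discretization compensation for porous-network softening.

    A quasi-random porous cloud at a given resolution and support retains
    only part of the compact-polymer stiffness through its bond network,
    and the retained fraction depends on the discretization.  Following
    the same logic as the bench calibration that maps overall foam
    properties to compact-particle properties, this factor scales the
    particle modulus and strengths so that the porous cloud's confined
    effective modulus reproduces the overall foam target
    M = E (1 - nu) / ((1 + nu)(1 - 2 nu)) with E = 58 MPa, nu = 0.30.

    Computed once per (resolution, vf, support) from the confined-crush
    benchmark on a small block and cached; deterministic.
    """
    from .materials import foam_material

    fm = foam_material()
    overall = fm.overall
    m_target = (
        overall.E
        * (1.0 - overall.nu)
        / ((1.0 + overall.nu) * (1.0 - 2.0 * overall.nu))
    )
    r_mm = resolution_um * 1e-3
    edge = max(8.0, 9.0 * r_mm)
    measured = effective_modulus(
        vf,
        edge_mm=edge,
        resolution_um=resolution_um,
        mat=fm.compact_static,
        seed=seed,
        support_factor=support_factor,
    )
    return m_target / measured


def effective_modulus(
    vf: float,
    edge_mm: float = 12.0,
    resolution_um: float = 1000.0,
    mat: MaterialModel | None = None,
    strain: float = 0.025,
    seed: int = 3,
    support_factor: float = 2.0,
) -> float:
    """Small-strain confined effective modulus (MPa) of a porous block.

    Transmitted stress divided by nominal platen strain; used to verify
    that stiffness grows monotonically with volume fraction.  The block
    must hold enough particles for the bond network to percolate at the
    lowest volume fraction of interest, hence the 12 mm default edge; the
    reaction is averaged over the settle window to suppress ringing.
    """
    if mat is None:
        from .materials import lookup_material

        mat = lookup_material("foam-10PCF-compact-static")
    mat = replace(mat, yield_stress=1e9, ultimate_stress=1e9)
    st, bottom, top, H = _block_state(edge_mm, resolution_um, vf, mat, seed,
                                      support_factor=support_factor)
    vel = [-0.3]
    st.prescribed_velocity = lambda t: np.array([0.0, 0.0, vel[0]])
    dt = mech.stable_dt(st)
    guard = 0
    while True:
        mech.advance(st, dt)
        guard += 1
        eps = -(st.x[top][:, 2].mean() - st.X[top][:, 2].mean()) / H
        if eps >= strain or guard > 500_000:
            break
    vel[0] = 0.0
    acc = 0.0
    n_avg = 0
    for k in range(2500):
        mech.advance(st, dt)
        if k >= 1500:
            acc += -st.last_forces[bottom][:, 2].sum()
            n_avg += 1
    force = acc / n_avg
    return float(force / (edge_mm * edge_mm) / strain)
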