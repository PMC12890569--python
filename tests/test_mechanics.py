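"""Explicit solver: kinematics, constitutive transmission, contact, damage."""

import numpy as np
import pytest

from cutsim import mechanics as mech
from cutsim.benchmarks import confined_crush
from cutsim.foam import FoamCloud, generate_porous_cloud
from cutsim.geometry import _box_solid
from cutsim.materials import FAILED, YIELDING, lookup_material


@pytest.fixture(scope="module")
def foam_mat():
    return lookup_material("foam-10PCF-compact-static")


def _single_particle_state(foam_mat):
    cloud = FoamCloud(
        np.zeros((1, 3)), 400.0, np.zeros(1, dtype=np.uint8), vf_target=1.0
    )
    return mech.assemble_simulation(cloud, [], foam_mat, [],
                                    damping_ratio=0.0, hourglass=0.0)


class TestKinematics:
    def test_free_particle_newtons_law(self, foam_mat):
        st = _single_particle_state(foam_mat)
        F = 1.0e-3  # N
        st.external_force = np.array([[F, 0.0, 0.0]])
        dt, t_end = 1e-3, 1.0
        for _ in range(int(t_end / dt)):
            mech.advance(st, dt)
        m = foam_mat.density * 0.4**3
        assert st.v[0, 0] == pytest.approx(F * t_end / m, rel=1e-6)

    def test_equilibrium_preserved_without_load(self, foam_mat, cube10):
        cloud = generate_porous_cloud(cube10, 1000.0, 1.0, seed=0)
        st = mech.assemble_simulation(cloud, [], foam_mat, [])
        for _ in range(20):
            mech.advance(st, 1e-3)
        assert np.abs(st.v).max() < 1e-10
        assert np.abs(st.x - st.X).max() < 1e-10

    def test_two_bonded_particles_oscillate_at_linearized_frequency(self, foam_mat):
        d0 = 1.0
        cloud = FoamCloud(
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d0]]),
            1000.0,
            np.zeros(2, dtype=np.uint8),
            vf_target=1.0,
        )
        st = mech.assemble_simulation(cloud, [], foam_mat, [],
                                      damping_ratio=0.0, hourglass=0.0)

        # independent stiffness oracle: numerical derivative of the axial
        # pair force with respect to separation
        def axial_force(dz):
            st.x = st.X.copy()
            st.x[1, 2] += dz
            f, _, _ = mech.internal_forces(st)
            return f[1, 2]

        h = 1e-6
        k = -(axial_force(h) - axial_force(-h)) / (2 * h)
        assert k > 0
        m = foam_mat.density  # 1 mm^3 particles
        omega = np.sqrt(k / (m / 2.0))  # reduced-mass two-body frequency

        # simulate a small symmetric stretch and time the oscillation
        st.x = st.X.copy()
        st.v = np.zeros_like(st.v)
        amp = 1e-4
        st.x[0, 2] -= amp / 2
        st.x[1, 2] += amp / 2
        dt = 0.02 / omega
        rel_prev = amp
        crossings = []
        t = 0.0
        for _ in range(20000):
            mech.advance(st, dt)
            t += dt
            rel = st.x[1, 2] - st.x[0, 2] - d0
            if rel_prev > 0 >= rel:
                crossings.append(t)
                if len(crossings) == 4:
                    break
            rel_prev = rel
        period = np.mean(np.diff(crossings))
        assert 2 * np.pi / period == pytest.approx(omega, rel=0.02)


class TestCrushOracle:
    def test_confined_crush_matches_closed_form(self):
        samples = confined_crush(edge_mm=5.0, nominal_strains=(0.03, 0.05),
                                 settle_steps=2000)
        for s in samples:
            assert s.relative_error < 0.05, (s.nominal_strain, s.relative_error)

    def test_yielding_caps_transmitted_force(self, foam_mat):
        # with damage enabled the same crush transmits no more than the
        # yield-capped envelope
        elastic = confined_crush(edge_mm=5.0, nominal_strains=(0.05,),
                                 settle_steps=1500, suppress_damage=True)[0]
        damaged = confined_crush(edge_mm=5.0, nominal_strains=(0.05,),
                                 settle_steps=1500, suppress_damage=False)[0]
        assert damaged.force_N <= elastic.force_N + 1e-6


class TestDamageEvolution:
    def test_counts_monotone_under_increasing_crush(self, foam_mat, cube10):
        cloud = generate_porous_cloud(cube10, 1250.0, 1.0, seed=0)
        st = mech.assemble_simulation(cloud, [], foam_mat, [], damping_ratio=1.0)
        X = st.X
        top = X[:, 2] > X[:, 2].max() - 1e-6
        bottom = X[:, 2] < X[:, 2].min() + 1e-6
        fix = np.zeros((st.n, 3), dtype=bool)
        fix[:, 0] = fix[:, 1] = True
        fix[bottom, 2] = True
        st.fix_mask = fix
        st.prescribed_mask = top
        st.prescribed_velocity = lambda t: np.array([0.0, 0.0, -0.8])
        dt = mech.stable_dt(st)
        prev_states = st.state.copy()
        prev_counts = (0, 0)
        for _ in range(800):
            mech.advance(st, dt)
            assert np.all(st.state >= prev_states)  # per-particle one-way
            counts = (st.yielding_count + st.failed_count, st.failed_count)
            assert counts[0] >= prev_counts[0] and counts[1] >= prev_counts[1]
            prev_states = st.state.copy()
            prev_counts = counts
        assert st.failed_count > 0  # the crush actually damaged material


class TestContact:
    def _foam_on_body_state(self, foam_mat):
        # one foam particle pressed against a flat rigid patch
        cloud = FoamCloud(
            np.array([[0.0, 0.0, 0.45]]), 1000.0, np.zeros(1, dtype=np.uint8),
            vf_target=1.0,
        )
        g = np.linspace(-2.0, 2.0, 9)
        gx, gy = np.meshgrid(g, g)
        pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        body = mech.RigidBody(
            name="patch", points=pts, radius=np.full(len(pts), 0.25),
            mass=10.0, constraint="free",
        )
        pair = mech.ContactPair("foam", "patch", stiffness=100.0, friction=0.0)
        st = mech.assemble_simulation(cloud, [body], foam_mat, [pair],
                                      damping_ratio=0.0, hourglass=0.0)
        return st

    def test_newtons_third_law_audit(self, foam_mat):
        st = self._foam_on_body_state(foam_mat)
        mech.advance(st, 1e-4)
        (fa, fb), = st.contact_forces_last.values()
        assert np.linalg.norm(fa) > 0  # contact engaged
        assert np.allclose(fa + fb, 0.0, atol=1e-6 * np.linalg.norm(fa))

    def test_prismatic_joint_translates_axially_only(self, foam_mat):
        # foam particle pressing obliquely on a prismatic rod: velocity may
        # develop along the joint axis only, with the off-axis reaction
        # reported at the base
        cloud = FoamCloud(
            np.array([[0.3, 0.0, 0.4]]), 1000.0, np.zeros(1, dtype=np.uint8),
            vf_target=1.0,
        )
        z = np.linspace(-5.0, 5.0, 21)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        axis = np.array([0.0, 0.0, 1.0])
        rod = mech.RigidBody(
            name="rod", points=pts, radius=np.full(len(pts), 0.3),
            mass=5.0, constraint="prismatic", axis=axis,
        )
        pair = mech.ContactPair("foam", "rod", stiffness=50.0, friction=0.3)
        st = mech.assemble_simulation(cloud, [rod], foam_mat, [pair],
                                      damping_ratio=0.0, hourglass=0.0)
        st.reaction_body = "rod"
        for _ in range(50):
            mech.advance(st, 1e-3)
        v = st.bodies["rod"].v
        assert np.linalg.norm(v - (v @ axis) * axis) < 1e-12
        u = st.bodies["rod"].u
        assert np.linalg.norm(u - (u @ axis) * axis) < 1e-12

    def test_rigid_body_stays_undeformed(self, foam_mat):
        st = self._foam_on_body_state(foam_mat)
        body = st.bodies["patch"]
        d0 = np.linalg.norm(body.points[0] - body.points[-1])
        for _ in range(100):
            mech.advance(st, 1e-3)
        pts = body.current_points
        assert np.linalg.norm(pts[0] - pts[-1]) == pytest.approx(d0, abs=1e-9)


class TestDeterminism:
    def test_identical_seeds_give_bitwise_identical_trajectories(self, foam_mat):
        def run():
            cube = _box_solid((6.0, 6.0, 6.0), "c")
            cloud = generate_porous_cloud(cube, 1200.0, 0.14, seed=5)
            st = mech.assemble_simulation(cloud, [], foam_mat, [])
            X = st.X
            top = X[:, 2] > X[:, 2].max() - 1e-6
            bottom = X[:, 2] < X[:, 2].min() + 1e-6
            fix = np.zeros((st.n, 3), dtype=bool)
            fix[bottom] = True
            st.fix_mask = fix
            st.prescribed_mask = top
            st.prescribed_velocity = lambda t: np.array([0.0, 0.0, -0.2])
            dt = mech.stable_dt(st)
            for _ in range(200):
                mech.advance(st, dt)
            return st.x.copy(), st.state.copy()

        x1, s1 = run()
        x2, s2 = run()
        assert np.array_equal(x1, x2)
        assert np.array_equal(s1, s2)
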