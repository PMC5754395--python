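"""Mesh construction, constitutive laws, dynamics and stress adaptation."""

import dataclasses

import numpy as np
import pytest

from emgface import fem
from emgface.mapping import ActivationSet
from emgface.synthetic import gen_activation_truth, truth_to_activation


def activation_for(model, frames, value=0.0, duration=2.0):
    labels = [m.name for m in model.muscles]
    return ActivationSet(
        values=np.full((len(labels), frames), float(value)),
        times=np.linspace(0.0, duration, frames),
        labels=labels, strategy="act_all",
    )


def single_hex_model():
    """A unit-cube single-element model (no muscles, free nodes)."""
    nodes = np.array([[x, y, z] for z in (0.0, 1.0) for y in (0.0, 1.0)
                      for x in (0.0, 1.0)])
    elems = np.array([[0, 1, 3, 2, 4, 5, 7, 6]])
    return fem.LipModel(
        nodes=nodes, elems=elems, layers=np.array(["outer"]),
        fixed=np.array([], dtype=int),
        marker_nodes=np.arange(8)[:1], marker_names=["n0"],
        material=fem.MaterialParams(gravity=(0, 0, 0)),
    )


class TestMesh:
    def test_default_element_and_node_count(self):
        model = fem.build_lip_mesh()
        assert model.n_elements == 2 * 16 * 4 * 3 == 384
        assert model.n_nodes == 2 * 17 * 5 * 4

    def test_inner_surface_nodes_are_fixed(self):
        model = fem.build_lip_mesh()
        cfg = model.mesh_config
        r = np.linalg.norm(model.nodes[:, [0, 2]], axis=1)
        inner = np.nonzero(np.abs(r - cfg.r_inner) < 1e-9)[0]
        assert set(inner) == set(model.fixed)
        assert model.fixed.size > 0

    def test_volume_matches_analytic_arc_slab(self):
        model = fem.build_lip_mesh()
        vol = model.assembly().w.sum()
        ref = model.mesh_config.analytic_volume()
        assert abs(vol - ref) / ref < 0.01

    def test_three_layers_labelled(self):
        model = fem.build_lip_mesh()
        assert set(model.layers) == {"inner", "centre", "outer"}

    def test_markers_on_outer_surface(self):
        model = fem.build_lip_mesh()
        cfg = model.mesh_config
        r = np.linalg.norm(model.nodes[model.marker_nodes][:, [0, 2]],
                           axis=1)
        np.testing.assert_allclose(r, cfg.r_outer)
        assert len(model.marker_nodes) == 10


class TestMuscleAssignment:
    def test_distance_rule_inclusion_boundary(self):
        model = single_hex_model()
        # element centroid at (0.5, 0.5, 0.5)
        near = fem.MuscleDef("near", [[0.5 - 4.0, 0.5, 0.5],
                                      [0.5 + 4.0, 0.5, 0.5]])
        # line at exactly 4 mm vertical offset -> included (4 <= 5)
        near.polyline[:, 1] += 4.0
        ids, dirs = fem.assign_muscle_elements(model, near, radius=5.0)
        assert list(ids) == [0]
        np.testing.assert_allclose(np.abs(dirs[0]), [1.0, 0.0, 0.0])

    def test_distance_rule_exclusion(self):
        model = single_hex_model()
        far = fem.MuscleDef("far", [[-1.0, 6.5, 0.5], [2.0, 6.5, 0.5]])
        with pytest.warns(UserWarning, match="inactive"):
            ids, _ = fem.assign_muscle_elements(model, far, radius=5.0)
        assert ids.size == 0

    def test_manual_override_hook(self):
        model = single_hex_model()
        manual = fem.MuscleDef("manual", [[0, 40, 0], [1, 40, 0]],
                               elements=np.array([0]))
        ids, dirs = fem.assign_muscle_elements(model, manual)
        assert list(ids) == [0]

    def test_matches_bruteforce_distance_scan(self, small_model):
        rng = np.random.default_rng(17)
        centroids = small_model.nodes[small_model.elems].mean(axis=1)

        def seg_dist(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            return np.linalg.norm(p - (a + t * ab))

        for trial in range(50):
            pts = rng.uniform([-40, -15, 20], [40, 15, 40], (3, 3))
            muscle = fem.MuscleDef(f"rand{trial}", pts)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ids, _ = fem.assign_muscle_elements(small_model, muscle,
                                                    radius=5.0)
            brute = [
                e for e in range(small_model.n_elements)
                if min(seg_dist(centroids[e], pts[s], pts[s + 1])
                       for s in range(2)) <= 5.0
            ]
            assert list(ids) == brute


class TestMooneyRivlin:
    def test_reference_state_is_stress_free(self):
        W, sigma = fem.mooney_rivlin_energy(np.eye(3))
        assert W == 0.0
        np.testing.assert_array_equal(sigma, 0.0)

    def test_isochoric_uniaxial_energy_hand_value(self):
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        I1 = lam**2 + 2.0 / lam
        expected = 2.5 * (I1 - 3) + 1.175 * (I1 - 3) ** 2
        W, _ = fem.mooney_rivlin_energy(F)
        assert W == pytest.approx(expected, rel=1e-12)

    def test_stress_is_energy_consistent(self):
        rng = np.random.default_rng(0)
        mat = fem.MaterialParams()
        checked = 0
        while checked < 20:
            F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
            if not 0.8 <= np.linalg.det(F) <= 1.2:
                continue
            checked += 1
            P = fem.mr_first_piola(F, mat)
            Pfd = np.zeros((3, 3))
            h = 1e-6
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    Wp, _, _ = fem._mr_energy_piola(Fp, mat)
                    Wm, _, _ = fem._mr_energy_piola(Fm, mat)
                    Pfd[i, j] = (Wp - Wm) / (2 * h)
            assert np.abs(P - Pfd).max() / np.abs(P).max() < 1e-6

    def test_inverted_gradient_rejected(self):
        with pytest.raises(fem.InvertedElementError):
            fem.mooney_rivlin_energy(np.diag([1.0, 1.0, -1.0]))

    @pytest.mark.parametrize("lam", [1.05, 1.1, 1.2])
    def test_single_element_patch_reproduces_closed_form(self, lam):
        """Prescribed isochoric uniaxial stretch on one hex: the traction
        recovered from assembled nodal forces matches the closed-form
        Cauchy stress (deviatoric push-forward of the invariant law)."""
        model = single_hex_model()
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        x = model.nodes @ F.T
        _, forces = fem.internal_energy_and_forces(model, x)
        # closed form: sigma = (2/J)(C10 + 2 C20 (I1~-3)) dev(B~) (J = 1)
        mat = model.material
        B = F @ F.T
        I1 = np.trace(B)
        sigma_ref = 2.0 * (mat.c10 + 2 * mat.c20 * (I1 - 3)) * \
            (B - I1 / 3 * np.eye(3))
        # traction on the +x face (nodes with X=1): force / deformed area
        face = np.nonzero(model.nodes[:, 0] == 1.0)[0]
        area = lam**-1.0  # 1*lam^-.5 x 1*lam^-.5
        traction = -forces[face].sum(axis=0) / area
        assert traction[0] == pytest.approx(sigma_ref[0, 0], rel=0.01)


class TestMuscleLaw:
    MUSCLE = fem.MuscleDef("m", [[0, 0, 0], [1, 0, 0]])

    def test_rest_state_passive_stress_is_zero(self):
        assert fem.muscle_fibre_stress(1.0, 0.0, self.MUSCLE) == 0.0

    def test_full_activation_at_optimal_length_gives_sigma_max(self):
        s = fem.muscle_fibre_stress(1.0, 1.0, self.MUSCLE, sigma_max=123.0)
        assert s == pytest.approx(123.0)

    def test_passive_law_c1_continuous_at_lam_star(self):
        m = self.MUSCLE
        eps = 1e-7
        below = fem.muscle_fibre_stress(m.lam_star - eps, 0.0, m, 1.0)
        above = fem.muscle_fibre_stress(m.lam_star + eps, 0.0, m, 1.0)
        exact = m.p1 * (np.exp(m.p2 * (m.lam_star - 1)) - 1)
        assert abs(float(below) - exact) < 1e-6
        assert abs(float(above) - exact) < 1e-6
        # slopes of the two branches agree analytically at lam*
        slope_exp = m.p1 * m.p2 * np.exp(m.p2 * (m.lam_star - 1))
        slope_fd = (fem.muscle_fibre_stress(m.lam_star + eps, 0.0, m, 1.0)
                    - exact) / eps
        assert abs(float(slope_fd) - slope_exp) / slope_exp < 1e-5

    def test_linear_branch_beyond_lam_star(self):
        m = self.MUSCLE
        s1 = float(fem.muscle_fibre_stress(1.5, 0.0, m, 1.0))
        s2 = float(fem.muscle_fibre_stress(1.6, 0.0, m, 1.0))
        s3 = float(fem.muscle_fibre_stress(1.7, 0.0, m, 1.0))
        assert s3 - s2 == pytest.approx(s2 - s1, rel=1e-9)

    def test_activation_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="activation"):
            fem.muscle_fibre_stress(1.0, 1.5, self.MUSCLE)

    def test_fibre_energy_derivative_matches_stress(self):
        lam = np.linspace(0.55, 1.8, 40)
        h = 1e-7
        Wp, _ = fem.fibre_energy(lam + h, 0.6, self.MUSCLE, 200.0)
        Wm, _ = fem.fibre_energy(lam - h, 0.6, self.MUSCLE, 200.0)
        _, dW = fem.fibre_energy(lam, 0.6, self.MUSCLE, 200.0)
        np.testing.assert_allclose((Wp - Wm) / (2 * h), dW, atol=1e-4)


class TestInternalForces:
    def test_forces_equal_negative_energy_gradient(self, tiny_model):
        rng = np.random.default_rng(1)
        x = tiny_model.nodes + 0.05 * rng.standard_normal(
            tiny_model.nodes.shape
        )
        act = np.full(len(tiny_model.muscles), 0.3)
        _, f = fem.internal_energy_and_forces(tiny_model, x, act)
        h = 1e-6
        for a in rng.choice(tiny_model.n_nodes, 12, replace=False):
            for c in range(3):
                xp, xm = x.copy(), x.copy()
                xp[a, c] += h
                xm[a, c] -= h
                ep, _ = fem.internal_energy_and_forces(tiny_model, xp, act)
                em, _ = fem.internal_energy_and_forces(tiny_model, xm, act)
                fd = -(ep - em) / (2 * h)
                assert fd == pytest.approx(f[a, c], rel=1e-5, abs=1e-8)


class TestSimulate:
    def test_rest_equilibrium_without_gravity(self, tiny_model):
        model = dataclasses.replace(
            tiny_model,
            material=fem.MaterialParams(gravity=(0, 0, 0)),
            _assembly=None,
        )
        traj = fem.simulate(model, activation_for(model, 160))
        drift = np.abs(traj.positions
                       - model.nodes[model.marker_nodes][:, None, :])
        assert drift.max() < 1e-9

    def test_mirror_symmetric_instruction_gives_mirror_motion(
            self, tiny_model):
        truth = gen_activation_truth("A", 2.0, seed=3)
        act = truth_to_activation(truth, 24)
        traj = fem.simulate(tiny_model, act, duration=2.0, pgtol=1e-7)
        mirror = [4, 3, 2, 1, 0, 9, 8, 7, 6, 5]
        flipped = traj.positions[mirror] * np.array([-1.0, 1.0, 1.0])
        assert np.abs(traj.positions - flipped).max() < 1e-6

    def test_objectivity_under_reference_rotation(self, tiny_model):
        from scipy.spatial.transform import Rotation
        truth = gen_activation_truth("A", 2.0, seed=3)
        act = truth_to_activation(truth, 12)
        base = fem.simulate(tiny_model, act, duration=2.0, pgtol=1e-7)
        R = Rotation.from_rotvec([0.4, 0.2, -0.3]).as_matrix()
        rotated = fem.simulate(tiny_model.rotated(R), act, duration=2.0,
                               pgtol=1e-7)
        err = np.sqrt(np.mean(
            (rotated.positions - base.positions @ R.T) ** 2
        ))
        assert err < 1e-6

    def test_peak_displacement_monotone_in_activation_scale(
            self, tiny_model):
        truth = gen_activation_truth("A", 2.0, seed=3)
        act = truth_to_activation(truth, 16)
        rest = tiny_model.nodes[tiny_model.marker_nodes][:, None, :]
        peaks = []
        for scale in (0.25, 0.5, 0.75, 1.0):
            scaled = dataclasses.replace(
                act, values=np.clip(scale * act.values, 0, 1)
            )
            traj = fem.simulate(tiny_model, scaled, duration=2.0)
            peaks.append(np.abs(traj.positions - rest).max())
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))

    def test_volumetric_penalty_generates_restoring_pressure(
            self, tiny_model):
        """Soft incompressibility keeps passive (gravity-only) volume
        ratios within a fraction of a percent of unity, and stiffening
        the bulk penalty monotonically tightens the volume excursions
        of an actively driven run."""
        truth = gen_activation_truth("A", 2.0, seed=3)
        act = truth_to_activation(truth, 24)
        passive = dataclasses.replace(
            act, values=np.zeros_like(act.values)
        )
        monitor: list = []
        fem.simulate(tiny_model, passive, duration=2.0, j_monitor=monitor)
        assert all(0.995 <= j <= 1.005 for pair in monitor for j in pair)

        excursions = []
        for bulk in (25.0, 100.0, 400.0):
            model = dataclasses.replace(
                tiny_model,
                material=dataclasses.replace(tiny_model.material,
                                             bulk_modulus=bulk),
                _assembly=None,
            )
            mon: list = []
            fem.simulate(model, act, duration=2.0, j_monitor=mon)
            jmin = min(j for j, _ in mon)
            jmax = max(j for _, j in mon)
            excursions.append(max(1.0 - jmin, jmax - 1.0))
        assert excursions[0] > excursions[1] > excursions[2]


class TestAdaptSigmaMax:
    def test_clean_scenario_returns_start_after_one_run(self, tiny_model):
        calls = []

        def fake_sim(model, act, **kw):
            calls.append(model.sigma_max)
            return "traj"

        res = fem.adapt_sigma_max(tiny_model, None, simulate_fn=fake_sim)
        assert res.sigma_max == 300.0
        assert calls == [300.0]

    def test_two_failures_give_243_kpa(self, tiny_model):
        def fake_sim(model, act, **kw):
            if model.sigma_max > 250.0:
                raise fem.InvertedElementError(5, step=2)
            return "traj"

        res = fem.adapt_sigma_max(tiny_model, None, simulate_fn=fake_sim)
        assert res.sigma_max == pytest.approx(300.0 * 0.9**2)
        assert res.attempts == pytest.approx([300.0, 270.0, 243.0])

    def test_attempt_sequence_is_geometric(self, tiny_model):
        def fake_sim(model, act, **kw):
            if model.sigma_max > 100.0:
                raise fem.InvertedElementError(0)
            return "traj"

        res = fem.adapt_sigma_max(tiny_model, None, simulate_fn=fake_sim)
        ratios = np.diff(np.log(res.attempts))
        np.testing.assert_allclose(ratios, np.log(0.9), rtol=1e-12)

    def test_floor_reached_raises_cannot_stabilise(self, tiny_model):
        def fake_sim(model, act, **kw):
            raise fem.InvertedElementError(0)

        with pytest.raises(fem.SimulationError, match="cannot stabilise"):
            fem.adapt_sigma_max(tiny_model, None, floor=200.0,
                                simulate_fn=fake_sim)
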