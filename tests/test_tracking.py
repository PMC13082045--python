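"""Tracking objective, transcription structure, and solution assembly.

Solver-level behavior (convergence, physics of solutions) is covered by the
acceptance tests; these tests exercise the parts that do not need an NLP
solve.
"""

import numpy as np
import pytest

from exorun import muscles as mu
from exorun import tracking as tr
from exorun.contact import ExotendonSpec


@pytest.fixture(scope="module")
def config():
    return tr.OcpConfig(mesh_intervals=10, maxiter=5)


@pytest.fixture(scope="module")
def problem(model, reference, config):
    return tr.build_tracking_problem(model, reference, None, config)


def fabricate_solution(model, reference, problem, met_w_per_muscle=40.0):
    """An OcpSolution filled from the reference data (no solve)."""
    n = problem.n_nodes
    t = problem._node_time
    coords = problem._cref.copy()
    speeds = np.gradient(coords, t, axis=0)
    grf_r, grf_l = reference.grf_at(problem._node_phase)
    sol = tr.OcpSolution(
        time=t, coords=coords, speeds=speeds,
        activations=np.full((n, 18), 0.3), excitations=np.full((n, 18), 0.3),
        torques=np.zeros((n, 5)), grf_r=grf_r, grf_l=grf_l,
        met_rate=np.full((n, 18), met_w_per_muscle),
        objective=0.0, objective_breakdown={}, average_cost_w_kg=0.0,
        converged=True, constraint_violation=0.0, solver_message="fabricated",
        config=problem.config, exotendon=None, model_mass=model.total_mass,
        stride_duration=2 * problem.T_half,
    )
    tr.mirror_half_cycle(sol, problem)
    return sol


class TestReferenceData:
    def test_invariants_enforced(self, reference):
        with pytest.raises(ValueError):
            tr.ReferenceData(time=np.array([0.0, 0.0, 1.0]),
                             coords=np.zeros((3, 20)), grf_r=np.zeros((3, 2)),
                             grf_l=np.zeros((3, 2)), speed=4.0, stride_duration=0.7)
        bad_grf = -np.ones((3, 2))
        with pytest.raises(ValueError):
            tr.ReferenceData(time=np.array([0.0, 0.5, 1.0]),
                             coords=np.zeros((3, 20)), grf_r=bad_grf,
                             grf_l=np.zeros((3, 2)), speed=4.0, stride_duration=0.7)

    def test_resampling_identity_on_own_grid(self, reference):
        ph = (reference.time - reference.time[0]) / reference.stride_duration
        c = reference.coords_at(ph, tx_time=reference.time - reference.time[0])
        assert np.allclose(c, reference.coords, atol=1e-9)


class TestOcpConfig:
    def test_weight_defaults(self):
        cfg = tr.OcpConfig()
        assert (cfg.w_kin, cfg.w_grf, cfg.w_act, cfg.w_met) == (1e-6, 14.0, 8.0, 4e-5)

    def test_validation(self):
        with pytest.raises(ValueError):
            tr.OcpConfig(w_act=-1.0)
        with pytest.raises(ValueError):
            tr.OcpConfig(mesh_intervals=2)


class TestEvaluateObjective:
    def test_perfect_tracking_zero_effort_gives_zero(self, model, reference):
        cfg = tr.OcpConfig()
        n = len(reference.time)
        traj = dict(time=reference.time, coords=reference.coords,
                    grf=np.concatenate([reference.grf_r, reference.grf_l], axis=1),
                    activations=np.zeros((n, 18)), met_rate=np.zeros((n, 18)))
        J, terms = tr.evaluate_objective(traj, reference, cfg,
                                         body_weight=model.total_mass * model.gravity)
        assert J == pytest.approx(0.0, abs=1e-15)

    def test_constant_deviation_closed_form(self, model, reference):
        """Constant offsets integrate to T * sum(w * dev^2) exactly."""
        cfg = tr.OcpConfig()
        bw = model.total_mass * model.gravity
        n = len(reference.time)
        T = reference.time[-1] - reference.time[0]
        dq, dg, a0, e0 = 0.1, 50.0, 0.2, 30.0
        coords = reference.coords.copy()
        coords[:, :2] += dq
        traj = dict(time=reference.time, coords=coords,
                    grf=np.concatenate([reference.grf_r, reference.grf_l], axis=1) + dg,
                    activations=np.full((n, 18), a0), met_rate=np.full((n, 18), e0))
        J, terms = tr.evaluate_objective(traj, reference, cfg, body_weight=bw)
        hand = T * (cfg.w_kin * 2 * dq**2 + cfg.w_grf * 4 * (dg / bw) ** 2
                    + cfg.w_act * 18 * a0**2 + cfg.w_met * 18 * e0**2)
        assert J == pytest.approx(hand, abs=1e-10)

    def test_matches_fine_grid_quadrature(self, model, reference):
        """Coarse trapezoidal quadrature vs a 10x-finer independent oracle."""
        cfg = tr.OcpConfig()
        bw = model.total_mass * model.gravity
        rng = np.random.default_rng(4)
        amp_q = rng.normal(0, 0.05, (3, 20))
        amp_g = rng.normal(0, 30.0, (3, 4))
        amp_a = rng.uniform(0, 0.1, (3, 18))

        def smooth(t, amps, base=0.0):
            T = reference.stride_duration
            out = base + sum(
                a[None, :] * np.sin(2 * np.pi * (k + 1) * t[:, None] / T + k)
                for k, a in enumerate(amps))
            return out

        def build(t):
            n = len(t)
            ph = t / reference.stride_duration
            coords = reference.coords_at(ph, tx_time=t) + smooth(t, amp_q)
            grf = np.concatenate(list(reference.grf_at(ph)), axis=1) + smooth(t, amp_g)
            act = 0.2 + smooth(t, amp_a)
            met = 40.0 + 100.0 * np.abs(smooth(t, amp_a))
            return dict(time=t, coords=coords, grf=grf, activations=act, met_rate=met)

        t_coarse = np.linspace(0, reference.stride_duration, 101)
        t_fine = np.linspace(0, reference.stride_duration, 1001)
        J_coarse, _ = tr.evaluate_objective(build(t_coarse), reference, cfg, bw)

        # independent oracle: recompute the weighted integrand on the fine
        # grid and integrate with trapezoid
        traj = build(t_fine)
        ph = t_fine / reference.stride_duration
        cref = reference.coords_at(ph, tx_time=t_fine)
        gr, gl = reference.grf_at(ph)
        gref = np.concatenate([gr, gl], axis=1)
        integrand = (cfg.w_kin * np.sum((traj["coords"] - cref) ** 2, axis=1)
                     + cfg.w_grf * np.sum(((traj["grf"] - gref) / bw) ** 2, axis=1)
                     + cfg.w_act * np.sum(traj["activations"] ** 2, axis=1)
                     + cfg.w_met * np.sum(traj["met_rate"] ** 2, axis=1))
        J_fine = np.trapezoid(integrand, t_fine)
        assert J_coarse == pytest.approx(J_fine, rel=1e-3)

    def test_grid_mismatch_raises(self, model, reference):
        cfg = tr.OcpConfig()
        traj = dict(time=reference.time, coords=reference.coords[:5],
                    grf=np.zeros((5, 4)), activations=np.zeros((5, 18)),
                    met_rate=np.zeros((5, 18)))
        with pytest.raises(ValueError):
            tr.evaluate_objective(traj, reference, cfg, body_weight=716.0)


class TestTranscriptionStructure:
    def test_decision_variable_count(self, problem, config):
        """(N+1) nodes x (3 coordinate blocks x 16 + 2 muscle blocks x 18 +
        5 torques) decision variables."""
        n_nodes = config.mesh_intervals + 1
        assert problem.nvar == n_nodes * (3 * 16 + 2 * 18 + 5)

    def test_natural_condition_has_no_exotendon_force(self, problem):
        V = problem.unpack(problem.initial_guess())
        dyn = problem.node_dynamics(V)
        assert np.all(dyn["tension"] == 0.0)

    def test_exotendon_condition_produces_tension(self, model, reference, config):
        exo = ExotendonSpec.from_percent(240.0, 12.5, name="short-stiff")
        p = tr.build_tracking_problem(model, reference, exo, config)
        V = p.unpack(p.initial_guess())
        dyn = p.node_dynamics(V)
        assert np.max(np.real(dyn["tension"])) > 10.0

    def test_symmetry_map_is_involution(self, problem):
        perm = problem._mirror_free
        assert np.array_equal(perm[perm], np.arange(len(perm)))
        pm = problem._mirror_musc
        assert np.array_equal(pm[pm], np.arange(18))

    def test_linear_constraints_satisfied_by_symmetric_trajectory(self, problem):
        """A trajectory built by mirroring the first half satisfies the
        symmetry + speed rows exactly."""
        z = problem.initial_guess()
        V = problem.unpack(z)
        # impose: end state = mirror of start state
        V["q"][-1] = V["q"][0][problem._mirror_free]
        txf = problem.free_names.index("pelvis_tx")
        V["q"][-1, txf] = V["q"][0, txf] + problem.reference.speed * problem.T_half
        V["qd"][-1] = V["qd"][0][problem._mirror_free]
        V["a"][-1] = V["a"][0][problem._mirror_musc]
        z2 = problem.pack(V)
        A, b = problem.linear_constraints()
        assert np.max(np.abs(A @ z2 - b)) < 1e-10


class TestSolutionAssembly:
    def test_mirror_full_cycle_structure(self, model, reference, problem):
        sol = fabricate_solution(model, reference, problem)
        n = len(sol.time)
        assert len(sol.full_time) == 2 * n - 1
        assert sol.full_time[-1] == pytest.approx(2 * sol.time[-1])
        hip_r = model.coord_index("hip_flexion_r")
        hip_l = model.coord_index("hip_flexion_l")
        # left leg in the second half replays the right leg of the first half
        assert np.allclose(sol.full_coords[n - 1:, hip_l],
                           sol.coords[:, hip_r], atol=1e-12)
        # right-foot GRF in the second half is the left-foot first half
        assert np.allclose(sol.full_grf_r[n - 1:], sol.grf_l, atol=1e-12)

    def test_average_cost_constant_rate(self, model, reference, problem):
        """Constant total rate P integrates to exactly P / mass."""
        P = 18 * 40.0
        sol = fabricate_solution(model, reference, problem, met_w_per_muscle=40.0)
        cost = tr.average_metabolic_cost(sol, model.total_mass)
        assert cost == pytest.approx(P / model.total_mass, rel=1e-12)
        assert cost > 0

    def test_average_cost_invariant_to_grid_refinement(self, model, reference, config):
        cfg_fine = tr.OcpConfig(mesh_intervals=50, maxiter=5)
        p1 = tr.build_tracking_problem(model, reference, None, config)
        p2 = tr.build_tracking_problem(model, reference, None, cfg_fine)
        rate = lambda t: 700.0 + 250.0 * np.sin(2 * np.pi * t / reference.stride_duration)
        s1 = fabricate_solution(model, reference, p1)
        s2 = fabricate_solution(model, reference, p2)
        for s in (s1, s2):
            s.full_met_rate = np.tile(rate(s.full_time)[:, None] / 18, (1, 18))
        c1 = tr.average_metabolic_cost(s1, model.total_mass)
        c2 = tr.average_metabolic_cost(s2, model.total_mass)
        assert c1 == pytest.approx(c2, rel=1e-3)

    def test_breakdown_sums_to_total(self, natural_solution):
        assert natural_solution.objective == pytest.approx(
            sum(natural_solution.objective_breakdown.values()), rel=1e-8)


def test_activation_rate_consistent_with_muscle_module(problem):
    P = mu.stacked_params(problem.muscles.muscles)
    e = np.full(18, 0.8)
    a = np.full(18, 0.3)
    batch = problem._activation_rate(e, a)
    for i, m in enumerate(problem.muscles.muscles):
        assert batch[i] == pytest.approx(mu.activation_rate(e[i], a[i], m), rel=1e-12)
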