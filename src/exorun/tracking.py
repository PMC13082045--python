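"""Muscle-driven tracking optimization over half a running gait cycle.

The optimal control problem: find joint kinematics, muscle activations and
upper-body torques over half a stride that stay consistent with the planar
skeletal dynamics (muscles, foot-ground contact, exotendon), track reference
kinematics and ground reaction forces, and minimize muscle effort:

    J = integral( sum_i w_kin (q_i - qbar_i)^2
                + sum_i w_grf (dGRF_i / BW)^2
                + sum_i w_act a_i^2
                + sum_i w_met Edot_met_i^2 ) dt

with weights w_kin = 1e-6, w_grf = 14, w_act = 8.0, w_met = 4e-5. Tracking
differences are squared (least-squares tracking); GRF errors are normalized
by body weight. Left-right symmetry maps the end of the half cycle onto the
mirrored start, and an average-speed constraint pins the stride length.

Transcription: trapezoidal direct collocation in implicit-dynamics form
(coordinate accelerations are decision variables, the Newton-Euler residual
is an equality constraint at every node). The sparse constraint Jacobian is
assembled by complex-step differentiation with a two-color node scheme, and
the NLP is solved with scipy's trust-constr. A tiny quadratic
regularization on the ideal torque actuators (reported separately in the
objective breakdown) keeps the torque controls well-posed.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize as sopt
import scipy.sparse as sp

from . import contact as ct
from . import muscles as mu
from . import skeleton as sk

__all__ = [
    "ReferenceData",
    "OcpConfig",
    "OcpSolution",
    "evaluate_objective",
    "build_tracking_problem",
    "solve",
    "solve_tracking",
    "mirror_half_cycle",
    "average_metabolic_cost",
]

TORQUE_COORDS = ["lumbar_extension", "arm_flex_r", "elbow_flex_r", "arm_flex_l", "elbow_flex_l"]
TORQUE_MAX = 150.0  # N m


@dataclass
class ReferenceData:
    """Reference full-gait-cycle kinematics and ground reaction forces."""

    time: np.ndarray        # (n,) s, strictly increasing, spans one stride
    coords: np.ndarray      # (n, 20) rad | m, full coordinate layout
    grf_r: np.ndarray       # (n, 2) N, right foot (fore-aft, vertical)
    grf_l: np.ndarray       # (n, 2) N, left foot
    speed: float            # m/s
    stride_duration: float  # s

    def __post_init__(self):
        t = np.asarray(self.time, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for g in (self.grf_r, self.grf_l):
            if np.any(np.asarray(g)[:, 1] < -1e-9):
                raise ValueError("vertical GRF must be non-negative")
        n = len(t)
        if not (len(self.coords) == len(self.grf_r) == len(self.grf_l) == n):
            raise ValueError("all trajectories must share the time grid")

    # -- phase-based resampling (phase 0..1 over the stride) ---------------
    def _phase(self):
        t = self.time - self.time[0]
        return t / t[-1]

    def coords_at(self, phase, tx_time=None, stride_duration=None):
        """Coordinates at stride phase(s). ``pelvis_tx`` is re-linearized as
        speed * time for the (possibly rescaled) stride duration."""
        ph = np.atleast_1d(phase)
        phm = np.mod(ph, 1.0)
        T = self.stride_duration if stride_duration is None else stride_duration
        out = np.stack([np.interp(phm, self._phase(), self.coords[:, j]) for j in range(self.coords.shape[1])], axis=-1)
        # forward translation: linear trend at target speed + reference wobble
        trend_ref = self.speed * (self._phase() * (self.time[-1] - self.time[0]))
        wobble = np.interp(phm, self._phase(), self.coords[:, 3] - self.coords[0, 3] - trend_ref)
        t_new = ph * T if tx_time is None else np.atleast_1d(tx_time)
        out[..., 3] = self.coords[0, 3] + self.speed * t_new + wobble
        return out if np.ndim(phase) else out[0]

    def grf_at(self, phase):
        ph = np.mod(np.atleast_1d(phase), 1.0)
        gr = np.stack([np.interp(ph, self._phase(), self.grf_r[:, j]) for j in range(2)], axis=-1)
        gl = np.stack([np.interp(ph, self._phase(), self.grf_l[:, j]) for j in range(2)], axis=-1)
        return (gr, gl) if np.ndim(phase) else (gr[0], gl[0])


@dataclass
class OcpConfig:
    w_kin: float = 1.0e-6
    w_grf: float = 14.0
    w_act: float = 8.0
    w_met: float = 4.0e-5
    w_reg: float = 1.0e-3          # torque regularization (not part of Eq-style terms)
    mesh_intervals: int = 25       # per half cycle
    stride_multiplier: float = 1.0
    maxiter: int = 300
    tol_feasibility: float = 1e-4
    tol_optimality: float = 1e-3
    exo_smoothing: float = 1e-3    # m, softplus width for spring inside the OCP
    basal_rate_w_kg: float = 0.0   # whole-body basal added to reported gross cost
    seed: int = 0
    grf_normalize: bool = True
    # Tracking-dominant warm start: stage 1 boosts the kinematic weight and
    # shrinks the effort weights so all conditions settle into the same
    # reference-gait basin before the true weights are applied (the effort-
    # dominated objective is multi-modal).
    warm_start: bool = True
    warm_start_maxiter: int = 150
    warm_kin_boost: float = 1e4
    warm_effort_scale: float = 0.1

    def __post_init__(self):
        for w in ("w_kin", "w_grf", "w_act", "w_met", "w_reg"):
            if getattr(self, w) < 0:
                raise ValueError("weights must be non-negative")
        if self.mesh_intervals < 4:
            raise ValueError("mesh must have at least 4 intervals")


@dataclass
class OcpSolution:
    time: np.ndarray               # (N+1,) half-cycle node times
    coords: np.ndarray             # (N+1, 20)
    speeds: np.ndarray             # (N+1, 20)
    activations: np.ndarray        # (N+1, 18)
    excitations: np.ndarray        # (N+1, 18)
    torques: np.ndarray            # (N+1, n_torque)
    grf_r: np.ndarray              # (N+1, 2) model GRFs
    grf_l: np.ndarray
    met_rate: np.ndarray           # (N+1, 18) W
    objective: float
    objective_breakdown: dict[str, float]
    average_cost_w_kg: float       # net of basal; see average_metabolic_cost
    converged: bool
    constraint_violation: float
    solver_message: str
    config: OcpConfig
    exotendon: ct.ExotendonSpec | None
    model_mass: float
    stride_duration: float         # full-cycle duration actually simulated
    full_time: np.ndarray = field(default=None)
    full_coords: np.ndarray = field(default=None)
    full_activations: np.ndarray = field(default=None)
    full_grf_r: np.ndarray = field(default=None)
    full_grf_l: np.ndarray = field(default=None)
    full_met_rate: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# objective evaluation on sampled trajectories (shared by the transcription
# and by standalone analyses)
# ---------------------------------------------------------------------------

def _integrand_terms(coords, coords_ref, grf, grf_ref, activations, met_rate,
                     torques, config: OcpConfig, body_weight):
    kin = config.w_kin * np.sum((coords - coords_ref) ** 2, axis=-1)
    scale = body_weight if config.grf_normalize else 1.0
    grf_t = config.w_grf * np.sum(((grf - grf_ref) / scale) ** 2, axis=-1)
    act = config.w_act * np.sum(np.asarray(activations) ** 2, axis=-1)
    met = config.w_met * np.sum(np.asarray(met_rate) ** 2, axis=-1)
    reg = config.w_reg * np.sum((np.asarray(torques) / TORQUE_MAX) ** 2, axis=-1)
    return dict(kinematics=kin, grf=grf_t, activation=act, metabolics=met, regularization=reg)


def evaluate_objective(traj: dict, reference: ReferenceData, config: OcpConfig,
                       body_weight: float):
    """Tracking objective J and per-term breakdown by trapezoidal quadrature.

    ``traj`` keys: time (n,), coords (n, 20), grf (n, 4) as
    [right fore-aft, right vertical, left fore-aft, left vertical],
    activations (n, n_musc), met_rate (n, n_musc) W, and optionally
    torques (n, n_torque). Reference values are resampled to the trajectory
    times by stride phase. Raises on mismatched grids.
    """
    t = np.asarray(traj["time"], float)
    n = len(t)
    for key in ("coords", "grf", "activations", "met_rate"):
        if len(np.asarray(traj[key])) != n:
            raise ValueError(f"trajectory '{key}' does not match the time grid")
    T = t[-1] - t[0]
    stride = traj.get("stride_duration", reference.stride_duration)
    phase = (t - t[0]) / stride
    cref = reference.coords_at(phase, tx_time=t - t[0], stride_duration=stride)
    gr, gl = reference.grf_at(np.mod(phase, 1.0))
    grf_ref = np.concatenate([gr, gl], axis=-1)
    torques = traj.get("torques", np.zeros((n, 1)))
    terms = _integrand_terms(traj["coords"], cref, traj["grf"], grf_ref,
                             traj["activations"], traj["met_rate"], torques,
                             config, body_weight)
    out = {k: float(np.trapezoid(v, t)) for k, v in terms.items()}
    out["total"] = sum(out.values())
    return out["total"], out


# ---------------------------------------------------------------------------
# transcription
# ---------------------------------------------------------------------------

class TrackingProblem:
    """Direct-collocation NLP for the half-cycle tracking problem."""

    def __init__(self, model: sk.SkeletonModel, reference: ReferenceData,
                 exotendon: ct.ExotendonSpec | None, config: OcpConfig,
                 muscle_set: mu.MuscleSet | None = None):
        self.model = model
        self.reference = reference
        self.exotendon = exotendon
        self.config = config
        self.muscles = muscle_set or mu.default_muscle_set()
        self.P = mu.stacked_params(self.muscles.muscles)
        self.sphere = ct.ContactSphereSpec()
        self.n_nodes = config.mesh_intervals + 1
        self.T_half = reference.stride_duration * config.stride_multiplier / 2.0
        self.h = self.T_half / config.mesh_intervals
        self.free = model.free_index()                 # 16 coordinate indices
        self.free_names = model.free_coordinates
        self.nq = len(self.free)
        self.nm = len(self.muscles)
        self.ntq = len(TORQUE_COORDS)
        self.tq_idx = np.array([model.coord_index(c) for c in TORQUE_COORDS])
        self.R_arm = self.muscles.arm_matrix(model.coordinates)  # (nm, 20)
        self.L_ref = self.muscles.reference_lengths()
        self.mass = model.total_mass
        self.bw = self.mass * model.gravity
        # per-node slot layout: q, qd, qdd, a, e, tq
        self.slots = {}
        off = 0
        for name, size in [("q", self.nq), ("qd", self.nq), ("qdd", self.nq),
                           ("a", self.nm), ("e", self.nm), ("tq", self.ntq)]:
            self.slots[name] = slice(off, off + size)
            off += size
        self.nslot = off
        self.nvar = self.n_nodes * self.nslot
        self.scale = np.ones(self.nslot)
        self.scale[self.slots["qd"]] = 10.0
        self.scale[self.slots["qdd"]] = 200.0
        self.scale[self.slots["tq"]] = 100.0
        self._contact_names_r = [n for n in model.points if n.startswith("contact") and n.endswith("_r")]
        self._contact_names_l = [n for n in model.points if n.startswith("contact") and n.endswith("_l")]
        self._mirror_free = self._mirror_permutation()
        self._mirror_musc = np.r_[np.arange(self.nm // 2, self.nm), np.arange(0, self.nm // 2)]
        self._node_phase = np.arange(self.n_nodes) * self.h / reference.stride_duration / config.stride_multiplier
        self._node_time = np.arange(self.n_nodes) * self.h
        self._cref = reference.coords_at(self._node_phase, tx_time=self._node_time,
                                         stride_duration=reference.stride_duration * config.stride_multiplier)
        gr, gl = reference.grf_at(self._node_phase)
        self._grf_ref = np.concatenate([gr, gl], axis=-1)
        self._build_constraint_index()

    # -- helpers -----------------------------------------------------------
    def _mirror_permutation(self):
        """Index permutation mapping each free coordinate to its mirror."""
        perm = []
        for name in self.free_names:
            if name.endswith("_r"):
                other = name[:-2] + "_l"
            elif name.endswith("_l"):
                other = name[:-2] + "_r"
            else:
                other = name
            perm.append(self.free_names.index(other))
        return np.array(perm)

    def unpack(self, z):
        z = np.asarray(z)
        Z = z.reshape(z.shape[:-1] + (self.n_nodes, self.nslot)) * self.scale
        return {k: Z[..., s] for k, s in self.slots.items()}

    def pack(self, parts):
        Z = np.zeros((self.n_nodes, self.nslot))
        for k, s in self.slots.items():
            Z[:, s] = parts[k]
        return (Z / self.scale).ravel()

    def _expand(self, arr_free):
        """(n, nq_free) -> (n, 20) with locked coordinates at zero."""
        out = np.zeros(arr_free.shape[:-1] + (self.model.n_coordinates,), dtype=arr_free.dtype)
        out[..., self.free] = arr_free
        return out

    # -- physics at all nodes ---------------------------------------------
    def node_dynamics(self, V):
        """Residuals, GRFs and metabolic rates at every node.

        ``V`` is the dict from :meth:`unpack` (complex dtypes supported).
        """
        q = self._expand(V["q"])
        qd = self._expand(V["qd"])
        qdd = self._expand(V["qdd"])
        a, e, tq = V["a"], V["e"], V["tq"]
        pk = sk.forward_kinematics(self.model, q, qd)
        # contact forces
        point_forces = []
        grf = {}
        for side, names in (("r", self._contact_names_r), ("l", self._contact_names_l)):
            total = 0.0
            for nme in names:
                p, v = pk.point(nme)
                f = ct.contact_force(self.sphere, p[..., :2], v[..., :2])
                point_forces.append((nme, f))
                total = total + f
            grf[side] = total
        # exotendon
        tension = np.zeros(q.shape[:-1])
        if self.exotendon is not None and self.exotendon.stiffness > 0:
            pr, _ = pk.point(self.exotendon.anchors[0])
            pl, _ = pk.point(self.exotendon.anchors[1])
            delta = pl - pr
            dist = np.sqrt(np.sum(delta**2, axis=-1) + 1e-12)
            tension = ct.exotendon_tension(dist, self.exotendon, smoothing=self.config.exo_smoothing)
            direction = delta / dist[..., None]
            f_on_r = tension[..., None] * direction[..., :2]
            point_forces.append((self.exotendon.anchors[0], f_on_r))
            point_forces.append((self.exotendon.anchors[1], -f_on_r))
        # muscles (rigid tendon)
        l_mtu = self.L_ref - q @ self.R_arm.T
        v_mtu = -(qd @ self.R_arm.T)
        f_tendon, lm_n, vm_n, f_fiber, v_fiber = mu.rigid_tendon_forces(self.P, a, l_mtu, v_mtu)
        tau = f_tendon @ self.R_arm                 # generalized muscle forces
        gen = np.array(tau, copy=True)
        gen[..., self.tq_idx] = gen[..., self.tq_idx] + tq
        met = mu.total_metabolic_rate(self.P, a, f_fiber, v_fiber)
        res = sk.dynamics_residual(self.model, q, qd, qdd,
                                   point_forces=point_forces, generalized_forces=gen)
        return dict(residual=res[..., self.free], grf_r=grf["r"], grf_l=grf["l"],
                    met=met, tension=tension, lm_norm=lm_n, vm_norm=vm_n)

    def node_integrand(self, V, dyn):
        grf = np.concatenate([dyn["grf_r"], dyn["grf_l"]], axis=-1)
        terms = _integrand_terms(self._expand(V["q"]), self._cref, grf, self._grf_ref,
                                 V["a"], dyn["met"], V["tq"], self.config, self.bw)
        return terms

    # -- constraint vector -------------------------------------------------
    def _build_constraint_index(self):
        N = self.config.mesh_intervals
        rows = []
        # per-node dynamics residual (scaled)
        self._n_res = self.n_nodes * self.nq
        self._n_defq = N * self.nq
        self._n_defqd = N * self.nq
        self._n_defa = N * self.nm
        self.n_nonlin = self._n_res + self._n_defq + self._n_defqd + self._n_defa

    def constraints(self, z, _cache={}):
        V = self.unpack(np.asarray(z))
        return self._constraints_from(V)

    def _constraints_from(self, V, dyn=None):
        """Nonlinear constraint vector; supports extra leading batch axes
        (node axis is second-to-last)."""
        h = self.h
        if dyn is None:
            dyn = self.node_dynamics(V)
        res = dyn["residual"] / 500.0
        q, qd, qdd, a, e = V["q"], V["qd"], V["qdd"], V["a"], V["e"]
        defq = q[..., 1:, :] - q[..., :-1, :] - 0.5 * h * (qd[..., 1:, :] + qd[..., :-1, :])
        defqd = (qd[..., 1:, :] - qd[..., :-1, :]
                 - 0.5 * h * (qdd[..., 1:, :] + qdd[..., :-1, :])) / 10.0
        adot = self._activation_rate(e, a)
        defa = a[..., 1:, :] - a[..., :-1, :] - 0.5 * h * (adot[..., 1:, :] + adot[..., :-1, :])
        flat = lambda x: x.reshape(x.shape[:-2] + (-1,))
        return np.concatenate([flat(res), flat(defq), flat(defqd), flat(defa)], axis=-1)

    def _activation_rate(self, e, a):
        d = e - a
        sig = 0.5 + 0.5 * np.tanh(d / 0.1)
        tau_inv = sig / self.P["tau_act"] + (1.0 - sig) / self.P["tau_deact"]
        return tau_inv * d

    def objective_terms(self, V, dyn=None):
        if dyn is None:
            dyn = self.node_dynamics(V)
        terms = self.node_integrand(V, dyn)
        w = np.full(self.n_nodes, self.h)
        w[0] = w[-1] = self.h / 2.0
        return {k: np.sum(w * v) for k, v in terms.items()}, dyn

    # -- linear coupling constraints ---------------------------------------
    def linear_constraints(self):
        """Half-cycle symmetry + average-speed constraint (all linear)."""
        N = self.config.mesh_intervals
        rows, cols, vals, rhs = [], [], [], []
        r = 0

        def var(k, name, i):
            return k * self.nslot + self.slots[name].start + i

        perm = self._mirror_free
        tx_free = self.free_names.index("pelvis_tx")
        for name in ("q", "qd"):
            for i in range(self.nq):
                if name == "q" and i == tx_free:
                    continue
                rows += [r, r]
                cols += [var(N, name, i), var(0, name, perm[i])]
                vals += [self.scale[self.slots[name]][i], -self.scale[self.slots[name]][perm[i]]]
                rhs.append(0.0)
                r += 1
        for i in range(self.nm):
            rows += [r, r]
            cols += [var(N, "a", i), var(0, "a", self._mirror_musc[i])]
            vals += [1.0, -1.0]
            rhs.append(0.0)
            r += 1
        # average speed: tx_N - tx_0 = v * T_half
        rows += [r, r]
        cols += [var(N, "q", tx_free), var(0, "q", tx_free)]
        vals += [1.0, -1.0]
        rhs.append(self.reference.speed * self.T_half)
        r += 1
        A = sp.csr_matrix((vals, (rows, cols)), shape=(r, self.nvar))
        return A, np.array(rhs)

    # -- bounds and initial guess ------------------------------------------
    _Q_BOUNDS = {
        "pelvis_tilt": (-0.6, 0.6), "pelvis_tx": (-2.0, 8.0), "pelvis_ty": (0.6, 1.5),
        "lumbar_extension": (-0.9, 0.9),
        "hip_flexion": (-1.3, 1.6), "knee_angle": (-2.4, 0.15),
        "ankle_angle": (-1.2, 0.9), "mtp_angle": (-0.9, 1.3),
        "arm_flex": (-1.8, 1.8), "elbow_flex": (-0.2, 2.7),
    }

    def bounds(self):
        lo = np.full((self.n_nodes, self.nslot), -np.inf)
        hi = np.full((self.n_nodes, self.nslot), np.inf)
        qb = np.zeros((self.nq, 2))
        for i, name in enumerate(self.free_names):
            base = name[:-2] if name.endswith(("_r", "_l")) else name
            qb[i] = self._Q_BOUNDS[base]
        lo[:, self.slots["q"]] = qb[:, 0]
        hi[:, self.slots["q"]] = qb[:, 1]
        lo[:, self.slots["qd"]] = -40.0
        hi[:, self.slots["qd"]] = 40.0
        lo[:, self.slots["qdd"]] = -3000.0
        hi[:, self.slots["qdd"]] = 3000.0
        lo[:, self.slots["a"]] = 0.0
        hi[:, self.slots["a"]] = 1.0
        lo[:, self.slots["e"]] = 0.0
        hi[:, self.slots["e"]] = 1.0
        lo[:, self.slots["tq"]] = -TORQUE_MAX
        hi[:, self.slots["tq"]] = TORQUE_MAX
        return (lo / self.scale).ravel(), (hi / self.scale).ravel()

    def initial_guess(self):
        rng = np.random.default_rng(self.config.seed)
        parts = {}
        q_ref = self._cref[:, self.free]
        parts["q"] = q_ref
        qd = np.gradient(q_ref, self._node_time, axis=0)
        parts["qd"] = qd
        parts["qdd"] = np.gradient(qd, self._node_time, axis=0)
        parts["a"] = np.full((self.n_nodes, self.nm), 0.05)
        parts["e"] = np.full((self.n_nodes, self.nm), 0.05)
        parts["tq"] = np.zeros((self.n_nodes, self.ntq))
        z = self.pack(parts)
        return z + 0.0 * rng.standard_normal(z.size)

    # -- colored complex-step jacobian -------------------------------------
    def _jacobian_sparsity(self):
        """(row, node, slot) triples: which node's variables each nonlinear
        constraint row depends on."""
        N = self.config.mesh_intervals
        deps = []  # list of (row, node)
        r = 0
        for k in range(self.n_nodes):
            for i in range(self.nq):
                deps.append((r, (k,)))
                r += 1
        for block in range(3):          # defq, defqd, defa
            nsize = self.nq if block < 2 else self.nm
            for k in range(N):
                for i in range(nsize):
                    deps.append((r, (k, k + 1)))
                    r += 1
        return deps

    def make_jacobian_workspace(self):
        deps = self._jacobian_sparsity()
        colors = []
        for parity in (0, 1):
            for s in range(self.nslot):
                nodes = np.arange(parity, self.n_nodes, 2)
                cols = nodes * self.nslot + s
                colors.append((parity, s, cols))
        # For each color, rows affected and their column index
        color_rows = []
        for parity, s, cols in colors:
            rws, cls = [], []
            for row, nodes in deps:
                for k in nodes:
                    if k % 2 == parity:
                        rws.append(row)
                        cls.append(k * self.nslot + s)
            color_rows.append((np.array(rws, dtype=np.intp), np.array(cls, dtype=np.intp)))
        return colors, color_rows

    def solve(self):
        return solve(self)


def build_tracking_problem(model, reference, exotendon, config,
                           muscle_set=None) -> TrackingProblem:
    return TrackingProblem(model, reference, exotendon, config, muscle_set=muscle_set)


def solve(problem: TrackingProblem) -> OcpSolution:
    """Solve the tracking NLP (deterministic for a given config and seed).

    With ``config.warm_start`` a tracking-dominant stage is solved first and
    its iterate seeds the true-weight problem; this keeps natural and
    exotendon conditions in comparable local basins.
    """
    from dataclasses import replace as _replace

    cfg = problem.config
    lo, hi = problem.bounds()
    z0 = np.clip(problem.initial_guess(), lo, hi)
    if cfg.warm_start:
        cfg1 = _replace(cfg, warm_start=False, maxiter=cfg.warm_start_maxiter,
                        w_kin=cfg.w_kin * cfg.warm_kin_boost,
                        w_act=cfg.w_act * cfg.warm_effort_scale,
                        w_met=cfg.w_met * cfg.warm_effort_scale)
        stage1 = TrackingProblem(problem.model, problem.reference,
                                 problem.exotendon, cfg1,
                                 muscle_set=problem.muscles)
        z1, _ = _solve_nlp(stage1, np.clip(z0, lo, hi))
        z0 = np.clip(z1, lo, hi)
    x, res = _solve_nlp(problem, z0)
    return _assemble_solution(problem, x, res)


def _solve_nlp(problem: TrackingProblem, z0):
    cfg = problem.config
    colors, color_rows = problem.make_jacobian_workspace()
    hstep = 1e-30

    cache = {}

    def evaluate(z):
        """Cheap values (objective, constraints) with last-point caching."""
        key = z.tobytes()
        if cache.get("key") != key:
            V = problem.unpack(z)
            dyn = problem.node_dynamics(V)
            c = problem._constraints_from(V, dyn)
            terms, _ = problem.objective_terms(V, dyn)
            cache.clear()
            cache.update(key=key, c=c, J=sum(terms.values()))
        return cache

    def derivatives(z):
        """Colored complex-step constraint Jacobian + objective gradient."""
        key = z.tobytes()
        c = evaluate(z)
        if "jac" in c and cache.get("key") == key:
            return cache
        # one batched complex evaluation across all colors
        C = len(colors)
        ZP = np.tile(z.astype(complex), (C, 1))
        for i, (parity, s, cols) in enumerate(colors):
            ZP[i, cols] += 1j * hstep
        Vp = problem.unpack(ZP)
        dynp = problem.node_dynamics(Vp)
        cp = problem._constraints_from(Vp, dynp)            # (C, n_nonlin)
        termsp = problem.node_integrand(Vp, dynp)
        dinteg = np.imag(sum(termsp.values())) / hstep      # (C, n_nodes)

        rows_all, cols_all, vals_all = [], [], []
        grad = np.zeros(problem.nvar)
        w_quad = np.full(problem.n_nodes, problem.h)
        w_quad[0] = w_quad[-1] = problem.h / 2.0
        for i, ((parity, s, cols), (rws, cls)) in enumerate(zip(colors, color_rows)):
            nodes = np.arange(parity, problem.n_nodes, 2)
            grad[cols] += w_quad[nodes] * dinteg[i, nodes]
            rows_all.append(rws)
            cols_all.append(cls)
            vals_all.append(np.imag(cp[i, rws]) / hstep)
        jac = sp.csr_matrix(
            (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(problem.n_nonlin, problem.nvar),
        )
        cache.update(grad=grad, jac=jac)
        return cache

    fun = lambda z: evaluate(z)["J"]
    grad = lambda z: derivatives(z)["grad"]
    cfun = lambda z: evaluate(z)["c"]
    cjac = lambda z: derivatives(z)["jac"]

    nlc = sopt.NonlinearConstraint(cfun, 0.0, 0.0, jac=cjac, hess=sopt.BFGS())
    A, b = problem.linear_constraints()
    lc = sopt.LinearConstraint(A, b, b)
    lo, hi = problem.bounds()

    t0 = _time.time()
    res = sopt.minimize(
        fun, z0, jac=grad, method="trust-constr",
        constraints=[nlc, lc], bounds=sopt.Bounds(lo, hi),
        options=dict(maxiter=cfg.maxiter, gtol=cfg.tol_optimality,
                     xtol=1e-10, verbose=0, initial_tr_radius=1.0),
    )
    res.wall_time = _time.time() - t0
    return res.x, res


def _assemble_solution(problem: TrackingProblem, x, res) -> OcpSolution:
    cfg = problem.config
    A, b = problem.linear_constraints()
    wall = res.wall_time
    V = problem.unpack(res.x)
    dyn = problem.node_dynamics(V)
    terms, _ = problem.objective_terms(V, dyn)
    cviol = float(np.max(np.abs(problem._constraints_from(V, dyn))))
    lviol = float(np.max(np.abs(A @ res.x - b))) if A.shape[0] else 0.0
    converged = cviol < cfg.tol_feasibility * 10 and lviol < 1e-6

    sol = OcpSolution(
        time=problem._node_time.copy(),
        coords=problem._expand(V["q"]).real,
        speeds=problem._expand(V["qd"]).real,
        activations=V["a"].real,
        excitations=V["e"].real,
        torques=V["tq"].real,
        grf_r=np.real(dyn["grf_r"]),
        grf_l=np.real(dyn["grf_l"]),
        met_rate=np.real(dyn["met"]),
        objective=float(sum(terms.values())),
        objective_breakdown={k: float(v) for k, v in terms.items()},
        average_cost_w_kg=0.0,
        converged=bool(converged),
        constraint_violation=max(cviol, lviol),
        solver_message=f"{res.message} (iters={res.niter}, wall={wall:.1f}s)",
        config=cfg,
        exotendon=problem.exotendon,
        model_mass=problem.mass,
        stride_duration=2 * problem.T_half,
    )
    mirror_half_cycle(sol, problem)
    sol.average_cost_w_kg = average_metabolic_cost(sol, problem.mass)
    return sol


def solve_tracking(model, reference, exotendon, config, muscle_set=None) -> OcpSolution:
    """Build and solve in one call."""
    return solve(build_tracking_problem(model, reference, exotendon, config,
                                        muscle_set=muscle_set))


def mirror_half_cycle(sol: OcpSolution, problem: TrackingProblem) -> OcpSolution:
    """Assemble the full stride by applying the left-right involution to the
    solved half cycle. The mirrored second half advances pelvis_tx by the
    half-stride displacement; applying the involution twice is the identity.
    """
    model = problem.model
    free = problem.free
    perm_free = problem._mirror_free
    perm20 = np.arange(model.n_coordinates)
    perm20[free] = free[perm_free]
    tx = model.coord_index("pelvis_tx")
    n = len(sol.time)
    dtx = sol.coords[-1, tx] - sol.coords[0, tx]

    cm = sol.coords[:, perm20].copy()
    cm[:, tx] = sol.coords[:, tx] + dtx
    sm = sol.speeds[:, perm20]
    am = sol.activations[:, problem._mirror_musc]
    em = sol.excitations[:, problem._mirror_musc]
    metm = sol.met_rate[:, problem._mirror_musc]

    sol.full_time = np.concatenate([sol.time, sol.time[1:] + sol.time[-1]])
    sol.full_coords = np.concatenate([sol.coords, cm[1:]])
    sol.full_activations = np.concatenate([sol.activations, am[1:]])
    sol.full_grf_r = np.concatenate([sol.grf_r, sol.grf_l[1:]])
    sol.full_grf_l = np.concatenate([sol.grf_l, sol.grf_r[1:]])
    sol.full_met_rate = np.concatenate([sol.met_rate, metm[1:]])
    return sol


def average_metabolic_cost(sol: OcpSolution, mass_kg: float,
                           include_basal: bool | None = None) -> float:
    """Stride-averaged whole-body metabolic rate (W/kg).

    Integrates the summed per-muscle metabolic rate over the full cycle and
    divides by duration and body mass. A whole-body basal rate
    (``config.basal_rate_w_kg``) is added when ``include_basal`` (default:
    only if the config sets it non-zero).
    """
    t = sol.full_time if sol.full_time is not None else sol.time
    met = sol.full_met_rate if sol.full_met_rate is not None else sol.met_rate
    total = np.sum(met, axis=-1)
    avg = float(np.trapezoid(total, t) / (t[-1] - t[0]) / mass_kg)
    basal = sol.config.basal_rate_w_kg if include_basal is None else (
        sol.config.basal_rate_w_kg if include_basal else 0.0)
    return avg + basal
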