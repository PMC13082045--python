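"""Hill-type muscle-tendon units: curves, activation dynamics, metabolics.

Eighteen muscle-tendon units (nine per leg: iliopsoas, gluteus maximus,
rectus femoris, biarticular hamstrings, vasti, biceps femoris short head,
gastrocnemius, soleus, tibialis anterior) actuate the hip, knee and ankle
through constant moment arms. Relative to generic strength, maximum
isometric forces are doubled and the active force-length operating range is
widened by 50% to represent trained runners.

All curves are smooth (C1) so they can sit inside a gradient-based
collocation transcription. Metabolic rate follows a smoothed
Bhargava-2004-style model: activation/maintenance heat, shortening/
lengthening heat, positive mechanical work, clamped non-negative; the
coefficients live in ``METABOLIC_COEFFS`` and are swappable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MuscleParams",
    "MuscleState",
    "MetabolicTerms",
    "MuscleSet",
    "default_muscle_set",
    "load_muscle_table",
    "save_muscle_table",
    "activation_rate",
    "active_force_length",
    "force_velocity",
    "passive_force_length",
    "tendon_force",
    "fiber_force",
    "mtu_equilibrium_residual",
    "solve_rigid_tendon_fiber_length",
    "metabolic_rate",
    "METABOLIC_COEFFS",
    "FORCE_MULTIPLIER",
    "FL_WIDEN_DEFAULT",
]

# Strength adaptations for trained runners: generic F_max doubled, active
# force-length width increased by 50%.
FORCE_MULTIPLIER = 2.0
FL_WIDEN_DEFAULT = 1.5

# Smoothed Bhargava-style metabolic model coefficients.
METABOLIC_COEFFS = {
    "activation_maintenance_slow": 40.0,   # W/kg at full activation, slow fibers
    "activation_maintenance_fast": 133.0,  # W/kg at full activation, fast fibers
    "fraction_fast": 0.5,                  # fast-twitch fraction (uniform default)
    "shortening_coeff": 0.25,              # heat per unit fiber force * velocity
    "lengthening_coeff": 0.0,              # eccentric heat (off by default)
    "basal_per_kg": 0.0,                   # per-muscle basal rate W/kg (whole-body
                                           # basal handled at the cost level)
    "specific_tension": 0.60e6,            # Pa, for muscle mass from F_max
    "density": 1059.7,                     # kg/m^3
    "velocity_smoothing": 0.02,            # lopt/s, shortening/lengthening blend
    "clamp_smoothing": 1e-3,               # W, soft non-negativity width
}

_FV_CONCENTRIC_SLOPE = 0.25   # Hill a/F0 shape parameter
_FV_ECCENTRIC_PLATEAU = 1.4   # eccentric force asymptote
_PASSIVE_STRAIN_AT_FMAX = 0.6
_TENDON_STRAIN_AT_FMAX = 0.049


@dataclass
class MuscleParams:
    name: str
    f_max: float            # N, maximum isometric force (already doubled)
    l_opt: float            # m, optimal fiber length
    l_slack: float          # m, tendon slack length
    pennation: float        # rad, at optimal fiber length
    v_max: float = 10.0     # optimal fiber lengths / s
    fl_widen: float = FL_WIDEN_DEFAULT
    tau_act: float = 0.015  # s
    tau_deact: float = 0.060
    mass: float = 0.0       # kg, derived if left 0

    def __post_init__(self):
        for f in ("f_max", "l_opt", "l_slack", "v_max", "tau_act", "tau_deact"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{self.name}: {f} must be positive")
        if self.fl_widen < 1.0:
            raise ValueError("force-length widening factor must be >= 1")
        if self.mass <= 0.0:
            c = METABOLIC_COEFFS
            self.mass = c["density"] * self.f_max * self.l_opt / c["specific_tension"]


@dataclass
class MuscleState:
    excitation: float
    activation: float
    lm_norm: float = 1.0    # fiber length / l_opt
    vm_norm: float = 0.0    # fiber velocity / (l_opt/s), shortening negative


@dataclass
class MetabolicTerms:
    activation_maintenance: float  # W
    shortening: float              # W
    work: float                    # W
    basal: float                   # W
    total: float = field(init=False)

    def __post_init__(self):
        self.total = self.activation_maintenance + self.shortening + self.work + self.basal


# ---------------------------------------------------------------------------
# curves (vectorized, complex-step safe)
# ---------------------------------------------------------------------------

def activation_rate(e, a, params: MuscleParams):
    """First-order activation dynamics da/dt (1/s).

    Smoothly blends the activation and deactivation time constants so the
    rate is C1 in (e, a); sign(rate) = sign(e - a).
    """
    e_arr, a_arr = np.asarray(e), np.asarray(a)
    if np.any(np.real(e_arr) < -1e-12) or np.any(np.real(e_arr) > 1 + 1e-12):
        raise ValueError("excitation out of [0, 1]")
    if np.any(np.real(a_arr) < -1e-12) or np.any(np.real(a_arr) > 1 + 1e-12):
        raise ValueError("activation out of [0, 1]")
    d = e_arr - a_arr
    sig = 0.5 + 0.5 * np.tanh(d / 0.1)
    tau_inv = sig / params.tau_act + (1.0 - sig) / params.tau_deact
    return tau_inv * d


def active_force_length(lm_norm, widen=FL_WIDEN_DEFAULT):
    """Bell-shaped active force-length multiplier, peak 1 at lm_norm = 1.

    ``widen`` rescales the deviation from the optimum by 1/widen, i.e. a
    widen of 1.5 stretches the operating range by 50%.
    """
    x = (np.asarray(lm_norm) - 1.0) / widen
    return np.exp(-(x**2) / 0.20)


# log-sinh smooth force-velocity coefficients (De-Groote-2016-style)
_FV_D = (-0.318323436899127, -8.149156043475250, -0.374121508647863, 0.885644059915004)


def _fv_raw(v):
    d1, d2, d3, d4 = _FV_D
    z = d2 * v + d3
    return d1 * np.log(z + np.sqrt(z**2 + 1.0)) + d4


def force_velocity(vm_norm):
    """Hill force-velocity multiplier; vm_norm = -1 is maximum shortening.

    Smooth monotone log-sinh parameterization: ~0 at maximum shortening
    velocity, exactly 1 isometric, slowly saturating eccentric plateau.
    """
    return _fv_raw(np.asarray(vm_norm)) / _fv_raw(0.0)


def passive_force_length(lm_norm):
    """Exponential passive fiber force multiplier (~0 below optimal length,
    1 at the nominal passive strain); smooth-max clamped non-negative."""
    x = (np.asarray(lm_norm) - 1.0) / _PASSIVE_STRAIN_AT_FMAX
    y = (np.exp(5.0 * x) - 1.0) / (np.exp(5.0) - 1.0)
    return 0.5 * (y + np.sqrt(y**2 + 1e-12))


def _softplus_mask(x, width=0.05):
    return 0.5 + 0.5 * np.tanh(x / width)


def tendon_force(lt_norm):
    """Normalized tendon force vs lt/l_slack; ~0 at slack, 1 at nominal strain."""
    strain = np.asarray(lt_norm) - 1.0
    k = 35.0
    c = _TENDON_STRAIN_AT_FMAX
    return (np.exp(k * strain) - 1.0) / (np.exp(k * c) - 1.0) * _softplus_mask(strain, 0.01)


def fiber_force(params: MuscleParams, a, lm_norm, vm_norm):
    """Total fiber force along the fiber (N)."""
    fl = active_force_length(lm_norm, params.fl_widen)
    fv = force_velocity(vm_norm)
    fp = passive_force_length(lm_norm)
    return params.f_max * (np.asarray(a) * fl * fv + fp)


def solve_rigid_tendon_fiber_length(params: MuscleParams, l_mtu):
    """Fiber length (m) under a rigid tendon, pennation-corrected."""
    proj = np.asarray(l_mtu) - params.l_slack
    h = params.l_opt * np.sin(params.pennation)
    # keep the sqrt argument positive and smooth near full collapse
    arg = proj**2 + h**2
    return np.sqrt(arg)


def mtu_equilibrium_residual(params: MuscleParams, state: MuscleState, l_mtu, v_mtu=0.0):
    """Fiber-tendon force balance residual (N) for a compliant tendon.

    Zero when the fiber force projected along the tendon equals the tendon
    force at the implied tendon length lt = l_mtu - lm*cos(pennation).
    """
    if np.any(np.real(np.asarray(l_mtu)) <= 0):
        raise ValueError("MTU length must be positive")
    lm = state.lm_norm * params.l_opt
    h = params.l_opt * np.sin(params.pennation)
    cos_p = np.sqrt(np.maximum(lm**2 - h**2, 1e-12)) / lm
    lt = np.asarray(l_mtu) - lm * cos_p
    ft = params.f_max * tendon_force(lt / params.l_slack)
    fm = fiber_force(params, state.activation, state.lm_norm, state.vm_norm)
    return fm * cos_p - ft


def metabolic_rate(params: MuscleParams, state: MuscleState, fiber_force_n=None,
                   fiber_velocity=None, coeffs=None) -> MetabolicTerms:
    """Per-muscle metabolic power breakdown (W), smoothed Bhargava-style.

    ``fiber_velocity`` is in m/s, shortening negative; defaults are derived
    from the normalized state if not given.
    """
    c = dict(METABOLIC_COEFFS)
    if coeffs:
        c.update(coeffs)
    a = state.activation
    if fiber_velocity is None:
        fiber_velocity = state.vm_norm * params.l_opt
    if fiber_force_n is None:
        fiber_force_n = fiber_force(params, a, state.lm_norm, state.vm_norm)
    ff = c["fraction_fast"]
    h_am_rate = (1.0 - ff) * c["activation_maintenance_slow"] + ff * c["activation_maintenance_fast"]
    h_am = params.mass * h_am_rate * a
    # shortening heat: alpha * F * |v| when shortening, smooth blend at v=0
    w = 0.5 - 0.5 * np.tanh(fiber_velocity / (c["velocity_smoothing"] * params.l_opt))
    h_s = (
        c["shortening_coeff"] * fiber_force_n * (-fiber_velocity) * w
        + c["lengthening_coeff"] * fiber_force_n * fiber_velocity * (1.0 - w)
    )
    # positive mechanical work rate (concentric only)
    p_mech = -fiber_force_n * fiber_velocity
    work = 0.5 * (p_mech + np.sqrt(p_mech**2 + c["clamp_smoothing"] ** 2))
    basal = c["basal_per_kg"] * params.mass
    # smooth non-negativity clamp on the heat sum
    heat = h_am + h_s
    heat = 0.5 * (heat + np.sqrt(heat**2 + c["clamp_smoothing"] ** 2))
    return MetabolicTerms(
        activation_maintenance=float(np.real(h_am)) if np.ndim(h_am) == 0 else h_am,
        shortening=float(np.real(heat - h_am)) if np.ndim(h_s) == 0 else heat - h_am,
        work=float(np.real(work)) if np.ndim(work) == 0 else work,
        basal=float(basal),
    )


def stacked_params(muscles: list[MuscleParams]) -> dict[str, np.ndarray]:
    """Per-muscle constants stacked into arrays for vectorized evaluation."""
    return {
        "f_max": np.array([m.f_max for m in muscles]),
        "l_opt": np.array([m.l_opt for m in muscles]),
        "l_slack": np.array([m.l_slack for m in muscles]),
        "pennation": np.array([m.pennation for m in muscles]),
        "v_max": np.array([m.v_max for m in muscles]),
        "fl_widen": np.array([m.fl_widen for m in muscles]),
        "mass": np.array([m.mass for m in muscles]),
        "tau_act": np.array([m.tau_act for m in muscles]),
        "tau_deact": np.array([m.tau_deact for m in muscles]),
    }


def rigid_tendon_forces(P: dict, a, l_mtu, v_mtu, smooth: float = 5e-3):
    """Vectorized rigid-tendon fiber mechanics over (..., n_muscles) arrays.

    Returns (force along tendon N, lm_norm, vm_norm, fiber force N,
    fiber velocity m/s). ``smooth`` keeps the fiber projection positive and
    differentiable when the MTU approaches/falls below tendon slack length.
    """
    proj = np.asarray(l_mtu) - P["l_slack"]
    proj = 0.5 * (proj + np.sqrt(proj**2 + smooth**2))
    h = P["l_opt"] * np.sin(P["pennation"])
    lm = np.sqrt(proj**2 + h**2)
    cos_p = proj / lm
    lm_norm = lm / P["l_opt"]
    vm = np.asarray(v_mtu) * cos_p              # fiber velocity m/s
    vm_norm = vm / (P["l_opt"] * P["v_max"])
    fl = active_force_length(lm_norm, P["fl_widen"])
    fv = force_velocity(vm_norm)
    fp = passive_force_length(lm_norm)
    f_fiber = P["f_max"] * (np.asarray(a) * fl * fv + fp)
    return f_fiber * cos_p, lm_norm, vm_norm, f_fiber, vm


def total_metabolic_rate(P: dict, a, f_fiber, v_fiber, coeffs=None):
    """Vectorized per-muscle total metabolic rate (W), same smoothed
    Bhargava-style model as :func:`metabolic_rate`."""
    c = dict(METABOLIC_COEFFS)
    if coeffs:
        c.update(coeffs)
    ff = c["fraction_fast"]
    h_am_rate = (1.0 - ff) * c["activation_maintenance_slow"] + ff * c["activation_maintenance_fast"]
    h_am = P["mass"] * h_am_rate * np.asarray(a)
    w = 0.5 - 0.5 * np.tanh(np.asarray(v_fiber) / (c["velocity_smoothing"] * P["l_opt"]))
    h_s = (
        c["shortening_coeff"] * f_fiber * (-np.asarray(v_fiber)) * w
        + c["lengthening_coeff"] * f_fiber * np.asarray(v_fiber) * (1.0 - w)
    )
    p_mech = -f_fiber * np.asarray(v_fiber)
    work = 0.5 * (p_mech + np.sqrt(p_mech**2 + c["clamp_smoothing"] ** 2))
    heat = h_am + h_s
    heat = 0.5 * (heat + np.sqrt(heat**2 + c["clamp_smoothing"] ** 2))
    basal = c["basal_per_kg"] * P["mass"]
    return heat + work + basal


# ---------------------------------------------------------------------------
# muscle set: the 18-unit lower-limb complement with constant moment arms
# ---------------------------------------------------------------------------

@dataclass
class MuscleSet:
    """The full muscle complement plus path geometry.

    ``moment_arms`` maps muscle index -> {coordinate name: arm (m)}; the MTU
    length is L_ref - sum(r_j * q_j) with L_ref = l_slack + l_opt*cos(penn)
    at the zero (standing) pose.
    """

    muscles: list[MuscleParams]
    moment_arms: list[dict[str, float]]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def __len__(self):
        return len(self.muscles)

    def reference_lengths(self) -> np.ndarray:
        return np.array([m.l_slack + m.l_opt * np.cos(m.pennation) for m in self.muscles])

    def arm_matrix(self, coordinates: list[str]) -> np.ndarray:
        """(n_muscles, n_coords) constant moment-arm matrix."""
        R = np.zeros((len(self.muscles), len(coordinates)))
        for i, arms in enumerate(self.moment_arms):
            for cname, r in arms.items():
                R[i, coordinates.index(cname)] = r
        return R

    def mtu_lengths(self, q, coordinates: list[str]):
        R = self.arm_matrix(coordinates)
        return self.reference_lengths() - np.asarray(q) @ R.T

    def mtu_velocities(self, qdot, coordinates: list[str]):
        R = self.arm_matrix(coordinates)
        return -np.asarray(qdot) @ R.T


def load_muscle_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf)
    required = {"name", "f_max_generic", "l_opt", "l_slack", "pennation",
                "v_max", "tau_act", "tau_deact", "r_hip", "r_knee", "r_ankle"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"muscle table missing columns: {sorted(missing)}")
    return df


def save_muscle_table(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


def default_muscle_set(force_multiplier: float = FORCE_MULTIPLIER,
                       fl_widen: float = FL_WIDEN_DEFAULT) -> MuscleSet:
    """The 18-muscle complement (9 per leg) with doubled isometric forces."""
    ref = importlib.resources.files("exorun.data").joinpath("muscles.csv")
    with ref.open() as fh:
        df = load_muscle_table(fh)
    muscles, arms = [], []
    for side in ("r", "l"):
        for _, row in df.iterrows():
            muscles.append(
                MuscleParams(
                    name=f"{row['name']}_{side}",
                    f_max=force_multiplier * row["f_max_generic"],
                    l_opt=row["l_opt"],
                    l_slack=row["l_slack"],
                    pennation=row["pennation"],
                    v_max=row["v_max"],
                    fl_widen=fl_widen,
                    tau_act=row["tau_act"],
                    tau_deact=row["tau_deact"],
                )
            )
            a = {}
            if row["r_hip"]:
                a[f"hip_flexion_{side}"] = row["r_hip"]
            if row["r_knee"]:
                a[f"knee_angle_{side}"] = row["r_knee"]
            if row["r_ankle"]:
                a[f"ankle_angle_{side}"] = row["r_ankle"]
            arms.append(a)
    return MuscleSet(muscles, arms)
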