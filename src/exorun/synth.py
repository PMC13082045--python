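"""Synthetic study data with known ground truth.

Every input the pipeline consumes can be generated here: a periodic planar
running gait (joint coordinates + single-stance-peak ground reaction
forces), shoe-marker trajectories consistent with a chosen exotendon, and
breath-by-breath calorimetry with subject/condition effects. Generators are
pure functions of their parameters and a seed, and always return the ground
truth next to the data; nothing downstream reads the ground truth.

The gait template uses literature-shaped running curves (hip roughly
-20..40 deg, knee 0..-100 deg, ankle -20..15 deg), a duty factor of 0.35
per leg at 4 m/s, and a vertical GRF bump per stance scaled so the stride
impulse balances body weight exactly. The pelvis height trajectory is
derived from the model's foot geometry so the stance foot lightly
penetrates the ground plane (a few mm), which makes the reference roughly
consistent with the contact model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from . import skeleton as sk
from .analysis import BreathRecord, MarkerTrial
from .contact import ExotendonSpec
from .tracking import ReferenceData

__all__ = [
    "GaitTemplate",
    "CalorimetrySpec",
    "default_gait_template",
    "generate_reference_gait",
    "generate_marker_trial",
    "generate_calorimetry_dataset",
    "generate_track_sessions",
    "BROCKWAY_O2",
    "BROCKWAY_CO2",
]

# Brockway gas-exchange energy equivalents, kJ per liter
BROCKWAY_O2 = 16.58
BROCKWAY_CO2 = 4.51

# Periodic control points (stride phase 0..1, value deg) for the right leg;
# left leg is the same shifted by half a cycle. Phase 0 = right heel strike.
_JOINT_CONTROL_DEG = {
    "hip_flexion": ([0.0, 0.15, 0.35, 0.50, 0.65, 0.85, 1.0],
                    [35, 10, -18, -5, 25, 42, 35]),
    "knee_angle": ([0.0, 0.12, 0.35, 0.50, 0.65, 0.80, 0.92, 1.0],
                   [-18, -45, -28, -60, -100, -60, -20, -18]),
    "ankle_angle": ([0.0, 0.10, 0.25, 0.38, 0.50, 0.70, 0.90, 1.0],
                    [0, 10, 15, -20, -5, 5, 2, 0]),
    "mtp_angle": ([0.0, 0.25, 0.32, 0.40, 0.60, 1.0],
                  [0, 5, 25, 10, 0, 0]),
    "arm_flex": ([0.0, 0.5, 1.0], [-25, 25, -25]),
    "elbow_flex": ([0.0, 0.5, 1.0], [75, 55, 75]),
}
_TRUNK_CONTROL_DEG = {
    "pelvis_tilt": ([0.0, 0.25, 0.5, 0.75, 1.0], [-7, -9, -7, -9, -7]),
    "lumbar_extension": ([0.0, 0.25, 0.5, 0.75, 1.0], [-4, -6, -4, -6, -4]),
}

DUTY_FACTOR = 0.35
STANCE_PENETRATION = 0.006   # m, reference stance-foot sink into the ground
FLIGHT_CLEARANCE = 0.03      # m


def _periodic_spline(phases, values):
    p = np.asarray(phases, float)
    v = np.asarray(values, float)
    if p[0] != 0.0 or p[-1] != 1.0 or v[0] != v[-1]:
        raise ValueError("control points must close the period")
    return CubicSpline(p, v, bc_type="periodic")


@dataclass
class GaitTemplate:
    """Periodic stride template: coordinate splines over phase + GRF shape."""

    stride_duration: float
    speed: float
    splines: dict = field(repr=False, default_factory=dict)  # coord name -> spline(phase)->rad|m
    duty_factor: float = DUTY_FACTOR
    grf_peak_n: float = 0.0          # vertical bump peak, set by normalization
    grf_brake_n: float = 0.0

    def coords(self, phase, coordinates: list[str]):
        ph = np.mod(np.atleast_1d(phase), 1.0)
        out = np.zeros((len(ph), len(coordinates)))
        for j, name in enumerate(coordinates):
            if name in self.splines:
                out[:, j] = self.splines[name](ph)
        # forward translation is linear + wobble spline
        j = coordinates.index("pelvis_tx")
        out[:, j] = self.speed * np.atleast_1d(phase) * self.stride_duration \
            + self.splines["pelvis_tx_wobble"](ph)
        return out if np.ndim(phase) else out[0]

    def grf(self, phase):
        """(fore-aft, vertical) N per foot at stride phase(s); right foot
        stance starts at phase 0, left at 0.5."""
        ph = np.mod(np.atleast_1d(phase), 1.0)

        def leg(ph0):
            s = np.mod(ph - ph0, 1.0) / self.duty_factor
            inside = s < 1.0
            fy = np.where(inside, self.grf_peak_n * np.sin(np.pi * np.clip(s, 0, 1)), 0.0)
            fx = np.where(inside, -self.grf_brake_n * np.sin(2 * np.pi * np.clip(s, 0, 1)), 0.0)
            return np.stack([fx, fy], axis=-1)

        r, l = leg(0.0), leg(0.5)
        return (r, l) if np.ndim(phase) else (r[0], l[0])


def default_gait_template(speed=4.0, stride_duration=0.70, model=None,
                          seed=0, jitter_deg=0.0) -> GaitTemplate:
    """Build the default running-stride template for a given model.

    ``jitter_deg`` adds a small seeded perturbation to the joint control
    points (deterministic per seed)."""
    if model is None:
        model = sk.scale_model(sk.build_default_model(), sk.ScaleSpec(1.78, 73.0))
    rng = np.random.default_rng(seed)
    splines = {}
    for base, (ph, vals) in _JOINT_CONTROL_DEG.items():
        v = np.asarray(vals, float)
        if jitter_deg:
            dv = rng.normal(0.0, jitter_deg, len(v) - 1)
            v = v + np.r_[dv, dv[0]]
        spl = _periodic_spline(ph, v)
        splines[f"{base}_r"] = _DegSpline(spl)
        splines[f"{base}_l"] = _DegSpline(spl, shift=0.5)
    for name, (ph, vals) in _TRUNK_CONTROL_DEG.items():
        splines[name] = _DegSpline(_periodic_spline(ph, vals))
    splines["pelvis_tx_wobble"] = _periodic_spline(
        [0.0, 0.25, 0.5, 0.75, 1.0], [0.0, 0.012, 0.0, 0.012, 0.0])
    tpl = GaitTemplate(stride_duration, speed, splines)
    # pelvis height from foot geometry: stance foot lightly penetrates
    tpl.splines["pelvis_ty"] = _derive_pelvis_height(tpl, model)
    # normalize vertical impulse: 2 legs * peak * (2/pi) * t_stance = m g T
    m, g, T = model.total_mass, model.gravity, stride_duration
    t_st = DUTY_FACTOR * T
    tpl.grf_peak_n = m * g * T * np.pi / (4.0 * t_st)
    tpl.grf_brake_n = 0.3 * m * g
    return tpl


class _DegSpline:
    """Degrees-to-radians periodic spline wrapper with optional phase shift."""

    def __init__(self, spline, shift=0.0):
        self._s = spline
        self._shift = shift

    def __call__(self, ph):
        return np.deg2rad(self._s(np.mod(np.asarray(ph) - self._shift, 1.0)))


def _derive_pelvis_height(tpl: GaitTemplate, model: sk.SkeletonModel):
    """Periodic pelvis_ty spline: lowest sole point tracks the ground with a
    small stance penetration and a flight-phase clearance bump."""
    ph = np.linspace(0.0, 1.0, 41)
    names = model.coordinates
    q = np.zeros((len(ph), len(names)))
    for j, name in enumerate(names):
        if name in tpl.splines:
            q[:, j] = tpl.splines[name](np.mod(ph, 1.0))
    sphere_r = 0.035
    pk = sk.forward_kinematics(model, q, np.zeros_like(q))
    soles = []
    for n in pk.names:
        if n.startswith("contact"):
            p, _ = pk.point(n)
            soles.append(p[..., 1] - sphere_r)
    sole_min = np.min(np.stack(soles, axis=0), axis=0)
    # clearance profile: penetration during stance windows, bump in flight
    df = tpl.duty_factor
    clear = np.full_like(ph, -STANCE_PENETRATION)
    for f0, f1 in ((df, 0.5), (0.5 + df, 1.0)):
        inflight = (ph > f0) & (ph < f1)
        s = (ph[inflight] - f0) / (f1 - f0)
        clear[inflight] = -STANCE_PENETRATION + (FLIGHT_CLEARANCE + STANCE_PENETRATION) * np.sin(np.pi * s) ** 2
    ty = -sole_min + clear
    ty[-1] = ty[0]
    return CubicSpline(ph, ty, bc_type="periodic")


def generate_reference_gait(speed: float = 4.0, stride_duration: float = 0.70,
                            seed: int = 0, model: sk.SkeletonModel | None = None,
                            n_samples: int = 201, jitter_deg: float = 0.0) -> ReferenceData:
    """Periodic reference running kinematics + GRFs for the tracking problem.

    Deterministic for a given (parameters, seed). The vertical GRF impulse
    over the stride equals m*g*T exactly by construction, and the average
    forward speed is exactly ``speed``.
    """
    if speed <= 0 or stride_duration <= 0:
        raise ValueError("speed and stride duration must be positive")
    if model is None:
        model = sk.scale_model(sk.build_default_model(), sk.ScaleSpec(1.78, 73.0))
    tpl = default_gait_template(speed, stride_duration, model, seed=seed,
                                jitter_deg=jitter_deg)
    phase = np.linspace(0.0, 1.0, n_samples)
    t = phase * stride_duration
    coords = tpl.coords(phase, model.coordinates)
    grf_r, grf_l = tpl.grf(phase)
    return ReferenceData(time=t, coords=coords, grf_r=grf_r, grf_l=grf_l,
                         speed=speed, stride_duration=stride_duration)


# ---------------------------------------------------------------------------
# marker trials
# ---------------------------------------------------------------------------

def default_separation_profile(phase, stride_length=None, speed=4.0,
                               stride_duration=0.70, ml_offset=0.25):
    """3-D inter-marker (shoe-to-shoe) distance over stride phase (m)."""
    if stride_length is None:
        stride_length = speed * stride_duration
    dx = 0.5 * 0.4 * stride_length * np.sin(2 * np.pi * np.asarray(phase))
    return np.sqrt((2 * dx) ** 2 + ml_offset**2)


def generate_marker_trial(spec: ExotendonSpec, duration: float = 20.0,
                          stride_duration: float = 0.70, speed: float = 4.0,
                          noise_m: float = 0.0, seed: int = 0,
                          rate_hz: float = 200.0, runner_id: str = "S01"):
    """Two shoe-marker trajectories at 200 Hz plus ground-truth tension.

    The inter-marker distance follows :func:`default_separation_profile`;
    tension ground truth is the exact piecewise spring law evaluated on the
    noiseless geometry. Marker vertical position has its per-cycle minima at
    heel strikes so gait segmentation works on the same data. Isotropic
    Gaussian noise (``noise_m``) is added after construction.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    phase = t / stride_duration
    sep = default_separation_profile(phase, speed=speed, stride_duration=stride_duration)
    ml = 0.25
    dx = np.sqrt(np.maximum(sep**2 - ml**2, 0.0))
    x_mid = speed * t
    y_r = 0.05 + 0.025 * (1.0 - np.cos(2 * np.pi * phase))        # minima at right strikes
    y_l = 0.05 + 0.025 * (1.0 - np.cos(2 * np.pi * (phase - 0.5)))
    # distribute the planar separation between the feet with the correct sign
    p_r = np.stack([x_mid + 0.5 * dx * np.sign(np.sin(2 * np.pi * phase)), y_r,
                    np.full(n, -ml / 2)], axis=-1)
    p_l = np.stack([x_mid - 0.5 * dx * np.sign(np.sin(2 * np.pi * phase)), y_l,
                    np.full(n, ml / 2)], axis=-1)
    # exact 3-D distance includes the small vertical offset; recompute truth
    dist_xy_z = np.sqrt(np.sum((p_l - p_r) ** 2, axis=-1))
    tension_truth = spec.stiffness * np.maximum(0.0, dist_xy_z - spec.slack_length)
    if noise_m > 0:
        p_r = p_r + rng.normal(0.0, noise_m, p_r.shape)
        p_l = p_l + rng.normal(0.0, noise_m, p_l.shape)
    trial = MarkerTrial(
        marker_names=["shoe_r", "shoe_l"],
        positions=np.stack([p_r, p_l], axis=1),
        rate_hz=rate_hz,
        exotendon=spec,
        runner_id=runner_id,
    )
    return trial, tension_truth


# ---------------------------------------------------------------------------
# calorimetry
# ---------------------------------------------------------------------------

#: measured-scale defaults: net running cost ~15.8 W/kg at 4 m/s so a
#: -0.9 W/kg change is the headline -5.7%; condition effects multiplicative.
DEFAULT_CONDITION_EFFECTS = {
    "natural": 1.0,
    "medium-original": 0.943,
    "long-compliant": 0.981,
    "short-stiff": 0.962,
    "long-stiff": 0.981,
}


@dataclass
class CalorimetrySpec:
    n_subjects: int = 11
    baseline_net_w_kg: float = 15.8
    baseline_sd_w_kg: float = 1.6
    standing_w_kg: float = 1.5
    standing_sd_w_kg: float = 0.15
    condition_effects: dict = field(default_factory=lambda: dict(DEFAULT_CONDITION_EFFECTS))
    effect_sd: float = 0.057          # between-subject SD of the condition effect
    breath_noise_sd: float = 0.06     # log-normal multiplicative on power
    breath_rate_hz: float = 0.75
    trial_minutes: float = 6.0
    standing_minutes: float = 5.0
    body_mass_kg: float = 68.0
    body_mass_sd: float = 7.0
    rer_mean: float = 0.88
    rer_sd: float = 0.035
    rer_exceed_rate: float = 0.0      # probability a trial's mean RER is ~1.02
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        for f in ("baseline_sd_w_kg", "effect_sd", "breath_noise_sd", "rer_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def _breath_series(rng, power_w, rer, minutes, rate_hz, noise_sd):
    n = int(round(minutes * 60 * rate_hz))
    dt = 1.0 / rate_hz
    t = np.cumsum(np.full(n, dt)) + rng.uniform(0, dt * 0.1, n).cumsum() * 0
    noise = np.exp(rng.normal(0.0, noise_sd, n)) if noise_sd > 0 else np.ones(n)
    p = power_w * noise
    # invert the Brockway equation at the trial RER
    vo2 = p * 60.0 / ((BROCKWAY_O2 + BROCKWAY_CO2 * rer) * 1000.0)
    vco2 = vo2 * rer
    return t, vo2, vco2


def generate_calorimetry_dataset(spec: CalorimetrySpec):
    """Breath-by-breath records per subject x condition + ground truth.

    Returns (records, truth): ``records`` maps subject id ->
    {"standing": BreathRecord, condition: BreathRecord}; ``truth`` maps
    condition -> expected percent change of net power vs natural and carries
    per-subject realized effects under "subject_effects".
    """
    rng = np.random.default_rng(spec.seed)
    records = {}
    subject_effects = {}
    conditions = [c for c in spec.condition_effects if c != "natural"]
    for s in range(spec.n_subjects):
        sid = f"S{s + 1:02d}"
        mass = max(40.0, rng.normal(spec.body_mass_kg, spec.body_mass_sd))
        net_nat = rng.normal(spec.baseline_net_w_kg, spec.baseline_sd_w_kg)
        standing = max(0.8, rng.normal(spec.standing_w_kg, spec.standing_sd_w_kg))
        rec = {}
        t, vo2, vco2 = _breath_series(
            rng, standing * mass, spec.rer_mean * 0.92, spec.standing_minutes,
            spec.breath_rate_hz, spec.breath_noise_sd)
        rec["standing"] = BreathRecord(time_s=t, vo2_l_min=vo2, vco2_l_min=vco2,
                                       label=f"{sid}-standing", body_mass_kg=mass)
        eff_s = {}
        for cond, eff in spec.condition_effects.items():
            mult = eff if cond == "natural" else eff * np.exp(rng.normal(0.0, spec.effect_sd))
            eff_s[cond] = mult
            rer = spec.rer_mean + rng.normal(0.0, spec.rer_sd)
            if spec.rer_exceed_rate > 0 and rng.random() < spec.rer_exceed_rate:
                rer = 1.02 + abs(rng.normal(0.0, 0.01))
            gross = (net_nat * mult + standing) * mass
            t, vo2, vco2 = _breath_series(rng, gross, rer, spec.trial_minutes,
                                          spec.breath_rate_hz, spec.breath_noise_sd)
            rec[cond] = BreathRecord(time_s=t, vo2_l_min=vo2, vco2_l_min=vco2,
                                     label=f"{sid}-{cond}", body_mass_kg=mass)
        records[sid] = rec
        subject_effects[sid] = eff_s
    truth = {c: 100.0 * (spec.condition_effects[c] - 1.0) for c in conditions}
    truth["subject_effects"] = subject_effects
    return records, truth


def generate_track_sessions(n_runners: int = 10, seed: int = 0,
                            time_effect_s: float = -13.5, time_sd_s: float = 24.6,
                            hr_effect_bpm: float = -3.9, hr_sd_bpm: float = 3.8,
                            cadence_effect_spm: float = 15.9, cadence_sd_spm: float = 9.6):
    """Paired 5-km track sessions (natural vs exotendon) per runner.

    Returns a tidy DataFrame: runner, condition, time_s, hr_bpm, cadence_spm.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_runners):
        rid = f"R{r + 1:02d}"
        t_nat = rng.normal(1150.0, 60.0)
        hr_nat = rng.normal(175.0, 6.0)
        cad_nat = rng.normal(172.0, 6.0)
        rows.append(dict(runner=rid, condition="natural", time_s=t_nat,
                         hr_bpm=hr_nat, cadence_spm=cad_nat))
        rows.append(dict(runner=rid, condition="exotendon",
                         time_s=t_nat + rng.normal(time_effect_s, time_sd_s),
                         hr_bpm=hr_nat + rng.normal(hr_effect_bpm, hr_sd_bpm),
                         cadence_spm=cad_nat + rng.normal(cadence_effect_spm, cadence_sd_spm)))
    return pd.DataFrame(rows)
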