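"""Smoothed Hunt-Crossley foot-ground contact and the exotendon spring.

Contact follows the smooth sphere-to-halfspace construction used by
gradient-based gait optimizers: a Hertz-type elastic normal force with
Hunt-Crossley velocity-dependent dissipation, made differentiable across
lift-off by a smooth penetration-depth blend, plus a smoothed Coulomb +
viscous friction law tangentially.

The exotendon is a linear extension spring between calcaneal anchor points:
tension = k * max(0, distance - slack). The optimizer uses a softplus-
smoothed variant (width ``smoothing`` m); analysis paths use the exact
piecewise form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactSphereSpec",
    "ExotendonSpec",
    "EXOTENDON_PRESETS",
    "DEFAULT_LEG_LENGTH",
    "contact_force",
    "exotendon_tension",
    "exotendon_generalized_forces",
]

DEFAULT_LEG_LENGTH = 0.92  # m, scaled simulation model

# smoothing width for the penetration-depth blend (m)
_DEPTH_SMOOTH = 1e-4


@dataclass
class ContactSphereSpec:
    radius: float = 0.035            # m
    stiffness: float = 10e6          # Pa (plane-strain modulus of the pair)
    dissipation: float = 1.0         # s/m
    mu_static: float = 0.8
    mu_dynamic: float = 0.8
    mu_viscous: float = 0.5
    transition_velocity: float = 0.2  # m/s
    center_offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        for f in ("stiffness", "dissipation", "mu_static", "mu_dynamic",
                  "mu_viscous", "transition_velocity"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass(frozen=True)
class ExotendonSpec:
    """Linear extension spring between the two calcaneal anchors.

    ``slack_length`` in meters; use :meth:`from_percent` to build from a
    slack length given as percent of leg length.
    """

    stiffness: float                 # N/m
    slack_length: float              # m
    anchors: tuple[str, str] = ("anchor_r", "anchor_l")
    name: str | None = None

    def __post_init__(self):
        if self.stiffness < 0:
            raise ValueError("stiffness must be >= 0")
        if self.slack_length <= 0:
            raise ValueError("slack length must be > 0")

    @classmethod
    def from_percent(cls, stiffness: float, slack_pct: float,
                     leg_length: float = DEFAULT_LEG_LENGTH, name=None):
        return cls(stiffness, slack_pct / 100.0 * leg_length, name=name)

    @property
    def slack_pct(self) -> float:
        return 100.0 * self.slack_length / DEFAULT_LEG_LENGTH

    def to_dict(self) -> dict:
        """Small JSON/YAML design schema."""
        return dict(stiffness_n_per_m=self.stiffness, slack_m=self.slack_length,
                    **({"name": self.name} if self.name else {}))

    @classmethod
    def from_dict(cls, d: dict, leg_length: float = DEFAULT_LEG_LENGTH):
        """Accepts {stiffness_n_per_m, slack_pct_leg_length | slack_m}."""
        k = d["stiffness_n_per_m"]
        if "slack_m" in d:
            return cls(k, d["slack_m"], name=d.get("name"))
        return cls.from_percent(k, d["slack_pct_leg_length"], leg_length=leg_length,
                                name=d.get("name"))


# The four named configurations carried forward to experiments:
# (stiffness N/m, slack length % leg length)
EXOTENDON_PRESETS = {
    "medium-original": (120.0, 25.0),
    "long-stiff": (240.0, 37.5),
    "short-stiff": (240.0, 12.5),
    "long-compliant": (30.0, 37.5),
}


def _smooth_pos(x, width):
    """Smooth max(0, x); exact as width -> 0, C-infinity, complex-safe."""
    return 0.5 * (x + np.sqrt(x**2 + width**2))


def contact_force(sphere: ContactSphereSpec, position, velocity, ground_height=0.0):
    """Ground-frame force (…, 2) on a sphere center at ``position`` (…, 2).

    Normal (y) component: smoothed Hertz/Hunt-Crossley
    ``(4/3) E* sqrt(r) d^(3/2) (1 + 1.5 c d_dot)``, clamped smoothly
    non-negative. Tangential (x) component: smoothed Coulomb
    (``mu_d * N * tanh(vx / v_t)``) plus viscous drag, opposing motion.
    """
    p = np.asarray(position)
    v = np.asarray(velocity)
    depth_raw = ground_height + sphere.radius - p[..., 1]
    ddot = -v[..., 1]
    d = _smooth_pos(depth_raw, _DEPTH_SMOOTH)
    k_hertz = (4.0 / 3.0) * sphere.stiffness * np.sqrt(sphere.radius)
    f_elastic = k_hertz * d ** 1.5
    hc = 1.0 + 1.5 * sphere.dissipation * ddot
    fn = _smooth_pos(f_elastic * hc, 1e-6)
    # suppress the (tiny) residual force when well above ground
    gate = 0.5 + 0.5 * np.tanh(depth_raw / _DEPTH_SMOOTH)
    fn = fn * gate
    vx = v[..., 0]
    ft = -fn * (sphere.mu_dynamic * np.tanh(vx / sphere.transition_velocity)
                + sphere.mu_viscous * vx)
    return np.stack([ft, fn], axis=-1)


def exotendon_tension(distance, spec: ExotendonSpec, smoothing: float = 0.0):
    """Spring tension (N) at a given anchor separation (m).

    ``smoothing`` > 0 selects the softplus-smoothed variant used inside the
    optimizer (max abs error < smoothing * k / 2); the default exact
    piecewise form is used on all analysis paths.
    """
    d = np.asarray(distance)
    if np.any(np.real(d) < 0):
        raise ValueError("anchor distance must be non-negative")
    stretch = d - spec.slack_length
    if smoothing > 0:
        return spec.stiffness * _smooth_pos(stretch, smoothing)
    return spec.stiffness * np.maximum(0.0, stretch)


def exotendon_generalized_forces(model, q, spec: ExotendonSpec, smoothing: float = 0.0):
    """Equal/opposite anchor forces from the exotendon at pose ``q``.

    Returns a list of (point_name, force (…, 2)) pairs suitable for
    :func:`exorun.skeleton.dynamics_residual`. The force acts along the 3-D
    line between the anchors (the constant mediolateral anchor offset enters
    the distance and the line of action; only the planar force components
    act on the planar dynamics).
    """
    from . import skeleton as sk

    q = np.asarray(q)
    pk = sk.forward_kinematics(model, q, np.zeros_like(q))
    pr, _ = pk.point(spec.anchors[0])
    pl, _ = pk.point(spec.anchors[1])
    delta = pl - pr                       # (…, 3)
    dist = np.sqrt(np.sum(delta**2, axis=-1) + 1e-12)
    tension = exotendon_tension(dist, spec, smoothing=smoothing)
    direction = delta / dist[..., None]
    f_on_r = tension[..., None] * direction[..., :2]
    return [(spec.anchors[0], f_on_r), (spec.anchors[1], -f_on_r)]
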