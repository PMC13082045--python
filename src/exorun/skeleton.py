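"""Planar 20-coordinate musculoskeletal skeleton: kinematics and dynamics.

The skeleton is a sagittal-plane rigid-body tree: a pelvis connected to the
ground through two translations and a rotation, a torso (lumbar joint), and
per side thigh, shank, foot (calcaneus), toes, upper arm and forearm. The
model carries the full 20-coordinate layout of its 3-D ancestors (pelvis
list/rotation and lumbar bending/rotation exist as coordinates) but those
out-of-plane coordinates are locked to zero by default, so the dynamics are
effectively planar.

Dynamics are evaluated with a recursive Newton-Euler pass over the planar
tree (batched over a leading sample axis and safe for complex-step
differentiation), returning the implicit residual

    residual(q, qdot, qddot, forces) = tau_required - tau_applied

which is zero exactly when the equations of motion are satisfied. The mass
matrix is assembled column-by-column from the same pass.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

GRAVITY = 9.81

__all__ = [
    "Segment",
    "Joint",
    "PointSpec",
    "ScaleSpec",
    "SkeletonModel",
    "PointKinematics",
    "build_default_model",
    "scale_model",
    "save_model",
    "load_model",
    "model_to_dict",
    "model_from_dict",
    "OPENSIM_COORDINATE_MAP",
    "forward_kinematics",
    "dynamics_residual",
    "mass_matrix",
    "forward_dynamics",
    "mechanical_energy",
]


@dataclass
class Segment:
    name: str
    mass: float          # kg
    inertia: float       # kg m^2, about COM, planar (z) axis
    length: float        # m, characteristic length
    com: np.ndarray      # (2,) COM offset in the segment frame


@dataclass
class Joint:
    name: str
    type: str            # "rotational" | "translational"
    parent: str
    child: str
    coordinate: str
    location: np.ndarray          # (2,) joint position in parent frame
    axis: np.ndarray | None = None  # (2,) translation axis in parent frame


@dataclass
class PointSpec:
    segment: str
    offset: np.ndarray   # (2,) in segment frame
    z: float             # constant mediolateral offset, m


@dataclass
class ScaleSpec:
    height_m: float
    mass_kg: float

    def __post_init__(self):
        if self.height_m <= 0 or self.mass_kg <= 0:
            raise ValueError("height and mass must be strictly positive")


@dataclass
class PointKinematics:
    """Ground-frame position/velocity of named model points.

    Positions are 3-vectors (x forward, y up, z mediolateral constant
    offset); velocities have zero z component.
    """

    names: list[str]
    position: np.ndarray   # (..., n_points, 3)
    velocity: np.ndarray   # (..., n_points, 3)

    def point(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.names.index(name)
        return self.position[..., i, :], self.velocity[..., i, :]


@dataclass
class SkeletonModel:
    height_m: float
    coordinates: list[str]
    locked: list[str]
    segments: dict[str, Segment]
    joints: list[Joint]
    points: dict[str, PointSpec]
    passive_joint_forces: dict[str, dict[str, float]]
    leg_length_segments: list[str]
    gravity: float = GRAVITY
    # derived, filled in __post_init__
    _tree: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self._build_tree()
        self._validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_coordinates(self) -> int:
        return len(self.coordinates)

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments.values()))

    @property
    def leg_length(self) -> float:
        return float(sum(self.segments[s].length for s in self.leg_length_segments))

    @property
    def free_coordinates(self) -> list[str]:
        return [c for c in self.coordinates if c not in self.locked]

    def coord_index(self, name: str) -> int:
        return self.coordinates.index(name)

    def free_index(self) -> np.ndarray:
        return np.array([self.coord_index(c) for c in self.free_coordinates])

    # -- internals ----------------------------------------------------------
    def _build_tree(self):
        """Flatten the joint list into a topologically ordered planar tree."""
        order: list[str] = []
        by_child = {j.child: j for j in self.joints}
        children: dict[str, list[str]] = {}
        for j in self.joints:
            children.setdefault(j.parent, []).append(j.child)
        stack = ["ground"]
        while stack:
            b = stack.pop()
            for c in sorted(children.get(b, [])):
                order.append(c)
                stack.append(c)
        tree = []
        body_index = {"ground": -1}
        cidx = {c: i for i, c in enumerate(self.coordinates)}
        for name in order:
            j = by_child[name]
            seg = self.segments.get(name)
            tree.append(
                dict(
                    body=name,
                    parent=body_index[j.parent],
                    jtype=j.type,
                    coord=cidx[j.coordinate],
                    loc=np.asarray(j.location, dtype=float),
                    axis=None if j.axis is None else np.asarray(j.axis, dtype=float),
                    mass=0.0 if seg is None else seg.mass,
                    inertia=0.0 if seg is None else seg.inertia,
                    com=np.zeros(2) if seg is None else np.asarray(seg.com, dtype=float),
                )
            )
            body_index[name] = len(tree) - 1
        self._tree = tree
        self._body_index = body_index

    def _validate(self):
        if len(self.coordinates) != 20:
            raise ValueError("model must carry exactly 20 generalized coordinates")
        if len(set(self.coordinates)) != 20:
            raise ValueError("duplicate coordinate names")
        for s in self.segments.values():
            if s.length <= 0:
                raise ValueError(f"segment {s.name} has non-positive length")
        if self.leg_length <= 0:
            raise ValueError("leg length must be positive")
        # left/right mirror symmetry of limb parameters
        for name, seg in self.segments.items():
            if name.endswith("_r"):
                other = self.segments[name[:-2] + "_l"]
                if not (
                    np.isclose(seg.mass, other.mass)
                    and np.isclose(seg.inertia, other.inertia)
                    and np.isclose(seg.length, other.length)
                ):
                    raise ValueError(f"left/right asymmetry in segment {name[:-2]}")


# Mapping from this package's coordinate names to the names used by common
# OpenSim lower-limb gait models (the dialect of the reference datasets).
# Identical names are included for completeness; an importer for external
# coordinate files should translate through this table.
OPENSIM_COORDINATE_MAP = {
    "pelvis_tilt": "pelvis_tilt",
    "pelvis_list": "pelvis_list",
    "pelvis_rotation": "pelvis_rotation",
    "pelvis_tx": "pelvis_tx",
    "pelvis_ty": "pelvis_ty",
    "lumbar_extension": "lumbar_extension",
    "lumbar_bending": "lumbar_bending",
    "lumbar_rotation": "lumbar_rotation",
    "hip_flexion_r": "hip_flexion_r",
    "knee_angle_r": "knee_angle_r",
    "ankle_angle_r": "ankle_angle_r",
    "mtp_angle_r": "mtp_angle_r",
    "hip_flexion_l": "hip_flexion_l",
    "knee_angle_l": "knee_angle_l",
    "ankle_angle_l": "ankle_angle_l",
    "mtp_angle_l": "mtp_angle_l",
    "arm_flex_r": "arm_flex_r",
    "elbow_flex_r": "elbow_flex_r",
    "arm_flex_l": "arm_flex_l",
    "elbow_flex_l": "elbow_flex_l",
}


def model_to_dict(model: SkeletonModel) -> dict:
    """Serializable document (segments, joints, points, coordinates)."""
    return dict(
        generic_height_m=model.height_m,
        gravity_m_s2=model.gravity,
        coordinates=[{"name": c, "kind": "translational" if c in ("pelvis_tx", "pelvis_ty")
                      else "rotational", "locked": c in model.locked}
                     for c in model.coordinates],
        segments={n: dict(mass=float(s.mass), inertia=float(s.inertia),
                          length=float(s.length), com=[float(v) for v in s.com])
                  for n, s in model.segments.items()},
        joints=[dict(name=j.name, type=j.type, parent=j.parent, child=j.child,
                     coordinate=j.coordinate,
                     location=[float(v) for v in j.location],
                     **({"axis": [float(v) for v in j.axis]} if j.axis is not None else {}))
                for j in model.joints],
        points={n: dict(segment=p.segment, offset=[float(v) for v in p.offset],
                        z=float(p.z)) for n, p in model.points.items()},
        passive_joint_forces=copy.deepcopy(model.passive_joint_forces),
        leg_length_segments=list(model.leg_length_segments),
    )


def model_from_dict(cfg: dict) -> SkeletonModel:
    segments = {
        name: Segment(name, d["mass"], d["inertia"], d["length"], np.asarray(d["com"], float))
        for name, d in cfg["segments"].items()
    }
    joints = [
        Joint(name=d["name"], type=d["type"], parent=d["parent"], child=d["child"],
              coordinate=d["coordinate"], location=np.asarray(d["location"], float),
              axis=np.asarray(d["axis"], float) if "axis" in d else None)
        for d in cfg["joints"]
    ]
    points = {
        name: PointSpec(d["segment"], np.asarray(d["offset"], float), float(d["z"]))
        for name, d in cfg["points"].items()
    }
    return SkeletonModel(
        height_m=cfg["generic_height_m"],
        coordinates=[c["name"] for c in cfg["coordinates"]],
        locked=[c["name"] for c in cfg["coordinates"] if c["locked"]],
        segments=segments,
        joints=joints,
        points=points,
        passive_joint_forces=cfg["passive_joint_forces"],
        leg_length_segments=cfg["leg_length_segments"],
        gravity=cfg["gravity_m_s2"],
    )


def save_model(model: SkeletonModel, path):
    """Write a model as a YAML document (round-trips with load_model)."""
    from pathlib import Path

    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def load_model(path) -> SkeletonModel:
    from pathlib import Path

    return model_from_dict(yaml.safe_load(Path(path).read_text()))


def _load_default_config() -> dict:
    ref = importlib.resources.files("exorun.data").joinpath("default_model.yaml")
    return yaml.safe_load(ref.read_text())


def build_default_model() -> SkeletonModel:
    """Generic (unscaled) planar running skeleton from the packaged config."""
    cfg = _load_default_config()
    segments = {
        name: Segment(name, d["mass"], d["inertia"], d["length"], np.asarray(d["com"], float))
        for name, d in cfg["segments"].items()
    }
    joints = [
        Joint(
            name=d["name"],
            type=d["type"],
            parent=d["parent"],
            child=d["child"],
            coordinate=d["coordinate"],
            location=np.asarray(d["location"], float),
            axis=np.asarray(d["axis"], float) if "axis" in d else None,
        )
        for d in cfg["joints"]
    ]
    points = {
        name: PointSpec(d["segment"], np.asarray(d["offset"], float), float(d["z"]))
        for name, d in cfg["points"].items()
    }
    coords = [c["name"] for c in cfg["coordinates"]]
    locked = [c["name"] for c in cfg["coordinates"] if c["locked"]]
    return SkeletonModel(
        height_m=cfg["generic_height_m"],
        coordinates=coords,
        locked=locked,
        segments=segments,
        joints=joints,
        points=points,
        passive_joint_forces=cfg["passive_joint_forces"],
        leg_length_segments=cfg["leg_length_segments"],
        gravity=cfg["gravity_m_s2"],
    )


def scale_model(model: SkeletonModel, spec: ScaleSpec) -> SkeletonModel:
    """Linearly scale a model to target anthropometry.

    Lengths (segment lengths, COM offsets, joint/point locations) scale with
    the height ratio, masses with the mass ratio, inertias with
    mass * length^2.
    """
    sh = spec.height_m / model.height_m
    sm = spec.mass_kg / model.total_mass
    segments = {
        n: Segment(n, s.mass * sm, s.inertia * sm * sh**2, s.length * sh, s.com * sh)
        for n, s in model.segments.items()
    }
    joints = [replace(j, location=j.location * sh) for j in model.joints]
    points = {
        n: PointSpec(p.segment, p.offset * sh, p.z * sh) for n, p in model.points.items()
    }
    return SkeletonModel(
        height_m=spec.height_m,
        coordinates=list(model.coordinates),
        locked=list(model.locked),
        segments=segments,
        joints=joints,
        points=points,
        passive_joint_forces=copy.deepcopy(model.passive_joint_forces),
        leg_length_segments=list(model.leg_length_segments),
        gravity=model.gravity,
    )


# ---------------------------------------------------------------------------
# Kinematics / dynamics kernels. All accept arrays with an arbitrary leading
# batch shape; complex inputs propagate (for complex-step derivatives).
# ---------------------------------------------------------------------------

def _perp(v):
    """z x v for a planar vector stored in the last axis."""
    return np.stack([-v[..., 1], v[..., 0]], axis=-1)


def _body_pass(model: SkeletonModel, q, qdot, qddot=None):
    """Propagate frame position/orientation/velocity (and acceleration) down
    the tree. Returns per-body dicts of arrays with batch shape preserved."""
    q = np.asarray(q)
    qdot = np.asarray(qdot)
    batch = q.shape[:-1]
    dt = np.result_type(q.dtype, qdot.dtype, np.float64 if qddot is None else np.asarray(qddot).dtype)
    zeros2 = np.zeros(batch + (2,), dtype=dt)
    zeros = np.zeros(batch, dtype=dt)
    bodies = []
    want_acc = qddot is not None
    for nd in model._tree:
        if nd["parent"] < 0:
            p_o, p_th = zeros2, zeros
            p_v, p_w = zeros2, zeros
            p_a, p_al = zeros2, zeros
        else:
            par = bodies[nd["parent"]]
            p_o, p_th, p_v, p_w = par["o"], par["th"], par["v"], par["w"]
            p_a, p_al = par["a"], par["al"]
        c, s = np.cos(p_th), np.sin(p_th)
        R = lambda v, c=c, s=s: np.stack(
            [c * v[..., 0] - s * v[..., 1], s * v[..., 0] + c * v[..., 1]], axis=-1
        )
        i = nd["coord"]
        qi = q[..., i]
        qdi = qdot[..., i]
        qddi = np.asarray(qddot)[..., i] if want_acc else zeros
        if nd["jtype"] == "rotational":
            r_w = R(np.broadcast_to(nd["loc"], batch + (2,)).astype(dt))
            o = p_o + r_w
            th = p_th + qi
            v = p_v + p_w[..., None] * _perp(r_w)
            w = p_w + qdi
            a = p_a + p_al[..., None] * _perp(r_w) - (p_w**2)[..., None] * r_w
            al = p_al + qddi
        else:
            u = np.broadcast_to(nd["axis"], batch + (2,)).astype(dt)
            disp = nd["loc"] + qi[..., None] * u
            r_w = R(disp)
            u_w = R(u)
            o = p_o + r_w
            th = p_th
            v = p_v + p_w[..., None] * _perp(r_w) + qdi[..., None] * u_w
            w = p_w
            a = (
                p_a
                + p_al[..., None] * _perp(r_w)
                - (p_w**2)[..., None] * r_w
                + 2.0 * p_w[..., None] * qdi[..., None] * _perp(u_w)
                + qddi[..., None] * u_w
            )
            al = p_al
        bodies.append(dict(o=o, th=th, v=v, w=w, a=a, al=al, u_w=u_w if nd["jtype"] == "translational" else None))
    return bodies


def forward_kinematics(model: SkeletonModel, q, qdot) -> PointKinematics:
    """Ground-frame kinematics of every named model point.

    ``q``/``qdot`` are length-20 coordinate vectors (batch axes allowed in
    front). Raises ``ValueError`` on wrong vector length.
    """
    q = np.asarray(q, dtype=float) if not np.iscomplexobj(q) else np.asarray(q)
    qdot = np.asarray(qdot)
    if q.shape[-1] != model.n_coordinates or qdot.shape[-1] != model.n_coordinates:
        raise ValueError(f"expected {model.n_coordinates}-vector coordinates")
    bodies = _body_pass(model, q, qdot)
    names = list(model.points)
    pos, vel = [], []
    for name in names:
        p = model.points[name]
        b = bodies[model._body_index[p.segment]]
        c, s = np.cos(b["th"]), np.sin(b["th"])
        off = np.stack(
            [c * p.offset[0] - s * p.offset[1], s * p.offset[0] + c * p.offset[1]],
            axis=-1,
        )
        xy = b["o"] + off
        vxy = b["v"] + b["w"][..., None] * _perp(off)
        z = np.broadcast_to(p.z, xy.shape[:-1])
        zz = np.zeros_like(z)
        pos.append(np.concatenate([xy, z[..., None]], axis=-1))
        vel.append(np.concatenate([vxy, zz[..., None]], axis=-1))
    return PointKinematics(names, np.stack(pos, axis=-2), np.stack(vel, axis=-2))


def _inverse_dynamics(model, q, qdot, qddot, point_forces=None, gravity=None):
    """Required generalized forces tau(q, qdot, qddot) with external point
    forces subtracted. ``point_forces``: list of (point_name, F(...,2))."""
    bodies = _body_pass(model, q, qdot, qddot)
    g = model.gravity if gravity is None else gravity
    batch = np.asarray(q).shape[:-1]
    dt = bodies[0]["o"].dtype
    ext_f = [np.zeros(batch + (2,), dtype=dt) for _ in model._tree]
    ext_n = [np.zeros(batch, dtype=dt) for _ in model._tree]
    if point_forces:
        for pname, F in point_forces:
            p = model.points[pname]
            bi = model._body_index[p.segment]
            b = bodies[bi]
            c, s = np.cos(b["th"]), np.sin(b["th"])
            off = np.stack(
                [c * p.offset[0] - s * p.offset[1], s * p.offset[0] + c * p.offset[1]],
                axis=-1,
            )
            pw = b["o"] + off
            F = np.asarray(F)
            ext_f[bi] = ext_f[bi] + F
            # torque about body origin
            ext_n[bi] = ext_n[bi] + (pw - b["o"])[..., 0] * F[..., 1] - (pw - b["o"])[..., 1] * F[..., 0]
    # backward pass
    n_b = len(model._tree)
    f = [None] * n_b
    n = [None] * n_b
    children: dict[int, list[int]] = {}
    for i, nd in enumerate(model._tree):
        children.setdefault(nd["parent"], []).append(i)
    tau = np.zeros(batch + (model.n_coordinates,), dtype=dt)
    for i in range(n_b - 1, -1, -1):
        nd = model._tree[i]
        b = bodies[i]
        c, s = np.cos(b["th"]), np.sin(b["th"])
        com_w = np.stack(
            [c * nd["com"][0] - s * nd["com"][1], s * nd["com"][0] + c * nd["com"][1]],
            axis=-1,
        )
        a_com = b["a"] + b["al"][..., None] * _perp(com_w) - (b["w"] ** 2)[..., None] * com_w
        Fg = np.zeros_like(a_com)
        Fg[..., 1] = -nd["mass"] * g
        F_net = nd["mass"] * a_com - Fg - ext_f[i]
        # ext_n holds moment about body origin; recompute about COM
        N_net = nd["inertia"] * b["al"] - (
            ext_n[i] - (com_w[..., 0] * ext_f[i][..., 1] - com_w[..., 1] * ext_f[i][..., 0])
        )
        fi = F_net.copy()
        ni = N_net + com_w[..., 0] * F_net[..., 1] - com_w[..., 1] * F_net[..., 0]
        for ci in children.get(i, []):
            d = bodies[ci]["o"] - b["o"]
            fi = fi + f[ci]
            ni = ni + n[ci] + d[..., 0] * f[ci][..., 1] - d[..., 1] * f[ci][..., 0]
        f[i], n[i] = fi, ni
        if nd["jtype"] == "rotational":
            tau[..., nd["coord"]] = ni
        else:
            tau[..., nd["coord"]] = np.sum(fi * b["u_w"], axis=-1)
    return tau


def dynamics_residual(
    model: SkeletonModel,
    q,
    qdot,
    qddot,
    point_forces=None,
    generalized_forces=None,
    include_passive=True,
):
    """Implicit equations-of-motion residual, one entry per coordinate.

    residual = M(q) qddot + bias(q, qdot) - tau_applied. Zero iff the
    dynamics are satisfied. Locked (out-of-plane) coordinates contribute a
    trivial ``qddot`` residual. ``point_forces`` is a list of
    (point_name, force (...,2)) pairs; ``generalized_forces`` a (..., 20)
    array of applied coordinate torques/forces (muscles, ideal actuators).
    """
    q, qdot, qddot = (np.asarray(a) for a in (q, qdot, qddot))
    nq = model.n_coordinates
    if not (q.shape[-1] == qdot.shape[-1] == qddot.shape[-1] == nq):
        raise ValueError(f"expected {nq}-vector coordinates")
    res = _inverse_dynamics(model, q, qdot, qddot, point_forces=point_forces)
    if include_passive:
        for cname, pf in model.passive_joint_forces.items():
            i = model.coord_index(cname)
            res[..., i] = res[..., i] + pf["stiffness"] * q[..., i] + pf["damping"] * qdot[..., i]
    if generalized_forces is not None:
        res = res - np.asarray(generalized_forces)
    for cname in model.locked:
        res[..., model.coord_index(cname)] = qddot[..., model.coord_index(cname)]
    return res


def mass_matrix(model: SkeletonModel, q, free_only: bool = True):
    """Joint-space mass matrix via inverse-dynamics columns (single sample)."""
    q = np.asarray(q, dtype=float)
    nq = model.n_coordinates
    qd0 = np.zeros(nq)
    bias = _inverse_dynamics(model, q, qd0, qd0, gravity=0.0)
    cols = []
    for i in range(nq):
        e = np.zeros(nq)
        e[i] = 1.0
        cols.append(_inverse_dynamics(model, q, qd0, e, gravity=0.0) - bias)
    M = np.stack(cols, axis=-1)
    for cname in model.locked:
        i = model.coord_index(cname)
        M[i, :] = 0.0
        M[:, i] = 0.0
        M[i, i] = 1.0
    if free_only:
        idx = model.free_index()
        M = M[np.ix_(idx, idx)]
    return M


def forward_dynamics(
    model: SkeletonModel,
    q,
    qdot,
    point_forces=None,
    generalized_forces=None,
    free_coords=None,
    include_passive=True,
):
    """Explicit accelerations qddot solving the equations of motion.

    ``free_coords``: optional list of coordinate names treated as dynamic;
    all others are held at their current value (zero acceleration). Used for
    reduced-model tests such as a passive pendulum.
    """
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    nq = model.n_coordinates
    names = free_coords if free_coords is not None else model.free_coordinates
    idx = np.array([model.coord_index(c) for c in names])
    z = np.zeros(nq)
    rhs = -dynamics_residual(
        model, q, qdot, z, point_forces=point_forces,
        generalized_forces=generalized_forces, include_passive=include_passive,
    )
    M = mass_matrix(model, q, free_only=False)
    qdd = np.zeros(nq)
    qdd[idx] = np.linalg.solve(M[np.ix_(idx, idx)], rhs[idx])
    return qdd


def mechanical_energy(model: SkeletonModel, q, qdot) -> float:
    """Kinetic + gravitational potential energy of the whole model (J)."""
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    M = mass_matrix(model, q, free_only=False)
    # locked coordinates have placeholder unit inertia; exclude their rates
    qd = qdot.copy()
    for cname in model.locked:
        qd[model.coord_index(cname)] = 0.0
    ke = 0.5 * qd @ M @ qd
    bodies = _body_pass(model, q, np.zeros_like(q))
    pe = 0.0
    for nd, b in zip(model._tree, bodies):
        c, s = np.cos(b["th"]), np.sin(b["th"])
        com_y = b["o"][..., 1] + s * nd["com"][0] + c * nd["com"][1]
        pe += nd["mass"] * model.gravity * com_y
    return float(ke + pe)
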