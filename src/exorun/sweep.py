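"""Design-space sweep over exotendon stiffness and slack length.

Drives the tracking optimization across the 5x5 stiffness/slack grid
(stiffness 30-240 N/m, slack 6.25-50% of leg length) and four stride
durations (90-105% of natural), keeps the minimum-cost converged stride per
design, and reports percent changes in average energetic cost relative to
natural running, peak exotendon tensions, and tension profiles over the
gait cycle (101 points from heel strike).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import skeleton as sk
from . import tracking as tr
from .contact import DEFAULT_LEG_LENGTH, EXOTENDON_PRESETS, ExotendonSpec, exotendon_tension

__all__ = [
    "DesignGrid",
    "DesignResult",
    "SweepResult",
    "enumerate_designs",
    "percent_change",
    "extract_tension_profile",
    "solution_tension",
    "run_sweep",
    "rank_designs",
]

STIFFNESS_GRID = (30.0, 60.0, 120.0, 180.0, 240.0)       # N/m
SLACK_GRID_PCT = (6.25, 12.5, 25.0, 37.5, 50.0)          # % leg length
STRIDE_MULTIPLIERS = (0.90, 0.95, 1.00, 1.05)


@dataclass
class DesignGrid:
    stiffness: tuple = STIFFNESS_GRID
    slack_pct: tuple = SLACK_GRID_PCT
    leg_length: float = DEFAULT_LEG_LENGTH
    stride_multipliers: tuple = STRIDE_MULTIPLIERS

    def __post_init__(self):
        if list(self.stride_multipliers) != sorted(self.stride_multipliers):
            raise ValueError("stride multipliers must be ascending")
        if not self.stiffness or not self.slack_pct:
            raise ValueError("grid axes must be non-empty")


@dataclass
class DesignResult:
    spec: ExotendonSpec
    converged: bool
    best_multiplier: float | None
    cost_w_kg: float
    percent_change: float
    peak_tension_n: float
    tension_profile: np.ndarray | None   # (101,) over the gait cycle
    per_stride: dict = field(default_factory=dict)  # multiplier -> (cost, converged)


@dataclass
class SweepResult:
    grid: DesignGrid
    natural_cost_w_kg: float
    natural_multiplier: float
    designs: list[DesignResult]

    def table(self) -> pd.DataFrame:
        """Percent-change table, rows = stiffness (N/m), columns = slack (%);
        non-converged cells hold NaN (never silently dropped)."""
        tab = pd.DataFrame(
            np.full((len(self.grid.stiffness), len(self.grid.slack_pct)), np.nan),
            index=pd.Index(self.grid.stiffness, name="stiffness_n_per_m"),
            columns=pd.Index(self.grid.slack_pct, name="slack_pct_leg_length"),
        )
        for d in self.designs:
            if d.converged:
                tab.loc[d.spec.stiffness, round(d.spec.slack_pct, 4)] = d.percent_change
        return tab


def enumerate_designs(grid: DesignGrid) -> list[ExotendonSpec]:
    """Cartesian product of the grid, stiffness-major deterministic order."""
    out = []
    for k in grid.stiffness:
        for pct in grid.slack_pct:
            out.append(ExotendonSpec.from_percent(k, pct, leg_length=grid.leg_length,
                                                  name=f"k{k:g}-l{pct:g}"))
    return out


def percent_change(cost: float, baseline: float) -> float:
    """100 * (cost - baseline) / baseline; negative means savings."""
    if baseline <= 0:
        raise ValueError("baseline cost must be positive")
    return 100.0 * (cost - baseline) / baseline


def _heel_strike_index(sol: tr.OcpSolution, threshold_bw: float = 0.05) -> int:
    """First upcrossing of the right vertical GRF through 5% body weight."""
    fy = sol.full_grf_r[:, 1]
    thr = threshold_bw * sol.model_mass * 9.81
    above = fy > thr
    ups = np.flatnonzero(~above[:-1] & above[1:])
    return int(ups[0] + 1) if len(ups) else 0


def solution_tension(sol: tr.OcpSolution, spec: ExotendonSpec,
                     model: sk.SkeletonModel) -> np.ndarray:
    """Exact pointwise exotendon tension at every full-cycle mesh point."""
    q = sol.full_coords
    pk = sk.forward_kinematics(model, q, np.zeros_like(q))
    pr, _ = pk.point(spec.anchors[0])
    pl, _ = pk.point(spec.anchors[1])
    dist = np.sqrt(np.sum((pl - pr) ** 2, axis=-1))
    return exotendon_tension(dist, spec)


def extract_tension_profile(sol: tr.OcpSolution, spec: ExotendonSpec,
                            model: sk.SkeletonModel, n_points: int = 101):
    """Exact exotendon tension over 0-100% gait cycle from heel strike.

    Recomputes tension pointwise (exact piecewise law, no optimizer
    smoothing) from the solution kinematics, rolls the cycle to start at
    heel strike, and resamples to ``n_points``.
    """
    tension = solution_tension(sol, spec, model)[:-1]  # periodic, drop endpoint
    i0 = _heel_strike_index(sol)
    tension = np.roll(tension, -i0)
    phase = np.linspace(0.0, 1.0, len(tension) + 1)[:-1]
    grid = np.linspace(0.0, 1.0, n_points)
    return np.interp(grid, np.r_[phase, 1.0], np.r_[tension, tension[0]])


def run_sweep(model: sk.SkeletonModel, reference: tr.ReferenceData,
              grid: DesignGrid, config: tr.OcpConfig,
              solver=None, progress=None) -> SweepResult:
    """Solve the full design grid and assemble the sweep table.

    For each design every stride multiplier is solved and the minimum-cost
    converged stride kept; designs whose strides all fail are marked failed
    (the table keeps an explicit hole). A failing natural baseline is a
    fatal configuration error. ``solver`` defaults to
    :func:`exorun.tracking.solve_tracking` and is injectable for testing.
    """
    from dataclasses import replace

    solver = solver or tr.solve_tracking

    def solve_at(exo, mult):
        cfg = replace(config, stride_multiplier=mult)
        return solver(model, reference, exo, cfg)

    # natural baseline across the same stride multipliers
    nat_best = None
    nat_mult = None
    for mult in grid.stride_multipliers:
        s = solve_at(None, mult)
        if s.converged and (nat_best is None or s.average_cost_w_kg < nat_best.average_cost_w_kg):
            nat_best, nat_mult = s, mult
    if nat_best is None:
        raise RuntimeError("natural baseline failed to converge at every stride duration")
    baseline = nat_best.average_cost_w_kg

    designs = []
    for spec in enumerate_designs(grid):
        per_stride = {}
        best = None
        best_mult = None
        for mult in grid.stride_multipliers:
            try:
                s = solve_at(spec, mult)
            except Exception as exc:   # keep sweeping; record the failure
                per_stride[mult] = (np.nan, False, str(exc))
                continue
            per_stride[mult] = (s.average_cost_w_kg, s.converged)
            if s.converged and (best is None or s.average_cost_w_kg < best.average_cost_w_kg):
                best, best_mult = s, mult
        if best is None:
            designs.append(DesignResult(spec, False, None, np.nan, np.nan, np.nan,
                                        None, per_stride))
        else:
            profile = extract_tension_profile(best, spec, model)
            peak = float(solution_tension(best, spec, model).max())
            designs.append(DesignResult(
                spec, True, best_mult, best.average_cost_w_kg,
                percent_change(best.average_cost_w_kg, baseline),
                peak, profile, per_stride))
        if progress:
            progress(designs[-1])
    return SweepResult(grid, baseline, nat_mult, designs)


def rank_designs(sweep: SweepResult):
    """Designs ordered by percent change ascending (ties keep grid order).

    Returns (ordered list, named selections): the four named experimental
    presets looked up in the grid plus the predicted-optimal design.
    """
    conv = [d for d in sweep.designs if d.converged]
    order = sorted(range(len(conv)), key=lambda i: (conv[i].percent_change, i))
    ranked = [conv[i] for i in order]
    named = {}
    for name, (k, pct) in EXOTENDON_PRESETS.items():
        for d in sweep.designs:
            if np.isclose(d.spec.stiffness, k) and np.isclose(d.spec.slack_pct, pct):
                named[name] = d
                break
    if ranked:
        named["predicted-optimal"] = ranked[0]
    return ranked, named
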