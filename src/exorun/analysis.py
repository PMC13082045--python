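"""Experimental data processing: calorimetry, marker tension, statistics.

Implements the measurement pipeline applied to (synthetic or real)
recordings: breath-by-breath indirect calorimetry to net metabolic power
(Brockway gas-exchange equation, final-minute time-weighted average,
standing-baseline subtraction, exclusion of trials with mean respiratory
exchange ratio above 1.0), exotendon tension from shoe-marker Euclidean
distances (tension = stiffness x stretch), gait-cycle segmentation from
marker vertical minima, and the paired statistical workflow (Shapiro-Wilk
normality check, paired t-tests, Bonferroni correction over the comparison
family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .contact import ExotendonSpec, exotendon_tension

__all__ = [
    "BreathRecord",
    "TrialMetabolics",
    "MarkerTrial",
    "TensionResult",
    "PairedStatsResult",
    "InsufficientDataError",
    "brockway_power_w",
    "net_metabolic_power",
    "percent_change_by_condition",
    "segment_gait_cycles",
    "tension_from_markers",
    "paired_comparison",
    "track_session_compare",
    "N_CYCLE_POINTS",
]

N_CYCLE_POINTS = 101          # gait-cycle resampling grid, 0-100% inclusive
AVERAGING_WINDOW_S = 60.0     # final-minute averaging window
RER_EXCLUDE_THRESHOLD = 1.0
MAX_GAP_SAMPLES = 5           # marker gaps longer than this drop the cycle

# Brockway (gas exchange to energy) equivalents, kJ per liter
_KJ_PER_L_O2 = 16.58
_KJ_PER_L_CO2 = 4.51


class InsufficientDataError(ValueError):
    """Raised when a record is too short or has too few cycles/pairs."""


@dataclass
class BreathRecord:
    time_s: np.ndarray
    vo2_l_min: np.ndarray
    vco2_l_min: np.ndarray
    label: str
    body_mass_kg: float

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.label}: timestamps must increase")
        if np.any(np.asarray(self.vo2_l_min) < 0) or np.any(np.asarray(self.vco2_l_min) < 0):
            raise ValueError(f"{self.label}: gas flows must be non-negative")
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")


@dataclass
class TrialMetabolics:
    gross_w_kg: float
    net_w_kg: float
    mean_rer: float
    excluded: bool
    label: str = ""


@dataclass
class MarkerTrial:
    marker_names: list[str]
    positions: np.ndarray     # (n, n_markers, 3) m; NaN marks dropped samples
    rate_hz: float
    exotendon: ExotendonSpec | None = None
    runner_id: str = ""

    def __post_init__(self):
        if self.positions.ndim != 3 or self.positions.shape[1] != len(self.marker_names):
            raise ValueError("positions must be (n_samples, n_markers, 3)")


@dataclass
class TensionResult:
    cycle_profiles: np.ndarray   # (n_cycles, 101) N
    mean_profile: np.ndarray     # (101,) N
    peak_n: float
    n_cycles_used: int
    n_cycles_dropped: int


@dataclass
class PairedStatsResult:
    comparison: str
    n: int
    mean_difference: float
    sd_difference: float
    shapiro_p: float
    t_statistic: float
    p_raw: float
    p_corrected: float
    m_comparisons: int
    alpha: float = 0.05
    significant: bool = field(init=False)

    def __post_init__(self):
        self.significant = bool(self.p_corrected < self.alpha)


# ---------------------------------------------------------------------------
# calorimetry
# ---------------------------------------------------------------------------

def brockway_power_w(vo2_l_min, vco2_l_min):
    """Instantaneous energy expenditure (W) from gas-exchange rates (L/min)."""
    return (_KJ_PER_L_O2 * np.asarray(vo2_l_min)
            + _KJ_PER_L_CO2 * np.asarray(vco2_l_min)) * 1000.0 / 60.0


def _window_average(t, y, window_s):
    """Time-weighted (trapezoidal) mean of y over the final ``window_s``."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    t1 = t[-1]
    t0 = t1 - window_s
    if t0 < t[0]:
        raise InsufficientDataError(
            f"record spans {t[-1] - t[0]:.0f} s, need >= {window_s:.0f} s")
    mask = t >= t0
    tt = np.r_[t0, t[mask]]
    yy = np.r_[np.interp(t0, t, y), y[mask]]
    return np.trapezoid(yy, tt) / (t1 - t0)


def net_metabolic_power(trial: BreathRecord, standing: BreathRecord,
                        window_s: float = AVERAGING_WINDOW_S) -> TrialMetabolics:
    """Net metabolic power (W/kg) for a running trial.

    Gross power is the time-weighted Brockway power averaged over the final
    minute; the standing baseline (same averaging) is subtracted. The mean
    respiratory exchange ratio over the same window sets the exclusion flag
    (RER > 1.0 indicates anaerobic contribution).
    """
    p_trial = brockway_power_w(trial.vo2_l_min, trial.vco2_l_min)
    p_stand = brockway_power_w(standing.vo2_l_min, standing.vco2_l_min)
    gross = _window_average(trial.time_s, p_trial, window_s) / trial.body_mass_kg
    base = _window_average(standing.time_s, p_stand, window_s) / standing.body_mass_kg
    rer = _window_average(trial.time_s,
                          np.asarray(trial.vco2_l_min) / np.maximum(trial.vo2_l_min, 1e-12),
                          window_s)
    return TrialMetabolics(
        gross_w_kg=gross,
        net_w_kg=gross - base,
        mean_rer=rer,
        excluded=bool(rer > RER_EXCLUDE_THRESHOLD),
        label=trial.label,
    )


def percent_change_by_condition(trials: dict[str, TrialMetabolics],
                                natural: TrialMetabolics) -> dict[str, float]:
    """Percent change of net power per condition vs the natural trial.

    Excluded conditions map to NaN (never zero). Raises if the natural trial
    itself is excluded.
    """
    if natural.excluded:
        raise ValueError("natural running trial excluded (RER > 1.0)")
    if natural.net_w_kg <= 0:
        raise ValueError("natural net power must be positive")
    out = {}
    for cond, tm in trials.items():
        out[cond] = np.nan if tm.excluded else \
            100.0 * (tm.net_w_kg - natural.net_w_kg) / natural.net_w_kg
    return out


# ---------------------------------------------------------------------------
# marker tension
# ---------------------------------------------------------------------------

def segment_gait_cycles(trial: MarkerTrial, marker: int = 0,
                        min_period_s: float = 0.4,
                        prominence_m: float = 0.01) -> np.ndarray:
    """Cycle boundary sample indices from marker vertical-position minima.

    Successive ipsilateral foot strikes are detected as local minima of the
    chosen marker's vertical coordinate, guarded by a minimum period and a
    prominence threshold. Raises :class:`InsufficientDataError` when fewer
    than 5 cycles are found.
    """
    y = np.asarray(trial.positions[:, marker, 1], float)
    y = np.where(np.isfinite(y), y, np.nanmax(y[np.isfinite(y)]) if np.any(np.isfinite(y)) else 0.0)
    distance = max(1, int(min_period_s * trial.rate_hz))
    idx, _ = signal.find_peaks(-y, distance=distance, prominence=prominence_m)
    if len(idx) < 6:
        raise InsufficientDataError(
            f"found {max(0, len(idx) - 1)} gait cycles, need >= 5")
    return idx


def _fill_small_gaps(pos):
    """Linear interpolation of NaN gaps up to MAX_GAP_SAMPLES; returns
    (filled positions, bad-sample mask for longer gaps)."""
    pos = np.array(pos, float)
    n = len(pos)
    bad = np.zeros(n, dtype=bool)
    for c in range(pos.shape[-1]):
        y = pos[:, c]
        isnan = ~np.isfinite(y)
        if not isnan.any():
            continue
        # locate runs of NaN
        edges = np.flatnonzero(np.diff(np.r_[0, isnan.view(np.int8), 0]))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start <= MAX_GAP_SAMPLES and start > 0 and stop < n:
                y[start:stop] = np.interp(np.arange(start, stop),
                                          [start - 1, stop], [y[start - 1], y[stop % n]])
            else:
                bad[start:stop] = True
        pos[:, c] = y
    return pos, bad


def tension_from_markers(trial: MarkerTrial, spec: ExotendonSpec | None = None,
                         boundaries: np.ndarray | None = None) -> TensionResult:
    """Exotendon tension profiles from the two shoe markers.

    Tension(t) = k * max(0, ||p_L(t) - p_R(t)|| - slack) pointwise on the 3-D
    marker distance; each detected cycle is time-normalized to 101 points of
    the gait cycle and averaged within the runner. Cycles containing marker
    gaps longer than 5 samples are dropped (counted in the result).
    """
    spec = spec or trial.exotendon
    if spec is None:
        raise ValueError("no exotendon specification available")
    if boundaries is None:
        boundaries = segment_gait_cycles(trial)
    p_r, bad_r = _fill_small_gaps(trial.positions[:, 0, :])
    p_l, bad_l = _fill_small_gaps(trial.positions[:, 1, :])
    bad = bad_r | bad_l
    dist = np.sqrt(np.sum((p_l - p_r) ** 2, axis=-1))
    tension = exotendon_tension(np.where(np.isfinite(dist), dist, 0.0), spec)
    grid = np.linspace(0.0, 1.0, N_CYCLE_POINTS)
    profiles, dropped = [], 0
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        if bad[s:e + 1].any():
            dropped += 1
            continue
        ph = np.linspace(0.0, 1.0, e - s + 1)
        profiles.append(np.interp(grid, ph, tension[s:e + 1]))
    if len(profiles) < 5:
        raise InsufficientDataError(
            f"only {len(profiles)} usable cycles after gap rejection, need >= 5")
    profiles = np.asarray(profiles)
    mean_profile = profiles.mean(axis=0)
    return TensionResult(
        cycle_profiles=profiles,
        mean_profile=mean_profile,
        peak_n=float(mean_profile.max()),
        n_cycles_used=len(profiles),
        n_cycles_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def paired_comparison(values_a, values_b, m: int, alpha: float = 0.05,
                      comparison: str = "") -> PairedStatsResult:
    """Two-sided paired t-test with Bonferroni correction over ``m`` tests.

    Differences are b - a; pairs with a missing value are dropped listwise.
    A Shapiro-Wilk p-value on the differences is reported alongside.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise InsufficientDataError(f"{len(a)} complete pairs, need >= 3")
    d = b - a
    if np.allclose(d, d[0]):
        warnings.warn("zero-variance differences; t-test is degenerate",
                      RuntimeWarning, stacklevel=2)
        shapiro_p = 1.0
        tstat = np.inf if d[0] != 0 else 0.0
        p_raw = 0.0 if d[0] != 0 else 1.0
    else:
        shapiro_p = float(stats.shapiro(d).pvalue)
        tres = stats.ttest_rel(b, a)
        tstat, p_raw = float(tres.statistic), float(tres.pvalue)
    p_corr = min(1.0, p_raw * m)
    return PairedStatsResult(
        comparison=comparison,
        n=len(a),
        mean_difference=float(np.mean(d)),
        sd_difference=float(np.std(d, ddof=1)),
        shapiro_p=shapiro_p,
        t_statistic=tstat,
        p_raw=p_raw,
        p_corrected=p_corr,
        m_comparisons=m,
        alpha=alpha,
    )


TRACK_METRICS = ("time_s", "hr_bpm", "cadence_spm")


def track_session_compare(sessions, alpha: float = 0.05) -> dict[str, PairedStatsResult]:
    """Paired comparison of 5-km track metrics (exotendon minus natural).

    ``sessions`` is a tidy DataFrame with columns runner, condition
    ('natural'/'exotendon'), time_s, hr_bpm, cadence_spm. Bonferroni
    correction spans the three metrics. A faster exotendon run gives a
    negative time difference.
    """
    nat = sessions[sessions["condition"] == "natural"].set_index("runner")
    exo = sessions[sessions["condition"] == "exotendon"].set_index("runner")
    runners = nat.index.intersection(exo.index)
    out = {}
    for metric in TRACK_METRICS:
        out[metric] = paired_comparison(
            nat.loc[runners, metric].to_numpy(),
            exo.loc[runners, metric].to_numpy(),
            m=len(TRACK_METRICS), alpha=alpha,
            comparison=f"exotendon vs natural: {metric}",
        )
    return out
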