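"""Ground-truth simulator for treadmill trip-perturbation gait trials.

The generator emulates a perturbed-treadmill protocol for older adults:
participants walk on a treadmill at a slow self-selected speed (and at
that speed increased by 33%), while a tether system blocks the swing
foot at pseudorandom steps — 4 right-foot and 3 left-foot perturbations
per condition under the ``random`` scheme — across an 8-condition grid
(speed x perturbation scheme x secondary task).

The gait model is deliberately kinematic, not dynamic: the centre of
mass (CoM) oscillates sinusoidally in the anterior–posterior (AP) axis
about a treadmill-fixed mean, stance feet translate backwards at belt
speed, and swing feet follow quintic Hermite arcs to their landing
position.  The landing position of every step is *solved* so that the
anterior-boundary margin of stability (MoS) at that heel strike equals a
drawn per-step target — which makes the ground truth exact by
construction and every downstream stage testable without recorded data.

A blocking perturbation holds the swing foot's AP position fixed for
``block_duration`` seconds early in swing and then releases it; the
shortened step places the anterior base-of-support boundary behind the
extrapolated CoM, so the perturbed-step MoS is negative.  Its magnitude
is modulated by the participant's fall-risk score through
``mos_risk_slope`` (positive by default: higher risk, larger MoS).

Ground truth is defined on the *sampled* trajectories, with CoM velocity
taken as the central difference of the sampled AP series — the same
velocity convention the analysis uses — so that at zero marker noise the
pipeline reproduces the true MoS to floating-point precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .recording import TrialRecording

__all__ = [
    "SimulationParams",
    "Condition",
    "CONDITIONS",
    "PerturbationSchedule",
    "GroundTruth",
    "CohortResult",
    "ScheduleInfeasibleError",
    "generate_schedule",
    "schedule_for_condition",
    "generate_trial",
    "generate_cohort",
    "sample_risk_scores",
]

G_DEFAULT = 9.81  # m/s^2

# Fraction of the stride spent in double support after the opposite heel
# strike, and of the swing spent before a blocking tether engages.
_DOUBLE_SUPPORT_FRAC = 0.12
# the tether engages a quarter into swing, after the foot has cleared the
# toe-off minimum of the relative AP coordinate
_HOLD_ONSET_FRAC = 0.25
# Lab-frame AP foot velocities at swing onset / landing (m/s); small and
# positive so relative-to-pelvis extrema fall exactly on the event frame.
_V_SWING_START = 0.20
_V_LANDING = 0.15

STEP_LABELS = (
    "baseline",
    "preperturbation",
    "perturbed",
    "recovery1",
    "recovery2",
    "recovery3",
    "other",
)


def _default_label_mos() -> dict[str, float]:
    # Per-label mean MoS targets (m) at the cohort-mean risk score,
    # reflecting slow perturbed treadmill walking in fit older adults:
    # clearly negative perturbed step, graded recovery back toward the
    # pre-perturbation level, baseline slightly above pre-perturbation.
    return {
        "baseline": 0.119,
        "preperturbation": 0.114,
        "perturbed": -0.106,
        "recovery1": 0.074,
        "recovery2": 0.088,
        "recovery3": 0.109,
        "other": 0.119,
    }


class ScheduleInfeasibleError(ValueError):
    """Raised when a perturbation schedule cannot satisfy the spacing rule."""


@dataclass(frozen=True)
class Condition:
    """One cell of the 8-condition grid (speed x scheme x task)."""

    speed: str  # slow | fast
    scheme: str  # none | series_right | series_left | random
    task: str  # none | buzzer | basket

    def __post_init__(self) -> None:
        if (self.speed, self.scheme, self.task) not in _CONDITION_GRID:
            raise ValueError(
                f"({self.speed}, {self.scheme}, {self.task}) is not one of the "
                f"8 supported conditions: {sorted(_CONDITION_GRID)}"
            )

    @property
    def name(self) -> str:
        if self.scheme == "none":
            return "unperturbed"
        parts = [self.speed, self.scheme]
        if self.task != "none":
            parts.append(self.task)
        return "_".join(parts)


_CONDITION_GRID = {
    ("slow", "none", "none"),
    ("slow", "series_right", "none"),
    ("slow", "series_left", "none"),
    ("slow", "random", "buzzer"),
    ("slow", "random", "basket"),
    ("fast", "random", "none"),
    ("fast", "random", "buzzer"),
    ("fast", "random", "basket"),
}

#: The full condition grid, in reporting order.
CONDITIONS = (
    Condition("slow", "none", "none"),
    Condition("slow", "series_right", "none"),
    Condition("slow", "series_left", "none"),
    Condition("slow", "random", "buzzer"),
    Condition("slow", "random", "basket"),
    Condition("fast", "random", "none"),
    Condition("fast", "random", "buzzer"),
    Condition("fast", "random", "basket"),
)


@dataclass(frozen=True)
class PerturbationSchedule:
    """Ordered perturbation slots: (target step ordinal, side).

    One pseudorandom sequence is generated per condition and reused for
    every participant (``shared=True``), mirroring a protocol in which a
    single sequence is fixed at the start of the study.
    """

    entries: tuple[tuple[int, str], ...]
    seed: int
    shared: bool = True

    def __post_init__(self) -> None:
        ordinals = [o for o, _ in self.entries]
        if any(b - a <= 0 for a, b in zip(ordinals, ordinals[1:])):
            raise ValueError("schedule ordinals must be strictly increasing")
        for _, side in self.entries:
            if side not in ("left", "right"):
                raise ValueError(f"invalid side {side!r}")

    @property
    def n_right(self) -> int:
        return sum(1 for _, s in self.entries if s == "right")

    @property
    def n_left(self) -> int:
        return sum(1 for _, s in self.entries if s == "left")


@dataclass
class SimulationParams:
    """Study-level generator settings.

    Defaults encode the emulated protocol: 19 participants, 100 Hz
    capture, slow speed 0.57 (SD 0.17) m/s truncated to 0.3–0.9 m/s,
    fast = slow x 1.33, FRAT-style risk scores with mean 23.6 (SD 4.17)
    truncated to 20.4–33.3%, and a positive risk -> MoS slope.
    """

    n_participants: int = 19
    sampling_rate: float = 100.0
    slow_speed_mean: float = 0.57
    slow_speed_sd: float = 0.17
    slow_speed_min: float = 0.3
    slow_speed_max: float = 0.9
    fast_factor: float = 1.33
    step_frequency_base: float = 1.7  # steps/s
    step_length_base: float = 0.34  # m, nominal (landings are MoS-solved)
    com_oscillation_amp: float = 0.02  # m, AP CoM oscillation
    com_height: float = 0.95  # m
    step_width: float = 0.18  # m between foot centre-lines
    foot_length: float = 0.18  # m heel-to-toe-marker AP offset
    marker_noise_sd: float = 0.001  # m
    block_duration: float = 0.25  # s, swing-phase tether hold
    steps_per_trial: int = 60
    timing_sd: float = 0.03  # fractional step-duration variability
    task_variability_factor: float = 1.5
    step_mos_sd: float = 0.030  # m, per-step MoS variability
    participant_mos_sd: float = 0.0  # m, extra between-participant spread
    risk_mean: float = 23.6
    risk_sd: float = 4.17
    risk_min: float = 20.4
    risk_max: float = 33.3
    mos_risk_slope: float = 10.0  # mm MoS per risk-%-point (signed)
    label_mos_means: dict[str, float] = field(default_factory=_default_label_mos)
    g: float = G_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.fast_factor <= 0:
            raise ValueError("fast_factor must be positive")
        if not (self.risk_min <= self.risk_mean <= self.risk_max):
            raise ValueError("require risk_min <= risk_mean <= risk_max")
        if self.slow_speed_mean <= 0 or self.slow_speed_min <= 0:
            raise ValueError("speeds must be positive")
        swing = self.nominal_swing_duration
        if not (0 < self.block_duration < swing):
            raise ValueError(
                f"block_duration must lie in (0, swing duration={swing:.3f} s)"
            )
        if self.block_duration >= (1 - _HOLD_ONSET_FRAC) * swing - 0.05:
            raise ValueError(
                "block_duration leaves no release phase: the hold engages a "
                f"quarter into the {swing:.3f}-s swing and must release at "
                "least 0.05 s before the next heel strike"
            )

    @property
    def nominal_step_duration(self) -> float:
        return 1.0 / self.step_frequency_base

    @property
    def nominal_swing_duration(self) -> float:
        stride = 2.0 * self.nominal_step_duration
        return stride - (self.nominal_step_duration + _DOUBLE_SUPPORT_FRAC * stride)


@dataclass
class GroundTruth:
    """Exact per-step truth for one simulated trial."""

    steps: pd.DataFrame  # ordinal, side, hs_frame, label, mos_mm, components...
    events: pd.DataFrame  # frame, time_s, kind, side
    perturbation_frames: np.ndarray  # hold-onset frame per schedule entry
    schedule: PerturbationSchedule
    belt_speed: float  # magnitude, m/s


# ---------------------------------------------------------------------------
# schedules


def generate_schedule(
    n_right: int,
    n_left: int,
    n_steps: int,
    seed: int,
    min_spacing: int = 5,
    start_side: str = "right",
) -> PerturbationSchedule:
    """Draw a pseudorandom perturbation schedule.

    Consecutive perturbed ordinals are separated by at least
    ``min_spacing`` unperturbed steps so the pre-perturbation step and
    the three recovery steps of adjacent perturbations never overlap.
    Sides appear in randomised order; a step's side is fixed by its
    ordinal parity (feet alternate, ``start_side`` takes ordinal 0), so
    ordinals are drawn with matching parity.
    """

    if n_right < 0 or n_left < 0:
        raise ValueError("perturbation counts must be non-negative")
    rng = np.random.default_rng(seed)
    sides = ["right"] * n_right + ["left"] * n_left
    if not sides:
        return PerturbationSchedule(entries=(), seed=seed)
    sides = [sides[i] for i in rng.permutation(len(sides))]

    gap = min_spacing + 1
    last_allowed = n_steps - 5  # leave room for the 3 recovery steps
    entries: list[tuple[int, str]] = []
    prev = min_spacing - gap  # first ordinal >= min_spacing
    for i, side in enumerate(sides):
        remaining = len(sides) - 1 - i
        lo = prev + gap
        # reserve gap+1 per remaining entry: foot parity can force one
        # extra step on top of the minimum spacing
        hi = last_allowed - remaining * (gap + 1)
        parity = 0 if side == start_side else 1
        candidates = [o for o in range(lo, hi + 1) if o % 2 == parity]
        if not candidates:
            raise ScheduleInfeasibleError(
                f"cannot place perturbation {i + 1}/{len(sides)} ({side}): no "
                f"ordinal in [{lo}, {hi}] with the required foot parity satisfies "
                f"the minimum spacing of {min_spacing} unperturbed steps within "
                f"{n_steps} steps"
            )
        prev = int(rng.choice(candidates))
        entries.append((prev, side))
    return PerturbationSchedule(entries=tuple(entries), seed=seed)


def schedule_for_condition(
    condition: Condition, n_steps: int, seed: int, min_spacing: int = 5
) -> PerturbationSchedule:
    """Schedule matching a condition's scheme.

    ``random`` uses the protocol's fixed 4-right + 3-left mix;
    ``series_right``/``series_left`` place all 7 perturbations on the
    named side; ``none`` is empty.
    """

    counts = {
        "none": (0, 0),
        "random": (4, 3),
        "series_right": (7, 0),
        "series_left": (0, 7),
    }[condition.scheme]
    return generate_schedule(*counts, n_steps=n_steps, seed=seed, min_spacing=min_spacing)


# ---------------------------------------------------------------------------
# trial generation


def _quintic_hermite(t, t0, t1, p0, v0, p1, v1):
    """Quintic Hermite arc with zero endpoint accelerations (vectorised)."""
    h = t1 - t0
    s = (np.asarray(t) - t0) / h
    s2, s3 = s * s, s**3
    s4, s5 = s3 * s, s3 * s * s
    h00 = 1 - 10 * s3 + 15 * s4 - 6 * s5
    h10 = s - 6 * s3 + 8 * s4 - 3 * s5
    h01 = 10 * s3 - 15 * s4 + 6 * s5
    h11 = -4 * s3 + 7 * s4 - 3 * s5
    return h00 * p0 + h * h10 * v0 + h01 * p1 + h * h11 * v1


def _solve_landing(mos_target, com, com_vel_cd, belt_signed, foot_y, foot_length, g):
    """Heel AP landing position such that MoS at heel strike equals target.

    Fixed-point iteration on the effective leg length (CoM-to-heel 3D
    distance), which depends weakly on the solved AP position.
    """
    cx, cy, cz = com
    vrel = com_vel_cd - belt_signed
    leg = cz  # good initial guess: CoM height
    for _ in range(60):
        xcom = cx + vrel / math.sqrt(g / leg)
        heel_x = xcom + mos_target - foot_length
        new_leg = math.sqrt((cx - heel_x) ** 2 + (cy - foot_y) ** 2 + cz**2)
        if abs(new_leg - leg) < 1e-15:
            leg = new_leg
            break
        leg = new_leg
    xcom = cx + vrel / math.sqrt(g / leg)
    heel_x = xcom + mos_target - foot_length
    return heel_x, leg, xcom


def generate_trial(
    params: SimulationParams,
    condition: Condition,
    schedule: PerturbationSchedule,
    participant_risk: float,
    seed: int,
    belt_speed: float | None = None,
    participant_mos_offset: float = 0.0,
    load_peaks: tuple[tuple[int, float, int], ...] = (),
) -> tuple[TrialRecording, GroundTruth]:
    """Simulate one walking bout under ``condition``.

    Parameters
    ----------
    belt_speed
        Belt-speed magnitude (m/s); defaults to the cohort slow-speed
        mean, scaled by ``fast_factor`` for fast conditions.
    participant_mos_offset
        Additive per-participant MoS offset in metres (drawn at cohort
        level from ``participant_mos_sd``).
    load_peaks
        Explicit harness-load episodes ``(start_frame, pct_bw, n_frames)``
        so the fall-event counter has exact ground truth; the load is
        otherwise near 0 %BW.
    """

    if condition.scheme == "none" and schedule.entries:
        raise ValueError("unperturbed condition requires an empty schedule")
    if condition.scheme != "none" and not schedule.entries:
        raise ValueError(f"condition {condition.name} requires a non-empty schedule")

    fs = params.sampling_rate
    n_steps = params.steps_per_trial
    if schedule.entries and schedule.entries[-1][0] > n_steps - 4:
        raise ValueError("schedule does not fit in steps_per_trial (need 3 recovery steps)")

    if belt_speed is None:
        belt_speed = params.slow_speed_mean
        if condition.speed == "fast":
            belt_speed *= params.fast_factor
    if belt_speed <= 0:
        raise ValueError("belt speed must be positive")
    v_b = float(belt_speed)
    belt_signed = -v_b  # belt surface moves against the direction of progression

    rng = np.random.default_rng(seed)
    T = params.nominal_step_duration
    tvf = params.task_variability_factor if condition.task != "none" else 1.0
    sd_frac = np.clip(params.timing_sd * tvf, 0.0, 0.12)
    durations = T * (1.0 + np.clip(sd_frac * rng.standard_normal(n_steps), -0.3, 0.3))

    # --- step timing on the frame grid -----------------------------------
    n_virtual = 2  # bootstrap steps before the recorded bout on each end
    lead_in = max(1.0, 2.2 * T)
    t_hs = np.empty(n_steps)
    t_hs[0] = lead_in
    t_hs[1:] = lead_in + np.cumsum(durations[1:])
    # extended sequence: virtual steps before and after the real bout
    t_ext = np.concatenate(
        [t_hs[0] - T * np.arange(n_virtual, 0, -1), t_hs, t_hs[-1] + T * np.arange(1, 3)]
    )
    f_ext = np.round(t_ext * fs).astype(int)
    if np.any(np.diff(f_ext) < 2):
        raise ValueError("step frequency too high for the sampling rate")
    t_ext = f_ext / fs  # snapped
    n_ext = len(t_ext)

    def side_of(ext_i: int) -> str:
        ordinal = ext_i - n_virtual
        return "right" if ordinal % 2 == 0 else "left"

    end_frame = f_ext[n_virtual + n_steps - 1] + int(round(0.5 * fs))
    n = end_frame + 1
    frames = np.arange(n)
    t = frames / fs

    # --- CoM: sinusoid phase-locked to the step sequence ------------------
    phase_nodes_t = np.concatenate([[t_ext[0] - T], t_ext, [t_ext[-1] + T]])
    phase_nodes = 2 * np.pi * np.arange(-1, n_ext + 1)
    phase = np.interp(t, phase_nodes_t, phase_nodes)
    # AP CoM is furthest forward (and its velocity zero) at each heel
    # strike, so relative-to-pelvis foot extrema fall on the event frame.
    A = params.com_oscillation_amp
    com_x = A * np.cos(phase)
    com_y = 0.03 * np.sin(phase / 2.0)
    com_z = params.com_height - 0.012 * np.cos(phase)

    def com_vel_cd(f: int) -> float:
        """Central-difference AP CoM velocity at an in-range frame."""
        return (com_x[f + 1] - com_x[f - 1]) * fs / 2.0

    # --- per-step labels and MoS targets ----------------------------------
    labels = np.array(["baseline" if not schedule.entries else "other"] * n_steps, dtype=object)
    perturbed_ordinals = []
    for ordinal, side in schedule.entries:
        if side_of(ordinal + n_virtual) != side:
            raise ValueError(
                f"schedule side {side!r} at ordinal {ordinal} contradicts the "
                "alternating-foot parity"
            )
        labels[ordinal] = "perturbed"
        perturbed_ordinals.append(ordinal)
        if ordinal - 1 >= 0:
            labels[ordinal - 1] = "preperturbation"
        for j, lab in enumerate(("recovery1", "recovery2", "recovery3"), start=1):
            if ordinal + j < n_steps:
                labels[ordinal + j] = lab

    risk_dev = participant_risk - params.risk_mean
    risk_shift = params.mos_risk_slope / 1000.0 * risk_dev + participant_mos_offset
    # the blocked-step overshoot scales with belt speed: the belt term in
    # the extrapolated CoM grows with v_b, so faster belts destabilise more
    speed_scale = v_b / params.slow_speed_mean

    def _label_mean(lab: str) -> float:
        mean = params.label_mos_means[lab]
        return mean * speed_scale if lab == "perturbed" else mean

    mos_targets = np.array(
        [
            _label_mean(lab) + risk_shift + params.step_mos_sd * rng.standard_normal()
            for lab in labels
        ]
    )
    baseline_mos = params.label_mos_means["baseline"] + risk_shift

    # --- solve landings ----------------------------------------------------
    half_w = params.step_width / 2.0
    heel_land = np.empty(n_ext)
    leg_true = np.empty(n_ext)
    xcom_true = np.empty(n_ext)
    nominal_land = np.empty(n_ext)  # landing had the step been unperturbed
    for i in range(n_ext):
        ordinal = i - n_virtual
        f = f_ext[i]
        foot_y = -half_w if side_of(i) == "right" else half_w
        if 1 <= f <= n - 2:
            com = (com_x[f], com_y[f], com_z[f])
            vcd = com_vel_cd(f)
        else:  # virtual step outside the recording: analytic stand-in
            ph = np.interp(f / fs, phase_nodes_t, phase_nodes)
            com = (A * math.cos(ph), 0.03 * math.sin(ph / 2.0), params.com_height - 0.012 * math.cos(ph))
            ph_p = np.interp((f + 1) / fs, phase_nodes_t, phase_nodes)
            ph_m = np.interp((f - 1) / fs, phase_nodes_t, phase_nodes)
            vcd = (A * math.cos(ph_p) - A * math.cos(ph_m)) * fs / 2.0
        target = mos_targets[ordinal] if 0 <= ordinal < n_steps else baseline_mos
        heel_land[i], leg_true[i], xcom_true[i] = _solve_landing(
            target, com, vcd, belt_signed, foot_y, params.foot_length, params.g
        )
        nominal_land[i], _, _ = _solve_landing(
            baseline_mos, com, vcd, belt_signed, foot_y, params.foot_length, params.g
        )

    # --- assemble foot trajectories (integer-frame segments) --------------
    pert_ext = {o + n_virtual for o in perturbed_ordinals}
    heel = {}
    foot_z = {}
    to_events: list[tuple[int, str]] = []
    hold_onsets: dict[int, int] = {}  # perturbed ext index -> hold-onset frame
    swing_lift = 0.05
    block_frames = int(round(params.block_duration * fs))

    for side in ("right", "left"):
        own = [i for i in range(n_ext) if side_of(i) == side]
        x = np.empty(n)
        z = np.zeros(n)
        # backward extension of the first stance
        f0 = f_ext[own[0]]
        pre = frames[: min(f0, n)]
        x[pre] = heel_land[own[0]] - v_b * (pre - f0) / fs
        for i_prev, i_next in zip(own[:-1], own[1:]):
            f_prev, f_next = f_ext[i_prev], f_ext[i_next]
            f_mid = f_ext[i_prev + 1]
            stride = f_next - f_prev
            f_to = f_mid + int(round(_DOUBLE_SUPPORT_FRAC * stride))
            # stance: [f_prev, f_to)
            seg = frames[f_prev : min(f_to, n)]
            x[seg] = heel_land[i_prev] - v_b * (seg - f_prev) / fs
            if f_to >= n:
                break
            x_to = heel_land[i_prev] - v_b * (f_to - f_prev) / fs
            to_events.append((f_to, side))
            # swing: [f_to, f_next)
            seg = frames[f_to : min(f_next, n)]
            t_to, t_next = f_to / fs, f_next / fs
            if i_next in pert_ext:
                swing_frames = f_next - f_to
                f_h0 = f_to + int(round(_HOLD_ONSET_FRAC * swing_frames))
                # release at latest 5 frames before landing; short swings
                # (step-timing variability) shorten the hold accordingly
                f_h1 = min(f_h0 + block_frames, f_next - 5)
                if f_h1 <= f_h0:
                    raise ValueError(
                        "block_duration leaves no swing to complete the "
                        "perturbed step (swing too short at this timing draw)"
                    )
                hold_onsets[i_next] = f_h0
                # the shortened landing must still fall ahead of toe-off so
                # the step stays geometrically detectable; if the drawn MoS
                # target would put it behind, clamp the landing and record
                # the realized (less extreme) ground-truth MoS instead
                min_land = x_to + 0.08
                if heel_land[i_next] < min_land and f_next <= n - 2:
                    heel_land[i_next] = min_land
                    ordv = i_next - n_virtual
                    foot_y = -half_w if side == "right" else half_w
                    cx, cy, cz = com_x[f_next], com_y[f_next], com_z[f_next]
                    leg = math.sqrt((cx - min_land) ** 2 + (cy - foot_y) ** 2 + cz**2)
                    vrel = com_vel_cd(f_next) - belt_signed
                    xcom = cx + vrel / math.sqrt(params.g / leg)
                    leg_true[i_next], xcom_true[i_next] = leg, xcom
                    if 0 <= ordv < n_steps:
                        mos_targets[ordv] = min_land + params.foot_length - xcom
                x_h = float(
                    _quintic_hermite(
                        f_h0 / fs, t_to, t_next, x_to, _V_SWING_START,
                        nominal_land[i_next], _V_LANDING,
                    )
                )
                # keep the hold above the toe-off dip of the relative AP
                # coordinate and clear of the landing peak's prominence
                x_h = min(x_h, heel_land[i_next] - 0.06)
                x_h = max(x_h, x_to + 0.02)
                # early swing decelerates into the tether hold position
                sa = seg[seg < f_h0]
                x[sa] = _quintic_hermite(
                    sa / fs, t_to, f_h0 / fs, x_to, _V_SWING_START, x_h, 0.0
                )
                sb = seg[(seg >= f_h0) & (seg < f_h1)]
                x[sb] = x_h
                sc = seg[seg >= f_h1]
                x[sc] = _quintic_hermite(
                    sc / fs, f_h1 / fs, t_next, x_h, 0.0, heel_land[i_next], _V_LANDING
                )
            else:
                x[seg] = _quintic_hermite(
                    seg / fs, t_to, t_next, x_to, _V_SWING_START,
                    heel_land[i_next], _V_LANDING,
                )
            z[seg] = swing_lift * np.sin(np.pi * (seg - f_to) / (f_next - f_to))
        # forward extension of the last reachable stance
        last = max(i for i in own if f_ext[i] <= end_frame)
        fl = f_ext[last]
        post = frames[fl:]
        x[post] = heel_land[last] - v_b * (post - fl) / fs
        z[post] = 0.0
        heel[side] = x
        foot_z[side] = z

    # --- channels ----------------------------------------------------------
    markers: dict[str, np.ndarray] = {}
    for side, key in (("left", "l"), ("right", "r")):
        y = np.full(n, half_w if side == "left" else -half_w)
        markers[f"{key}_heel"] = np.column_stack([heel[side], y, foot_z[side]])
        markers[f"{key}_toe"] = np.column_stack(
            [heel[side] + params.foot_length, y, foot_z[side]]
        )
    com = np.column_stack([com_x, com_y, com_z])
    markers["com"] = com
    markers["pelvis"] = com + np.array([-0.03, 0.0, 0.10])

    # ground truth is defined on the noise-free kinematics above
    hs_frames = f_ext[n_virtual : n_virtual + n_steps]
    gt_rows = []
    for k in range(n_steps):
        i = k + n_virtual
        f = hs_frames[k]
        gt_rows.append(
            {
                "ordinal": k,
                "side": side_of(i),
                "hs_frame": int(f),
                "label": labels[k],
                "mos_mm": mos_targets[k] * 1000.0,
                "com_ap": com_x[f],
                "com_vel_ap": com_vel_cd(f),
                "belt_speed": belt_signed,
                "leg_length": leg_true[i],
                "xcom_ap": xcom_true[i],
                "bos_boundary_ap": heel_land[i] + params.foot_length,
                "perturbation_frame": hold_onsets.get(i, -1),
            }
        )
    steps_df = pd.DataFrame(gt_rows)

    ev_rows = [
        {"frame": int(f), "time_s": f / fs, "kind": "heel_strike", "side": side_of(k + n_virtual)}
        for k, f in enumerate(hs_frames)
    ]
    for f_to, side in to_events:
        if hs_frames[0] <= f_to <= hs_frames[-1]:
            ev_rows.append({"frame": int(f_to), "time_s": f_to / fs, "kind": "toe_off", "side": side})
    events_df = pd.DataFrame(ev_rows).sort_values("frame", kind="stable").reset_index(drop=True)

    perturbation_frames = np.array(
        [hold_onsets[o + n_virtual] for o, _ in schedule.entries], dtype=int
    )

    if params.marker_noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(0.0, params.marker_noise_sd, (n, 3))

    load = np.zeros(n)
    for start, pct, dur in load_peaks:
        load[start : start + dur] = np.maximum(load[start : start + dur], pct)

    recording = TrialRecording(
        markers=markers,
        belt_speed=np.full(n, belt_signed),
        harness_load=load,
        sampling_rate=fs,
        meta={
            "condition": condition.name,
            "risk_score": participant_risk,
            "belt_speed_mps": v_b,
            "seed": seed,
        },
    )
    truth = GroundTruth(
        steps=steps_df,
        events=events_df,
        perturbation_frames=perturbation_frames,
        schedule=schedule,
        belt_speed=v_b,
    )
    return recording, truth


# ---------------------------------------------------------------------------
# cohorts


@lru_cache(maxsize=16)
def _truncnorm_for_moments(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float, float, float]:
    """(a, b, loc, scale) of a truncated normal moment-matched on [lo, hi].

    The truncation bounds shift a distribution's moments, so the normal's
    own location/scale are solved such that the *truncated* mean hits
    ``mean`` and the truncated SD approaches ``sd`` as closely as the
    family allows (the mean is weighted heavily: on a strongly
    asymmetric range the two cannot always be matched simultaneously).
    """
    from scipy import optimize

    def resid(p):
        loc, log_scale = p
        s = float(np.exp(log_scale))
        a, b = (lo - loc) / s, (hi - loc) / s
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=s, moments="mv")
        return [10.0 * (m - mean) / sd, (np.sqrt(v) - sd) / sd]

    sol = optimize.least_squares(
        resid, x0=[mean, np.log(sd)], bounds=([lo - 60 * sd, np.log(sd * 1e-3)], [hi, np.log(sd * 1e3)])
    )
    loc, scale = float(sol.x[0]), float(np.exp(sol.x[1]))
    return (lo - loc) / scale, (hi - loc) / scale, loc, scale


def sample_risk_scores(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Fall-risk scores (percent) from the moment-matched truncated normal."""
    a, b, loc, scale = _truncnorm_for_moments(
        params.risk_mean, params.risk_sd, params.risk_min, params.risk_max
    )
    return stats.truncnorm.rvs(
        a, b, loc=loc, scale=scale, size=params.n_participants, random_state=rng
    )


@dataclass
class CohortResult:
    """Simulated cohort: participant table plus per-trial recordings."""

    participants: pd.DataFrame  # participant_id, risk_score, slow/fast speed
    trials: list[tuple[str, Condition, TrialRecording, GroundTruth]]
    params: SimulationParams


def generate_cohort(
    params: SimulationParams,
    conditions: tuple[Condition, ...] | None = None,
) -> CohortResult:
    """Simulate the full cohort: one trial per participant x condition.

    Risk scores and slow speeds are drawn from truncated normals; fast
    speed is slow x ``fast_factor``.  Perturbation schedules are drawn
    once per condition and shared across participants.  Fully
    reproducible from ``params.seed``.  Pass ``conditions=()`` to obtain
    the participant table alone.
    """

    if conditions is None:
        conditions = CONDITIONS
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    risks = sample_risk_scores(params, rng)
    a, b, loc, scale = _truncnorm_for_moments(
        params.slow_speed_mean, params.slow_speed_sd,
        params.slow_speed_min, params.slow_speed_max,
    )
    slow = stats.truncnorm.rvs(
        a, b, loc=loc, scale=scale, size=params.n_participants, random_state=rng
    )
    offsets = (
        params.participant_mos_sd * rng.standard_normal(params.n_participants)
        if params.participant_mos_sd > 0
        else np.zeros(params.n_participants)
    )
    ids = [f"P{i + 1:02d}" for i in range(params.n_participants)]
    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "risk_score": risks,
            "slow_speed_mps": slow,
            "fast_speed_mps": slow * params.fast_factor,
        }
    )

    schedules = {
        cond.name: schedule_for_condition(
            cond, params.steps_per_trial, seed=int(ss.generate_state(1)[0] % 2**31) + ci
        )
        for ci, cond in enumerate(conditions)
    }
    trial_seeds = ss.spawn(params.n_participants * len(conditions) + 1)[1:]
    trials = []
    si = 0
    for p in range(params.n_participants):
        for cond in conditions:
            speed = slow[p] * (params.fast_factor if cond.speed == "fast" else 1.0)
            seed = int(trial_seeds[si].generate_state(1)[0] % 2**31)
            si += 1
            rec, truth = generate_trial(
                params,
                cond,
                schedules[cond.name],
                participant_risk=float(risks[p]),
                seed=seed,
                belt_speed=float(speed),
                participant_mos_offset=float(offsets[p]),
            )
            rec.meta["participant_id"] = ids[p]
            trials.append((ids[p], cond, rec, truth))
    return CohortResult(participants=participants, trials=trials, params=params)
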