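"""Gait event detection and perturbation-relative step labeling.

Heel strikes and toe-offs are detected from marker kinematics with a
coordinate-based (Zeni-style) rule relative to the pelvis: a heel strike
is a local maximum of (heel AP - pelvis AP) and a toe-off a local
minimum of (toe AP - pelvis AP), which is the standard choice for
treadmill data without force plates.  Manual overrides can replace or
insert events, mimicking frame-by-frame review of ambiguous strides.

A *step* is the interval between consecutive heel strikes of opposite
feet, indexed by its terminating heel strike (where the margin of
stability is evaluated).  Given the perturbation onset frames, each
perturbation is assigned to the step whose swing phase contains it; that
step is ``perturbed``, its predecessor ``preperturbation`` and its three
successors ``recovery1..3``.  Steps of an unperturbed bout are
``baseline``; everything else is ``other``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .recording import TrialRecording
from .synthetic_data import PerturbationSchedule

__all__ = ["GaitEvent", "StepRecord", "detect_events", "segment_steps", "LabelConflictError"]

#: replace rather than insert a manual event within this many frames
OVERRIDE_RADIUS = 10


class LabelConflictError(ValueError):
    """Two perturbations claim overlapping step-label windows."""


@dataclass(frozen=True, order=True)
class GaitEvent:
    frame: int
    time: float
    kind: str  # heel_strike | toe_off
    side: str  # left | right
    source: str = "auto"  # auto | manual

    def __post_init__(self):
        if self.kind not in ("heel_strike", "toe_off"):
            raise ValueError(f"invalid event kind {self.kind!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"invalid side {self.side!r}")


@dataclass
class StepRecord:
    ordinal: int
    side: str
    hs_frame: int
    label: str = "other"
    condition: str | None = None
    perturbation_id: int | None = None


def _relative_extrema(series: np.ndarray, fs: float, maxima: bool) -> np.ndarray:
    """Peak frames of a relative AP coordinate, >=0.4 median stride apart."""
    sig = series if maxima else -series
    if np.ptp(sig) < 1e-6:
        raise ValueError("trajectory has no gait-like oscillation (flat signal)")
    # robust amplitude (2nd-98th percentile) so lead-in/out transients do
    # not inflate the prominence floor and drop shortened perturbed steps
    span = float(np.percentile(sig, 98) - np.percentile(sig, 2))
    if span < 1e-6:
        raise ValueError("trajectory has no gait-like oscillation (flat signal)")
    prominence = 0.05 * span
    # first pass with a conservative physiological bound, then refine the
    # spacing constraint with the observed median stride period
    first, _ = find_peaks(sig, distance=max(int(0.3 * fs), 1), prominence=prominence)
    if len(first) < 3:
        raise ValueError("fewer than 2 detectable strides")
    stride = np.median(np.diff(first))
    peaks, _ = find_peaks(sig, distance=max(int(0.4 * stride), 1), prominence=prominence)
    if len(peaks) < 3:
        raise ValueError("fewer than 2 detectable strides")
    return peaks


def detect_events(recording: TrialRecording) -> list[GaitEvent]:
    """Detect heel-strike and toe-off events for both sides.

    Requires gap-filled heel, toe and pelvis markers.  Raises
    ``ValueError`` when fewer than two strides are detectable.
    """

    recording.require_markers(("l_heel", "r_heel", "l_toe", "r_toe", "pelvis"))
    fs = recording.sampling_rate
    pelvis = recording.markers["pelvis"][:, 0]
    events: list[GaitEvent] = []
    for side, key in (("left", "l"), ("right", "r")):
        heel = recording.markers[f"{key}_heel"][:, 0] - pelvis
        toe = recording.markers[f"{key}_toe"][:, 0] - pelvis
        for f in _relative_extrema(heel, fs, maxima=True):
            events.append(GaitEvent(int(f), f / fs, "heel_strike", side))
        for f in _relative_extrema(toe, fs, maxima=False):
            events.append(GaitEvent(int(f), f / fs, "toe_off", side))
    return sorted(events)


def apply_overrides(
    events: Sequence[GaitEvent], overrides: Iterable[GaitEvent]
) -> list[GaitEvent]:
    """Merge manual events: replace an automatic event of the same kind
    and side within ``OVERRIDE_RADIUS`` frames, otherwise insert."""
    merged = list(events)
    for ov in overrides:
        matches = [
            i
            for i, ev in enumerate(merged)
            if ev.kind == ov.kind and ev.side == ov.side and abs(ev.frame - ov.frame) <= OVERRIDE_RADIUS
        ]
        if matches:
            closest = min(matches, key=lambda i: abs(merged[i].frame - ov.frame))
            merged[closest] = ov
        else:
            merged.append(ov)
    return sorted(merged)


def _check_alternation(events: Sequence[GaitEvent]) -> None:
    for side in ("left", "right"):
        kinds = [ev.kind for ev in events if ev.side == side]
        for a, b in zip(kinds, kinds[1:]):
            if a == b:
                raise ValueError(
                    f"{side} events do not alternate heel_strike/toe_off ({a!r} twice)"
                )


def segment_steps(
    events: Sequence[GaitEvent],
    schedule: PerturbationSchedule,
    perturbation_frames: Sequence[int],
    manual_overrides: Iterable[GaitEvent] | None = None,
    condition: str | None = None,
    strict_alternation: bool = True,
) -> list[StepRecord]:
    """Build labeled steps from events and perturbation onsets.

    Each perturbation onset frame is assigned to the step whose swing
    phase contains it (the interval ending at the next heel strike).
    Overlapping label windows raise :class:`LabelConflictError` naming
    the colliding perturbations; a perturbation too close to the end of
    the bout receives only the recovery labels that exist (with a
    warning).
    """

    if manual_overrides:
        events = apply_overrides(events, manual_overrides)
    if strict_alternation:
        _check_alternation(events)
    hs = [ev for ev in events if ev.kind == "heel_strike"]
    hs.sort()
    steps = [
        StepRecord(ordinal=i, side=ev.side, hs_frame=ev.frame, condition=condition)
        for i, ev in enumerate(hs)
    ]
    if len(perturbation_frames) != len(schedule.entries):
        raise ValueError("one perturbation frame per schedule entry is required")

    if not schedule.entries:
        for s in steps:
            s.label = "baseline"
        return steps

    claimed: dict[int, int] = {}  # step index -> perturbation id
    frames = np.array([s.hs_frame for s in steps])
    for pid, (entry, pframe) in enumerate(zip(schedule.entries, perturbation_frames)):
        idx = int(np.searchsorted(frames, pframe, side="left"))
        if idx >= len(steps):
            warnings.warn(f"perturbation {pid} at frame {pframe} is after the last heel strike")
            continue
        if steps[idx].side != entry[1]:
            warnings.warn(
                f"perturbation {pid}: detected step side {steps[idx].side!r} "
                f"differs from scheduled side {entry[1]!r}"
            )
        window = {idx: "perturbed"}
        if idx - 1 >= 0:
            window[idx - 1] = "preperturbation"
        n_rec = 0
        for j, lab in enumerate(("recovery1", "recovery2", "recovery3"), start=1):
            if idx + j < len(steps):
                window[idx + j] = lab
                n_rec += 1
        if n_rec < 3:
            warnings.warn(
                f"perturbation {pid} near the end of the bout: only {n_rec} recovery "
                "steps available"
            )
        for si in window:
            if si in claimed and claimed[si] != pid:
                raise LabelConflictError(
                    f"perturbations {claimed[si]} and {pid} claim step {si}: "
                    "label windows overlap"
                )
        for si, lab in window.items():
            claimed[si] = pid
            steps[si].label = lab
            if lab == "perturbed":
                steps[si].perturbation_id = pid
    return steps
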