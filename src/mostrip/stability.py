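"""Anterior–posterior margin of stability on a treadmill, and fall events.

The margin of stability (MoS) of Hof extends static balance to gait: the
centre of mass (CoM) position is advanced by its velocity scaled by the
inverted-pendulum eigenfrequency sqrt(g/l), giving the extrapolated CoM

    x_CoM = CoM + (v_CoM - v_treadmill) / sqrt(g / l)

where the treadmill belt velocity is subtracted from the CoM velocity so
that the relative velocity is the one a fixed-ground walker would have.
Under this package's axis convention (+AP = direction of progression)
the belt-surface velocity is negative during forward walking, so
(v_CoM - v_treadmill) is positive.  The MoS at a heel strike is the
distance from x_CoM to the anterior base-of-support boundary (the
leading toe marker), reported in millimetres; a negative MoS means the
extrapolated CoM has overshot the boundary and the walker must take
corrective action.

Fall events are read from the safety-harness load cell: any maximal run
of frames with more than 30% of body weight on the harness counts as
one episode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gait_events import GaitEvent, StepRecord
from .recording import TrialRecording

__all__ = [
    "MoSRecord",
    "FallEpisode",
    "effective_leg_length",
    "extrapolated_com",
    "margin_of_stability",
    "compute_step_mos",
    "detect_fall_events",
]

G_DEFAULT = 9.81


@dataclass
class MoSRecord:
    """Per-step MoS with its components (SI internally, MoS in mm)."""

    ordinal: int
    side: str
    hs_frame: int
    label: str
    com_ap: float
    com_vel_ap: float
    belt_speed: float
    leg_length: float
    xcom_ap: float
    bos_boundary_ap: float
    mos: float  # mm
    valid: bool = True


@dataclass(frozen=True)
class FallEpisode:
    start_frame: int
    end_frame: int  # inclusive
    peak_load: float  # % body weight

    @property
    def duration(self) -> int:
        return self.end_frame - self.start_frame + 1


def effective_leg_length(com: np.ndarray, heel: np.ndarray) -> float:
    """Euclidean CoM-to-heel distance at heel strike (metres)."""
    com = np.asarray(com, dtype=float)
    heel = np.asarray(heel, dtype=float)
    if not (np.all(np.isfinite(com)) and np.all(np.isfinite(heel))):
        raise ValueError("CoM and heel positions must be finite")
    d = float(np.linalg.norm(com - heel))
    if d < 1e-6:
        raise ValueError("degenerate markers: CoM coincides with the heel")
    return d


def extrapolated_com(
    com_ap: float,
    com_vel_ap: float,
    belt_speed: float,
    leg_length: float,
    g: float = G_DEFAULT,
) -> float:
    """AP extrapolated CoM with the treadmill-modified velocity.

    ``belt_speed`` is the signed belt-surface AP velocity (negative
    during forward walking under the package's axis convention).
    """
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    if g <= 0:
        raise ValueError("g must be positive")
    omega0 = np.sqrt(g / leg_length)
    return com_ap + (com_vel_ap - belt_speed) / omega0


def margin_of_stability(bos_boundary_ap: float, xcom_ap: float) -> float:
    """MoS in millimetres: (anterior BoS boundary - extrapolated CoM)."""
    return (bos_boundary_ap - xcom_ap) * 1000.0


def compute_step_mos(
    recording: TrialRecording,
    steps: list[StepRecord],
    events: list[GaitEvent] | None = None,
    boundary: str = "leading_toe",
    g: float = G_DEFAULT,
    belt_mode: str = "instantaneous",
) -> list[MoSRecord]:
    """MoS at every step's heel strike.

    CoM velocity is the central difference of the (preprocessed) CoM AP
    series; belt speed is read from the speed channel at the heel-strike
    frame (``belt_mode="nominal"`` uses the channel median instead); leg
    length is recomputed at each heel strike; the anterior boundary is
    the AP position of the leading (newly contacting) limb's toe marker
    (``boundary="max_toe"`` takes the more anterior of the two toes).
    Steps whose inputs contain non-finite samples are flagged invalid.
    """

    if boundary not in ("leading_toe", "max_toe"):
        raise ValueError(f"unknown boundary mode {boundary!r}")
    if belt_mode not in ("instantaneous", "nominal"):
        raise ValueError(f"unknown belt_mode {belt_mode!r}")
    recording.require_markers(("l_heel", "r_heel", "l_toe", "r_toe"))
    if "com" in recording.markers:
        com = recording.markers["com"]
    elif "pelvis" in recording.markers:
        com = recording.markers["pelvis"]  # pelvis-centroid fallback
    else:
        raise KeyError("recording lacks both 'com' and 'pelvis' channels")

    fs = recording.sampling_rate
    com_ap = com[:, 0]
    vel_ap = np.gradient(com_ap, 1.0 / fs)
    nominal_belt = float(np.nanmedian(recording.belt_speed))
    n = recording.n_frames

    out: list[MoSRecord] = []
    for step in steps:
        f = step.hs_frame
        if not (0 <= f < n):
            raise ValueError(f"step {step.ordinal}: heel-strike frame {f} out of range")
        key = "l" if step.side == "left" else "r"
        heel = recording.markers[f"{key}_heel"][f]
        toe_lead = recording.markers[f"{key}_toe"][f, 0]
        if boundary == "max_toe":
            other = "r" if key == "l" else "l"
            toe_lead = max(toe_lead, recording.markers[f"{other}_toe"][f, 0])
        belt = recording.belt_speed[f] if belt_mode == "instantaneous" else nominal_belt
        pieces = np.array([com_ap[f], vel_ap[f], belt, toe_lead, *heel, *com[f]])
        if not np.all(np.isfinite(pieces)):
            out.append(
                MoSRecord(
                    step.ordinal, step.side, f, step.label,
                    np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                    valid=False,
                )
            )
            continue
        leg = effective_leg_length(com[f], heel)
        xcom = extrapolated_com(com_ap[f], vel_ap[f], belt, leg, g=g)
        mos = margin_of_stability(toe_lead, xcom)
        out.append(
            MoSRecord(
                step.ordinal, step.side, f, step.label,
                float(com_ap[f]), float(vel_ap[f]), float(belt), leg,
                float(xcom), float(toe_lead), float(mos),
            )
        )
    return out


def mos_records_to_frame(records: list[MoSRecord]) -> pd.DataFrame:
    """Tidy table of MoS records (one row per step)."""
    return pd.DataFrame([vars(r) for r in records])


def detect_fall_events(
    load: np.ndarray, threshold: float = 0.30
) -> list[FallEpisode]:
    """Maximal runs of harness load strictly above ``threshold`` x body weight.

    ``load`` is in percent body weight; the default threshold 0.30 marks
    a fall event whenever more than 30 %BW rests on the harness.
    """

    load = np.asarray(load, dtype=float)
    if not np.all(np.isfinite(load)):
        raise ValueError("harness load series must be finite")
    above = load > threshold * 100.0
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    return [
        FallEpisode(int(s), int(e), float(load[s : e + 1].max()))
        for s, e in zip(starts, ends)
    ]
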