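"""Core container for one treadmill walking bout.

Axis conventions used throughout the package:

* axis 0 (x) — anterior–posterior (AP), positive in the direction of
  progression.  The treadmill belt surface therefore moves in the
  *negative* direction, and the signed belt-speed channel is negative
  during forward walking.
* axis 1 (y) — mediolateral, positive to the participant's left.
* axis 2 (z) — vertical, positive up.

All positions are metres, velocities m/s, time seconds.  Frames are
0-based and ``time = frame / sampling_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Marker channels every trial must carry (plus the "com" channel).
REQUIRED_MARKERS = ("l_heel", "r_heel", "l_toe", "r_toe", "pelvis", "com")


@dataclass
class TrialRecording:
    """Synchronised channels of one walking bout.

    Parameters
    ----------
    markers
        Mapping of marker name to an ``(n_frames, 3)`` array in metres.
        Must include the names in :data:`REQUIRED_MARKERS`; ``"com"`` is
        the whole-body centre-of-mass channel (a pelvis-centroid fallback
        may be substituted upstream when no CoM model output exists).
    belt_speed
        Signed AP belt-surface velocity per frame (m/s); negative during
        forward walking under the axis convention above.
    harness_load
        Safety-harness load-cell series in percent body weight.
    sampling_rate
        Frames per second (Hz).
    meta
        Free-form metadata (participant_id, condition, body_weight_kg, ...).
    """

    markers: dict[str, np.ndarray]
    belt_speed: np.ndarray
    harness_load: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {name: arr.shape[0] for name, arr in self.markers.items()}
        lengths["belt_speed"] = len(self.belt_speed)
        lengths["harness_load"] = len(self.harness_load)
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        for name, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name!r} must have shape (n, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.belt_speed)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate

    def require_markers(self, names=REQUIRED_MARKERS) -> None:
        missing = [m for m in names if m not in self.markers]
        if missing:
            raise KeyError(
                f"recording lacks required marker(s) {missing}; available: "
                f"{sorted(self.markers)}"
            )

    def copy(self) -> "TrialRecording":
        return TrialRecording(
            markers={k: v.copy() for k, v in self.markers.items()},
            belt_speed=self.belt_speed.copy(),
            harness_load=self.harness_load.copy(),
            sampling_rate=self.sampling_rate,
            meta=dict(self.meta),
        )
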