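"""Moving-bar stimulus schedules.

A schedule records, for every stimulus sweep of a calcium-imaging or
electrophysiology experiment, the motion direction, the trial (block)
index, and the half-open frame window ``[onset_frame, offset_frame)``
during which the bar is on screen.  All downstream stages (ΔF/F₀
baseline isolation, per-direction peak extraction, permutation tests)
are driven by this structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class Sweep:
    direction_deg: float
    trial_index: int
    onset_frame: int
    offset_frame: int  # exclusive

    def __post_init__(self) -> None:
        if not 0 <= self.direction_deg < 360:
            raise ValueError(f"direction {self.direction_deg} outside [0, 360)")
        if self.onset_frame >= self.offset_frame:
            raise ValueError("sweep window must satisfy onset < offset")


@dataclass
class StimulusSchedule:
    """Direction/trial/frame-window structure of a moving-bar run."""

    frame_rate_hz: float
    sweeps: list[Sweep] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        seen = set()
        for s in self.sweeps:
            key = (s.direction_deg, s.trial_index)
            if key in seen:
                raise ValueError(f"duplicate (direction, trial) pair {key}")
            seen.add(key)
        windows = sorted((s.onset_frame, s.offset_frame) for s in self.sweeps)
        for (a0, a1), (b0, _) in zip(windows, windows[1:]):
            if b0 < a1:
                raise ValueError("sweep windows overlap")

    @property
    def directions_deg(self) -> list[float]:
        return sorted({s.direction_deg for s in self.sweeps})

    @property
    def n_directions(self) -> int:
        return len(self.directions_deg)

    @property
    def n_trials(self) -> int:
        return len({s.trial_index for s in self.sweeps})

    @property
    def n_frames_min(self) -> int:
        """Smallest movie length covering every sweep window."""
        return max(s.offset_frame for s in self.sweeps) if self.sweeps else 0

    def stimulus_frame_mask(self, n_frames: int):
        """Boolean mask, True on frames inside any sweep window."""
        import numpy as np

        if n_frames < self.n_frames_min:
            raise ValueError("movie shorter than schedule")
        mask = np.zeros(n_frames, dtype=bool)
        for s in self.sweeps:
            mask[s.onset_frame : s.offset_frame] = True
        return mask

    def sweeps_for(self, direction_deg: float) -> list[Sweep]:
        return sorted(
            (s for s in self.sweeps if s.direction_deg == direction_deg),
            key=lambda s: s.trial_index,
        )

    # ------------------------------------------------------------------ io
    def to_json(self, path: str | Path) -> None:
        payload = {
            "frame_rate_hz": self.frame_rate_hz,
            "sweeps": [
                {
                    "direction_deg": s.direction_deg,
                    "trial_index": s.trial_index,
                    "onset_frame": s.onset_frame,
                    "offset_frame": s.offset_frame,
                }
                for s in self.sweeps
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(
            frame_rate_hz=payload["frame_rate_hz"],
            sweeps=[Sweep(**s) for s in payload["sweeps"]],
        )
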