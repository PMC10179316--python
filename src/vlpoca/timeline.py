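"""Session timeline: labelled paradigm segments plus the homeostatic pressure trace."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

SEGMENT_LABELS = ("baseline", "SD_h1", "SD_h2", "SD_h3", "recovery")


@dataclass
class Segment:
    label: str
    start_s: float
    end_s: float
    imaged: bool = True

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("segment must have positive duration")


@dataclass
class SessionTimeline:
    """Ordered, non-overlapping paradigm segments and per-epoch pressure P(t).

    `pressure[i]` is the homeostatic pressure at the start of epoch i; during
    sleep deprivation only the last-10-minute window of each hour carries
    `imaged=True`, mirroring an acquisition scheme that spares the indicator.
    """

    segments: list
    pressure: np.ndarray = field(default_factory=lambda: np.zeros(0))
    epoch_s: float = 10.0

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure, dtype=float)
        prev_end = -np.inf
        for seg in self.segments:
            if seg.start_s < prev_end:
                raise ValueError("segments overlap or are out of order")
            prev_end = seg.end_s
        if self.pressure.size and (
            self.pressure.min() < -1e-12 or self.pressure.max() > 1 + 1e-12
        ):
            raise ValueError("pressure must lie in [0, 1]")

    @property
    def labels(self) -> set:
        return {seg.label for seg in self.segments}

    @property
    def duration_s(self) -> float:
        return max(seg.end_s for seg in self.segments)

    def segment_of(self, t_s: float) -> Segment | None:
        for seg in self.segments:
            if seg.start_s <= t_s < seg.end_s:
                return seg
        return None

    def epochs_in(self, label: str, imaged_only: bool = False) -> np.ndarray:
        """Epoch indices whose start falls in any segment with `label`."""
        out = []
        for seg in self.segments:
            if seg.label != label or (imaged_only and not seg.imaged):
                continue
            first = int(np.ceil(seg.start_s / self.epoch_s - 1e-9))
            last = int(np.floor((seg.end_s - 1e-9) / self.epoch_s))
            out.append(np.arange(first, last + 1))
        if not out:
            return np.zeros(0, dtype=int)
        return np.unique(np.concatenate(out))

    def epoch_labels(self, n_epochs: int) -> np.ndarray:
        """Segment label per epoch ('' where uncovered)."""
        labels = np.full(n_epochs, "", dtype=object)
        for i in range(n_epochs):
            seg = self.segment_of(i * self.epoch_s)
            if seg is not None:
                labels[i] = seg.label
        return labels

    def to_json(self, path) -> None:
        payload = {
            "epoch_s": self.epoch_s,
            "segments": [
                {
                    "label": s.label,
                    "start_s": s.start_s,
                    "end_s": s.end_s,
                    "imaged": s.imaged,
                }
                for s in self.segments
            ],
            "pressure": self.pressure.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SessionTimeline":
        with open(path) as fh:
            payload = json.load(fh)
        segs = [Segment(**d) for d in payload["segments"]]
        return cls(
            segments=segs,
            pressure=np.asarray(payload.get("pressure", []), dtype=float),
            epoch_s=payload.get("epoch_s", 10.0),
        )


def spontaneous_timeline(duration_s: float, pressure, epoch_s: float = 10.0) -> SessionTimeline:
    """A single fully-imaged baseline segment covering the whole session."""
    return SessionTimeline(
        segments=[Segment("baseline", 0.0, duration_s, imaged=True)],
        pressure=pressure,
        epoch_s=epoch_s,
    )
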