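"""Hypnogram container: an ordered sequence of fixed-length scored epochs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import STATES


@dataclass
class Hypnogram:
    """Sleep-wake states in contiguous, non-overlapping fixed epochs."""

    states: np.ndarray           # array of labels from STATES
    epoch_s: float = 10.0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=object)
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_epochs(self) -> int:
        return len(self.states)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    @property
    def start_s(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_s

    def epochs_of(self, state: str) -> np.ndarray:
        """Indices of all epochs scored as `state`."""
        return np.flatnonzero(self.states == state)

    def state_fraction(self, state: str) -> float:
        return float(np.mean(self.states == state)) if self.n_epochs else 0.0

    def state_counts(self) -> dict:
        return {s: int(np.sum(self.states == s)) for s in STATES}

    def frame_states(self, frame_rate: float) -> np.ndarray:
        """Expand to one label per frame at `frame_rate`."""
        fpe = int(round(frame_rate * self.epoch_s))
        return np.repeat(self.states, fpe)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(self.n_epochs),
                "start_s": self.start_s,
                "state": self.states,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, epoch_s: float | None = None) -> "Hypnogram":
        df = pd.read_csv(path)
        if epoch_s is None:
            starts = df["start_s"].to_numpy(dtype=float)
            epoch_s = float(starts[1] - starts[0]) if len(starts) > 1 else 10.0
        return cls(states=df["state"].to_numpy(dtype=object), epoch_s=epoch_s)

    @classmethod
    def concatenate(cls, parts: list["Hypnogram"]) -> "Hypnogram":
        if not parts:
            raise ValueError("nothing to concatenate")
        epoch_s = parts[0].epoch_s
        if any(p.epoch_s != epoch_s for p in parts):
            raise ValueError("epoch lengths differ")
        return cls(states=np.concatenate([p.states for p in parts]), epoch_s=epoch_s)

    def agreement(self, other: "Hypnogram") -> float:
        """Fraction of epochs on which two hypnograms agree (over the overlap)."""
        n = min(self.n_epochs, other.n_epochs)
        if n == 0:
            raise ValueError("no overlapping epochs")
        return float(np.mean(self.states[:n] == other.states[:n]))
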