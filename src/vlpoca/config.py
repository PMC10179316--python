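"""Configuration objects for the simulator, scorer, and classifier.

All tunable parameters of the pipeline live here as dataclasses with
validated defaults.  Every generator parameter (bout-length means, firing
rates, kernel constants, homeostatic time constants) is a configurable
stand-in for quantities the analysed recordings do not pin down; the
defaults describe a mouse in the light phase with a GCaMP6-class indicator.
Configs round-trip through YAML (`to_yaml` / `from_yaml`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: Canonical sleep-wake state labels, in display order.
STATES = ("AW", "QW", "NREM", "REM")
WAKE_STATES = frozenset({"AW", "QW"})
SLEEP_STATES = frozenset({"NREM", "REM"})

#: Neuron phenotype subtypes used throughout the pipeline.
SLEEP_ACTIVE_SUBTYPES = ("nonREMS/REMS-max", "nonREMS-max", "REMS-active")
WAKE_ACTIVE_SUBTYPES = ("wake-max", "wake/REMS-max")
STATE_INDIFFERENT = "state-indifferent"
PHENOTYPES = SLEEP_ACTIVE_SUBTYPES + WAKE_ACTIVE_SUBTYPES + (STATE_INDIFFERENT,)

#: Subtype -> broad category.
CATEGORY_OF = {
    **{s: "sleep-active" for s in SLEEP_ACTIVE_SUBTYPES},
    **{s: "wake-active" for s in WAKE_ACTIVE_SUBTYPES},
    STATE_INDIFFERENT: "state-indifferent",
}


def _default_bouts() -> dict:
    # Mean bout lengths (s); exponential renewal, floored at one epoch.
    return {"AW": 90.0, "QW": 40.0, "NREM": 180.0, "REM": 60.0}


def _default_transitions() -> dict:
    # Successor-state weights.  Wake enters sleep only through QW; REM is
    # entered only from NREM (classic rodent stage sequencing).
    return {
        "AW": {"QW": 1.0},
        "QW": {"AW": 0.4, "NREM": 0.6},
        "NREM": {"AW": 0.4, "QW": 0.25, "REM": 0.35},
        "REM": {"AW": 0.8, "QW": 0.2},
    }


def _default_rates() -> dict:
    # Poisson event rates (events/s) per phenotype and state.  Kept below
    # ~0.35 events/s in the preferred state so the running-percentile
    # ΔF/F₀ baseline has transient-free samples in every 30 s window.
    return {
        "nonREMS/REMS-max": {"AW": 0.05, "QW": 0.10, "NREM": 0.28, "REM": 0.31},
        "nonREMS-max": {"AW": 0.08, "QW": 0.14, "NREM": 0.30, "REM": 0.055},
        "REMS-active": {"AW": 0.04, "QW": 0.08, "NREM": 0.055, "REM": 0.28},
        "wake-max": {"AW": 0.30, "QW": 0.17, "NREM": 0.08, "REM": 0.06},
        "wake/REMS-max": {"AW": 0.30, "QW": 0.17, "NREM": 0.075, "REM": 0.28},
        "state-indifferent": {"AW": 0.17, "QW": 0.17, "NREM": 0.17, "REM": 0.17},
    }


def _default_emg_rms() -> dict:
    return {"AW": 1.0, "QW": 0.40, "NREM": 0.12, "REM": 0.08}


def _default_eeg_broadband() -> dict:
    return {"AW": 0.30, "QW": 0.30, "NREM": 0.10, "REM": 0.10}


@dataclass
class SimConfig:
    """Parameters of the synthetic miniscope/EEG session generator."""

    frame_rate: float = 10.0        # Hz, calcium sampling
    epoch_s: float = 10.0           # s, scoring epoch
    mean_bout_s: dict = field(default_factory=_default_bouts)
    transition_weights: dict = field(default_factory=_default_transitions)
    phenotype_rates: dict = field(default_factory=_default_rates)

    # GCaMP6-like double-exponential kernel (s) and event amplitude in
    # units of the resting fluorescence F0.
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.8
    kernel_amplitude: float = 2.5
    noise_sd: float = 0.1           # Gaussian, in F0 units, per frame
    baseline_fluorescence: float = 1.0
    baseline_percentile: float = 20.0
    baseline_window_s: float = 30.0

    # Process-S-like homeostatic pressure P(t) in [0, 1].
    pressure_tau_wake_s: float = 7200.0
    pressure_tau_sleep_s: float = 3600.0
    pressure_init: float = 0.2
    pressure_gain: float = 1.0            # multiplies sleep-active rates
    pressure_wake_suppression: float = 0.5  # divides into wake-active rates
    delta_gain: float = 1.0               # scales NREM 2-4 Hz EEG power

    # EEG/EMG synthesis.
    eeg_fs: float = 100.0
    emg_rms: dict = field(default_factory=_default_emg_rms)
    eeg_broadband_sd: dict = field(default_factory=_default_eeg_broadband)
    eeg_delta_amp: float = 1.0
    eeg_theta_amp: float = 0.8

    # Sleep-deprivation paradigm timing (s).
    sd_baseline_s: float = 3600.0
    sd_hour_s: float = 3600.0
    sd_hours: int = 3
    sd_imaged_s: float = 600.0       # last 10 min of each SD hour
    sd_recovery_s: float = 3600.0
    sleep_attempt_rate: float = 0.05  # per-epoch attempt prob at P = 1
    recovery_nrem_boost: float = 2.0  # NREM bout-mean multiplier in recovery
    recovery_wake_shrink: float = 0.5  # wake bout-mean multiplier in recovery

    def validate(self) -> "SimConfig":
        if self.frame_rate <= 0 or self.epoch_s <= 0:
            raise ValueError("frame_rate and epoch_s must be positive")
        fpe = self.frame_rate * self.epoch_s
        if abs(fpe - round(fpe)) > 1e-9:
            raise ValueError("frame_rate * epoch_s must be an integer")
        for s in STATES:
            if self.mean_bout_s[s] <= self.epoch_s:
                raise ValueError(f"mean bout of {s} must exceed one epoch")
        for s, w in self.transition_weights.items():
            tot = sum(w.values())
            if not math.isclose(tot, 1.0, abs_tol=1e-9):
                raise ValueError(f"transition weights of {s} sum to {tot}, not 1")
            if any(v < 0 for v in w.values()):
                raise ValueError("transition weights must be non-negative")
        if set(self.transition_weights.get("AW", {})) & SLEEP_STATES:
            raise ValueError("AW may not transition directly into sleep")
        if "REM" in self.transition_weights.get("QW", {}):
            raise ValueError("REM may be entered only from NREM")
        for ph, rates in self.phenotype_rates.items():
            if ph not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {ph!r}")
            if any(r < 0 for r in rates.values()):
                raise ValueError("firing rates must be non-negative")
        if not 0 <= self.pressure_init <= 1:
            raise ValueError("pressure_init must lie in [0, 1]")
        if self.kernel_decay_s <= self.kernel_rise_s:
            raise ValueError("kernel decay must exceed rise")
        return self

    @property
    def frames_per_epoch(self) -> int:
        return int(round(self.frame_rate * self.epoch_s))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ClassifierThresholds:
    """Ratio cuts of the phenotype classifier and strength-grade bands.

    The cuts express the >=25% between-state change criterion: a unit is
    wake-active when NREM/AW < 0.75, nonREM-sleep-active when NREM/AW > 1.25,
    REM-active when both REM/AW and REM/NREM exceed 2.0, and
    state-indifferent when all state means sit within +/-25% of the AW mean.
    """

    wake_cut: float = 0.75
    sleep_cut: float = 1.25
    rem_cut: float = 2.0
    rem_retention_cut: float = 0.5   # REM/NREM split of nonREM-sleep-active
    indifferent_band: float = 0.25
    grade_weak: tuple = (0.25, 0.5)   # fold-change-minus-one, inclusive
    grade_moderate: tuple = (0.5, 1.0)  # exclusive low, inclusive high

    def validate(self) -> "ClassifierThresholds":
        if not (0 < self.wake_cut < 1 < self.sleep_cut):
            raise ValueError("need 0 < wake_cut < 1 < sleep_cut")
        if self.rem_cut <= 1:
            raise ValueError("rem_cut must exceed 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "ClassifierThresholds":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("grade_weak", "grade_moderate"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()


@dataclass
class ScoringConfig:
    """Thresholds of the rule-based EEG/EMG epoch scorer.

    Defaults are calibrated to the synthetic generator's EMG RMS levels
    (AW 1.0, QW 0.40, NREM 0.12, REM 0.08) and band amplitudes; with real
    signals they must be recalibrated per animal.
    """

    epoch_s: float = 10.0
    emg_high: float = 0.65       # RMS above -> AW
    emg_low: float = 0.22        # RMS between low and high -> QW
    theta_delta_cut: float = 1.0  # theta/delta above -> REM (else NREM)
    delta_band: tuple = (2.0, 4.0)
    theta_band: tuple = (6.0, 9.0)
    welch_segment_s: float = 2.0
    welch_overlap: float = 0.5
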