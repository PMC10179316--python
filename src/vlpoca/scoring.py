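"""Rule-based sleep scoring and NREM delta-power quantification.

The epoch scorer is a transparent stand-in for manual scoring: per 10 s
epoch it computes the EMG RMS and the EEG delta (2-4 Hz) and theta (6-9 Hz)
band powers, then applies EMG thresholds (high -> AW, intermediate -> QW)
and, under atonia, the theta/delta ratio (high -> REM, else NREM).  Delta
power per NREM epoch is the Welch PSD integrated over 2-4 Hz; the recovery
rebound is the recovery-over-baseline ratio of mean NREM delta power,
expressed in percent (the classic slow-wave-activity rebound readout of
homeostatic sleep pressure).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import ScoringConfig
from .hypnogram import Hypnogram
from .timeline import SessionTimeline

__all__ = [
    "epoch_band_power",
    "score_hypnogram",
    "nrem_delta_power",
    "delta_rebound",
]


def _welch_psd(x: np.ndarray, fs: float, cfg: ScoringConfig):
    nperseg = min(len(x), int(round(cfg.welch_segment_s * fs)))
    noverlap = int(nperseg * cfg.welch_overlap)
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)


def epoch_band_power(x: np.ndarray, fs: float, band: tuple, cfg: ScoringConfig | None = None) -> float:
    """Band power of one epoch: trapezoidal integral of the Welch PSD over [lo, hi]."""
    cfg = cfg or ScoringConfig()
    f, pxx = _welch_psd(np.asarray(x, dtype=float), fs, cfg)
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(pxx[mask], f[mask]))


def score_hypnogram(
    eeg: np.ndarray,
    emg: np.ndarray,
    fs: float,
    cfg: ScoringConfig | None = None,
) -> Hypnogram:
    """Score 10 s epochs into AW/QW/NREM/REM from EEG and EMG."""
    cfg = cfg or ScoringConfig()
    eeg = np.asarray(eeg, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if eeg.shape != emg.shape:
        raise ValueError("EEG and EMG must cover an identical time span")
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    spe = int(round(fs * cfg.epoch_s))
    n_ep = len(eeg) // spe
    if n_ep == 0:
        raise ValueError("signals shorter than one epoch")

    states = np.empty(n_ep, dtype=object)
    for i in range(n_ep):
        sl = slice(i * spe, (i + 1) * spe)
        rms = float(np.sqrt(np.mean(emg[sl] ** 2)))
        if rms > cfg.emg_high:
            states[i] = "AW"
        elif rms > cfg.emg_low:
            states[i] = "QW"
        else:
            delta = epoch_band_power(eeg[sl], fs, cfg.delta_band, cfg)
            theta = epoch_band_power(eeg[sl], fs, cfg.theta_band, cfg)
            ratio = theta / delta if delta > 0 else np.inf
            states[i] = "REM" if ratio > cfg.theta_delta_cut else "NREM"
    return Hypnogram(states=states, epoch_s=cfg.epoch_s)


def nrem_delta_power(
    eeg: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    timeline: SessionTimeline | None = None,
    cfg: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Delta (2-4 Hz) power for every NREM epoch.

    Returns a table with columns `epoch_index`, `segment` (from the timeline,
    '' if none given), and `delta_power`; non-NREM epochs are absent.  An
    empty table with a warning is returned when the hypnogram has no NREM.
    """
    cfg = cfg or ScoringConfig()
    eeg = np.asarray(eeg, dtype=float)
    spe = int(round(fs * hypnogram.epoch_s))
    n_ep = min(hypnogram.n_epochs, len(eeg) // spe)

    idx = [i for i in hypnogram.epochs_of("NREM") if i < n_ep]
    if not idx:
        warnings.warn("hypnogram contains no NREM epochs; delta series is empty")
        return pd.DataFrame(columns=["epoch_index", "segment", "delta_power"])

    labels = (
        timeline.epoch_labels(n_ep)
        if timeline is not None
        else np.full(n_ep, "", dtype=object)
    )
    rows = []
    for i in idx:
        power = epoch_band_power(eeg[i * spe : (i + 1) * spe], fs, cfg.delta_band, cfg)
        rows.append((i, labels[i], power))
    return pd.DataFrame(rows, columns=["epoch_index", "segment", "delta_power"])


def delta_rebound(delta: pd.DataFrame, baseline_label: str = "baseline", recovery_label: str = "recovery") -> float:
    """Recovery NREM delta power as a percentage of baseline NREM delta power.

    100 * mean(recovery NREM delta) / mean(baseline NREM delta); raises if
    either segment lacks NREM epochs.
    """
    base = delta.loc[delta["segment"] == baseline_label, "delta_power"]
    rec = delta.loc[delta["segment"] == recovery_label, "delta_power"]
    if base.empty or rec.empty:
        raise ValueError("both baseline and recovery must contain NREM epochs")
    return float(100.0 * rec.mean() / base.mean())
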