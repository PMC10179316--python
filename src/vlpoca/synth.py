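"""Synthetic miniscope session generator.

Emulates the statistical structure the downstream analysis assumes:

* a 4-state semi-Markov hypnogram (AW/QW/NREM/REM) with exponential bout
  lengths quantized to 10 s epochs, where wake enters sleep only through QW
  and REM is entered only from NREM;
* per-unit spiking as an inhomogeneous Poisson process whose rate depends on
  the current state and, for sleep-active phenotypes, on a saturating
  Process-S-like homeostatic pressure P(t); fluorescence is the spike train
  convolved with a GCaMP6-like double-exponential kernel plus Gaussian noise,
  converted to ΔF/F₀ against a running-percentile baseline;
* EEG/EMG with state-dependent spectral content (2-4 Hz delta in NREM whose
  power scales with 1 + delta_gain * P, 6-9 Hz theta in REM, broadband
  low-amplitude wake EEG) and EMG RMS ordering AW > QW > NREM/REM;
* the sleep-deprivation paradigm: spontaneous baseline, 3 h of enforced
  wakefulness during which P accumulates (with optional one-epoch "sleep
  attempt" NREM intrusions) and only the last 10 min of each hour is imaged,
  then 1 h of recovery sleep with elevated NREM fraction while P discharges.

Everything is driven by `numpy.random.Generator`s spawned deterministically
from a single seed, so identical (config, seed) reproduce identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import (
    CATEGORY_OF,
    PHENOTYPES,
    SLEEP_STATES,
    STATES,
    WAKE_STATES,
    SimConfig,
)
from .hypnogram import Hypnogram
from .timeline import Segment, SessionTimeline, spontaneous_timeline

__all__ = [
    "simulate_hypnogram",
    "pressure_series",
    "simulate_sd_protocol",
    "simulate_unit",
    "simulate_eeg_emg",
    "simulate_session",
    "write_session",
    "Session",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Hypnogram


def simulate_hypnogram(
    cfg: SimConfig,
    duration_s: float,
    seed,
    *,
    initial_state: str = "AW",
    states: tuple = STATES,
    bout_scale: dict | None = None,
) -> Hypnogram:
    """Draw a semi-Markov state sequence quantized to whole epochs.

    Bout lengths are exponential with state-specific means (optionally
    rescaled via `bout_scale`), floored at one epoch; successors are drawn
    from `cfg.transition_weights` restricted to `states`.
    """
    cfg.validate()
    if duration_s < cfg.epoch_s:
        raise ValueError("duration shorter than one epoch")
    rng = _rng(seed)
    n_target = int(duration_s // cfg.epoch_s)
    scale = bout_scale or {}

    seq: list = []
    state = initial_state
    while len(seq) < n_target:
        mean = cfg.mean_bout_s[state] * scale.get(state, 1.0)
        bout = max(cfg.epoch_s, rng.exponential(mean))
        n_ep = max(1, int(round(bout / cfg.epoch_s)))
        seq.extend([state] * n_ep)
        weights = {
            s: w for s, w in cfg.transition_weights[state].items() if s in states
        }
        if not weights:  # absorbing under the state restriction
            seq.extend([state] * (n_target - len(seq)))
            break
        succ = list(weights)
        p = np.asarray([weights[s] for s in succ], dtype=float)
        state = succ[rng.choice(len(succ), p=p / p.sum())]
    return Hypnogram(states=np.asarray(seq[:n_target], dtype=object), epoch_s=cfg.epoch_s)


# ---------------------------------------------------------------------------
# Homeostatic pressure


def _step_pressure(p: float, state: str, dt: float, cfg: SimConfig) -> float:
    """Exact one-step update of dP/dt = (1-P)/tau_w (wake) or -P/tau_s (sleep)."""
    if state in WAKE_STATES:
        tau = cfg.pressure_tau_wake_s
        decay = np.exp(-dt / tau) if np.isfinite(tau) else 1.0
        return 1.0 - (1.0 - p) * decay
    tau = cfg.pressure_tau_sleep_s
    decay = np.exp(-dt / tau) if np.isfinite(tau) else 1.0
    return p * decay


def pressure_series(hypnogram: Hypnogram, cfg: SimConfig, p0: float | None = None) -> np.ndarray:
    """Homeostatic pressure at the start of each epoch (length = n_epochs)."""
    p = cfg.pressure_init if p0 is None else p0
    out = np.empty(hypnogram.n_epochs)
    for i, state in enumerate(hypnogram.states):
        out[i] = p
        p = _step_pressure(p, state, hypnogram.epoch_s, cfg)
    return out


# ---------------------------------------------------------------------------
# Sleep-deprivation paradigm


def simulate_sd_protocol(cfg: SimConfig, seed) -> tuple:
    """Baseline -> 3 h enforced wake -> 1 h recovery, with pressure and imaging windows.

    Returns `(SessionTimeline, Hypnogram)`.  During SD the hypnogram holds
    AW/QW only, except optional single-epoch NREM "sleep attempts" whose
    per-epoch probability is `sleep_attempt_rate * P(t)` (attempts grow more
    frequent as pressure builds); the epoch after an attempt is forced AW.
    Recovery is simulated with NREM bouts lengthened and wake bouts shortened,
    so the recovery NREM fraction exceeds baseline.
    """
    cfg.validate()
    ss = np.random.SeedSequence(_seed_int(seed))
    r_base, r_sd, r_att, r_rec = [np.random.default_rng(s) for s in ss.spawn(4)]

    epoch = cfg.epoch_s
    baseline = simulate_hypnogram(cfg, cfg.sd_baseline_s, r_base)

    # Enforced wakefulness: AW/QW sub-chain for each SD hour.
    sd_parts = [
        simulate_hypnogram(
            cfg, cfg.sd_hour_s, r_sd, initial_state="AW", states=("AW", "QW")
        )
        for _ in range(cfg.sd_hours)
    ]
    sd = Hypnogram.concatenate(sd_parts)

    recovery = simulate_hypnogram(
        cfg,
        cfg.sd_recovery_s,
        r_rec,
        initial_state="NREM",
        bout_scale={
            "NREM": cfg.recovery_nrem_boost,
            "AW": cfg.recovery_wake_shrink,
            "QW": cfg.recovery_wake_shrink,
        },
    )

    states = np.concatenate([baseline.states, sd.states, recovery.states])
    n_base = baseline.n_epochs
    n_sd = sd.n_epochs

    # Walk pressure through the session; sleep attempts are drawn online so
    # that their probability tracks the accumulating pressure.
    p = cfg.pressure_init
    pressure = np.empty(len(states))
    forced_aw = False
    for i, state in enumerate(states):
        if n_base <= i < n_base + n_sd:
            if forced_aw:
                states[i] = state = "AW"
                forced_aw = False
            elif r_att.random() < cfg.sleep_attempt_rate * p:
                states[i] = state = "NREM"
                forced_aw = True
        pressure[i] = p
        p = _step_pressure(p, state, epoch, cfg)

    segments = [Segment("baseline", 0.0, cfg.sd_baseline_s, imaged=True)]
    t = cfg.sd_baseline_s
    for h in range(cfg.sd_hours):
        label = f"SD_h{h + 1}"
        dark = cfg.sd_hour_s - cfg.sd_imaged_s
        segments.append(Segment(label, t, t + dark, imaged=False))
        segments.append(Segment(label, t + dark, t + cfg.sd_hour_s, imaged=True))
        t += cfg.sd_hour_s
    segments.append(Segment("recovery", t, t + cfg.sd_recovery_s, imaged=True))

    timeline = SessionTimeline(segments=segments, pressure=pressure, epoch_s=epoch)
    return timeline, Hypnogram(states=states, epoch_s=epoch)


# ---------------------------------------------------------------------------
# Fluorescence


def calcium_kernel(cfg: SimConfig) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel sampled at the frame rate."""
    dt = 1.0 / cfg.frame_rate
    t = np.arange(0.0, 8.0 * cfg.kernel_decay_s, dt)
    h = np.exp(-t / cfg.kernel_decay_s) - np.exp(-t / cfg.kernel_rise_s)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return cfg.kernel_amplitude * h / peak


def running_percentile_baseline(f: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Block-wise running percentile, linearly interpolated between block centres.

    The percentile is computed on non-overlapping `baseline_window_s` blocks
    and interpolated, an O(n) stand-in for a dense sliding percentile that
    tracks slow baseline drift the same way.
    """
    win = max(1, int(round(cfg.baseline_window_s * cfg.frame_rate)))
    n = len(f)
    edges = np.arange(0, n, win)
    centres, vals = [], []
    for s in edges:
        block = f[s : s + win]
        centres.append(s + (len(block) - 1) / 2.0)
        vals.append(np.percentile(block, cfg.baseline_percentile))
    if len(vals) == 1:
        return np.full(n, vals[0])
    return np.interp(np.arange(n), centres, vals)


def simulate_unit(
    phenotype: str,
    hypnogram: Hypnogram,
    pressure: np.ndarray,
    cfg: SimConfig,
    seed,
) -> tuple:
    """Simulate one unit's ΔF/F₀ trace; returns `(dff, spike_times_s)`.

    Per-frame spike counts are Poisson with rate `lambda(state) * g(t)` where
    the pressure gain g is `1 + pressure_gain * P` for sleep-active
    phenotypes, `max(0.1, 1 - pressure_wake_suppression * P)` for wake-active
    phenotypes (pressure-driven inhibition), and 1 for state-indifferent
    units.  Fluorescence is the kernel-convolved spike train on a resting
    baseline plus Gaussian noise; ΔF/F₀ uses a running-percentile F₀.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    cfg.validate()
    rng = _rng(seed)

    frame_states = hypnogram.frame_states(cfg.frame_rate)
    n = len(frame_states)
    rates = cfg.phenotype_rates[phenotype]
    lam = np.asarray([rates[s] for s in frame_states])

    p_frames = np.repeat(np.asarray(pressure, dtype=float), cfg.frames_per_epoch)[:n]
    category = CATEGORY_OF[phenotype]
    if category == "sleep-active":
        gain = 1.0 + cfg.pressure_gain * p_frames
    elif category == "wake-active":
        gain = np.maximum(0.1, 1.0 - cfg.pressure_wake_suppression * p_frames)
    else:
        gain = np.ones(n)

    counts = rng.poisson(lam * gain / cfg.frame_rate)
    kernel = calcium_kernel(cfg)
    fluor = cfg.baseline_fluorescence + sps.fftconvolve(counts.astype(float), kernel)[:n]
    if cfg.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, cfg.noise_sd, size=n)

    f0 = running_percentile_baseline(fluor, cfg)
    f0 = np.maximum(f0, 1e-6)
    dff = (fluor - f0) / f0

    frame_t = np.arange(n) / cfg.frame_rate
    spike_times = np.repeat(frame_t, counts)
    return dff, spike_times


# ---------------------------------------------------------------------------
# EEG / EMG


def _unit_band_noise(n: int, band: tuple, fs: float, rng) -> np.ndarray:
    """Band-limited Gaussian noise normalized to unit variance."""
    white = rng.normal(size=n)
    ny = fs / 2.0
    b, a = sps.butter(4, [band[0] / ny, band[1] / ny], btype="band")
    x = sps.filtfilt(b, a, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_eeg_emg(
    hypnogram: Hypnogram, pressure: np.ndarray, cfg: SimConfig, seed
) -> tuple:
    """Synthesize EEG and EMG for a scored session; returns `(eeg, emg)` at cfg.eeg_fs.

    NREM epochs carry 2-4 Hz delta whose amplitude scales with
    sqrt(1 + delta_gain * P) (so band power scales with 1 + delta_gain * P),
    REM epochs carry 6-9 Hz theta, wake carries broadband low-amplitude EEG;
    EMG is white noise with state-dependent RMS (atonia in sleep).
    """
    cfg.validate()
    ss = np.random.SeedSequence(_seed_int(seed))
    r_bb, r_delta, r_theta, r_emg = [np.random.default_rng(s) for s in ss.spawn(4)]

    fs = cfg.eeg_fs
    if fs < 100:
        raise ValueError("EEG sampling rate must be at least 100 Hz")
    spe = int(round(fs * hypnogram.epoch_s))
    n = spe * hypnogram.n_epochs

    delta = _unit_band_noise(n, (2.0, 4.0), fs, r_delta)
    theta = _unit_band_noise(n, (6.0, 9.0), fs, r_theta)
    white = r_bb.normal(size=n)

    p = np.asarray(pressure, dtype=float)
    states = hypnogram.states
    bb_amp = np.asarray([cfg.eeg_broadband_sd[s] for s in states])
    delta_amp = np.where(
        states == "NREM", cfg.eeg_delta_amp * np.sqrt(1.0 + cfg.delta_gain * p), 0.0
    )
    theta_amp = np.where(states == "REM", cfg.eeg_theta_amp, 0.0)
    emg_amp = np.asarray([cfg.emg_rms[s] for s in states])

    rep = lambda a: np.repeat(a, spe)
    eeg = rep(bb_amp) * white + rep(delta_amp) * delta + rep(theta_amp) * theta
    emg = rep(emg_amp) * r_emg.normal(size=n)
    return eeg, emg


# ---------------------------------------------------------------------------
# Whole sessions


@dataclass
class Session:
    """A complete synthetic recording with its ground truth."""

    cfg: SimConfig
    hypnogram: Hypnogram
    timeline: SessionTimeline
    traces: pd.DataFrame            # frames x units, ΔF/F₀
    ground_truth: dict              # unit_id -> phenotype
    eeg: np.ndarray
    emg: np.ndarray
    metadata: pd.DataFrame          # unit_id, animal_id, genotype
    spikes: dict = field(default_factory=dict)

    @property
    def pressure(self) -> np.ndarray:
        return self.timeline.pressure


def default_phenotype_counts(n_units: int = 100) -> dict:
    """A study-like phenotype mix (proportions follow the reference census)."""
    props = {
        "nonREMS/REMS-max": 0.32,
        "nonREMS-max": 0.08,
        "REMS-active": 0.10,
        "wake-max": 0.38,
        "wake/REMS-max": 0.05,
        "state-indifferent": 0.07,
    }
    counts = {ph: int(round(p * n_units)) for ph, p in props.items()}
    # adjust rounding drift on the largest class
    counts["wake-max"] += n_units - sum(counts.values())
    return counts


def _seed_int(seed) -> int:
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(0, 2**31 - 1))
    return int(seed)


def simulate_session(
    cfg: SimConfig,
    seed,
    paradigm: str = "spontaneous",
    duration_s: float = 3600.0,
    phenotype_counts: dict | None = None,
    animal_id: str = "m01",
    genotype: str = "VGAT",
    with_eeg: bool = True,
) -> Session:
    """Generate a full session: hypnogram, timeline, traces, EEG/EMG, ground truth."""
    cfg.validate()
    if paradigm not in ("spontaneous", "sd"):
        raise ValueError("paradigm must be 'spontaneous' or 'sd'")
    ss = np.random.SeedSequence(_seed_int(seed))
    s_hyp, s_units, s_eeg = ss.spawn(3)

    if paradigm == "sd":
        timeline, hyp = simulate_sd_protocol(cfg, np.random.default_rng(s_hyp))
        pressure = timeline.pressure
    else:
        hyp = simulate_hypnogram(cfg, duration_s, np.random.default_rng(s_hyp))
        pressure = pressure_series(hyp, cfg)
        timeline = spontaneous_timeline(hyp.duration_s, pressure, cfg.epoch_s)

    counts = phenotype_counts or default_phenotype_counts()
    unit_seeds = s_units.spawn(sum(counts.values()))
    traces, truth, spikes = {}, {}, {}
    k = 0
    for phenotype in PHENOTYPES:
        for _ in range(counts.get(phenotype, 0)):
            uid = f"u{k:03d}"
            dff, st = simulate_unit(
                phenotype, hyp, pressure, cfg, np.random.default_rng(unit_seeds[k])
            )
            traces[uid] = dff
            truth[uid] = phenotype
            spikes[uid] = st
            k += 1

    if with_eeg:
        eeg, emg = simulate_eeg_emg(hyp, pressure, cfg, np.random.default_rng(s_eeg))
    else:
        eeg = emg = np.zeros(0)

    meta = pd.DataFrame(
        {
            "unit_id": list(traces),
            "animal_id": animal_id,
            "genotype": genotype,
        }
    )
    return Session(
        cfg=cfg,
        hypnogram=hyp,
        timeline=timeline,
        traces=pd.DataFrame(traces),
        ground_truth=truth,
        eeg=eeg,
        emg=emg,
        metadata=meta,
        spikes=spikes,
    )


def write_session(session: Session, outdir) -> None:
    """Write a session to disk in the pipeline's plain-text formats."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    session.traces.to_csv(out / "traces.csv", index=False)
    session.hypnogram.write_csv(out / "hypnogram.csv")
    session.timeline.to_json(out / "timeline.json")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(session.ground_truth, fh, indent=1)
    session.metadata.to_csv(out / "metadata.csv", index=False)
    if session.eeg.size:
        t = np.arange(len(session.eeg)) / session.cfg.eeg_fs
        pd.DataFrame({"time_s": t, "value": session.eeg}).to_csv(
            out / "eeg.csv", index=False
        )
        pd.DataFrame({"time_s": t, "value": session.emg}).to_csv(
            out / "emg.csv", index=False
        )
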