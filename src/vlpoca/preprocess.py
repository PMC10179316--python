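"""Trace conditioning: z-scoring, quality filtering, epoch downsampling, alignment.

The raw input is a frames x units table of ΔF/F₀ sampled at 10 Hz.  Traces
are optionally z-scored over the whole session, aligned to the hypnogram by
discarding a short acquisition-start offset, averaged into 10 s epochs
(matching the scoring epochs), and units whose average fluorescence across
the sleep-waking states falls below a threshold are removed from analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import STATES
from .hypnogram import Hypnogram

__all__ = [
    "DegenerateTraceError",
    "zscore_trace",
    "align_and_epoch",
    "epoch_matrix",
    "state_means",
    "quality_filter",
    "read_traces_csv",
    "write_traces_csv",
]


class DegenerateTraceError(ValueError):
    """Raised when a trace has no variance and cannot be normalized."""


def zscore_trace(values) -> np.ndarray:
    """Whole-session z-score: output has mean 0 and SD 1.

    Idempotent up to floating tolerance; raises `DegenerateTraceError` for a
    constant trace.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D trace with at least 2 frames")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite values")
    sd = x.std()
    if sd == 0:
        raise DegenerateTraceError("constant trace has no variance to normalize")
    return (x - x.mean()) / sd


def align_and_epoch(
    values,
    frame_rate: float = 10.0,
    epoch_s: float = 10.0,
    start_offset_s: float = 0.0,
    n_epochs_max: int | None = None,
) -> np.ndarray:
    """Discard the start offset and average frames into consecutive epochs.

    The acquisition-start offset (0-10 s, a whole number of frames) is
    dropped, the remaining frames are binned into `epoch_s` epochs by
    arithmetic mean, and a trailing partial epoch is dropped.  If
    `n_epochs_max` is given (the hypnogram length) the result is truncated
    to it.
    """
    x = np.asarray(values, dtype=float)
    if not 0 <= start_offset_s <= 10:
        raise ValueError("start offset must lie in [0, 10] s")
    off = start_offset_s * frame_rate
    if abs(off - round(off)) > 1e-9:
        raise ValueError("start offset must be a whole number of frames")
    off = int(round(off))
    x = x[off:]
    fpe = int(round(frame_rate * epoch_s))
    n_ep = len(x) // fpe
    if n_ep == 0:
        raise ValueError("no complete epoch after alignment")
    if n_epochs_max is not None:
        n_ep = min(n_ep, n_epochs_max)
    return x[: n_ep * fpe].reshape(n_ep, fpe).mean(axis=1)


def epoch_matrix(
    traces: pd.DataFrame,
    hypnogram: Hypnogram,
    frame_rate: float = 10.0,
    start_offset_s: float = 0.0,
) -> pd.DataFrame:
    """Per-epoch mean ΔF/F₀ for every unit, aligned to the hypnogram.

    Rows are epochs (truncated to the hypnogram length), columns units.
    """
    cols = {
        uid: align_and_epoch(
            traces[uid].to_numpy(),
            frame_rate=frame_rate,
            epoch_s=hypnogram.epoch_s,
            start_offset_s=start_offset_s,
            n_epochs_max=hypnogram.n_epochs,
        )
        for uid in traces.columns
    }
    em = pd.DataFrame(cols)
    em.index.name = "epoch_index"
    return em


def state_means(em: pd.DataFrame, hypnogram: Hypnogram) -> pd.DataFrame:
    """Mean per-epoch ΔF/F₀ of every unit in each state (units x states).

    States with no epochs yield NaN.
    """
    n = len(em)
    states = hypnogram.states[:n]
    out = {}
    for s in STATES:
        mask = states == s
        out[s] = em.iloc[mask].mean(axis=0) if mask.any() else pd.Series(
            np.nan, index=em.columns
        )
    sm = pd.DataFrame(out)
    sm.index.name = "unit_id"
    return sm


def quality_filter(sm: pd.DataFrame, threshold: float = 0.5) -> tuple:
    """Remove units whose average fluorescence across states is below threshold.

    The quality metric is the mean of the per-state mean ΔF/F₀ over the
    states actually present (NaN states ignored).  A unit is removed iff the
    metric is strictly below `threshold` (a boundary value is kept).
    Returns `(kept_ids, removed_table)` where the table logs each removed
    unit's metric and state means.
    """
    if sm.shape[1] == 0 or sm.isna().all(axis=1).any():
        bad = sm.index[sm.isna().all(axis=1)].tolist() if sm.shape[1] else []
        raise ValueError(f"units with no scored states cannot be quality-filtered: {bad}")
    metric = sm.mean(axis=1, skipna=True)
    removed_mask = metric < threshold
    removed = sm.loc[removed_mask].copy()
    removed.insert(0, "mean_across_states", metric[removed_mask])
    kept = list(sm.index[~removed_mask])
    return kept, removed


def write_traces_csv(traces: pd.DataFrame, path) -> None:
    """Header row of unit IDs; one row per frame."""
    traces.to_csv(path, index=False)


def read_traces_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
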