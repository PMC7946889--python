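"""Spontaneous columnar event (SCE) detection and spontaneous-activity metrics.

SCEs are transient translaminar activations in the absence of a stimulus,
detected as peaks of the single-trial AVREC trace exceeding the median of
the whole trace by 3 standard deviations, with at least 150 ms between
individual peaks (closer peaks merge, keeping the larger).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .csd import avrec_relres, layer_rms
from .datatypes import CSDProfile, LayerMap


def sce_threshold(avrec: np.ndarray, k_sd: float = 3.0) -> float:
    """Detection threshold: median + ``k_sd``·SD of the supplied AVREC data
    (pass the concatenated traces of a recording for a global criterion)."""
    x = np.asarray(avrec, dtype=float).ravel()
    return float(np.median(x) + k_sd * x.std())


@dataclass
class SCEEvent:
    peak_time: float  # s
    amplitude: float  # AVREC units
    duration_ms: float  # width of the supra-threshold excursion


def detect_sce(
    avrec: np.ndarray,
    fs: float,
    k_sd: float = 3.0,
    min_sep_ms: float = 150.0,
    smooth_ms: float = 0.0,
    threshold: float | None = None,
) -> list[SCEEvent]:
    """Peak detection on a single-trial AVREC trace.

    Threshold T = median(trace) + ``k_sd``·SD(trace); by default both
    statistics are taken over the given trace, which makes the detector
    invariant to constant offsets.  When a recording is cut into several
    6 s traces, passing ``threshold`` computed from the whole recording
    (see :func:`sce_threshold`) keeps the criterion identical across cuts
    — the reading of "the whole spontaneous trace" the pipeline uses.
    ``smooth_ms`` optionally box-smooths the trace before peak picking
    (default off).  A constant trace (SD 0) yields no events.
    """
    x = np.asarray(avrec, dtype=float)
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms / 1000.0 * fs)))
        x = np.convolve(x, np.ones(w) / w, mode="same")
    if threshold is None:
        if x.std() == 0:
            return []
        thresh = sce_threshold(x, k_sd)
    else:
        thresh = float(threshold)
    distance = max(1, int(round(min_sep_ms / 1000.0 * fs)))
    peaks, _ = find_peaks(x, height=thresh, distance=distance)
    above = x > thresh
    # run boundaries of supra-threshold excursions, for event durations
    edges = np.diff(np.concatenate([[0], above.view(np.int8), [0]]))
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0]
    events = []
    for p in peaks:
        i = np.searchsorted(starts, p, side="right") - 1
        dur = (stops[i] - starts[i]) / fs * 1000.0
        events.append(SCEEvent(peak_time=p / fs, amplitude=float(x[p]), duration_ms=dur))
    return events


def sce_rate(events, duration: float) -> float:
    """Events per second; ``events`` is a count or a list of events."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = events if isinstance(events, (int, np.integer)) else len(events)
    return n / duration


def spontaneous_metrics(csd: CSDProfile, lmap: LayerMap) -> pd.DataFrame:
    """Per-trace RMS metrics of spontaneous activity.

    For each (6 s) trace: per-layer CSD RMS, AVREC RMS and RelResCSD RMS
    over the full trace.  Columns are layer names plus ``AVREC`` and
    ``RelResCSD``; rows are traces.
    """
    lr = layer_rms(csd, lmap, (0, csd.n_samples))
    col = avrec_relres(csd)
    out = lr.T
    out["AVREC"] = np.sqrt(np.mean(col.avrec**2, axis=1))
    out["RelResCSD"] = np.sqrt(np.mean(col.relres**2, axis=1))
    out.index.name = "trace"
    return out
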