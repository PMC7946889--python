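"""Frequency-response analysis: response detection, best frequency,
octave-binned tuning curves, Q40dB bandwidth and the Layer-Symmetry-Index.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: ordered octave-distance bins relative to the best frequency
OCTAVE_BINS = ("-3-4 oct", "-1-2 oct", "BF", "+1-2 oct", "+3-4 oct")


def _first_sustained_run(mask: np.ndarray, min_len: int, start: int) -> int | None:
    """Index of the first run of True longer than ``min_len``, at/after start."""
    m = np.asarray(mask[start:], dtype=bool)
    if not m.any():
        return None
    edges = np.diff(np.concatenate([[0], m.view(np.int8), [0]]))
    run_starts = np.nonzero(edges == 1)[0]
    run_stops = np.nonzero(edges == -1)[0]
    for lo, hi in zip(run_starts, run_stops):
        if hi - lo > min_len:
            return start + int(lo)
    return None


def detect_response(
    trace: np.ndarray,
    baseline: tuple[int, int],
    fs: float,
    k_sd: float = 2.0,
    min_dur_ms: float = 5.0,
    mode: str = "abs",
    search_from: int | None = None,
    search_to: int | None = None,
) -> tuple[bool, int | None]:
    """Sustained-threshold response detection.

    A response is present iff the trace deviates from the baseline mean by
    more than ``k_sd`` baseline standard deviations *continuously for more
    than* ``min_dur_ms`` (strictly longer — the criterion is "> 5 ms").

    ``mode`` selects the deviation: ``"abs"`` (either direction, the
    response-threshold criterion), ``"below"`` (sink onsets) or ``"above"``.
    A zero-SD baseline with no excursion yields ``(False, None)``.

    Returns ``(detected, onset_sample)``; the onset is the first sample of
    the qualifying excursion.
    """
    x = np.asarray(trace, dtype=float)
    lo, hi = baseline
    if hi <= lo:
        raise ValueError("empty baseline window")
    base = x[lo:hi]
    bm = base.mean()
    bs = base.std(ddof=1) if base.size > 1 else 0.0
    if mode == "abs":
        mask = np.abs(x - bm) > k_sd * bs
    elif mode == "below":
        mask = x < bm - k_sd * bs
    elif mode == "above":
        mask = x > bm + k_sd * bs
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if bs == 0 and not mask.any():
        return False, None
    if search_to is not None:
        mask = mask[:search_to]
    min_len = int(round(min_dur_ms / 1000.0 * fs))
    onset = _first_sustained_run(mask, min_len, search_from or 0)
    return (onset is not None), onset


def best_frequency(granular_rms: Mapping[float, float] | pd.Series) -> float:
    """Frequency evoking the highest granular (III/IV) RMS amplitude.

    Ties break toward the lower frequency.
    """
    s = pd.Series(dict(granular_rms)).sort_index()
    if s.empty:
        raise ValueError("empty tuning table")
    return float(s.idxmax())


def bin_by_octave(freqs, bf: float) -> pd.Series:
    """Assign each frequency to an octave-distance bin around ``bf``.

    The octave distance ``d = log2(f / bf)`` is rounded to the nearest
    integer; |d| of 1–2 falls in the inner bins, 3–4 in the outer bins and
    |d| > 4 is excluded (NaN).
    """
    f = np.asarray(freqs, dtype=float)
    if bf <= 0 or np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    d = np.rint(np.log2(f / bf)).astype(int)
    labels = np.full(f.shape, None, dtype=object)
    labels[d == 0] = "BF"
    labels[(d >= 1) & (d <= 2)] = "+1-2 oct"
    labels[(d >= 3) & (d <= 4)] = "+3-4 oct"
    labels[(d <= -1) & (d >= -2)] = "-1-2 oct"
    labels[(d <= -3) & (d >= -4)] = "-3-4 oct"
    return pd.Series(
        pd.Categorical(labels, categories=list(OCTAVE_BINS), ordered=True),
        index=np.arange(f.size),
    )


def tuning_table(
    freqs_per_trial, values_per_trial, bf: float
) -> pd.DataFrame:
    """Octave-binned tuning curve: mean, SEM and n per bin."""
    bins = bin_by_octave(freqs_per_trial, bf)
    df = pd.DataFrame({"bin": bins.values, "value": np.asarray(values_per_trial)})
    g = df.dropna(subset=["bin"]).groupby("bin", observed=False)["value"]
    out = pd.DataFrame(
        {"mean": g.mean(), "sem": g.sem(), "n": g.count()}
    ).reindex(list(OCTAVE_BINS))
    return out


def q40_bandwidth(
    responses: Mapping[float, np.ndarray],
    baseline: tuple[int, int],
    fs: float,
    octave_spacing: float = 1.0,
    k_sd: float = 2.0,
    min_dur_ms: float = 5.0,
    search_from: int | None = None,
    search_to: int | None = None,
) -> float:
    """Response bandwidth in octaves at 40 dB above threshold.

    ``responses`` maps each stimulus frequency (already presented at 40 dB
    above threshold) to its trial-averaged response trace.  The bandwidth is
    the number of frequencies passing the sustained-threshold criterion
    times the octave spacing of the stimulus grid; contiguity around the
    best frequency is not required (the two readings coincide for unimodal
    tuning).
    """
    n_pass = sum(
        detect_response(
            trace, baseline, fs, k_sd=k_sd, min_dur_ms=min_dur_ms,
            search_from=search_from, search_to=search_to,
        )[0]
        for trace in responses.values()
    )
    return n_pass * octave_spacing


def lsi(rms_supra: float, rms_vb: float) -> float:
    """Layer-Symmetry-Index, (I/II − Vb) / (I/II + Vb) on layer RMS values.

    Positive values indicate supragranular dominance.  Undefined (NaN) when
    both inputs are zero.
    """
    if rms_supra < 0 or rms_vb < 0:
        raise ValueError("RMS values must be nonnegative")
    denom = rms_supra + rms_vb
    if denom == 0:
        return float("nan")
    return (rms_supra - rms_vb) / denom
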