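"""Current-source-density estimation and columnar current-flow measures.

The CSD is the discrete second spatial derivative of the laminar LFP,

    CSD(z) ≈ [θ(z + nΔz) − 2 θ(z) + θ(z − nΔz)] / (nΔz)²,

computed after Hamming-weighted spatial smoothing over 7 channels (a 300 µm
kernel at 50 µm pitch).  Boundaries are handled by extending the depth
profile with 4 virtual channels on each end via linear extrapolation through
the outermost two contacts, so every physical channel receives a CSD value.
Sinks (transmembrane positive-charge influx) are negative.

Columnar measures derived per single trial:

* AVREC(t)      = Σᵢ |CSDᵢ(t)| / n       — overall current-flow magnitude
* RelResCSD(t)  = Σᵢ CSDᵢ(t) / Σᵢ |CSDᵢ(t)| — sink/source imbalance, a proxy
  for lateral (cross-columnar) synaptic input; defined as 0 when no current
  flows.

Both are computed from CSD of the *unsmoothed* LFP; layer-resolved RMS and
onset latencies use the smoothed CSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CSDProfile, LaminarRecording, LayerMap


def _extend_linear(x: np.ndarray, n_ext: int) -> np.ndarray:
    """Extend a (channels, ...) array by ``n_ext`` virtual channels per end.

    The extension is the straight line through the outermost two channels,
    the minimal linear boundary rule (an affine depth profile extends to
    itself exactly).
    """
    if x.shape[0] < 2:
        raise ValueError("need at least two channels to extrapolate")
    steps = np.arange(1, n_ext + 1).reshape((-1,) + (1,) * (x.ndim - 1))
    top = x[0] - steps[::-1] * (x[1] - x[0])
    bot = x[-1] + steps * (x[-1] - x[-2])
    return np.concatenate([top, x, bot], axis=0)


def spatial_smooth(
    lfp_trial: np.ndarray, window_len: int = 7, n_ext: int = 4
) -> np.ndarray:
    """Hamming-weighted average over ``window_len`` neighboring channels.

    ``lfp_trial`` is (channels, samples).  Weights are normalized to sum 1,
    so constant and (with the linear boundary extension) affine-in-depth
    profiles pass through unchanged.
    """
    window_len = int(window_len)
    if window_len % 2 == 0 or window_len < 3:
        raise ValueError("window_len must be odd and >= 3")
    n_ch = lfp_trial.shape[0]
    if window_len > n_ch:
        raise ValueError("window longer than the channel count")
    half = window_len // 2
    pad = max(n_ext, half)
    ext = _extend_linear(np.asarray(lfp_trial, float), pad)
    w = np.hamming(window_len)
    w /= w.sum()
    out = np.zeros_like(lfp_trial, dtype=float)
    for j, wj in enumerate(w):
        off = pad - half + j
        out += wj * ext[off : off + n_ch]
    return out


def compute_csd(
    rec: LaminarRecording,
    grid_n: int = 1,
    window_len: int | None = 7,
    n_ext: int = 4,
) -> CSDProfile:
    """Second-spatial-difference CSD of a multi-trial recording.

    ``window_len=None`` (or 0) skips the spatial smoothing — the path used
    for the AVREC/RelResCSD measures.  ``grid_n`` is the differentiation
    grid ``n``; the default 1 relies on the smoothing to set the effective
    spatial scale.
    """
    grid_n = int(grid_n)
    if grid_n < 1:
        raise ValueError("grid_n must be >= 1")
    if rec.n_channels < 2 * grid_n + 1:
        raise ValueError("differentiation grid too large for the channel count")
    pad = max(n_ext, grid_n)
    h2 = (grid_n * rec.dz) ** 2
    out = np.empty_like(rec.lfp)
    for tr in range(rec.n_trials):
        theta = rec.lfp[tr]
        if window_len:
            theta = spatial_smooth(theta, window_len, n_ext)
        ext = _extend_linear(theta, pad)
        c = slice(pad, pad + rec.n_channels)
        up = slice(pad - grid_n, pad - grid_n + rec.n_channels)
        dn = slice(pad + grid_n, pad + grid_n + rec.n_channels)
        out[tr] = (ext[dn] - 2 * ext[c] + ext[up]) / h2
    return CSDProfile(
        csd=out,
        fs=rec.fs,
        dz=rec.dz,
        stim_onset=rec.stim_onset,
        provenance={
            "window_len": int(window_len or 0),
            "grid_n": grid_n,
            "boundary": f"linear extrapolation, {n_ext} channels",
        },
    )


@dataclass
class ColumnarTraces:
    """Per-trial AVREC and RelResCSD traces."""

    avrec: np.ndarray  # (n_trials, n_samples), >= 0
    relres: np.ndarray  # (n_trials, n_samples), in [-1, 1]
    n_channels_used: int
    fs: float


def avrec_relres(csd: CSDProfile) -> ColumnarTraces:
    """AVREC and RelResCSD per trial and sample (RelRes 0 where AVREC 0)."""
    absum = np.abs(csd.csd).sum(axis=1)
    signed = csd.csd.sum(axis=1)
    avrec = absum / csd.n_channels
    with np.errstate(divide="ignore", invalid="ignore"):
        relres = np.where(absum > 0, signed / np.where(absum > 0, absum, 1.0), 0.0)
    return ColumnarTraces(
        avrec=avrec, relres=relres, n_channels_used=csd.n_channels, fs=csd.fs
    )


def layer_rms(
    csd: CSDProfile, lmap: LayerMap, window: tuple[int, int]
) -> pd.DataFrame:
    """Layer RMS table (layers × trials) over sample window ``[start, stop)``.

    RMS is taken per channel over the window first, then averaged across the
    layer's channels — not RMS of the channel-averaged trace.
    """
    lo, hi = window
    if not (0 <= lo < hi <= csd.n_samples):
        raise ValueError("window outside the trace")
    lmap.check_bounds(csd.n_channels)
    rows = {}
    for name in lmap.names:
        ch = lmap.channels(name)
        if ch.size == 0:
            raise ValueError(f"layer {name} has no channels")
        per_channel = np.sqrt(np.mean(csd.csd[:, ch, lo:hi] ** 2, axis=2))
        rows[name] = per_channel.mean(axis=1)
    return pd.DataFrame(rows).T


def onset_latency(
    csd: CSDProfile,
    lmap: LayerMap,
    baseline: tuple[int, int],
    onset: int | None = None,
    k_sd: float = 2.0,
    min_dur_ms: float = 5.0,
) -> pd.Series:
    """Sink onset latency per layer, in ms relative to stimulus onset.

    The trial-averaged, layer-averaged CSD must drop below
    (baseline mean − ``k_sd``·SD) continuously for more than ``min_dur_ms``
    — the same sustained-threshold criterion as response detection.  Layers
    with no such excursion get NaN.
    """
    from .tuning import detect_response  # single threshold implementation

    onset = csd.stim_onset if onset is None else onset
    if onset is None:
        raise ValueError("no stimulus onset available")
    if baseline[1] > onset:
        raise ValueError("baseline must precede stimulus onset")
    mean_csd = csd.csd.mean(axis=0)
    out = {}
    for name in lmap.names:
        trace = mean_csd[lmap.channels(name)].mean(axis=0)
        hit, idx = detect_response(
            trace,
            baseline,
            fs=csd.fs,
            k_sd=k_sd,
            min_dur_ms=min_dur_ms,
            mode="below",
            search_from=onset,
        )
        out[name] = (idx - onset) / csd.fs * 1000.0 if hit else np.nan
    return pd.Series(out, name="latency_ms")


@dataclass
class StabilityResult:
    """Spatial cross-correlogram between condition depth profiles."""

    lags: np.ndarray
    correlation: np.ndarray
    peak_lag: int


def stability_xcorr(
    csd_pre: CSDProfile,
    csd_post: CSDProfile,
    onset_window: tuple[int, int] | None = None,
    max_lag: int = 5,
) -> StabilityResult:
    """Electrode-stability check across conditions.

    Each condition is reduced to a single depth profile — the per-channel
    mean over the first 50 ms after stimulus onset, averaged across trials —
    and the two profiles are Pearson-correlated at integer channel shifts in
    ``[-max_lag, +max_lag]`` over their overlap.  A stable electrode track
    peaks at (or within one channel of) zero lag even when per-layer
    amplitudes change between conditions.
    """
    if csd_pre.n_channels != csd_post.n_channels:
        raise ValueError("channel counts differ")
    n_ch = csd_pre.n_channels
    if not 0 < max_lag < n_ch:
        raise ValueError("max_lag must be in (0, n_channels)")

    def profile(csd: CSDProfile) -> np.ndarray:
        if onset_window is None:
            if csd.stim_onset is None:
                raise ValueError("no stimulus onset available")
            lo = csd.stim_onset
            hi = lo + int(round(0.050 * csd.fs))
        else:
            lo, hi = onset_window
        return csd.csd[:, :, lo:hi].mean(axis=(0, 2))

    a, b = profile(csd_pre), profile(csd_post)
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    for i, s in enumerate(lags):
        if s >= 0:
            x, y = a[: n_ch - s], b[s:]
        else:
            x, y = a[-s:], b[: n_ch + s]
        corr[i] = np.corrcoef(x, y)[0, 1]
    return StabilityResult(
        lags=lags, correlation=corr, peak_lag=int(lags[np.argmax(corr)])
    )
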