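"""Multitaper spectral estimation of layer CSD traces and the per-bin
group comparison with Benjamini–Hochberg control.

Spectra use K = 5 Slepian (DPSS) tapers on 600 ms epochs with
time-bandwidth product NW = 3 and no zero-padding, giving a frequency
resolution of 1/0.6 s ≈ 1.667 Hz and a concentration half-bandwidth of
W = NW / T = 5 Hz.  The retained grid is 1–100 Hz and every spectrum is
normalized to unit sum over it.

Two estimators are provided:

* evoked:      complex spectra averaged across trials per taper *before*
               squaring — keeps only phase-locked energy;
* spontaneous: power per trial and taper, then averaged — keeps induced,
               non-phase-locked energy too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss as _dpss

from .stats import bh_correct, paired_t_rows


@dataclass
class TaperSpec:
    epoch_s: float = 0.6
    nw: float = 3.0
    k: int = 5


@dataclass
class SpectrumSet:
    """Normalized power spectra with their taper parameters.

    ``power`` has shape (n_spectra, n_bins) — one row per subject (or
    trial-set); each row sums to 1 over the retained frequency grid.
    """

    freqs: np.ndarray
    power: np.ndarray
    taper: TaperSpec
    kind: str  # "evoked" | "spontaneous"


def dpss_tapers(n_samples: int, nw: float = 3.0, k: int = 5) -> np.ndarray:
    """Orthonormal DPSS tapers, shape (k, n_samples).

    The usable taper count is bounded by 2·NW − 1; the leading tapers are
    energy-concentrated within the half-bandwidth W = NW·fs / n_samples.
    """
    if k > int(2 * nw - 1):
        raise ValueError("taper count k must be <= 2*nw - 1")
    if n_samples <= k:
        raise ValueError("epoch too short for the taper count")
    return _dpss(n_samples, nw, Kmax=k, norm=2)


def _prep(trials: np.ndarray, fs: float, spec: TaperSpec):
    x = np.atleast_2d(np.asarray(trials, dtype=float))
    n = int(round(spec.epoch_s * fs))
    if x.shape[1] < n:
        raise ValueError(
            f"epoch of {n} samples required, trials have {x.shape[1]}"
        )
    x = x[:, :n]
    x = x - x.mean(axis=1, keepdims=True)
    tapers = dpss_tapers(n, spec.nw, spec.k)
    freqs = rfftfreq(n, 1.0 / fs)
    sel = (freqs >= 1.0) & (freqs <= 100.0)
    return x, tapers, freqs, sel


def evoked_spectrum(
    trials: np.ndarray, fs: float, spec: TaperSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-locked (evoked) multitaper spectrum of one layer's trials.

    Per taper, the complex trial-averaged spectrum is squared, then powers
    are averaged across tapers; restricted to 1–100 Hz and normalized to
    unit sum.  Returns ``(freqs, power)``.
    """
    spec = spec or TaperSpec()
    x, tapers, freqs, sel = _prep(trials, fs, spec)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    # (trials, tapers, freq) -> trial-average of complex spectra per taper
    ft = rfft(x[:, None, :] * tapers[None, :, :], axis=-1)
    power = (np.abs(ft.mean(axis=0)) ** 2).mean(axis=0)
    p = power[sel]
    return freqs[sel], p / p.sum()


def spontaneous_spectrum(
    trials: np.ndarray, fs: float, spec: TaperSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Total-power multitaper spectrum (induced + evoked energy)."""
    spec = spec or TaperSpec()
    x, tapers, freqs, sel = _prep(trials, fs, spec)
    ft = rfft(x[:, None, :] * tapers[None, :, :], axis=-1)
    power = (np.abs(ft) ** 2).mean(axis=(0, 1))
    p = power[sel]
    return freqs[sel], p / p.sum()


@dataclass
class SpectralComparison:
    """Per-bin paired-t comparison of two matched spectrum sets.

    Sign convention: t is computed on (pre − post), so negative t means
    higher power in the post condition.
    """

    freqs: np.ndarray
    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    critical_p: float
    fdr_q: float


def compare_spectra(
    pre: SpectrumSet, post: SpectrumSet, fdr_q: float = 0.1
) -> SpectralComparison:
    """Paired t per frequency bin across matched subjects, BH-corrected."""
    if pre.power.shape != post.power.shape:
        raise ValueError("spectrum sets are not matched")
    if pre.power.shape[0] < 3:
        raise ValueError("need at least 3 matched subjects")
    t, p = paired_t_rows(pre.power, post.power)
    # identical conditions give zero-variance differences: t = 0, no effect
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    mask, crit = bh_correct(p, fdr_q)
    return SpectralComparison(
        freqs=pre.freqs, t=t, p=p, mask=mask, critical_p=crit, fdr_q=fdr_q
    )
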