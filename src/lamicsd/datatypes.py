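"""Shared data model for laminar recordings and derived arrays.

Conventions used throughout the package:

* channel index 0 is the most superficial contact; depth grows with index
* all sample indices are 0-based; time windows are half-open ``[start, stop)``
* current sinks are negative, sources positive
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: canonical layer order, superficial to deep
LAYERS = ("I/II", "III/IV", "Vb", "VI")


class FormatError(ValueError):
    """A container is missing a required dataset or attribute."""


class DataError(ValueError):
    """A container holds invalid data (e.g. NaN samples)."""


@dataclass
class LaminarRecording:
    """Multi-trial laminar LFP with stimulus metadata.

    Parameters
    ----------
    lfp : ndarray, shape (n_trials, n_channels, n_samples)
        Field potential in microvolts.
    fs : float
        Sampling rate in Hz.
    dz : float
        Inter-channel spacing in mm (0.05 mm for a 50 µm probe).
    condition : str
        Condition label, conventionally ``"pre"`` or ``"post"``.
    stim_freq : ndarray or None
        Per-trial tone frequency in Hz; ``None`` for spontaneous data.
    stim_onset : int or None
        Sample index of tone onset; ``None`` for spontaneous data.
    """

    lfp: np.ndarray
    fs: float
    dz: float
    condition: str = "pre"
    subject_id: str = "sub-00"
    stim_freq: np.ndarray | None = None
    stim_onset: int | None = None

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        if self.lfp.ndim != 3:
            raise DataError("lfp must be (n_trials, n_channels, n_samples)")
        if self.n_channels < 7:
            raise DataError("need at least 7 channels for the spatial filter")
        if not (self.fs > 0 and self.dz > 0):
            raise DataError("fs and dz must be positive")
        if np.isnan(self.lfp).any():
            raise DataError("lfp contains NaN")
        if self.stim_freq is not None:
            self.stim_freq = np.asarray(self.stim_freq, dtype=float)
            if self.stim_freq.shape != (self.n_trials,):
                raise DataError("stim_freq must have one entry per trial")
        if self.stim_onset is not None:
            self.stim_onset = int(self.stim_onset)
            if not 0 <= self.stim_onset < self.n_samples:
                raise DataError("stim_onset outside the trial")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[1]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[2]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class LayerMap:
    """Ordered assignment of channel ranges to cortical layers.

    ``spans`` is a sequence of ``(layer_name, (lo, hi))`` with half-open
    channel ranges, ordered superficial to deep and non-overlapping.
    Channels outside every span are intentionally unassigned (pial surface,
    layer Va transition, white matter).
    """

    spans: Sequence[tuple[str, tuple[int, int]]]

    def __post_init__(self) -> None:
        prev_hi = -1
        for name, (lo, hi) in self.spans:
            if not (0 <= lo < hi):
                raise ValueError(f"invalid span for layer {name}: [{lo}, {hi})")
            if lo < prev_hi:
                raise ValueError(
                    f"layer spans overlap or are out of order at {name}"
                )
            prev_hi = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.spans)

    def channels(self, layer: str) -> np.ndarray:
        for name, (lo, hi) in self.spans:
            if name == layer:
                return np.arange(lo, hi)
        raise KeyError(layer)

    def check_bounds(self, n_channels: int) -> None:
        for name, (lo, hi) in self.spans:
            if hi > n_channels:
                raise ValueError(
                    f"layer {name} span [{lo}, {hi}) exceeds {n_channels} channels"
                )


#: documented default split of a 32-channel probe (50 µm pitch); layer
#: boundaries in real data come from the sink pattern and should be passed
#: explicitly per dataset — this is a convention, not an inference.
DEFAULT_SPANS_32 = (
    ("I/II", (1, 7)),
    ("III/IV", (8, 14)),
    ("Vb", (15, 21)),
    ("VI", (23, 29)),
)


def default_layer_map(
    n_channels: int = 32,
    overrides: dict[str, tuple[int, int]] | None = None,
) -> LayerMap:
    """Default four-layer map for an ``n_channels``-contact probe.

    The 32-channel split above is scaled proportionally for other probe
    lengths.  ``overrides`` replaces individual layer spans; the result is
    re-validated, so overlapping custom ranges raise.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels to place four layers")
    scale = n_channels / 32.0
    spans = []
    for name, (lo, hi) in DEFAULT_SPANS_32:
        lo_s, hi_s = int(round(lo * scale)), int(round(hi * scale))
        hi_s = max(hi_s, lo_s + 1)
        spans.append((name, (lo_s, hi_s)))
    if overrides:
        spans = [(n, overrides.get(n, span)) for n, span in spans]
    lm = LayerMap(spans)
    lm.check_bounds(n_channels)
    return lm


@dataclass
class CSDProfile:
    """Per-trial current-source-density array (sinks negative).

    ``provenance`` records how the profile was computed: spatial smoothing
    window length (0 = unsmoothed), differentiation grid ``n`` and the
    boundary policy.
    """

    csd: np.ndarray  # (n_trials, n_channels, n_samples)
    fs: float
    dz: float
    stim_onset: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.csd = np.asarray(self.csd, dtype=float)
        if self.csd.ndim != 3:
            raise DataError("csd must be (n_trials, n_channels, n_samples)")
        if not np.isfinite(self.csd).all():
            raise DataError("csd contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.csd.shape[0]

    @property
    def n_channels(self) -> int:
        return self.csd.shape[1]

    @property
    def n_samples(self) -> int:
        return self.csd.shape[2]
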