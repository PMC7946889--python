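"""HDF5 container and configuration I/O.

The recording container is a plain HDF5 group with datasets ``lfp``
(trials × channels × time) and, for evoked data, per-trial ``stim_freq``;
scalar metadata lives in attributes ``fs``, ``dz``, ``condition``,
``subject_id`` and (evoked) ``stim_onset``.  Round trips are lossless.
"""

from __future__ import annotations

import h5py
import numpy as np
import yaml

from .datatypes import FormatError, LaminarRecording, LayerMap

_REQUIRED_ATTRS = ("fs", "dz", "condition")


def write_recording(rec: LaminarRecording, path, group: str = "/") -> None:
    """Write a recording to ``path`` under HDF5 group ``group``."""
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        for name in ("lfp", "stim_freq"):
            if name in g:
                del g[name]
        g.create_dataset("lfp", data=rec.lfp)
        if rec.stim_freq is not None:
            g.create_dataset("stim_freq", data=rec.stim_freq)
        g.attrs["fs"] = rec.fs
        g.attrs["dz"] = rec.dz
        g.attrs["condition"] = rec.condition
        g.attrs["subject_id"] = rec.subject_id
        if rec.stim_onset is not None:
            g.attrs["stim_onset"] = rec.stim_onset


def read_recording(path, group: str = "/") -> LaminarRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` naming the first missing dataset or
    attribute, and :class:`~lamicsd.datatypes.DataError` for NaN samples.
    """
    with h5py.File(path, "r") as f:
        if group not in f:
            raise FormatError(f"missing group {group!r}")
        g = f[group]
        if "lfp" not in g:
            raise FormatError("missing dataset 'lfp'")
        for attr in _REQUIRED_ATTRS:
            if attr not in g.attrs:
                raise FormatError(f"missing attribute {attr!r}")
        lfp = g["lfp"][()]
        stim_freq = g["stim_freq"][()] if "stim_freq" in g else None
        stim_onset = (
            int(g.attrs["stim_onset"]) if "stim_onset" in g.attrs else None
        )
        return LaminarRecording(
            lfp=lfp,
            fs=float(g.attrs["fs"]),
            dz=float(g.attrs["dz"]),
            condition=str(g.attrs["condition"]),
            subject_id=str(g.attrs.get("subject_id", "sub-00")),
            stim_freq=stim_freq,
            stim_onset=stim_onset,
        )


def layer_map_from_yaml(path) -> LayerMap:
    """Load a layer map from a YAML mapping ``layer name -> [lo, hi)``."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    spans = [(name, (int(lo), int(hi))) for name, (lo, hi) in raw.items()]
    spans.sort(key=lambda item: item[1][0])  # superficial to deep
    return LayerMap(spans)


def layer_map_to_yaml(lmap: LayerMap, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(
            {n: [int(lo), int(hi)] for n, (lo, hi) in lmap.spans},
            f,
            sort_keys=False,
        )
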