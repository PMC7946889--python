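"""Shared statistical primitives: BH step-up FDR control and paired t.

Both the spectral comparison (Q = 0.1) and the Granger-causality network
comparison (Q = 0.05) flow through :func:`bh_correct`; the false discovery
rate is always an explicit argument.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as sps


class PairedT(NamedTuple):
    t: float
    p: float
    df: int
    zero_variance: bool


def bh_correct(pvals, q: float) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up procedure.

    p-values are ranked ascending; with ``m`` tests the critical value of
    rank ``i`` is ``(i/m) * q``.  All hypotheses up to the largest rank whose
    p-value sits below its critical value are rejected.

    Returns
    -------
    mask : boolean ndarray aligned with ``pvals`` (True = rejected)
    critical_p : the largest rejected p-value (0.0 if nothing is rejected)
    """
    p = np.asarray(pvals, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    below = p[order] <= (np.arange(1, m + 1) / m) * q
    if not below.any():
        return np.zeros(m, dtype=bool), 0.0
    i_star = int(np.nonzero(below)[0].max())
    critical_p = float(p[order][i_star])
    return p <= critical_p, critical_p


def paired_t(a, b) -> PairedT:
    """Paired Student's t on matched samples, df = n − 1, two-sided p.

    Zero-variance differences leave t undefined; the result is flagged and
    carries NaN statistics rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be matched 1-d samples")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 matched pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if np.allclose(d, 0):
            return PairedT(0.0, 1.0, df, False)
        return PairedT(np.nan, np.nan, df, True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df)
    return PairedT(float(t), float(p), df, False)


def paired_t_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired t along axis 0 (subjects) for each column.

    Returns (t, p) arrays; columns with zero-variance differences get NaN.
    Sign convention: ``t`` is computed on ``a − b``, so a negative t means
    the quantity is larger in ``b``.
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d.mean(axis=0) / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.nan, t)
    p = 2 * sps.t.sf(np.abs(t), n - 1)
    return t, p
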