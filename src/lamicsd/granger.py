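"""Time-domain conditional Granger causality between layer CSD traces.

For each ordered pair (source j → target i) of the k layer series, two
vector autoregressions are compared: the *full* model, which regresses the
target on the past of all k series, and the *reduced* model, which omits
the source while keeping the remaining k − 2 series as conditioning
variables.  The causal estimate is the log residual-variance ratio

    F[i, j] = ln( var(ε′_i) / var(ε_i) )  ≥ 0,

where ε′ and ε are the reduced- and full-model innovations of the target.

Following the standard autocovariance route, the full model is fitted once
per subject (pooled across trials, per-trial demeaned, no regression across
trial boundaries); its implied autocovariance sequence is obtained from the
discrete Lyapunov equation and the reduced models are solved from the
sub-autocovariances via the Yule–Walker equations at full lag depth, which
accounts for the moving-average character of the marginalized process.

Preprocessing mirrors common practice for CSD traces: first temporal
differencing, with per-series augmented Dickey–Fuller stationarity checks
that flag (rather than reject) residual non-stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .stats import bh_correct, paired_t


# ---------------------------------------------------------------- utilities


def _as_trials(traces: np.ndarray) -> np.ndarray:
    x = np.asarray(traces, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("traces must be (trials, series, samples)")
    return x


def companion(coefs: np.ndarray) -> np.ndarray:
    """Companion matrix of VAR coefficients ``coefs`` with shape (p, k, k)."""
    p, k, _ = coefs.shape
    top = np.concatenate(list(coefs), axis=1)
    if p == 1:
        return top
    eye = np.eye(k * (p - 1))
    bottom = np.concatenate([eye, np.zeros((k * (p - 1), k))], axis=1)
    return np.concatenate([top, bottom], axis=0)


def spectral_radius(coefs: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(companion(coefs))).max())


# ------------------------------------------------------------ stationarize


def adf_pvalues(
    traces: np.ndarray, max_samples: int = 6000, maxlag: int = 10
) -> pd.Series:
    """Augmented Dickey–Fuller p-value per series (trials concatenated,
    per-trial demeaned).  Small p rejects a unit root, i.e. stationarity.

    A fixed lag depth is used (the autolag grid search adds nothing at
    these sample sizes) and very long series are truncated.
    """
    from statsmodels.tsa.stattools import adfuller

    x = _as_trials(traces)
    x = x - x.mean(axis=2, keepdims=True)
    out = {}
    for s in range(x.shape[1]):
        series = x[:, s, :].ravel()
        if series.size > max_samples:
            series = series[:max_samples]
        out[s] = adfuller(series, maxlag=maxlag, autolag=None)[1]
    return pd.Series(out, name="adf_p")


def stationarize(
    traces: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, pd.DataFrame]:
    """First temporal difference per trial and series, plus an ADF report.

    Differencing shortens each trial by exactly one sample.  Series whose
    differenced version still fails the ADF test at ``alpha`` are flagged in
    the report but not rejected (single differencing is the protocol; a
    second difference is the caller's choice).
    """
    x = _as_trials(traces)
    if x.shape[2] < 50:
        raise ValueError("need at least 50 samples per trial")
    dx = np.diff(x, axis=2)
    pvals = adf_pvalues(dx)
    report = pd.DataFrame(
        {"adf_p": pvals, "stationary": pvals < alpha}
    )
    return dx, report


# ------------------------------------------------------------- VAR fitting


@dataclass
class VarModel:
    """Fitted VAR(p): coefficients, innovation covariance and diagnostics."""

    order: int
    coefs: np.ndarray  # (p, k, k): x_t = sum_j coefs[j] @ x_{t-j} + e_t
    sigma: np.ndarray  # (k, k) innovation covariance
    n_eff: int  # pooled regression rows
    loglik: float
    spectral_radius: float
    adf_p: pd.Series | None = None

    @property
    def k(self) -> int:
        return self.sigma.shape[0]


def _pooled_design(x: np.ndarray, p: int, offset: int | None = None):
    """Stack lagged regressors within trials (no cross-trial lags).

    ``offset`` discards that many presample points per trial (>= p), which
    lets order selection compare models on the identical sample.
    """
    n_tr, k, n = x.shape
    off = p if offset is None else offset
    if off < p:
        raise ValueError("offset must be >= order")
    rows = n - off
    if rows < 1:
        raise ValueError("trials too short for the requested order")
    Y = np.concatenate([x[tr, :, off:].T for tr in range(n_tr)], axis=0)
    X = np.concatenate(
        [
            np.concatenate(
                [x[tr, :, off - j : n - j].T for j in range(1, p + 1)], axis=1
            )
            for tr in range(n_tr)
        ],
        axis=0,
    )
    return X, Y


def empirical_autocov(traces: np.ndarray, n_lags: int) -> np.ndarray:
    """Pooled empirical autocovariance Γ̂(0..n_lags), Γ(h) = E[x_t x_{t−h}ᵀ].

    Per-trial demeaned, per-trial lagged products (no cross-trial lags),
    biased normalization (divide by the trial length) so the sequence is a
    valid positive-definite autocovariance.
    """
    x = _as_trials(traces)
    x = x - x.mean(axis=2, keepdims=True)
    n_tr, k, n = x.shape
    if n_lags >= n:
        raise ValueError("n_lags must be shorter than a trial")
    gam = np.zeros((n_lags + 1, k, k))
    for h in range(n_lags + 1):
        gam[h] = np.einsum(
            "tis,tjs->ij", x[:, :, h:], x[:, :, : n - h]
        ) / (n_tr * n)
    return gam


def fit_var(
    traces: np.ndarray,
    p: int,
    offset: int | None = None,
    method: str = "ols",
) -> VarModel:
    """Multi-trial VAR fit (per-trial demeaned, no cross-trial lags).

    ``method="ols"`` pools lagged regressions across trials by least
    squares; ``method="lwr"`` solves the Yule–Walker equations of the
    pooled empirical autocovariance (the Levinson–Wiggins–Robinson /
    multivariate Durbin estimate — solved here directly as the small
    block-Toeplitz system rather than by the recursion).  The two agree up
    to boundary terms of order p over the trial length.
    """
    x = _as_trials(traces)
    x = x - x.mean(axis=2, keepdims=True)
    n_tr, k, n = x.shape
    p = int(p)
    if p < 1:
        raise ValueError("order must be >= 1")
    if method == "lwr":
        gam = empirical_autocov(x, p)
        coefs, sigma = yw_from_autocov(gam, p)
        N = n_tr * (n - p)
        dets = np.linalg.slogdet(sigma)
        if dets[0] <= 0:
            bad = int(np.argmin(np.diag(sigma)))
            raise ValueError(f"singular residual covariance (series {bad})")
        loglik = -0.5 * N * (k * np.log(2 * np.pi) + dets[1] + k)
        return VarModel(
            order=p,
            coefs=coefs,
            sigma=sigma,
            n_eff=N,
            loglik=float(loglik),
            spectral_radius=spectral_radius(coefs),
        )
    if method != "ols":
        raise ValueError(f"unknown method {method!r}")
    X, Y = _pooled_design(x, p, offset)
    N = Y.shape[0]
    if N <= k * p:
        raise ValueError("not enough samples for the parameter count")
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    # df-corrected residual covariance: the ML divisor N biases the
    # innovation variance down by ~(k p)/N, which matters at long lag depths
    sigma = resid.T @ resid / (N - k * p)
    if not np.all(np.isfinite(sigma)):
        raise ValueError("singular fit")
    dets = np.linalg.slogdet(sigma)
    data_scale = float(np.mean(Y**2))
    # deterministic recursions explain the data exactly; a vanishing
    # residual covariance is then a feature, not degeneracy
    perfect_fit = data_scale > 0 and np.abs(sigma).max() < 1e-12 * data_scale
    if dets[0] <= 0 and not perfect_fit:
        bad = int(np.argmin(np.diag(sigma)))
        raise ValueError(f"singular residual covariance (series {bad})")
    coefs = np.stack(
        [B[j * k : (j + 1) * k, :].T for j in range(p)], axis=0
    )
    loglik = -0.5 * N * (k * np.log(2 * np.pi) + dets[1] + k)
    return VarModel(
        order=p,
        coefs=coefs,
        sigma=sigma,
        n_eff=N,
        loglik=float(loglik),
        spectral_radius=spectral_radius(coefs),
    )


def select_order(traces: np.ndarray, max_order: int = 20) -> int:
    """AIC order selection over 1..max_order on a common sample.

    AIC(p) = ln det Σ̂_ML + 2 p k² / N, with all candidate orders compared
    on the sample that discards ``max_order`` presample points per trial.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    x = _as_trials(traces)
    k = x.shape[1]
    best_p, best_aic = None, np.inf
    for p in range(1, max_order + 1):
        try:
            m = fit_var(x, p, offset=max_order)
        except ValueError:
            continue
        if m.spectral_radius >= 1:
            continue
        # AIC on the ML covariance (undo the df correction)
        lndet_ml = (
            np.linalg.slogdet(m.sigma)[1]
            + k * np.log((m.n_eff - k * p) / m.n_eff)
        )
        aic = lndet_ml + 2.0 * p * k * k / m.n_eff
        if aic < best_aic:
            best_p, best_aic = p, aic
    if best_p is None:
        raise ValueError("no stable VAR fit at any candidate order")
    return best_p


# ---------------------------------------------------- autocovariance route


def autocov_sequence(model: VarModel, n_lags: int) -> np.ndarray:
    """Model-implied autocovariance Γ(0..n_lags), Γ(h) = E[x_t x_{t−h}ᵀ].

    Γ(0..p−1) solves the discrete Lyapunov equation of the companion form;
    higher lags follow the Yule–Walker recursion Γ(h) = Σ_j A_j Γ(h−j).
    """
    if model.spectral_radius >= 1:
        raise ValueError("model is not stable")
    p, k = model.order, model.k
    A = companion(model.coefs)
    Q = np.zeros((k * p, k * p))
    Q[:k, :k] = model.sigma
    P = sla.solve_discrete_lyapunov(A, Q)
    gam = np.zeros((n_lags + 1, k, k))
    for h in range(min(p, n_lags + 1)):
        gam[h] = P[:k, h * k : (h + 1) * k]
    for h in range(p, n_lags + 1):
        gam[h] = sum(model.coefs[j] @ gam[h - 1 - j] for j in range(p))
    return gam


def yw_from_autocov(gammas: np.ndarray, order: int):
    """Solve the multivariate Yule–Walker equations for a VAR(order).

    ``gammas`` holds Γ(0..L) with L >= order.  Returns (coefs, sigma) with
    Σ = Γ(0) − Σ_j A_j Γ(j)ᵀ.  Raises on an ill-conditioned block-Toeplitz
    system, reporting the condition estimate.
    """
    L = gammas.shape[0] - 1
    q = int(order)
    if q > L:
        raise ValueError("not enough autocovariance lags for the order")
    m = gammas.shape[1]

    def g(h):
        return gammas[h] if h >= 0 else gammas[-h].T

    G = np.block([[g(h - j) for h in range(1, q + 1)] for j in range(1, q + 1)])
    R = np.concatenate([g(h) for h in range(1, q + 1)], axis=1)  # m × mq
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"ill-conditioned Yule-Walker system (cond ~ {cond:.2e})")
    # solve [A_1 .. A_q] G = R
    A_flat = np.linalg.solve(G.T, R.T).T
    coefs = np.stack([A_flat[:, j * m : (j + 1) * m] for j in range(q)], axis=0)
    sigma = g(0) - sum(coefs[j] @ g(j + 1).T for j in range(q))
    sigma = 0.5 * (sigma + sigma.T)
    return coefs, sigma


def reduced_model(
    gammas: np.ndarray,
    keep: np.ndarray | list[int],
    order: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduced VAR over the series subset ``keep``.

    Solves the Yule–Walker equations of the sub-autocovariance.  By default
    the full available lag depth is used, absorbing the VARMA structure of
    the marginalized process into a long autoregression.  Returns
    ``(coefs, sigma)`` of the reduced model.
    """
    keep = np.asarray(keep, dtype=int)
    sub = gammas[np.ix_(np.arange(gammas.shape[0]), keep, keep)]
    q = gammas.shape[0] - 1 if order is None else order
    return yw_from_autocov(sub, q)


# ------------------------------------------------------------ conditional GC


@dataclass
class GCMatrix:
    """Pairwise-conditional Granger estimates F[i, j] for edge j → i.

    The diagonal is NaN.  Negative finite-sample estimates are clipped to 0
    and flagged in ``clipped``.
    """

    F: np.ndarray
    order: int
    subject_id: str = ""
    condition: str = ""
    clipped: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.F.shape[0]


def conditional_gc(
    traces: np.ndarray,
    p: int,
    n_lags: int | None = None,
    reduced_order: int | None = None,
    subject_id: str = "",
    condition: str = "",
) -> GCMatrix:
    """Pairwise-conditional GC matrix of k series.

    The full VAR(p) is fitted once from the pooled autocovariance (LWR
    route, so the model-implied autocovariance reproduces the empirical one
    up to lag p exactly); for every excluded source j, one reduced model
    over the remaining k − 1 series is solved from the implied
    sub-autocovariance via Yule–Walker, delivering the residual variances
    of all its targets — k reduced solves cover all k(k−1) edges.  The
    target is univariate, so the covariance ratio of the causal estimate
    reduces to a variance ratio.

    ``reduced_order`` defaults to ``p`` (the reduced autoregression of the
    same order as the full model); larger values absorb more of the
    moving-average structure of the marginalized process.
    """
    x = _as_trials(traces)
    k = x.shape[1]
    full = fit_var(x, p, method="lwr")
    q = p if reduced_order is None else int(reduced_order)
    if n_lags is None:
        n_lags = max(q, min(4 * p, 40))
    gam = autocov_sequence(full, n_lags)
    F = np.full((k, k), np.nan)
    clipped = np.zeros((k, k), dtype=bool)
    errors = {}
    for j in range(k):
        keep = np.array([s for s in range(k) if s != j])
        try:
            _, sig_red = reduced_model(gam, keep, order=q)
        except ValueError as e:  # flag the column, keep the rest
            errors[j] = str(e)
            continue
        for ti, i in enumerate(keep):
            f = np.log(sig_red[ti, ti] / full.sigma[i, i])
            if f < 0:
                clipped[i, j] = True
                f = 0.0
            F[i, j] = f
    return GCMatrix(
        F=F,
        order=p,
        subject_id=subject_id,
        condition=condition,
        clipped=clipped,
        diagnostics={
            "spectral_radius": full.spectral_radius,
            "n_eff": full.n_eff,
            "n_lags": n_lags,
            "errors": errors,
        },
    )


def conditional_gc_ols(traces: np.ndarray, p: int) -> np.ndarray:
    """Direct-regression conditional GC (full and reduced models fitted by
    pooled OLS at order p).

    The independent route used to cross-check the autocovariance method.
    The two routes estimate the same population quantity but differ in
    finite samples by boundary-convention terms of order p over the trial
    length (the Yule–Walker solve implicitly windows the trials, OLS does
    not); they coincide as the trials grow long.
    """
    x = _as_trials(traces)
    k = x.shape[1]
    full = fit_var(x, p, method="ols")
    F = np.full((k, k), np.nan)
    for j in range(k):
        keep = np.array([s for s in range(k) if s != j])
        red = fit_var(x[:, keep, :], p, method="ols")
        for ti, i in enumerate(keep):
            F[i, j] = np.log(red.sigma[ti, ti] / full.sigma[i, i])
    return F


# ------------------------------------------------------- group comparison


@dataclass
class GCComparison:
    """Edge-wise paired-t comparison of log GC between conditions."""

    table: pd.DataFrame  # edge, t, p, significant, direction
    critical_p: float
    fdr_q: float


def compare_gc(
    pre: list[GCMatrix],
    post: list[GCMatrix],
    fdr_q: float = 0.05,
    layer_names: tuple[str, ...] | None = None,
) -> GCComparison:
    """Paired t on ln F per edge across matched subjects, BH at ``fdr_q``.

    Zero (clipped) estimates have no log; such subject pairs are excluded
    edge-wise.  Edges with fewer than 3 usable pairs are flagged untestable
    (p = NaN, never significant).  ``direction`` is +1 where post > pre.
    """
    if len(pre) != len(post) or len(pre) == 0:
        raise ValueError("conditions must have matched subjects")
    k = pre[0].k
    names = layer_names or tuple(str(i) for i in range(k))
    rows = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            a = np.array([m.F[i, j] for m in pre])
            b = np.array([m.F[i, j] for m in post])
            ok = (a > 0) & (b > 0) & np.isfinite(a) & np.isfinite(b)
            edge = f"{names[j]}->{names[i]}"
            if ok.sum() < 3:
                rows.append((edge, np.nan, np.nan, 0, False, ok.sum()))
                continue
            la, lb = np.log(a[ok]), np.log(b[ok])
            res = paired_t(lb, la)  # positive t = increase after treatment
            direction = int(np.sign(np.mean(lb - la)))
            rows.append(
                (edge, res.t, 1.0 if res.zero_variance else res.p,
                 direction, False, ok.sum())
            )
    df = pd.DataFrame(
        rows, columns=["edge", "t", "p", "direction", "significant", "n_pairs"]
    ).set_index("edge")
    testable = df["p"].notna()
    mask, crit = bh_correct(df.loc[testable, "p"].to_numpy(), fdr_q)
    df.loc[testable, "significant"] = mask
    df["significant"] = df["significant"].astype(bool)
    return GCComparison(table=df, critical_p=crit, fdr_q=fdr_q)
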