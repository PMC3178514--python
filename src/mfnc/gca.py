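"""VAR fitting, BIC order selection and conditional Granger causality.

A k-channel process S(t) = sum_m A_m S(t-m) + E(t) is fit either by the
Levinson-Wiggins-Robinson (Whittle) recursion on the autocovariance
sequence (single long series) or by pooled least squares with lag-trimmed
designs stacked across trials (event-related data, each trial an
independent realization of the same stationary process).

The causal magnitude is the conditional Geweke measure
``F_{j->i} = ln(var_restricted_i / var_full_i)`` where the restricted
regression omits channel j's lags; edge significance is a block F-test on
those p lags, Bonferroni-corrected over the n(n-1) ordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class VARModel:
    order: int
    coefficients: np.ndarray  # (p, k, k)
    noise_cov: np.ndarray  # (k, k)
    n_effective: int
    fit_mode: str  # "lwr" or "ols"

    @property
    def k(self) -> int:
        return self.noise_cov.shape[0]


@dataclass
class GCGraph:
    magnitudes: np.ndarray  # (k, k), [i, j] = influence j -> i; diagonal nan
    p_values: np.ndarray
    adjacency: np.ndarray  # bool, Bonferroni-corrected
    alpha_nominal: float
    n_nodes: int
    order: int = 1

    def edge_list(self) -> list[tuple[int, int]]:
        """Significant ordered (source, target) pairs."""
        src, tgt = np.nonzero(self.adjacency.T)
        return list(zip(src.tolist(), tgt.tolist()))


def _as_trials(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        return data[None]
    if data.ndim == 3:
        return data
    raise ValueError("data must be (k, T) or (n_trials, k, T)")


def _design(trials: np.ndarray, p: int):
    """Lag-trimmed regression arrays pooled over trials.

    Returns targets Y (k, N), regressors Z (k*p, N) with Z rows ordered by
    lag then channel, and N pooled over trials.  Each trial's channel means
    are removed first.
    """
    n_trials, k, T = trials.shape
    if T <= p:
        raise ValueError(f"trial length {T} too short for order {p}")
    Ys, Zs = [], []
    for tr in trials:
        tr = tr - tr.mean(axis=1, keepdims=True)
        Ys.append(tr[:, p:])
        Zs.append(np.vstack([tr[:, p - m : T - m] for m in range(1, p + 1)]))
    return np.hstack(Ys), np.hstack(Zs)


def _ols_fit(Y: np.ndarray, Z: np.ndarray):
    """Least-squares coefficients B (k x kp) and per-target RSS."""
    B, *_ = np.linalg.lstsq(Z.T, Y.T, rcond=None)
    resid = Y - B.T @ Z
    return B.T, resid


def fit_var(data: np.ndarray, p: int, mode: str | None = None) -> VARModel:
    """Fit a VAR(p).

    Single series default to the LWR recursion on sample autocovariances;
    trial data (3-d) use pooled lag-trimmed least squares.  ``mode`` forces
    "lwr" or "ols".
    """
    if p < 1:
        raise ValueError("order p must be >= 1")
    data = np.asarray(data, dtype=float)
    if mode is None:
        mode = "lwr" if data.ndim == 2 else "ols"
    if mode == "lwr":
        if data.ndim != 2:
            raise ValueError("LWR applies to a single (k, T) series")
        return _fit_lwr(data, p)
    trials = _as_trials(data)
    Y, Z = _design(trials, p)
    N = Y.shape[1]
    k = Y.shape[0]
    if N <= k * p + 1:
        raise ValueError(f"insufficient samples: N_eff={N} for k*p+1={k * p + 1}")
    B, resid = _ols_fit(Y, Z)
    sigma = resid @ resid.T / N
    coeffs = np.stack([B[:, m * k : (m + 1) * k] for m in range(p)])
    return VARModel(order=p, coefficients=coeffs, noise_cov=sigma, n_effective=N, fit_mode="ols")


def _autocov(x: np.ndarray, p: int) -> np.ndarray:
    """Biased sample autocovariances R(0..p), R[j] = E[S(t) S(t-j)^T]."""
    k, T = x.shape
    x = x - x.mean(axis=1, keepdims=True)
    R = np.empty((p + 1, k, k))
    for j in range(p + 1):
        R[j] = x[:, j:] @ x[:, : T - j or None].T / T
    return R


def _fit_lwr(series: np.ndarray, p: int) -> VARModel:
    """Whittle's multichannel Levinson recursion on the Yule-Walker equations."""
    k, T = series.shape
    if T <= k * p + 1:
        raise ValueError(f"series too short (T={T}) for order {p}")
    R = _autocov(series, p)
    # order 1 initialisation
    A = [R[1] @ np.linalg.inv(R[0])]  # forward coefficients A_1..A_m
    Bw = [R[1].T @ np.linalg.inv(R[0])]  # backward coefficients
    Vf = R[0] - A[0] @ R[1].T
    Vb = R[0] - Bw[0] @ R[1]
    for m in range(1, p):
        Df = R[m + 1] - sum(A[i] @ R[m - i] for i in range(m))
        Db = R[m + 1].T - sum(Bw[i] @ R[m - i].T for i in range(m))
        Anew = Df @ np.linalg.inv(Vb)
        Bnew = Db @ np.linalg.inv(Vf)
        A_upd = [A[i] - Anew @ Bw[m - 1 - i] for i in range(m)] + [Anew]
        B_upd = [Bw[i] - Bnew @ A[m - 1 - i] for i in range(m)] + [Bnew]
        Vf = Vf - Anew @ Db
        Vb = Vb - Bnew @ Df
        A, Bw = A_upd, B_upd
    sigma = 0.5 * (Vf + Vf.T)
    return VARModel(order=p, coefficients=np.stack(A), noise_cov=sigma, n_effective=T, fit_mode="lwr")


def select_order_bic(data: np.ndarray, p_max: int = 10) -> int:
    """VAR order minimising BIC(p) = ln det Sigma(p) + k^2 p ln(N)/N."""
    trials = _as_trials(data)
    k, T = trials.shape[1], trials.shape[2]
    if T <= p_max or trials.shape[0] * (T - p_max) <= k * p_max + 1:
        raise ValueError(
            f"insufficient samples for p_max={p_max}: need trial length > {p_max} "
            f"and pooled samples > {k * p_max + 1}"
        )
    best_p, best_bic = 1, np.inf
    for p in range(1, p_max + 1):
        Y, Z = _design(trials, p)
        N = Y.shape[1]
        _, resid = _ols_fit(Y, Z)
        sigma = resid @ resid.T / N
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        bic = logdet + k * k * p * np.log(N) / N
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p


def _gc_statistics(data: np.ndarray, p: int):
    """Per-pair restricted/full residual sums of squares.

    Returns (rss_full (k,), rss_restricted (k, k) with [i, j] the RSS of
    target i when channel j's lags are omitted, N_eff).
    """
    trials = _as_trials(data)
    k = trials.shape[1]
    Y, Z = _design(trials, p)
    N = Y.shape[1]
    if N - k * p - 1 <= 0:
        raise ValueError(f"non-positive residual degrees of freedom (N={N}, k={k}, p={p})")
    _, resid_f = _ols_fit(Y, Z)
    rss_f = np.sum(resid_f**2, axis=1)
    rss_r = np.full((k, k), np.nan)
    lag_rows = np.arange(p) * k
    for j in range(k):
        keep = np.setdiff1d(np.arange(k * p), lag_rows + j)
        _, resid_r = _ols_fit(Y, Z[keep])
        rss_r[:, j] = np.sum(resid_r**2, axis=1)
    return rss_f, rss_r, N


def gc_magnitude(data: np.ndarray, p: int) -> np.ndarray:
    """Conditional Geweke magnitudes, [i, j] = ln(RSS_r[i,j] / RSS_f[i])."""
    rss_f, rss_r, _ = _gc_statistics(data, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.log(rss_r / rss_f[:, None])
    np.fill_diagonal(F, np.nan)
    return F


def gc_edges(data: np.ndarray, p: int, alpha_nominal: float = 0.01) -> GCGraph:
    """Directed graph of Bonferroni-significant conditional GC edges.

    Per ordered pair (j -> i) a block F-test compares the full regression
    with the one omitting channel j's p lags for target i; the per-edge
    threshold is ``alpha_nominal / (n (n - 1))``.
    """
    rss_f, rss_r, N = _gc_statistics(data, p)
    k = rss_f.shape[0]
    df2 = N - k * p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        Fstat = ((rss_r - rss_f[:, None]) / p) / (rss_f[:, None] / df2)
        mags = np.log(rss_r / rss_f[:, None])
    Fstat = np.maximum(Fstat, 0.0)
    pvals = stats.f.sf(Fstat, p, df2)
    np.fill_diagonal(pvals, np.nan)
    np.fill_diagonal(mags, np.nan)
    thresh = alpha_nominal / (k * (k - 1))
    adj = np.zeros((k, k), dtype=bool)
    off = ~np.eye(k, dtype=bool)
    adj[off] = pvals[off] < thresh
    return GCGraph(
        magnitudes=mags, p_values=pvals, adjacency=adj,
        alpha_nominal=alpha_nominal, n_nodes=k, order=p,
    )
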