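"""Non-negative factor decomposition of model-fit maps and multivariate
Granger causality between factor sets.

Whole-brain ssRSA fit maps (vertex x time, participants z-scored per
vertex over time and concatenated along time) are decomposed by NMF with
multiplicative updates: negative fits are zeroed, the factorisation is
restarted several times per candidate rank, and the rank with the least
best-of-restarts RMS residual over the searched range is kept.  Factor
time courses (factor x time x participant) from two model RDMs then enter
a vector-autoregressive (VAR) model; the time-domain conditional Granger
statistic — the log ratio of the target's residual variance without vs
with the source's past — is tested against surrogates built by shuffling
contiguous windows (of length = model order) of the source series, with a
generalised-Pareto tail refinement of extreme p-values and BH-FDR over
all tested connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import genpareto

from .constraints import fdr_correct


# ---------------------------------------------------------------------------
# NMF
# ---------------------------------------------------------------------------

@dataclass
class FactorSet:
    """NMF result: non-negative spatial bases W (vertex x k) and factor
    time series H (k x time [x participant])."""

    bases: np.ndarray
    time_series: np.ndarray           # (k, time, participant)
    k: int
    rms: float
    rms_by_k: dict[int, float] = field(default_factory=dict)
    restart_rms: list[float] = field(default_factory=list)
    rms_trace: list[float] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(self.bases < 0) or np.any(self.time_series < 0):
            raise ValueError("NMF bases and time series must be non-negative")


def _nmf_mu(X: np.ndarray, k: int, *, n_iter: int, seed: int,
            tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative-update NMF minimising Frobenius error; returns
    (W, H, RMS trace)."""
    rng = np.random.default_rng(seed)
    n, m = X.shape
    scale = np.sqrt(X.mean() / max(k, 1)) if X.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    eps = 1e-12
    trace: list[float] = []
    prev = np.inf
    for _ in range(n_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        rms = float(np.sqrt(np.mean((X - W @ H) ** 2)))
        trace.append(rms)
        if prev - rms < tol * max(prev, 1e-12):
            break
        prev = rms
    return W, H, trace


def nmf_decompose(
    fit_maps: Sequence[np.ndarray] | np.ndarray,
    *,
    k_range: Sequence[int] = range(2, 51),
    n_restarts: int = 20,
    n_iter: int = 300,
    seed: int = 0,
    normalize: bool = True,
    label: str = "",
) -> FactorSet:
    """Decompose per-participant fit maps into non-negative factors.

    ``fit_maps`` is a sequence of (vertex x time) maps, one per
    participant.  Each map is z-scored per vertex over time (when
    ``normalize``), maps are concatenated along time, negatives are
    zeroed, and NMF is run ``n_restarts`` times per candidate k; per k the
    best restart by RMS residual is kept and the k with least RMS over
    ``k_range`` is chosen.
    """
    maps = [np.asarray(m, dtype=float) for m in np.asarray(fit_maps)]
    if not maps:
        raise ValueError("no fit maps")
    n_vert, n_time = maps[0].shape
    if any(m.shape != (n_vert, n_time) for m in maps):
        raise ValueError("fit maps differ in shape")
    if any(not np.all(np.isfinite(m)) for m in maps):
        raise ValueError("non-finite fit map values")
    proc = []
    for m in maps:
        if normalize:
            mu = m.mean(axis=1, keepdims=True)
            sd = m.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            m = (m - mu) / sd
        proc.append(m)
    X = np.concatenate(proc, axis=1)
    X = np.maximum(X, 0.0)  # negative model fits zeroed
    if not np.any(X > 0):
        raise ValueError("degenerate input: all zero after zeroing negatives")

    best: tuple[float, int, np.ndarray, np.ndarray, list[float], list[float]] | None = None
    rms_by_k: dict[int, float] = {}
    for k in k_range:
        k_best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
        restart_rms: list[float] = []
        for r in range(n_restarts):
            W, H, trace = _nmf_mu(X, k, n_iter=n_iter,
                                  seed=seed * 100_003 + k * 1009 + r)
            restart_rms.append(trace[-1])
            if k_best is None or trace[-1] < k_best[0]:
                k_best = (trace[-1], W, H, trace)
        rms_by_k[k] = k_best[0]
        if best is None or k_best[0] < best[0]:
            best = (k_best[0], k, k_best[1], k_best[2], k_best[3], restart_rms)

    rms, k, W, H, trace, restart_rms = best
    n_part = len(maps)
    H3 = H.reshape(k, n_part, n_time).transpose(0, 2, 1)  # (k, time, participant)
    return FactorSet(bases=W, time_series=H3, k=k, rms=rms, rms_by_k=rms_by_k,
                     restart_rms=restart_rms, rms_trace=trace, label=label)


# ---------------------------------------------------------------------------
# VAR / Granger causality
# ---------------------------------------------------------------------------

@dataclass
class GCResult:
    source: str
    target: str
    statistic: float
    order: int
    p: float | None = None
    p_refined: float | None = None
    fdr_significant: bool | None = None
    flagged: bool = False


def _lagged_design(series: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Pooled lagged design over participants.

    ``series`` is (n_vars, n_time, n_participants); returns (Y, Z) with Y
    the time-(t) values (n_obs, n_vars) and Z the stacked lags
    (n_obs, n_vars * order + 1) including an intercept.
    """
    n_vars, n_time, n_part = series.shape
    Ys, Zs = [], []
    for p in range(n_part):
        S = series[:, :, p]
        Y = S[:, order:].T
        lags = [S[:, order - l:n_time - l].T for l in range(1, order + 1)]
        Z = np.concatenate(lags, axis=1)
        Ys.append(Y)
        Zs.append(Z)
    Y = np.concatenate(Ys)
    Z = np.concatenate(Zs)
    Z = np.column_stack([np.ones(len(Z)), Z])
    return Y, Z


def _resid_var(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ beta
    return resid.var(axis=0, ddof=0)


def _var_aic(series: np.ndarray, order: int) -> float:
    n_vars = series.shape[0]
    Y, Z = _lagged_design(series, order)
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ beta
    sigma = np.cov(resid, rowvar=False, ddof=0)
    sigma = np.atleast_2d(sigma)
    sign, logdet = np.linalg.slogdet(sigma + 1e-12 * np.eye(n_vars))
    n_obs = len(Y)
    n_params = n_vars * (n_vars * order + 1)
    return float(n_obs * logdet + 2 * n_params)


def select_var_order(series: np.ndarray, max_order: int = 10) -> int:
    """AIC-minimising VAR order on the pooled series.

    Orders are admissible only if the pooled observation count is at
    least three times the per-equation parameter count.
    """
    n_vars, n_time, n_part = series.shape
    orders = [p for p in range(1, max_order + 1)
              if p < n_time and n_part * (n_time - p) >= 3 * (n_vars * p + 1)]
    if not orders:
        raise ValueError("series too short for any VAR order")
    aics = {p: _var_aic(series, p) for p in orders}
    return min(aics, key=aics.get)


def _spectral_radius(series: np.ndarray, order: int) -> float:
    n_vars = series.shape[0]
    Y, Z = _lagged_design(series, order)
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    A = beta[1:].T  # (n_vars, n_vars*order)
    top = np.concatenate([A], axis=0)
    companion = np.zeros((n_vars * order, n_vars * order))
    companion[:n_vars] = top
    if order > 1:
        companion[n_vars:, :n_vars * (order - 1)] = np.eye(n_vars * (order - 1))
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def _gc_stat(series: np.ndarray, order: int, src: int, tgt: int) -> float:
    """Conditional GC: log ratio of the target's residual variance with the
    source's lags removed vs the full VAR."""
    Y, Z = _lagged_design(series, order)
    n_vars = series.shape[0]
    full_var = _resid_var(Y[:, [tgt]], Z)[0]
    keep = [0] + [1 + l * n_vars + v
                  for l in range(order) for v in range(n_vars) if v != src]
    red_var = _resid_var(Y[:, [tgt]], Z[:, keep])[0]
    if full_var <= 0:
        return 0.0
    return float(np.log(red_var / full_var))


def gc_pairwise(
    factors_a: np.ndarray,
    factors_b: np.ndarray,
    *,
    max_order: int = 10,
    labels_a: Sequence[str] | None = None,
    labels_b: Sequence[str] | None = None,
    include_within: bool = False,
) -> list[GCResult]:
    """Conditional GC for each directed cross-set factor pair.

    Inputs are (k, time, participant) factor arrays (2-D input is treated
    as a single participant).  A joint VAR over all factors of both sets
    is fitted with AIC order selection; each connection's statistic is the
    conditional GC given all remaining factors.  Connections with a
    zero-variance series or an unstable VAR are flagged and skipped.
    """
    A = np.atleast_3d(np.asarray(factors_a, dtype=float))
    B = np.atleast_3d(np.asarray(factors_b, dtype=float))
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("factor sets must share time and participant axes")
    ka, kb = A.shape[0], B.shape[0]
    labels_a = list(labels_a) if labels_a else [f"A{i}" for i in range(ka)]
    labels_b = list(labels_b) if labels_b else [f"B{i}" for i in range(kb)]
    joint = np.concatenate([A, B], axis=0)
    labels = labels_a + labels_b

    flat = joint.reshape(joint.shape[0], -1)
    degenerate = np.flatnonzero(flat.std(axis=1) == 0)
    results: list[GCResult] = []
    pairs = [(i, ka + j) for i in range(ka) for j in range(kb)]
    pairs += [(ka + j, i) for i in range(ka) for j in range(kb)]
    if include_within:
        pairs += [(i, j) for i in range(ka) for j in range(ka) if i != j]
        pairs += [(ka + i, ka + j) for i in range(kb) for j in range(kb) if i != j]
    if degenerate.size:
        warnings.warn("zero-variance factor series flagged and skipped")
        for s, t in pairs:
            if s in degenerate or t in degenerate:
                results.append(GCResult(labels[s], labels[t], np.nan, 0,
                                        flagged=True))
        pairs = [(s, t) for s, t in pairs
                 if s not in degenerate and t not in degenerate]
        if not pairs:
            return results
    order = select_var_order(joint, max_order)
    if _spectral_radius(joint, order) >= 1.0:
        warnings.warn("unstable VAR (spectral radius >= 1); connections flagged")
        for s, t in pairs:
            results.append(GCResult(labels[s], labels[t], np.nan, order,
                                    flagged=True))
        return results
    for s, t in pairs:
        results.append(GCResult(labels[s], labels[t],
                                _gc_stat(joint, order, s, t), order))
    return results


def _window_shuffle(x: np.ndarray, order: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Rearrange contiguous windows of length ``order``; trailing samples
    not filling a window are dropped from the shuffle (kept in place)."""
    n = x.shape[0]
    n_win = n // order
    if n_win < 2:
        raise ValueError("fewer than 2 windows: surrogate impossible")
    head = x[:n_win * order].reshape(n_win, order)
    out = x.copy()
    out[:n_win * order] = head[rng.permutation(n_win)].reshape(-1)
    return out


def gc_significance(
    factors_a: np.ndarray,
    factors_b: np.ndarray,
    results: Sequence[GCResult],
    *,
    n_surrogates: int = 1000,
    seed: int = 0,
    gpd_threshold: float = 0.005,
    fdr_alpha: float = 0.05,
) -> list[GCResult]:
    """Surrogate-based significance of GC connections.

    For each unflagged connection, ``n_surrogates`` surrogates are built
    by shuffling contiguous windows (length = model order) of the source
    factor's time course per participant and recomputing the statistic;
    p is the add-one permutation estimate.  p-values below
    ``gpd_threshold`` are refined by a generalised-Pareto fit to the top
    10% of surrogate values; BH-FDR is applied over all tested
    connections.
    """
    A = np.atleast_3d(np.asarray(factors_a, dtype=float))
    B = np.atleast_3d(np.asarray(factors_b, dtype=float))
    ka = A.shape[0]
    joint = np.concatenate([A, B], axis=0)
    labels = ([f"A{i}" for i in range(ka)]
              + [f"B{i}" for i in range(B.shape[0])])
    all_labels = {lab: i for i, lab in enumerate(labels)}

    rng = np.random.default_rng(seed)
    out: list[GCResult] = []
    tested: list[GCResult] = []
    for res in results:
        if res.flagged or not np.isfinite(res.statistic):
            out.append(res)
            continue
        src = all_labels.get(res.source)
        tgt = all_labels.get(res.target)
        if src is None or tgt is None:
            # custom labels: recover positional order from the result list
            raise ValueError(
                f"cannot map connection {res.source}->{res.target} to factor "
                "indices; use default labels for significance testing")
        null = np.empty(n_surrogates)
        for i in range(n_surrogates):
            surr = joint.copy()
            for p in range(joint.shape[2]):
                surr[src, :, p] = _window_shuffle(joint[src, :, p],
                                                  max(res.order, 1), rng)
            null[i] = _gc_stat(surr, res.order, src, tgt)
        p_perm = float((1 + np.sum(null >= res.statistic)) / (n_surrogates + 1))
        p_ref = p_perm
        if p_perm < gpd_threshold:
            p_ref = _gpd_tail_p(res.statistic, null, p_perm)
        res = GCResult(res.source, res.target, res.statistic, res.order,
                       p=p_perm, p_refined=p_ref)
        out.append(res)
        tested.append(res)
    if tested:
        reject, _ = fdr_correct([r.p_refined for r in tested], alpha=fdr_alpha)
        for r, rej in zip(tested, reject):
            r.fdr_significant = bool(rej)
    return out


def _gpd_tail_p(observed: float, null: np.ndarray, p_perm: float) -> float:
    """Knijnenburg-style tail refinement: fit a generalised Pareto to the
    top 10% of surrogate exceedances; fall back to the permutation p when
    the fit is not applicable."""
    thr = float(np.quantile(null, 0.9))
    exceed = null[null > thr] - thr
    if observed <= thr or exceed.size < 10:
        return p_perm
    try:
        c, loc, scale = genpareto.fit(exceed, floc=0.0)
        tail = genpareto.sf(observed - thr, c, loc=0.0, scale=scale)
        p = float(exceed.size / null.size * tail)
        if not np.isfinite(p) or p <= 0:
            return p_perm
        return min(p, p_perm)
    except Exception:
        return p_perm


def gc_report(results: Sequence[GCResult]) -> pd.DataFrame:
    """GC connections as a delimited-text-ready table."""
    return pd.DataFrame([
        {"source": r.source, "target": r.target, "statistic": r.statistic,
         "order": r.order, "p": r.p, "p_refined": r.p_refined,
         "fdr_significant": r.fdr_significant, "flagged": r.flagged}
        for r in results
    ])
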