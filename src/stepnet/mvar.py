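"""Multivariate autoregressive modelling: Vieira-Morf lattice estimation,
companion-matrix stability, residual-whiteness battery, and information-
criterion model-order selection.

The Vieira-Morf estimator is a multichannel lattice (Levinson-type)
recursion whose reflection coefficients are formed from the geometric-mean
normalization of the forward/backward partial covariances; multi-trial data
are handled by accumulating the forward/backward covariances across trials
before each reflection step, which is what makes very short analysis
windows usable when many movement cycles are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "MVARWindowModel",
    "WhitenessReport",
    "OrderSelection",
    "fit_mvar_vieira_morf",
    "mvar_residuals",
    "check_stability",
    "test_whiteness",
    "ljung_box",
    "box_pierce",
    "mcleod_li",
    "select_model_order",
]


@dataclass
class MVARWindowModel:
    """A fitted VAR(p) model: x[t] = sum_k A[k] x[t-k] + e[t]."""

    order: int
    A: np.ndarray               # (p, M, M) coefficient matrices
    sigma: np.ndarray           # innovation covariance (M, M)
    n_eff: int                  # pooled sample count used for the fit
    n_trials: int = 1
    window_center: float = 0.0  # seconds
    jitter: float = 0.0         # regularization added to a singular covariance

    @property
    def n_channels(self) -> int:
        return self.sigma.shape[0]

    def companion(self) -> np.ndarray:
        p, m = self.order, self.n_channels
        if p == 0:
            return np.zeros((0, 0))
        C = np.zeros((p * m, p * m))
        C[:m] = self.A.transpose(1, 0, 2).reshape(m, p * m)
        if p > 1:
            C[m:, :-m] = np.eye((p - 1) * m)
        return C


def _as_trials(data: np.ndarray) -> np.ndarray:
    X = np.asarray(data, float)
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3:
        raise ValueError("data must be (M, N) or (trials, M, N)")
    return X


def fit_mvar_vieira_morf(data: np.ndarray, p: int,
                         window_center: float = 0.0) -> MVARWindowModel:
    """Fit a VAR(p) by the Vieira-Morf lattice algorithm.

    ``data`` is (M, N) or (trials, M, N); trials are pooled by accumulating
    forward/backward covariances at every lattice stage. ``p = 0`` returns
    only the sample covariance. A singular stage covariance is regularized
    with a logged diagonal jitter.
    """
    X = _as_trials(data)
    n_trials, m, n = X.shape
    if p < 0:
        raise ValueError("order must be >= 0")
    n_eff = n_trials * n
    if p > 0 and n_trials * (n - p) <= p * m:
        raise ValueError(
            f"pooled samples {n_trials * (n - p)} insufficient for p={p}, M={m}")
    X = X - X.mean(axis=2, keepdims=True)
    if p == 0:
        sigma = sum(x @ x.T for x in X) / n_eff
        return MVARWindowModel(order=0, A=np.zeros((0, m, m)), sigma=sigma,
                               n_eff=n_eff, n_trials=n_trials,
                               window_center=window_center)

    ef = X.copy()                  # forward prediction errors (T, M, N)
    eb = X.copy()                  # backward prediction errors (T, M, N)
    A = np.zeros((p, m, m))        # forward coefficients
    B = np.zeros((p, m, m))        # backward coefficients
    total_jitter = 0.0

    for k in range(1, p + 1):
        # accumulate stage covariances across trials (valid samples only)
        fk = ef[:, :, k:]
        bk = eb[:, :, k - 1:-1]
        Pf = np.einsum("tin,tjn->ij", fk, fk)
        Pb = np.einsum("tin,tjn->ij", bk, bk)
        Pfb = np.einsum("tin,tjn->ij", fk, bk)

        def chol(Pm):
            nonlocal total_jitter
            jit = 0.0
            eye = np.eye(m)
            while True:
                try:
                    return np.linalg.cholesky(Pm + jit * eye)
                except np.linalg.LinAlgError:
                    jit = max(jit * 10, 1e-10 * max(np.trace(Pm) / m, 1e-30))
                    total_jitter += jit

        Sf = chol(Pf)
        Sb = chol(Pb)
        # geometric-mean-normalized partial cross-correlation
        rho = np.linalg.solve(Sf, Pfb) @ np.linalg.inv(Sb).T
        Kf = Sf @ rho @ np.linalg.inv(Sb)        # forward reflection
        Kb = Sb @ rho.T @ np.linalg.inv(Sf)      # backward reflection

        A_prev = A.copy()
        B_prev = B.copy()
        A[k - 1] = Kf
        B[k - 1] = Kb
        for i in range(1, k):
            A[i - 1] = A_prev[i - 1] - Kf @ B_prev[k - i - 1]
            B[i - 1] = B_prev[i - 1] - Kb @ A_prev[k - i - 1]

        # update error series, keeping absolute-time alignment
        f_new = fk - np.einsum("ij,tjn->tin", Kf, bk)
        b_new = bk - np.einsum("ij,tjn->tin", Kb, fk)
        ef[:, :, k:] = f_new
        eb[:, :, k:] = b_new

    n_valid = n_trials * (n - p)
    fk = ef[:, :, p:]
    sigma = np.einsum("tin,tjn->ij", fk, fk) / n_valid
    sigma = (sigma + sigma.T) / 2.0
    return MVARWindowModel(order=p, A=A, sigma=sigma, n_eff=n_valid,
                           n_trials=n_trials, window_center=window_center,
                           jitter=total_jitter)


def mvar_residuals(model: MVARWindowModel, data: np.ndarray) -> np.ndarray:
    """One-step prediction residuals, (trials, M, N - p); data are centered
    per trial as in the fit."""
    X = _as_trials(data)
    X = X - X.mean(axis=2, keepdims=True)
    p = model.order
    n = X.shape[2]
    res = X[:, :, p:].copy()
    for k in range(1, p + 1):
        res -= np.einsum("ij,tjn->tin", model.A[k - 1], X[:, :, p - k:n - k])
    return res


def check_stability(model: MVARWindowModel):
    """(stable flag, spectral radius) from the companion-matrix eigenvalues."""
    if model.order == 0:
        return True, 0.0
    radius = float(np.abs(np.linalg.eigvals(model.companion())).max())
    return radius < 1.0, radius


# ---------------------------------------------------------------------------
# whiteness battery
# ---------------------------------------------------------------------------


def _autocorr(x: np.ndarray, h: int) -> np.ndarray:
    """Sample autocorrelations r_1..r_h of a 1-D series (mean removed)."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = x.size
    denom = float(x @ x)
    if denom == 0:
        return np.zeros(h)
    return np.array([x[k:] @ x[:-k] for k in range(1, h + 1)]) / denom


def ljung_box(x: np.ndarray, h: int, p: int = 0):
    """Ljung-Box portmanteau: Q = N(N+2) sum_k r_k^2 / (N-k), df = h - p."""
    x = np.asarray(x, float)
    n = x.size
    r = _autocorr(x, h)
    q = n * (n + 2) * np.sum(r ** 2 / (n - np.arange(1, h + 1)))
    df = max(h - p, 1)
    return float(q), float(sp_stats.chi2.sf(q, df))


def box_pierce(x: np.ndarray, h: int, p: int = 0):
    """Box-Pierce portmanteau: Q = N sum_k r_k^2, df = h - p."""
    x = np.asarray(x, float)
    n = x.size
    r = _autocorr(x, h)
    q = n * np.sum(r ** 2)
    df = max(h - p, 1)
    return float(q), float(sp_stats.chi2.sf(q, df))


def mcleod_li(x: np.ndarray, h: int):
    """McLeod-Li test: Ljung-Box applied to the squared series, df = h."""
    return ljung_box(np.asarray(x, float) ** 2, h, p=0)


@dataclass
class WhitenessReport:
    """Residual-whiteness battery over channels (and trials when pooled).

    For multi-trial residuals each test is run per (trial, channel) at the
    trial's own sample size and the battery passes when the rejection
    fraction stays within a binomial bound of the nominal level — the
    calibrated aggregate for ensembles of short windows. Single-trial
    residuals use a Bonferroni bound across channels.
    """

    h: int
    alpha: float
    ljung_box_pass: bool
    box_pierce_pass: bool
    mcleod_li_pass: bool
    acf_pass: bool
    reject_fractions: dict          # test name -> fraction of rejections
    acf_exceedance: float           # fraction of |r_k| beyond 1.96/sqrt(N)
    pvalues: dict = field(default_factory=dict)  # test name -> array

    @property
    def passed(self) -> bool:
        return (self.ljung_box_pass and self.box_pierce_pass
                and self.mcleod_li_pass and self.acf_pass)


def _batch_portmanteau(R: np.ndarray, h: int):
    """Vectorized LB/BP/McLeod-Li statistics per (trial, channel).

    ``R`` is (trials, M, N) mean-removed residuals; returns a dict of
    (trials, M) statistic arrays plus the autocorrelations (trials, M, h).
    """
    n = R.shape[-1]
    X = R - R.mean(-1, keepdims=True)
    denom = (X * X).sum(-1)
    denom = np.where(denom > 0, denom, 1.0)
    r = np.stack([(X[..., k:] * X[..., :-k]).sum(-1) / denom
                  for k in range(1, h + 1)], axis=-1)
    lags = np.arange(1, h + 1)
    lb = n * (n + 2) * (r ** 2 / (n - lags)).sum(-1)
    bp = n * (r ** 2).sum(-1)
    X2 = X ** 2
    X2 = X2 - X2.mean(-1, keepdims=True)
    d2 = (X2 * X2).sum(-1)
    d2 = np.where(d2 > 0, d2, 1.0)
    r2 = np.stack([(X2[..., k:] * X2[..., :-k]).sum(-1) / d2
                   for k in range(1, h + 1)], axis=-1)
    ml = n * (n + 2) * (r2 ** 2 / (n - lags)).sum(-1)
    return {"ljung_box": lb, "box_pierce": bp, "mcleod_li": ml}, r


_NULL_CRIT_CACHE: dict = {}


def _empirical_criticals(n_res: int, m: int, p: int, h: int, alpha: float,
                         n_null_trials: int = 400, seed: int = 987654321):
    """Small-sample critical values of the portmanteau statistics.

    The chi-square reference badly over-rejects on the ~25-sample windows of
    a sliding-window analysis, so for the multi-trial regime the (1 - alpha)
    critical value of each statistic is taken from a matched, seeded
    empirical null: iid Gaussian windows of the same shape, fit with the
    same VAR(p) pooling, residual statistics pooled over trials x channels.
    """
    key = (n_res, m, p, h, round(alpha, 6))
    if key not in _NULL_CRIT_CACHE:
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n_null_trials, m, n_res + p))
        if p > 0:
            model = fit_mvar_vieira_morf(X, p)
            res = mvar_residuals(model, X)
        else:
            res = X
        stats, _ = _batch_portmanteau(res, h)
        _NULL_CRIT_CACHE[key] = {
            name: float(np.quantile(s, 1 - alpha)) for name, s in stats.items()}
    return _NULL_CRIT_CACHE[key]


def test_whiteness(residuals: np.ndarray, h: int = 8, alpha: float = 0.05,
                   p: int = 0, calibrate: Optional[bool] = None
                   ) -> WhitenessReport:
    """Run the four-test whiteness battery on model residuals.

    ``residuals`` is (M, N) or (trials, M, N); ``p`` is the fitted model
    order (degrees-of-freedom correction for the portmanteau tests on raw
    residuals). Requires N > h and h > p.

    Single series use the asymptotic chi-square references with a
    Bonferroni bound across channels. Multi-trial ensembles (the sliding-
    window regime, where each window holds only ~25 samples) instead test
    every (trial, channel) unit against seeded empirical-null critical
    values matched to the window size and fit (``calibrate``, default on
    for multi-trial input) and pass when the rejection fraction stays
    within a two-sigma binomial bound of the nominal level.
    """
    R = _as_trials(residuals)
    n_trials, m, n = R.shape
    if n <= h:
        raise ValueError(f"residual length {n} must exceed h={h}")
    if h <= p:
        raise ValueError(f"h={h} must exceed model order p={p}")
    if calibrate is None:
        calibrate = n_trials > 1

    stats, r = _batch_portmanteau(R, h)
    dof = {"ljung_box": max(h - p, 1), "box_pierce": max(h - p, 1),
           "mcleod_li": h}
    if calibrate:
        crit = _empirical_criticals(n, m, p, h, alpha)
        rejects = {name: stats[name] > crit[name] for name in stats}
        pvals = {name: np.where(rejects[name], 0.0, 1.0) for name in stats}
    else:
        pvals = {name: sp_stats.chi2.sf(stats[name], dof[name])
                 for name in stats}
        rejects = {name: pvals[name] < alpha for name in stats}
    reject = {name: float(rj.mean()) for name, rj in rejects.items()}
    bound = 1.96 / np.sqrt(n)
    acf_frac = float((np.abs(r) > bound).mean())
    if n_trials > 1:
        # binomial bound on the rejection fraction at nominal level alpha
        slack = 2.0 * np.sqrt(alpha * (1 - alpha) / n_trials)
        passes = {name: reject[name] <= alpha + slack for name in stats}
        acf_pass = acf_frac <= 0.05 + 2.0 * np.sqrt(0.05 * 0.95 / n_trials)
    else:
        passes = {name: bool((pvals[name] > alpha / m).all()) for name in stats}
        acf_pass = acf_frac <= 0.05 + 2.0 * np.sqrt(0.05 * 0.95 / (m * h))
    return WhitenessReport(
        h=h, alpha=alpha,
        ljung_box_pass=bool(passes["ljung_box"]),
        box_pierce_pass=bool(passes["box_pierce"]),
        mcleod_li_pass=bool(passes["mcleod_li"]),
        acf_pass=bool(acf_pass),
        reject_fractions=reject, acf_exceedance=acf_frac,
        pvalues=pvals)


# ---------------------------------------------------------------------------
# model-order selection
# ---------------------------------------------------------------------------


@dataclass
class OrderSelection:
    """Outcome of information-criterion + stability/whiteness order search."""

    order: int
    passed: bool                 # False if no candidate met all requirements
    table: "object"              # pandas DataFrame of criteria per candidate
    details: dict = field(default_factory=dict)


def _log_det(sigma: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(sigma)
    return ld if sign > 0 else float("inf")


def select_model_order(windows: Sequence[np.ndarray],
                       candidates: Sequence[int] = tuple(range(1, 11)),
                       alpha: float = 0.05, h: int = 8,
                       pass_fraction: float = 0.5) -> OrderSelection:
    """Choose the smallest stable, white model order over a set of windows.

    ``windows`` is a sequence of (trials, M, N) arrays (the pooled sliding
    windows). For every candidate order the Akaike (AIC), Schwarz-Bayes
    (SBC) and Hannan-Quinn (HQ) criteria are tabulated,

        AIC(p) = ln det S_p + 2 p M^2 / N,
        SBC(p) = ln det S_p + p M^2 ln(N) / N,
        HQ(p)  = ln det S_p + 2 p M^2 ln(ln N) / N,

    and, scanning candidates in ascending order, the first whose fits are
    stable in every window and whose residual battery passes in at least
    ``pass_fraction`` of windows is returned. If none passes, the best-
    effort order (smallest SBC among stable candidates, else smallest SBC
    overall) is returned flagged ``passed=False``.
    """
    import pandas as pd

    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("empty candidate set")
    windows = [_as_trials(w) for w in windows]
    if not windows:
        raise ValueError("no windows given")
    rows = []
    stability = {}
    whiteness = {}
    for p in candidates:
        ld, aic, sbc, hq = [], [], [], []
        stable_all = True
        white_pass = 0
        for W in windows:
            model = fit_mvar_vieira_morf(W, p)
            m = model.n_channels
            n_eff = model.n_eff
            l = _log_det(model.sigma)
            ld.append(l)
            aic.append(l + 2 * p * m * m / n_eff)
            sbc.append(l + p * m * m * np.log(n_eff) / n_eff)
            hq.append(l + 2 * p * m * m * np.log(np.log(n_eff)) / n_eff)
            stable, _ = check_stability(model)
            stable_all &= stable
            res = mvar_residuals(model, W)
            h_eff = max(h, p + 1)   # portmanteau df must stay positive
            if res.shape[2] > h_eff:
                rep = test_whiteness(res, h=h_eff, alpha=alpha, p=p)
                white_pass += int(rep.passed)
        frac_white = white_pass / len(windows)
        stability[p] = stable_all
        whiteness[p] = frac_white
        rows.append({"order": p, "logdet": float(np.mean(ld)),
                     "AIC": float(np.mean(aic)), "SBC": float(np.mean(sbc)),
                     "HQ": float(np.mean(hq)), "stable": stable_all,
                     "whiteness_fraction": frac_white})
    table = pd.DataFrame(rows)
    for p in candidates:
        if stability[p] and whiteness[p] >= pass_fraction:
            return OrderSelection(order=p, passed=True, table=table,
                                  details={"stability": stability,
                                           "whiteness": whiteness})
    stable_ps = [p for p in candidates if stability[p]]
    pool = stable_ps or candidates
    sbc = {r["order"]: r["SBC"] for r in rows}
    best = min(pool, key=lambda p: sbc[p])
    return OrderSelection(order=best, passed=False, table=table,
                          details={"stability": stability,
                                   "whiteness": whiteness})
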