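"""Exact Gaussian inference for a (mode-)time-varying linear dynamical system.

Filtering log-likelihood, RTS smoothing, and posterior sampling of the
latent continuous path (the simulation smoother / forward-filter
backward-sampler) for the model

    r_{i+1} = mu_i + F_i r_i + N(0, Sigma_i),      psi_i = H r_i + N(0, R).

Covariance updates use the Joseph form and a small diagonal jitter on
innovation covariances; all returned covariances are symmetrized.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .dynamics import DiscreteStateParams

_JITTER = 1e-9


class FilterError(RuntimeError):
    pass


@dataclass
class ObservationModel:
    """Linear observation psi = H r + N(0, R); H a (d_obs, d) selector."""

    H: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        if np.linalg.matrix_rank(self.H) < self.H.shape[0]:
            raise ValueError("H must have full row rank")

    @property
    def d_obs(self) -> int:
        return self.H.shape[0]

    @property
    def d(self) -> int:
        return self.H.shape[1]


@dataclass
class FilterResult:
    loglik: float
    pred_mean: np.ndarray    # (T, d) one-step-ahead state means (pred_mean[0] = init)
    pred_cov: np.ndarray     # (T, d, d)
    filt_mean: np.ndarray    # (T, d)
    filt_cov: np.ndarray     # (T, d, d)


@dataclass
class SmootherResult:
    mean: np.ndarray         # (T, d)
    cov: np.ndarray          # (T, d, d)


def _per_step(params, T):
    """Normalize a single shared parameter set to a length T-1 sequence."""
    if isinstance(params, DiscreteStateParams):
        return [params] * (T - 1)
    params = list(params)
    if len(params) != T - 1:
        raise ValueError(f"need {T - 1} per-step parameter sets, got {len(params)}")
    return params


def _sym(a):
    return 0.5 * (a + a.T)


def _logpdf(v, S, step):
    d = v.size
    S = _sym(S)
    scale = max(1.0, np.trace(S) / d)
    # tiered jitter: a negligible 1e-12 first, the coarser fallback only
    # when the innovation covariance is genuinely near-singular
    for jit in (1e-12 * scale, _JITTER * scale):
        try:
            L = np.linalg.cholesky(S + jit * np.eye(d))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise FilterError(
            f"singular innovation covariance at step {step}; "
            "consider adding jitter to R")
    z = np.linalg.solve(L, v)
    return -0.5 * (d * np.log(2 * np.pi) + z @ z) - np.log(np.diagonal(L)).sum(), L


def kalman_filter(psi, params, obs: ObservationModel, init_mean, init_cov) -> FilterResult:
    """Forward filter; returns log-likelihood and predicted/filtered moments.

    ``params`` is a sequence of T-1 :class:`DiscreteStateParams` (one per
    transition) or a single shared set.
    """
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    T = psi.shape[0]
    seq = _per_step(params, T) if T > 1 else []
    H, R = obs.H, obs.R
    d = obs.d
    m = np.asarray(init_mean, dtype=float).copy()
    P = _sym(np.asarray(init_cov, dtype=float))
    I = np.eye(d)

    pm = np.empty((T, d)); pP = np.empty((T, d, d))
    fm = np.empty((T, d)); fP = np.empty((T, d, d))
    ll = 0.0
    for i in range(T):
        if i > 0:
            p = seq[i - 1]
            m = p.mu + p.F @ m
            P = _sym(p.F @ P @ p.F.T + p.Sigma)
        pm[i], pP[i] = m, P
        v = psi[i] - H @ m
        S = H @ P @ H.T + R
        li, L = _logpdf(v, S, i)
        ll += li
        K = P @ H.T @ np.linalg.solve(L.T, np.linalg.solve(L, np.eye(obs.d_obs)))
        m = m + K @ v
        IKH = I - K @ H
        P = _sym(IKH @ P @ IKH.T + K @ R @ K.T)
        fm[i], fP[i] = m, P
    if not np.isfinite(ll):
        raise FilterError("non-finite filter log-likelihood")
    return FilterResult(loglik=float(ll), pred_mean=pm, pred_cov=pP,
                        filt_mean=fm, filt_cov=fP)


def rts_smoother(filt: FilterResult, params, obs: ObservationModel = None) -> SmootherResult:
    """Rauch-Tung-Striebel backward pass over a :class:`FilterResult`."""
    T, d = filt.filt_mean.shape
    seq = _per_step(params, T) if T > 1 else []
    sm = filt.filt_mean.copy()
    sP = filt.filt_cov.copy()
    for i in range(T - 2, -1, -1):
        F = seq[i].F
        Ppred = filt.pred_cov[i + 1]
        J = np.linalg.solve(Ppred + _JITTER * np.eye(d), F @ filt.filt_cov[i]).T
        sm[i] = filt.filt_mean[i] + J @ (sm[i + 1] - filt.pred_mean[i + 1])
        sP[i] = _sym(filt.filt_cov[i] + J @ (sP[i + 1] - Ppred) @ J.T)
    return SmootherResult(mean=sm, cov=sP)


def _draw_gauss(mean, cov, rng):
    w, V = np.linalg.eigh(_sym(cov))
    w = np.clip(w, 0.0, None)
    return mean + (V * np.sqrt(w)) @ rng.standard_normal(mean.size)


def simulation_smoother(psi, params, obs: ObservationModel, init_mean, init_cov,
                        seed=None, rng=None) -> np.ndarray:
    """One exact posterior draw of the latent path r_{0:T-1} given psi and modes.

    Forward filter then backward sampling; degenerate (rank-deficient)
    conditionals are handled by eigenvalue clipping, so noise-free limits
    collapse to the deterministic path.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    T = psi.shape[0]
    seq = _per_step(params, T) if T > 1 else []
    filt = kalman_filter(psi, params if T > 1 else [], obs, init_mean, init_cov)
    d = filt.filt_mean.shape[1]
    x = np.empty((T, d))
    x[T - 1] = _draw_gauss(filt.filt_mean[T - 1], filt.filt_cov[T - 1], rng)
    for i in range(T - 2, -1, -1):
        F = seq[i].F
        Ppred = filt.pred_cov[i + 1]
        J = np.linalg.solve(Ppred + _JITTER * np.eye(d), F @ filt.filt_cov[i]).T
        mean = filt.filt_mean[i] + J @ (x[i + 1] - filt.pred_mean[i + 1])
        cov = filt.filt_cov[i] - J @ Ppred @ J.T
        x[i] = _draw_gauss(mean, cov, rng)
    return x
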