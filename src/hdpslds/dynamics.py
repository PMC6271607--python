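"""Continuous- and discrete-time parameterizations of one SLDS state.

Each hidden dynamical state ("mode") of a switching linear dynamical
system is an overdamped-Langevin / Ornstein-Uhlenbeck process

    dr_t = Phi B (rbar - r_t) dt + sqrt(2) C dW_t,      Phi = C C^T / kBT,

observed at a uniform interval ``dt`` through additive Gaussian
measurement noise.  Sampled exactly, it is the linear-Gaussian recursion

    r_{i+1} = mu + F r_i + eta_i,      eta_i ~ N(0, Sigma),
    psi_i   = H r_i + eps_i,           eps_i ~ N(0, R),

with F = exp(-Phi B dt), mu = (I - F) rbar and Sigma the finite-horizon
Lyapunov integral of the diffusion.  This module holds both
parameterizations and the exact maps between them.

Sign/stationarity convention: with the restoring force B(rbar - r), the
stationary mean of the discrete recursion solves m = mu + F m, i.e.
m = (I - F)^{-1} mu.  The equivalent form -F^{-1} mu (valid when F is
invertible and mu = (I - F) rbar) appears in parts of the SPT literature;
we implement (I - F)^{-1} mu, which is defined for every stable F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, logm, solve_discrete_lyapunov, sqrtm


class InvalidParameterError(ValueError):
    """A dynamical parameter matrix violates its contract."""


def _as_matrix(a, d, name):
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.shape != (d, d):
        raise InvalidParameterError(f"{name} must be {d}x{d}, got {a.shape}")
    return a


def _check_psd(a, name, tol=1e-10):
    if not np.allclose(a, a.T, atol=1e-8 * (1 + np.abs(a).max())):
        raise InvalidParameterError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(0.5 * (a + a.T))
    if w.min() < -tol * max(1.0, w.max()):
        raise InvalidParameterError(f"{name} must be PSD (min eigenvalue {w.min():g})")


@dataclass
class ContinuousStateParams:
    """SDE-form kinetics of one mode.

    Parameters
    ----------
    rbar : (d,) array
        Fixed point of the restoring force, in length units (um).
    B : (d, d) array
        Confinement matrix (1/time); sets the corral radius / mean
        reversion through the eigenvalues of ``Phi @ B``.
    C : (d, d) array
        Noise loading (length/sqrt(time)); ``D = C @ C.T`` is the
        diffusion matrix.
    kBT : float
        Energy scale; ``Phi = D / kBT``. A pure scale here, default 1.
    R : (d_obs, d_obs) array
        Measurement-noise covariance (length^2).
    """

    rbar: np.ndarray
    B: np.ndarray
    C: np.ndarray
    kBT: float = 1.0
    R: np.ndarray = field(default=None)

    def __post_init__(self):
        self.rbar = np.atleast_1d(np.asarray(self.rbar, dtype=float))
        d = self.rbar.size
        self.B = _as_matrix(self.B, d, "B")
        self.C = _as_matrix(self.C, d, "C")
        if self.R is None:
            self.R = np.zeros((d, d))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        _check_psd(self.D, "D")
        _check_psd(self.R, "R")
        ev = np.linalg.eigvals(self.PhiB)
        if np.any(ev.real < -1e-12):
            raise InvalidParameterError(
                f"Phi@B must have eigenvalues with nonnegative real part, got {ev}"
            )

    @property
    def d(self) -> int:
        return self.rbar.size

    @property
    def D(self) -> np.ndarray:
        """Diffusion matrix C C^T (length^2/time)."""
        return self.C @ self.C.T

    @property
    def PhiB(self) -> np.ndarray:
        """Effective mean-reversion rate matrix Phi @ B (1/time)."""
        return (self.D / self.kBT) @ self.B

    @classmethod
    def from_rates(cls, rbar, rates, D, R=None, kBT=1.0):
        """Build from the effective reversion-rate matrix ``Phi B`` directly.

        ``rates`` may be a (d,) diagonal or a (d, d) matrix; ``D`` a scalar,
        (d,) diagonal or (d, d) matrix.  B is recovered as kBT * D^{-1} rates.
        """
        rbar = np.atleast_1d(np.asarray(rbar, dtype=float))
        d = rbar.size
        rates = np.asarray(rates, dtype=float)
        A = np.diag(rates) if rates.ndim == 1 else rates
        Dm = np.asarray(D, dtype=float)
        if Dm.ndim == 0:
            Dm = Dm * np.eye(d)
        elif Dm.ndim == 1:
            Dm = np.diag(Dm)
        B = kBT * np.linalg.solve(Dm, A)
        C = np.real_if_close(sqrtm(Dm))
        return cls(rbar=rbar, B=B, C=np.asarray(C, dtype=float), kBT=kBT, R=R)


@dataclass
class DiscreteStateParams:
    """Discrete-time kinetics of one mode: r_{i+1} = mu + F r_i + N(0, Sigma)."""

    mu: np.ndarray
    F: np.ndarray
    Sigma: np.ndarray
    R: np.ndarray
    dt: float

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        d = self.mu.size
        self.F = _as_matrix(self.F, d, "F")
        self.Sigma = 0.5 * (np.atleast_2d(np.asarray(self.Sigma, dtype=float))
                            + np.atleast_2d(np.asarray(self.Sigma, dtype=float)).T)
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        _check_psd(self.Sigma, "Sigma", tol=1e-9)
        _check_psd(self.R, "R")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")

    @property
    def d(self) -> int:
        return self.mu.size


def discretize(cont: ContinuousStateParams, dt: float) -> DiscreteStateParams:
    """Exact one-step discretization of the OU mode at sampling interval dt.

    F = exp(-Phi B dt); mu = (I - F) rbar;
    Sigma = int_0^dt exp(-Phi B s) (2 D) exp(-(Phi B)^T s) ds, evaluated
    exactly with the van Loan block matrix-exponential construction.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    d = cont.d
    A = -cont.PhiB  # continuous drift matrix: dr = A (r - rbar) dt + ...
    Q = 2.0 * cont.D
    # van Loan: expm([[A, Q], [0, -A^T]] dt) -> F = M22^T? use standard blocks
    M = np.zeros((2 * d, 2 * d))
    M[:d, :d] = -A
    M[:d, d:] = Q
    M[d:, d:] = A.T
    EM = expm(M * dt)
    F = expm(A * dt)
    Sigma = F @ EM[:d, d:]
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(Sigma))):
        raise InvalidParameterError("matrix exponential of Phi@B is non-finite")
    Sigma = 0.5 * (Sigma + Sigma.T)
    wmin = np.linalg.eigvalsh(Sigma).min()
    if wmin < -1e-12 * max(1.0, np.abs(Sigma).max()):
        raise InvalidParameterError(f"Lyapunov integral produced indefinite Sigma ({wmin:g})")
    mu = (np.eye(d) - F) @ cont.rbar
    return DiscreteStateParams(mu=mu, F=F, Sigma=Sigma, R=cont.R.copy(), dt=dt)


def continuize(disc: DiscreteStateParams, kBT: float = 1.0) -> ContinuousStateParams:
    """Invert :func:`discretize`: recover (rbar, B, C) from (mu, F, Sigma, dt).

    Requires the principal matrix logarithm of F to exist (no eigenvalues on
    the closed negative real axis) and |eig(F)| <= 1.
    """
    d = disc.d
    F = disc.F
    ev = np.linalg.eigvals(F)
    if np.any(np.abs(ev) > 1 + 1e-9):
        raise InvalidParameterError("F has eigenvalues outside the unit disk")
    if np.any((ev.real <= 0) & (np.abs(ev.imag) < 1e-12)):
        raise InvalidParameterError(
            "F has eigenvalues on the negative real axis; the discrete model "
            "has no continuous OU embedding at this dt"
        )
    A = logm(F) / disc.dt  # = -Phi B
    if np.abs(A.imag).max() > 1e-8 * max(1.0, np.abs(A.real).max()):
        raise InvalidParameterError("matrix logarithm of F is not real")
    A = A.real
    # Sigma = int_0^dt e^{A s} Q e^{A^T s} ds  <=>  vec(Sigma) = K vec(Q),
    # K = int_0^dt e^{(A (+) A) s} ds with (+) the Kronecker sum; the
    # integral is itself the upper-right block of a van Loan exponential,
    # defined even when A (+) A is singular.
    d2 = d * d
    Ksum = np.kron(A, np.eye(d)) + np.kron(np.eye(d), A)
    Mv = np.zeros((2 * d2, 2 * d2))
    Mv[:d2, :d2] = Ksum
    Mv[:d2, d2:] = np.eye(d2)
    K = expm(Mv * disc.dt)[:d2, d2:]
    Q = np.linalg.solve(K, disc.Sigma.reshape(d2)).reshape(d, d)
    Q = 0.5 * (Q + Q.T)
    D = 0.5 * Q
    _check_psd(D, "recovered D", tol=1e-8)
    # drift A = -(D/kBT) B
    B = -kBT * np.linalg.solve(D, A)
    C = np.real_if_close(sqrtm(D))
    mean = np.linalg.solve(np.eye(d) - F, disc.mu) if np.abs(1 - ev).min() > 1e-12 \
        else np.zeros(d)
    return ContinuousStateParams(rbar=mean, B=B, C=np.asarray(C, dtype=float),
                                 kBT=kBT, R=disc.R.copy())


def stationary_moments(disc: DiscreteStateParams):
    """Stationary mean and covariance of a stable discrete mode.

    mean solves m = mu + F m  (i.e. (I - F)^{-1} mu); cov solves the
    discrete Lyapunov equation P = F P F^T + Sigma.
    """
    ev = np.abs(np.linalg.eigvals(disc.F))
    if ev.max() >= 1 - 1e-12:
        raise InvalidParameterError(
            "F has a (near) unit root; no stationary distribution exists — "
            "use non-stationary initialization instead"
        )
    mean = np.linalg.solve(np.eye(disc.d) - disc.F, disc.mu)
    cov = solve_discrete_lyapunov(disc.F, disc.Sigma)
    return mean, 0.5 * (cov + cov.T)
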