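"""Sticky HDP-SLDS blocked Gibbs sampler (weak-limit truncation).

One sweep resamples, in order,

1. the latent continuous path ``r_{0:T-1}`` given the mode sequence
   (simulation smoother),
2. the mode sequence given the path (forward-filter backward-sample over
   the L truncated modes; the emission of mode k at step i is the
   Gaussian transition density N(r_{i+1}; mu_k + F_k r_i, Sigma_k)),
3. per-mode dynamics (matrix-normal-inverse-Wishart conjugate updates)
   and the shared measurement covariance R (inverse-Wishart on the pooled
   residuals psi - H r),
4. the transition structure: rows pi^(j) ~ Dirichlet(alpha beta + kappa
   delta_j + counts) and the shared stick weights beta via the usual
   auxiliary table counts,
5. the concentrations gamma and (alpha + kappa) (auxiliary-variable Gamma
   updates) and the stickiness ratio rho = kappa / (kappa + alpha) (Beta
   conditional).

The sticky prior DP(alpha + kappa, (alpha beta + kappa delta_j)/(alpha +
kappa)) biases each row toward self-transition; rho quantifies that bias.
Everything is driven by one numpy Generator, so chains are reproducible
from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment

from . import _kernels
from .dynamics import DiscreteStateParams
from .kalman import ObservationModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration / containers


@dataclass
class MNIWPrior:
    """Base measure lambda: matrix-normal-inverse-Wishart over (mu, F, Sigma), IW over R.

    The regression form stacks A = [F mu] against regressors [r; 1]:
    Sigma ~ IW(nu0, Psi0); A | Sigma ~ MN(M0, Sigma, V0); R ~ IW(nu_R, Psi_R).
    """

    M0: np.ndarray          # (d, d+1)
    V0: np.ndarray          # (d+1, d+1) column covariance
    nu0: float
    Psi0: np.ndarray        # (d, d)
    nu_R: float
    Psi_R: np.ndarray       # (d_obs, d_obs)

    def __post_init__(self):
        self.M0 = np.atleast_2d(np.asarray(self.M0, dtype=float))
        self.V0 = np.atleast_2d(np.asarray(self.V0, dtype=float))
        self.Psi0 = np.atleast_2d(np.asarray(self.Psi0, dtype=float))
        self.Psi_R = np.atleast_2d(np.asarray(self.Psi_R, dtype=float))
        d = self.Psi0.shape[0]
        if self.nu0 <= d + 1:
            raise ValueError("nu0 must exceed d+1 so the prior mean of Sigma exists")
        if self.nu_R <= self.Psi_R.shape[0] + 1:
            raise ValueError("nu_R must exceed d_obs+1 so the prior mean of R exists")

    @property
    def d(self) -> int:
        return self.Psi0.shape[0]

    @property
    def mean_Sigma(self) -> np.ndarray:
        return self.Psi0 / (self.nu0 - self.d - 1)

    @property
    def mean_R(self) -> np.ndarray:
        return self.Psi_R / (self.nu_R - self.Psi_R.shape[0] - 1)

    @classmethod
    def default(cls, d: int, d_obs: int, Sigma_mean: np.ndarray, R_mean: np.ndarray,
                V0_scale: float = 10.0, r_pseudo: float = 1000.0) -> "MNIWPrior":
        """Prior centered on the given Sigma and R means.

        Per-mode dynamics stay vague (df = dim + 2, the smallest with a
        defined mean; A centered on a random walk F = I, mu = 0, column
        covariance V0_scale * I) because each mode's diffusivity and drift
        must be learned from its own segment.  The measurement covariance
        prior instead carries ``r_pseudo`` pseudo-observations: localization
        noise in SPT is calibrated independently of any one trajectory, so
        the benchmark treats it as known up to that weight (default 1000,
        one benchmark trajectory's worth).
        """
        M0 = np.hstack([np.eye(d), np.zeros((d, 1))])
        nu_R = d_obs + 2 + r_pseudo
        return cls(M0=M0, V0=V0_scale * np.eye(d + 1),
                   nu0=d + 2, Psi0=np.asarray(Sigma_mean, dtype=float) * 1.0,
                   nu_R=nu_R,
                   Psi_R=np.asarray(R_mean, dtype=float) * (nu_R - d_obs - 1))


@dataclass
class HDPHyperConfig:
    """Truncation level, base measure and concentration hyperpriors.

    gamma ~ Gamma(a_gamma, rate=b_gamma); (alpha+kappa) ~ Gamma(a_ak, rate=b_ak);
    rho ~ Beta(c_rho, d_rho).
    """

    base_measure: MNIWPrior
    L: int = 10
    a_gamma: float = 1.0
    b_gamma: float = 0.01
    a_ak: float = 1.0
    b_ak: float = 0.01
    c_rho: float = 25.0
    d_rho: float = 1.0
    n_sweeps: int = 2000
    burn_in: Optional[int] = None     # default: first half
    seed: int = 0

    def __post_init__(self):
        if self.L < 2:
            raise ValueError("truncation level L must be >= 2")
        for name in ("a_gamma", "b_gamma", "a_ak", "b_ak", "c_rho", "d_rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def effective_burn_in(self) -> int:
        return self.n_sweeps // 2 if self.burn_in is None else self.burn_in


@dataclass
class PosteriorSample:
    """One Gibbs sweep's state."""

    modes: np.ndarray               # (T,) labels in 0..L-1
    beta: np.ndarray                # (L,)
    pi: np.ndarray                  # (L, L)
    mus: np.ndarray                 # (L, d)
    Fs: np.ndarray                  # (L, d, d)
    Sigmas: np.ndarray              # (L, d, d)
    R: np.ndarray                   # (d_obs, d_obs)
    gamma: float
    alpha_plus_kappa: float
    rho: float
    r_path: np.ndarray              # (T, d)
    joint_loglik: float


@dataclass
class Chain:
    """Collected sweeps of one trajectory's sampler run."""

    samples: list
    cfg: HDPHyperConfig
    dt: float

    @property
    def n_sweeps(self) -> int:
        return len(self.samples)

    def post_burn_in(self) -> list:
        return self.samples[self.cfg.effective_burn_in:]

    def modes_array(self, post_burn_in: bool = True) -> np.ndarray:
        src = self.post_burn_in() if post_burn_in else self.samples
        return np.array([s.modes for s in src])

    def active_mode_counts(self) -> np.ndarray:
        return np.array([np.unique(s.modes).size for s in self.samples])

    def joint_logliks(self) -> np.ndarray:
        return np.array([s.joint_loglik for s in self.samples])


@dataclass
class SegmentationEstimate:
    labels: np.ndarray              # (T,) aligned labels in 0..L-1
    marginals: np.ndarray           # (T, L) per-time aligned marginal probabilities


def inv_wishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One IW(df, scale) draw via the Bartlett decomposition.

    If A is the Bartlett factor of Wishart(df, I) and Lp = chol(scale),
    then Lp (A A^T)^{-1} Lp^T ~ IW(df, scale).
    """
    p = scale.shape[0]
    A = np.zeros((p, p))
    idx = np.tril_indices(p, -1)
    A[idx] = rng.standard_normal(idx[0].size)
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    Lp = np.linalg.cholesky(scale)
    B = solve_triangular(A, Lp.T, lower=True)   # B = A^{-1} Lp^T
    return B.T @ B


# ---------------------------------------------------------------------------
# conditional updates


def _stack(thetas: Sequence[DiscreteStateParams]):
    mus = np.array([t.mu for t in thetas])
    Fs = np.array([t.F for t in thetas])
    Sigmas = np.array([t.Sigma for t in thetas])
    return mus, Fs, Sigmas


def sample_mode_sequence(r_path, thetas, pi, seed=None, rng=None) -> np.ndarray:
    """Exact joint draw of the label chain given the continuous path.

    ``thetas`` is a sequence of L DiscreteStateParams (or stacked
    (mus, Fs, Sigmas)); returns labels in 0..L-1.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    r_path = np.asarray(r_path, dtype=float)
    if isinstance(thetas, tuple):
        mus, Fs, Sigmas = thetas
    else:
        mus, Fs, Sigmas = _stack(thetas)
    L = mus.shape[0]
    d = mus.shape[1]
    chols = np.linalg.cholesky(Sigmas + 1e-12 * np.eye(d))
    em = _kernels.mode_emission_logliks(r_path, mus, Fs, chols)
    if np.any(np.isnan(em)):
        raise FloatingPointError("NaN in mode emission log-likelihoods")
    u = rng.random(r_path.shape[0])
    return _kernels.ffbs_modes(em, np.asarray(pi, dtype=float), u)


def _dirichlet(conc, rng):
    """Dirichlet draw robust to very small concentrations (gamma underflow)."""
    g = rng.gamma(np.maximum(conc, 1e-12))
    s = g.sum()
    if s <= 0 or not np.isfinite(s):
        g = np.full_like(conc, 1.0)
        s = g.sum()
    return g / s


def _table_counts(n, beta, alpha, kappa, rng):
    """Chinese-restaurant table counts m_jk for each (row j, dish k).

    m_jk = sum_{i=1}^{n_jk} Bernoulli( c_jk / (c_jk + i - 1) ) with
    c_jk = alpha beta_k + kappa delta_jk.
    """
    L = n.shape[0]
    m = np.zeros((L, L), dtype=np.int64)
    for j in range(L):
        for k in range(L):
            njk = int(n[j, k])
            if njk == 0:
                continue
            c = alpha * beta[k] + (kappa if j == k else 0.0)
            if c <= 0:
                continue
            i = np.arange(njk, dtype=float)
            m[j, k] = int((rng.random(njk) < c / (c + i)).sum())
    return m


@dataclass
class TransitionDraw:
    beta: np.ndarray
    pi: np.ndarray
    m: np.ndarray        # (L, L) table counts
    w: np.ndarray        # (L,) sticky override counts
    n: np.ndarray        # (L, L) transition counts


def transition_counts(modes, L) -> np.ndarray:
    n = np.zeros((L, L), dtype=np.int64)
    np.add.at(n, (modes[:-1], modes[1:]), 1)
    return n


def sample_transition_params(modes, beta, gamma, alpha_plus_kappa, rho,
                             seed=None, rng=None, L=None,
                             resample_beta: bool = True) -> TransitionDraw:
    """Resample (beta, pi) given the label chain and concentrations.

    Weak-limit HDP: rows pi^(j) ~ Dirichlet(alpha beta + kappa delta_j +
    n_j); beta ~ Dirichlet(gamma/L + mbar_col) where mbar removes the
    sticky-override tables w_j ~ Binomial(m_jj, rho / (rho + beta_j (1 - rho))).
    ``resample_beta=False`` keeps the supplied beta and draws only the
    rows' pi | beta conditional.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    modes = np.asarray(modes)
    beta = np.asarray(beta, dtype=float)
    if L is None:
        L = beta.size
    alpha = (1.0 - rho) * alpha_plus_kappa
    kappa = rho * alpha_plus_kappa
    n = transition_counts(modes, L)

    m = _table_counts(n, beta, alpha, kappa, rng)
    w = np.zeros(L, dtype=np.int64)
    for j in range(L):
        if m[j, j] > 0 and rho > 0:
            p = rho / (rho + beta[j] * (1.0 - rho))
            w[j] = rng.binomial(m[j, j], p)
    mbar = m.copy()
    np.fill_diagonal(mbar, np.diagonal(m) - w)

    new_beta = _dirichlet(gamma / L + mbar.sum(axis=0), rng) if resample_beta \
        else beta.copy()
    pi = np.empty((L, L))
    for j in range(L):
        conc = alpha * new_beta + n[j].astype(float)
        conc[j] += kappa
        pi[j] = _dirichlet(conc, rng)
    return TransitionDraw(beta=new_beta, pi=pi, m=m, w=w, n=n)


def sample_mode_params(r_path, modes, prior: MNIWPrior, L, psi=None,
                       obs: Optional[ObservationModel] = None,
                       seed=None, rng=None):
    """Conjugate MNIW draws of each mode's (mu, F, Sigma) and the shared R.

    Modes with no assigned transitions are refreshed from the base
    measure (the conjugate update with empty data).  R is drawn from the
    inverse-Wishart conditional on the pooled residuals psi - H r when
    (psi, obs) are given, otherwise from its prior.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    r_path = np.asarray(r_path, dtype=float)
    modes = np.asarray(modes)
    d = prior.d
    T = r_path.shape[0]
    X_all = np.hstack([r_path[:-1], np.ones((T - 1, 1))])
    Y_all = r_path[1:]
    V0_inv = np.linalg.inv(prior.V0)
    M0V0i = prior.M0 @ V0_inv

    thetas = []
    step_modes = modes[:-1]
    for k in range(L):
        sel = step_modes == k
        X = X_all[sel]
        Y = Y_all[sel]
        nk = X.shape[0]
        Vn_inv = V0_inv + X.T @ X
        Vn = np.linalg.inv(Vn_inv)
        Mn = (M0V0i + Y.T @ X) @ Vn
        Psin = prior.Psi0 + Y.T @ Y + prior.M0 @ M0V0i.T - Mn @ Vn_inv @ Mn.T
        Psin = 0.5 * (Psin + Psin.T) + 1e-12 * np.eye(d)
        Sigma = inv_wishart_rvs(prior.nu0 + nk, Psin, rng)
        Ls = np.linalg.cholesky(0.5 * (Sigma + Sigma.T) + 1e-14 * np.eye(d))
        Lv = np.linalg.cholesky(0.5 * (Vn + Vn.T) + 1e-14 * np.eye(d + 1))
        A = Mn + Ls @ rng.standard_normal((d, d + 1)) @ Lv.T
        thetas.append((A[:, :d], A[:, d], 0.5 * (Sigma + Sigma.T)))

    if psi is not None and obs is not None:
        resid = np.asarray(psi, dtype=float) - r_path @ obs.H.T
        Psi = prior.Psi_R + resid.T @ resid
        R = inv_wishart_rvs(prior.nu_R + resid.shape[0], 0.5 * (Psi + Psi.T), rng)
    else:
        R = inv_wishart_rvs(prior.nu_R, prior.Psi_R, rng)
    return thetas, 0.5 * (R + R.T)


def sample_hyperparameters(draw: TransitionDraw, cfg: HDPHyperConfig,
                           seed=None, rng=None):
    """Auxiliary-variable Gibbs updates of gamma, (alpha+kappa) and rho.

    (alpha+kappa): per-row Beta/Bernoulli augmentation with the row totals
    n_j. and table totals m_j. .  gamma: Escobar-West augmentation with the
    top-level "data" = mbar table counts.  rho: Beta conditional from the
    override counts w.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_rows = draw.n.sum(axis=1).astype(float)
    m_rows = draw.m.sum(axis=1).astype(float)
    m_total = float(draw.m.sum())
    w_total = float(draw.w.sum())

    # --- alpha + kappa
    ak = cfg.a_ak / cfg.b_ak
    for _ in range(20):
        shape = cfg.a_ak + m_total
        rate = cfg.b_ak
        for j in np.flatnonzero(n_rows > 0):
            r_j = rng.beta(ak + 1.0, n_rows[j])
            s_j = rng.random() < n_rows[j] / (n_rows[j] + ak)
            shape -= float(s_j)
            rate -= np.log(max(r_j, 1e-300))
        ak = rng.gamma(max(shape, 1e-8)) / rate
    alpha_plus_kappa = ak

    # --- gamma (top-level concentration)
    mbar = draw.m.copy()
    np.fill_diagonal(mbar, np.diagonal(draw.m) - draw.w)
    mbar_total = float(mbar.sum())
    Kbar = int((mbar.sum(axis=0) > 0).sum())
    gamma = cfg.a_gamma / cfg.b_gamma
    if mbar_total > 0 and Kbar > 0:
        for _ in range(20):
            eta = rng.beta(gamma + 1.0, mbar_total)
            b_post = cfg.b_gamma - np.log(max(eta, 1e-300))
            pi_mix = (cfg.a_gamma + Kbar - 1) / (
                cfg.a_gamma + Kbar - 1 + mbar_total * b_post)
            shape = cfg.a_gamma + Kbar if rng.random() < pi_mix \
                else cfg.a_gamma + Kbar - 1
            gamma = rng.gamma(max(shape, 1e-8)) / b_post
    else:
        gamma = rng.gamma(cfg.a_gamma) / cfg.b_gamma

    # --- rho
    rho = rng.beta(cfg.c_rho + w_total, cfg.d_rho + m_total - w_total)
    return float(gamma), float(alpha_plus_kappa), float(min(max(rho, 1e-12), 1 - 1e-12))


# ---------------------------------------------------------------------------
# full sweep driver


def _diffuse_init(psi, obs: ObservationModel):
    """Diffuse initialization: lift the first measurement, broad covariance."""
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    Hp = np.linalg.pinv(obs.H)
    m0 = Hp @ psi[0]
    scale = float(np.mean(np.var(psi, axis=0))) + 1e-12
    P0 = 1e3 * scale * np.eye(obs.d)
    return m0, P0


def run_mcmc(psi, obs: ObservationModel, cfg: HDPHyperConfig, dt: float,
             keep_paths: bool = False) -> Chain:
    """Run the blocked Gibbs sampler on one trajectory of measurements.

    Sweep order: (r_path | modes) -> (modes | r_path) -> theta, R ->
    (beta, pi) -> hyperparameters.  Fully reproducible from cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    T = psi.shape[0]
    L = cfg.L
    prior = cfg.base_measure
    d = prior.d

    # initialization: one occupied mode, parameters at prior means
    modes = np.zeros(T, dtype=np.int64)
    beta = np.full(L, 1.0 / L)
    gamma = cfg.a_gamma / cfg.b_gamma
    ak = cfg.a_ak / cfg.b_ak
    rho = cfg.c_rho / (cfg.c_rho + cfg.d_rho)
    alpha = (1 - rho) * ak
    kappa = rho * ak
    pi = np.tile(alpha * beta / ak, (L, 1))
    np.fill_diagonal(pi, pi.diagonal() + kappa / ak)
    pi /= pi.sum(axis=1, keepdims=True)
    # all modes start at the prior mean, so the first label sweep scatters
    # steps across modes (the modes are likelihood-identical); this is the
    # exploration phase — duplicate modes created here merge away over the
    # chain because a wholesale relabeling is a single FFBS move
    mus = np.tile(prior.M0[:, d], (L, 1))
    Fs = np.tile(prior.M0[:, :d], (L, 1, 1))
    Sigmas = np.tile(prior.mean_Sigma, (L, 1, 1))
    R = prior.mean_R.copy()
    m0, P0 = _diffuse_init(psi, obs)
    H = obs.H

    samples = []
    for sweep in range(cfg.n_sweeps):
        try:
            normals = rng.standard_normal((T, d))
            r_path, ll = _kernels.ffbs_path(psi, modes, mus, Fs, Sigmas,
                                            H, R, m0, P0, normals)
            if not np.all(np.isfinite(r_path)):
                raise FloatingPointError("non-finite sampled path")
            modes = sample_mode_sequence(r_path, (mus, Fs, Sigmas), pi, rng=rng)
            thetas, R = sample_mode_params(r_path, modes, prior, L,
                                           psi=psi, obs=obs, rng=rng)
            Fs = np.array([t[0] for t in thetas])
            mus = np.array([t[1] for t in thetas])
            Sigmas = np.array([t[2] for t in thetas])
            tdraw = sample_transition_params(modes, beta, gamma, ak, rho, rng=rng, L=L)
            beta, pi = tdraw.beta, tdraw.pi
            gamma, ak, rho = sample_hyperparameters(tdraw, cfg, rng=rng)
        except Exception as e:
            raise RuntimeError(f"sampler failure at sweep {sweep}: {e}") from e
        with np.errstate(divide="ignore"):
            mode_ll = float(np.log(pi[modes[:-1], modes[1:]]).sum())
        samples.append(PosteriorSample(
            modes=modes.copy(), beta=beta.copy(), pi=pi.copy(),
            mus=mus.copy(), Fs=Fs.copy(), Sigmas=Sigmas.copy(), R=R.copy(),
            gamma=gamma, alpha_plus_kappa=ak, rho=rho,
            r_path=r_path if keep_paths else np.empty((0, d)),
            joint_loglik=ll + mode_ll,
        ))
        if sweep % 500 == 0:
            logger.debug("sweep %d: loglik %.2f, %d active modes",
                         sweep, ll, np.unique(modes).size)
    return Chain(samples=samples, cfg=cfg, dt=dt)


# ---------------------------------------------------------------------------
# point estimation


def _align_to_reference(ref, labels, L):
    """Permutation of `labels` maximizing agreement with `ref` (Hungarian)."""
    agree = np.zeros((L, L))
    np.add.at(agree, (labels, ref), 1)
    row, col = linear_sum_assignment(-agree)
    perm = np.arange(L)
    perm[row] = col
    return perm


def point_estimate(chain: Chain, burn_in: Optional[int] = None) -> SegmentationEstimate:
    """Per-time modal label of the post-burn-in marginal, after aligning
    every sweep's arbitrary labels to the final sweep's by optimal
    assignment."""
    if burn_in is None:
        burn_in = chain.cfg.effective_burn_in
    post = chain.samples[burn_in:]
    if len(post) < 2:
        raise ValueError("need at least 2 post-burn-in sweeps")
    L = chain.cfg.L
    ref = post[-1].modes
    T = ref.size
    counts = np.zeros((T, L))
    t_idx = np.arange(T)
    for s in post:
        perm = _align_to_reference(ref, s.modes, L)
        counts[t_idx, perm[s.modes]] += 1
    marginals = counts / counts.sum(axis=1, keepdims=True)
    labels = np.argmax(marginals, axis=1)
    return SegmentationEstimate(labels=labels, marginals=marginals)
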