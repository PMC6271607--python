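"""Numba kernels for the Gibbs sweep hot loops.

Small fixed-dimension (d <= 3) linear algebra is hand-rolled so a full
sweep over a 1000-step trajectory costs ~1 ms instead of the tens of ms a
generic BLAS-dispatched implementation takes.  Correctness of both kernels
is pinned against the plain numpy implementations in :mod:`hdpslds.kalman`
by the test suite.

All randomness enters through pre-drawn arrays (standard normals /
uniforms) generated by the caller's Generator, keeping runs reproducible.
"""

import numpy as np
from numba import njit

_NOPT = dict(cache=True)


@njit(**_NOPT)
def _chol(A, L):
    """Lower Cholesky of PSD A (d x d) into L; tiny jitter on failure-prone pivots."""
    d = A.shape[0]
    for i in range(d):
        for j in range(d):
            L[i, j] = 0.0
    for j in range(d):
        s = A[j, j]
        for k in range(j):
            s -= L[j, k] * L[j, k]
        if s < 1e-300:
            s = 1e-300
        L[j, j] = np.sqrt(s)
        for i in range(j + 1, d):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            L[i, j] = s / L[j, j]


@njit(**_NOPT)
def _chol_solve_vec(L, b, x):
    """Solve (L L^T) x = b."""
    d = L.shape[0]
    for i in range(d):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(d - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, d):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]


@njit(**_NOPT)
def _chol_solve_mat(L, B, X):
    """Solve (L L^T) X = B for matrix B (d x m)."""
    d, m = B.shape
    for c in range(m):
        for i in range(d):
            s = B[i, c]
            for k in range(i):
                s -= L[i, k] * X[k, c]
            X[i, c] = s / L[i, i]
        for i in range(d - 1, -1, -1):
            s = X[i, c]
            for k in range(i + 1, d):
                s -= L[k, i] * X[k, c]
            X[i, c] = s / L[i, i]


@njit(**_NOPT)
def _mm(A, B, out):
    n, k = A.shape
    m = B.shape[1]
    for i in range(n):
        for j in range(m):
            s = 0.0
            for l in range(k):
                s += A[i, l] * B[l, j]
            out[i, j] = s


@njit(**_NOPT)
def _mmT(A, B, out):
    """out = A @ B.T"""
    n, k = A.shape
    m = B.shape[0]
    for i in range(n):
        for j in range(m):
            s = 0.0
            for l in range(k):
                s += A[i, l] * B[j, l]
            out[i, j] = s


@njit(**_NOPT)
def _mv(A, b, out):
    n, k = A.shape
    for i in range(n):
        s = 0.0
        for l in range(k):
            s += A[i, l] * b[l]
        out[i] = s


@njit(**_NOPT)
def ffbs_path(psi, labels, mus, Fs, Sigmas, H, R, m0, P0, normals):
    """Simulation smoother with per-step mode-indexed parameters.

    Transition i -> i+1 uses mode ``labels[i]``.  Returns (x, loglik) where
    x is one exact draw of the latent path and loglik the filter
    log-likelihood of psi under the mode sequence.
    """
    T = psi.shape[0]
    dobs = psi.shape[1]
    d = m0.shape[0]
    jit = 1e-9

    fm = np.empty((T, d))
    fP = np.empty((T, d, d))
    pm = np.empty((T, d))
    pP = np.empty((T, d, d))

    m = m0.copy()
    P = P0.copy()
    S = np.empty((dobs, dobs))
    Ls = np.empty((dobs, dobs))
    v = np.empty(dobs)
    z = np.empty(dobs)
    PHt = np.empty((d, dobs))
    K = np.empty((d, dobs))
    KH = np.empty((d, d))
    tmp_dd = np.empty((d, d))
    tmp_dd2 = np.empty((d, d))
    Kt = np.empty((dobs, d))
    Kt2 = np.empty((dobs, d))
    KR = np.empty((d, dobs))
    v9 = np.empty(d)
    loglik = 0.0
    log2pi = np.log(2.0 * np.pi)

    for i in range(T):
        if i > 0:
            k = labels[i - 1]
            # predict: m = mu + F m ; P = F P F^T + Sigma
            _mv(Fs[k], m, v9)
            for a in range(d):
                m[a] = mus[k, a] + v9[a]
            _mm(Fs[k], P, tmp_dd)
            _mmT(tmp_dd, Fs[k], tmp_dd2)
            for a in range(d):
                for b in range(d):
                    P[a, b] = 0.5 * (tmp_dd2[a, b] + tmp_dd2[b, a]) + Sigmas[k, a, b]
        for a in range(d):
            pm[i, a] = m[a]
            for b in range(d):
                pP[i, a, b] = P[a, b]
        # innovation
        for a in range(dobs):
            s = 0.0
            for b in range(d):
                s += H[a, b] * m[b]
            v[a] = psi[i, a] - s
        # PHt = P H^T ; S = H PHt + R
        _mmT(P, H, PHt)
        for a in range(dobs):
            for b in range(dobs):
                s = R[a, b]
                for l in range(d):
                    s += H[a, l] * PHt[l, b]
                S[a, b] = s
            S[a, a] += 1e-12 * (1.0 + S[a, a])
        _chol(S, Ls)
        # loglik contribution
        for a in range(dobs):
            s = v[a]
            for k2 in range(a):
                s -= Ls[a, k2] * z[k2]
            z[a] = s / Ls[a, a]
        quad = 0.0
        ldet = 0.0
        for a in range(dobs):
            quad += z[a] * z[a]
            ldet += np.log(Ls[a, a])
        loglik += -0.5 * (dobs * log2pi + quad) - ldet
        # K = PHt S^{-1}  (solve S K^T = PHt^T)
        for a in range(dobs):
            for b in range(d):
                Kt[a, b] = PHt[b, a]
        _chol_solve_mat(Ls, Kt, Kt2)
        for a in range(d):
            for b in range(dobs):
                K[a, b] = Kt2[b, a]
        # m += K v ; P = (I-KH) P (I-KH)^T + K R K^T (Joseph)
        for a in range(d):
            s = 0.0
            for b in range(dobs):
                s += K[a, b] * v[b]
            m[a] += s
        _mm(K, H, KH)
        for a in range(d):
            for b in range(d):
                tmp_dd[a, b] = (1.0 if a == b else 0.0) - KH[a, b]
        _mm(tmp_dd, P, tmp_dd2)
        _mmT(tmp_dd2, tmp_dd, P)
        # + K R K^T, with out-of-place symmetrization (in-place would read
        # already-overwritten entries)
        _mm(K, R, KR)
        _mmT(KR, K, tmp_dd2)
        for a in range(d):
            for b in range(d):
                tmp_dd[a, b] = 0.5 * (P[a, b] + P[b, a]) \
                    + 0.5 * (tmp_dd2[a, b] + tmp_dd2[b, a])
        for a in range(d):
            for b in range(d):
                P[a, b] = tmp_dd[a, b]
        for a in range(d):
            fm[i, a] = m[a]
            for b in range(d):
                fP[i, a, b] = P[a, b]

    # backward sampling
    x = np.empty((T, d))
    Lc = np.empty((d, d))
    C = np.empty((d, d))
    _chol(fP[T - 1] + jit * np.eye(d), Lc)
    for a in range(d):
        s = fm[T - 1, a]
        for b in range(a + 1):
            s += Lc[a, b] * normals[T - 1, b]
        x[T - 1, a] = s
    J = np.empty((d, d))
    Jt = np.empty((d, d))
    FP = np.empty((d, d))
    Lp = np.empty((d, d))
    mean = np.empty(d)
    for i in range(T - 2, -1, -1):
        k = labels[i]
        # J = fP[i] F^T pP[i+1]^{-1}
        _mm(Fs[k], fP[i], FP)          # FP = F fP[i]  (so J^T = pP^{-1} FP)
        for a in range(d):
            for b in range(d):
                C[a, b] = pP[i + 1, a, b]
            C[a, a] += jit
        _chol(C, Lp)
        _chol_solve_mat(Lp, FP, Jt)
        for a in range(d):
            for b in range(d):
                J[a, b] = Jt[b, a]
        # mean = fm[i] + J (x[i+1] - pm[i+1]); C = fP[i] - J pP[i+1] J^T
        for a in range(d):
            s = fm[i, a]
            for b in range(d):
                s += J[a, b] * (x[i + 1, b] - pm[i + 1, b])
            mean[a] = s
        _mm(J, pP[i + 1], tmp_dd)
        _mmT(tmp_dd, J, tmp_dd2)
        for a in range(d):
            for b in range(d):
                C[a, b] = 0.5 * (fP[i, a, b] + fP[i, b, a]) \
                    - 0.5 * (tmp_dd2[a, b] + tmp_dd2[b, a])
            C[a, a] += jit
        _chol(C, Lc)
        for a in range(d):
            s = mean[a]
            for b in range(a + 1):
                s += Lc[a, b] * normals[i, b]
            x[i, a] = s
    return x, loglik


@njit(**_NOPT)
def mode_emission_logliks(x, mus, Fs, Sig_chols):
    """Log N(x_{i+1}; mu_k + F_k x_i, Sigma_k) for i = 0..T-2, k = 0..L-1."""
    T, d = x.shape
    L = mus.shape[0]
    out = np.empty((T - 1, L))
    resid = np.empty(d)
    z = np.empty(d)
    log2pi = np.log(2.0 * np.pi)
    for k in range(L):
        ldet = 0.0
        for a in range(d):
            ldet += np.log(Sig_chols[k, a, a])
        for i in range(T - 1):
            for a in range(d):
                s = x[i + 1, a] - mus[k, a]
                for b in range(d):
                    s -= Fs[k, a, b] * x[i, b]
                resid[a] = s
            for a in range(d):
                s = resid[a]
                for b in range(a):
                    s -= Sig_chols[k, a, b] * z[b]
                z[a] = s / Sig_chols[k, a, a]
            quad = 0.0
            for a in range(d):
                quad += z[a] * z[a]
            out[i, k] = -0.5 * (d * log2pi + quad) - ldet
    return out


@njit(**_NOPT)
def ffbs_modes(em, Pi, uniforms):
    """Forward-filter backward-sample the mode chain.

    em : (T-1, L) emission log-likelihoods (mode at step i emits transition
         i -> i+1; the final label has no emission).
    Pi : (L, L) transition matrix.
    uniforms : (T,) uniform variates for the backward draws.
    Returns labels (T,) in 0..L-1.  Initial label prior is uniform.
    """
    Tm1, L = em.shape
    T = Tm1 + 1
    alpha = np.empty((T, L))
    lik = np.empty(L)
    # i = 0: uniform prior times emission of step 0
    mx = em[0, 0]
    for k in range(1, L):
        if em[0, k] > mx:
            mx = em[0, k]
    s = 0.0
    for k in range(L):
        alpha[0, k] = np.exp(em[0, k] - mx)
        s += alpha[0, k]
    for k in range(L):
        alpha[0, k] /= s
    for i in range(1, T):
        if i < Tm1:
            mx = em[i, 0]
            for k in range(1, L):
                if em[i, k] > mx:
                    mx = em[i, k]
            for k in range(L):
                lik[k] = np.exp(em[i, k] - mx)
        else:
            for k in range(L):
                lik[k] = 1.0
        s = 0.0
        for k in range(L):
            a = 0.0
            for j in range(L):
                a += alpha[i - 1, j] * Pi[j, k]
            alpha[i, k] = a * lik[k]
            s += alpha[i, k]
        if s <= 0.0:
            for k in range(L):
                alpha[i, k] = 1.0 / L
        else:
            for k in range(L):
                alpha[i, k] /= s

    labels = np.empty(T, dtype=np.int64)
    # draw s_{T-1}
    u = uniforms[T - 1]
    c = 0.0
    lab = L - 1
    for k in range(L):
        c += alpha[T - 1, k]
        if u <= c:
            lab = k
            break
    labels[T - 1] = lab
    for i in range(T - 2, -1, -1):
        nxt = labels[i + 1]
        s = 0.0
        for k in range(L):
            lik[k] = alpha[i, k] * Pi[k, nxt]
            s += lik[k]
        u = uniforms[i] * s
        c = 0.0
        lab = L - 1
        for k in range(L):
            c += lik[k]
            if u <= c:
                lab = k
                break
        labels[i] = lab
    return labels
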