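"""Vectorised single-marker logistic fits.

The association scan and the expansion sweep of the independence screen
both fit one logistic model per marker, where every model shares a common
base design (intercept + covariates [+ already-accepted markers]) and
differs only in the single appended marker column.  Fitting those models
one by one through the scalar IRLS would be dominated by Python overhead,
so this module runs the same IRLS (with per-marker step-halving) across
all markers at once with batched linear algebra.

Also provides the vectorised Rao score test used by the stepwise forward
sweep: the score statistic for adding each candidate column needs only
the current fit, not a refit per candidate.
"""

from __future__ import annotations

import numpy as np

SEPARATION_CAP = 15.0


def batched_marker_fits(
    X_base: np.ndarray,
    D: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = 50,
    tol: float = 1e-10,
    chunk: int = 2048,
):
    """Fit ``logit(y) ~ X_base + d_m`` for every column ``d_m`` of ``D``.

    Returns arrays over markers: marker coefficient ``beta``, its standard
    error ``se``, model ``deviance``, and a boolean ``converged``.
    Monomorphic (zero-variance) columns come back as NaN beta/se with
    deviance equal to the base-model deviance.
    """
    y = np.asarray(y, dtype=float).ravel()
    n, k = X_base.shape
    M = D.shape[1]
    beta_out = np.full(M, np.nan)
    se_out = np.full(M, np.nan)
    dev_out = np.full(M, np.nan)
    conv_out = np.zeros(M, dtype=bool)

    mono = D.std(axis=0) == 0.0
    cols = np.flatnonzero(~mono)
    for lo in range(0, cols.size, chunk):
        idx = cols[lo : lo + chunk]
        b, s, d, c = _fit_chunk(X_base, D[:, idx], y, max_iter, tol)
        beta_out[idx] = b
        se_out[idx] = s
        dev_out[idx] = d
        conv_out[idx] = c
    if mono.any():
        from .glm_core import fit_logistic

        base_dev = fit_logistic(X_base, y, check_rank=False).deviance
        dev_out[mono] = base_dev
    return beta_out, se_out, dev_out, conv_out


def _fit_chunk(X, D, y, max_iter, tol):
    n, k = X.shape
    m = D.shape[1]
    p = k + 1
    B = np.zeros((m, p))  # [base coefs..., marker coef]
    eta = np.zeros((n, m))
    mu = np.full((n, m), 0.5)
    dev = _dev(y, mu)
    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        a = np.flatnonzero(active)
        w = mu[:, a] * (1.0 - mu[:, a])
        w = np.maximum(w, 1e-12)
        d_a = D[:, a]
        # per-marker information matrix in block form
        # A = X' W X  (m,k,k);  b = X' W d  (m,k);  c = d' W d  (m,)
        A = np.einsum("nm,nj,nl->mjl", w, X, X, optimize=True)
        bv = np.einsum("nm,nj,nm->mj", w, X, d_a, optimize=True)
        cv = np.einsum("nm,nm->m", w, d_a * d_a)
        H = np.empty((a.size, p, p))
        H[:, :k, :k] = A
        H[:, :k, k] = bv
        H[:, k, :k] = bv
        H[:, k, k] = cv
        r = (y[:, None] - mu[:, a])
        g = np.empty((a.size, p))
        g[:, :k] = (X.T @ r).T
        g[:, k] = np.einsum("nm,nm->m", d_a, r)
        try:
            step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(H[i], g[i], rcond=None)[0] for i in range(a.size)]
            )

        scale = np.ones(a.size)
        B_a = B[a]
        dev_a = dev[a]
        for _ in range(30):
            B_try = B_a + scale[:, None] * step
            eta_try = X @ B_try[:, :k].T + d_a * B_try[:, k]
            mu_try = 1.0 / (1.0 + np.exp(-eta_try))
            dev_try = _dev(y, mu_try)
            bad = dev_try > dev_a + 1e-12
            if not bad.any():
                break
            scale[bad] *= 0.5
        delta = dev_a - dev_try
        B[a] = B_try
        mu[:, a] = mu_try
        dev[a] = dev_try
        done = np.abs(delta) < tol * (np.abs(dev_try) + 0.1)
        converged[a[done]] = True
        active[a[done]] = False

    sep = np.abs(B).max(axis=1) > SEPARATION_CAP
    if sep.any():
        # rescale the whole coefficient vector to the ±cap boundary rather
        # than clipping components (which would wreck the fitted surface)
        scale_b = SEPARATION_CAP / np.abs(B[sep]).max(axis=1)
        B[sep] *= scale_b[:, None]
        eta_s = X @ B[sep, :k].T + D[:, sep] * B[sep, k]
        mu[:, sep] = 1.0 / (1.0 + np.exp(-eta_s))
        dev[sep] = _dev(y, mu[:, sep])
        converged[sep] = False

    # SE of the marker coefficient from the inverse information
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    se = np.empty(m)
    for lo in range(0, m, 4096):
        hi = min(lo + 4096, m)
        w_c = w[:, lo:hi]
        d_c = D[:, lo:hi]
        A = np.einsum("nm,nj,nl->mjl", w_c, X, X, optimize=True)
        bv = np.einsum("nm,nj,nm->mj", w_c, X, d_c, optimize=True)
        cv = np.einsum("nm,nm->m", w_c, d_c * d_c)
        # Schur complement of the base block gives Var(beta_marker)^{-1}
        sol = np.linalg.solve(A, bv[:, :, None])[:, :, 0]
        schur = cv - np.einsum("mj,mj->m", bv, sol)
        se[lo:hi] = np.sqrt(1.0 / np.maximum(schur, 1e-300))
    return B[:, k], se, dev, converged


def _dev(y, mu):
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    if mu.ndim == 1:
        return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    yv = y[:, None]
    return -2.0 * np.sum(yv * np.log(mu) + (1 - yv) * np.log1p(-mu), axis=0)


def score_test_candidates(fit_mu: np.ndarray, X: np.ndarray, D: np.ndarray, y: np.ndarray):
    """Rao score chi-square (1 df) for adding each column of ``D`` to a
    fitted model with design ``X`` and fitted probabilities ``fit_mu``.

    Returns the vector of score statistics; the test needs no refits.
    """
    y = np.asarray(y, dtype=float).ravel()
    w = np.maximum(fit_mu * (1.0 - fit_mu), 1e-12)
    r = y - fit_mu
    U = D.T @ r
    XtWX = (X.T * w) @ X
    C = X.T @ (w[:, None] * D)  # (p, M)
    sol = np.linalg.solve(XtWX, C)
    V = np.einsum("nm,nm->m", D * w[:, None], D) - np.einsum("pm,pm->m", C, sol)
    V = np.maximum(V, 1e-300)
    return U * U / V
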