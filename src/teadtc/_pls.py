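"""Compact SIMPLS engine used inside the wavelength selectors.

The selectors (UVE, CARS) need the full coefficient path over latent-variable
counts 1..A from every cross-validation fold; SIMPLS yields the whole path in
one deflation pass, which keeps leave-one-out loops affordable.  For a single
response SIMPLS and NIPALS coefficients coincide, so the final PLSR models
(sklearn's ``PLSRegression``) double as an independent cross-check in tests.

All fits mean-centre X and y and do not scale columns to unit variance —
standard chemometric practice for spectra on a common reflectance scale.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simpls_paths", "pls_fit", "cross_val_pls", "loo_splits", "kfold_splits"]

_EPS = 1e-12


def simpls_paths(X: np.ndarray, y: np.ndarray, n_components: int):
    """Coefficient paths for 1..A latent variables.

    Returns ``(B, b0)``: ``B`` is (p, A) where column a-1 holds the regression
    vector using a components, ``b0`` the matching intercepts (length A).  A is
    capped at min(n_components, p, n-1) and may shrink further if X deflates to
    numerical zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    A = max(1, min(n_components, p, n - 1))
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    S = Xc.T @ yc
    R = np.zeros((p, A))
    Q = np.zeros(A)
    V = np.zeros((p, A))
    achieved = 0
    for a in range(A):
        r = S.copy()
        t = Xc @ r
        t_norm = np.linalg.norm(t)
        if t_norm < _EPS:
            break
        t /= t_norm
        r /= t_norm
        loadings = Xc.T @ t
        q = yc @ t
        v = loadings.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ loadings)
        v_norm = np.linalg.norm(v)
        if v_norm < _EPS:
            break
        v /= v_norm
        S -= v * (v @ S)
        R[:, a], Q[a], V[:, a] = r, q, v
        achieved = a + 1
    if achieved == 0:
        # y is orthogonal to X (e.g. constant y): coefficient 0, intercept mean
        B = np.zeros((p, 1))
        return B, np.array([y_mean])
    B = np.cumsum(R[:, :achieved] * Q[:achieved], axis=1)
    b0 = y_mean - x_mean @ B
    return B, b0


def pls_fit(X, y, n_components: int):
    """Single-fit coefficients ``(b, b0)`` at exactly ``n_components`` (capped)."""
    B, b0 = simpls_paths(X, y, n_components)
    return B[:, -1], b0[-1]


def loo_splits(n: int):
    idx = np.arange(n)
    return [(np.delete(idx, i), idx[i : i + 1]) for i in range(n)]


def kfold_splits(n: int, k: int, rng: np.random.Generator | None = None):
    if k < 2:
        raise ValueError("k-fold needs k >= 2")
    idx = np.arange(n) if rng is None else rng.permutation(n)
    folds = np.array_split(idx, k)
    return [
        (np.concatenate([f for j, f in enumerate(folds) if j != i]), folds[i])
        for i in range(k)
    ]


def cross_val_pls(X, y, max_components: int, splits, collect_coefs: bool = False):
    """Cross-validated RMSE over the latent-variable path.

    Returns ``(rmse, coefs)``: ``rmse[a-1]`` is the pooled CV RMSE using a
    components; ``coefs`` is (n_folds, p, A) of per-fold coefficient paths when
    requested, else None.  Folds whose deflation stops early repeat their last
    achieved column so the path stays rectangular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    A = max(1, min(max_components, p, n - max(len(te) for _, te in splits) - 1))
    sq_err = np.zeros(A)
    count = 0
    coefs = np.zeros((len(splits), p, A)) if collect_coefs else None
    for f, (tr, te) in enumerate(splits):
        B, b0 = simpls_paths(X[tr], y[tr], A)
        achieved = B.shape[1]
        if achieved < A:  # pad with the last achieved component
            B = np.hstack([B, np.repeat(B[:, -1:], A - achieved, axis=1)])
            b0 = np.concatenate([b0, np.repeat(b0[-1:], A - achieved)])
        pred = X[te] @ B + b0  # (n_te, A)
        sq_err += ((pred - y[te][:, None]) ** 2).sum(axis=0)
        count += len(te)
        if collect_coefs:
            coefs[f] = B
    rmse = np.sqrt(sq_err / count)
    return rmse, coefs
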