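"""Characteristic-wavelength selection: UVE, CARS and SPA, implemented from scratch.

All three reduce a samples x bands matrix to the informative bands for a
scalar response (here the drought tolerance coefficient):

* **UVE** (uninformative variable elimination) appends artificial noise
  variables, collects PLS coefficient vectors over leave-one-out folds, and
  keeps real bands whose coefficient stability ``mean/sd`` beats the best
  stability any noise variable achieves.
* **CARS** (competitive adaptive reweighted sampling) runs Monte-Carlo PLS
  fits while an exponentially decreasing function shrinks the retained band
  pool — forced removal to the top coefficients, then weighted resampling —
  and returns the pool with the lowest cross-validated RMSE.
* **SPA** (successive projections algorithm) grows chains of maximally
  orthogonal bands by repeated projection onto the orthogonal complement of
  the chosen span, scoring every chain prefix by held-out RMSE of a plain
  linear regression.

Selectors follow the sklearn feature-selector protocol (``fit`` sets
``support_``; ``transform`` subsets columns) and are deterministic under a
fixed ``random_state``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from ._pls import cross_val_pls, kfold_splits, loo_splits, pls_fit

__all__ = [
    "SelectionResult",
    "CVConfig",
    "UVESelector",
    "CARSSelector",
    "SPASelector",
    "uve_select",
    "cars_select",
    "spa_select",
]


@dataclass
class SelectionResult:
    """Outcome of one selector run: ordered band indices plus method diagnostics."""

    method: str
    selected: np.ndarray              # ordered band indices (0-based)
    wavelengths: np.ndarray | None    # nm of the selected bands, when an axis is known
    diagnostics: dict
    seed: int | None

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            if isinstance(v, list):
                return [_clean(x) for x in v]
            return v

        return {
            "method": self.method,
            "selected": self.selected.tolist(),
            "wavelengths": None if self.wavelengths is None else self.wavelengths.tolist(),
            "diagnostics": {k: _clean(v) for k, v in self.diagnostics.items()},
            "seed": self.seed,
        }


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings for the selectors' internal PLS engine."""

    scheme: str = "loo"              # "loo" | "kfold"
    k: int = 5
    max_latent_variables: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("loo", "kfold"):
            raise ValueError("scheme must be 'loo' or 'kfold'")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("k-fold needs k >= 2")
        if self.max_latent_variables < 1:
            raise ValueError("max_latent_variables must be >= 1")

    def splits(self, n: int, rng: np.random.Generator):
        if self.scheme == "loo":
            return loo_splits(n)
        return kfold_splits(n, min(self.k, n), rng)


def _validate_xy(X, y, min_n: int):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x bands)")
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    if X.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} samples")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 bands")
    return X, y


class _BandSelector(SelectorMixin, BaseEstimator):
    """Shared plumbing: support mask + SelectionResult exposure."""

    def _get_support_mask(self):
        return self.support_

    def _finalize(self, p: int, selected: np.ndarray, diagnostics: dict, seed):
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        self.n_features_in_ = p
        wl = getattr(self, "wavelengths", None)
        wl_sel = None if wl is None else np.asarray(wl, float)[selected]
        self.result_ = SelectionResult(self._method, np.asarray(selected), wl_sel,
                                       diagnostics, seed)
        return self


class UVESelector(_BandSelector):
    """Uninformative variable elimination with a same-size artificial-noise block.

    Parameters
    ----------
    cutoff_factor : multiple of the best noise-variable stability a real band
        must exceed; raising it never enlarges the selection.
    noise_scale : amplitude of the appended uniform noise block relative to the
        mean absolute magnitude of X (tiny by construction, so the noise block
        cannot perturb the fit — only its stability distribution matters).
    cv : :class:`CVConfig`; leave-one-out by default.
    """

    _method = "UVE"

    def __init__(
        self,
        cutoff_factor: float = 1.0,
        noise_scale: float = 1e-10,
        cv: CVConfig | None = None,
        wavelengths=None,
        random_state: int | None = 0,
    ):
        self.cutoff_factor = cutoff_factor
        self.noise_scale = noise_scale
        self.cv = cv
        self.wavelengths = wavelengths
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate_xy(X, y, min_n=5)
        n, p = X.shape
        cv = self.cv or CVConfig()
        rng = np.random.default_rng(self.random_state)
        magnitude = np.abs(X).mean()
        noise = rng.uniform(0.0, 1.0, size=(n, p)) * self.noise_scale * max(magnitude, 1e-300)
        Xa = np.hstack([X, noise])
        rmse, coefs = cross_val_pls(
            Xa, y, cv.max_latent_variables, cv.splits(n, rng), collect_coefs=True
        )
        a_star = int(np.argmin(rmse)) + 1
        C = coefs[:, :, a_star - 1]  # folds x 2p
        mean = C.mean(axis=0)
        sd = C.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            stability = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0),
                                 np.where(mean != 0, np.inf * np.sign(mean), 0.0))
        cutoff = self.cutoff_factor * np.max(np.abs(stability[p:]))
        keep = np.flatnonzero(np.abs(stability[:p]) > cutoff)
        if keep.size == 0:
            raise ValueError(
                "UVE eliminated every band; lower cutoff_factor to keep weaker bands"
            )
        self.stability_ = stability[:p]
        self.noise_stability_ = stability[p:]
        self.cutoff_ = float(cutoff)
        self.n_components_ = a_star
        diagnostics = {
            "stability": stability[:p],
            "noise_stability_max": float(np.max(np.abs(stability[p:]))),
            "cutoff": float(cutoff),
            "n_components": a_star,
            "cv_rmse_path": rmse,
        }
        return self._finalize(p, keep, diagnostics, self.random_state)


class CARSSelector(_BandSelector):
    """Competitive adaptive reweighted sampling.

    Per iteration i of ``n_runs``: a Monte-Carlo subset (``mc_fraction`` of the
    samples) fits PLS on the retained bands; the pool shrinks to the top
    ``ceil(r_i * p)`` bands by |coefficient| where ``r_i = a e^{-k i}`` runs
    from 1 down to 2/p; adaptive reweighted sampling (weighted draw with
    replacement, weight proportional to |coefficient|) thins the pool further; a
    5-fold RMSECV of the new pool is recorded.  The pool with minimal RMSECV
    wins.  The pool never drops below 2 bands (clamped, recorded).
    """

    _method = "CARS"

    def __init__(
        self,
        n_runs: int = 50,
        mc_fraction: float = 0.8,
        cv: CVConfig | None = None,
        wavelengths=None,
        random_state: int | None = 0,
    ):
        self.n_runs = n_runs
        self.mc_fraction = mc_fraction
        self.cv = cv
        self.wavelengths = wavelengths
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate_xy(X, y, min_n=10)
        n, p = X.shape
        cv = self.cv or CVConfig(scheme="kfold", k=5)
        rng = np.random.default_rng(self.random_state)
        N = self.n_runs
        if N < 2:
            raise ValueError("n_runs must be >= 2")
        # exponentially decreasing fraction: r_1 = 1, r_N = 2/p
        k_edf = np.log(p / 2.0) / (N - 1)
        r = np.exp(k_edf) * np.exp(-k_edf * np.arange(1, N + 1))
        n_mc = max(2, int(round(self.mc_fraction * n)))
        retained = np.arange(p)
        counts, rmsecv_trace, pools, lv_trace = [], [], [], []
        clamped = False
        for i in range(N):
            mc = rng.choice(n, size=n_mc, replace=False)
            a_cap = min(cv.max_latent_variables, retained.size, n_mc - 1)
            coef, _ = pls_fit(X[np.ix_(mc, retained)], y[mc], a_cap)
            weight = np.abs(coef)
            target = int(np.ceil(r[i] * p))
            target = max(2, min(target, retained.size))
            order = np.argsort(-weight, kind="stable")  # ties -> lower band index
            kept_local = order[:target]
            kept_weight = weight[kept_local]
            if kept_weight.sum() > 0:
                draw = rng.choice(
                    kept_local, size=target, replace=True, p=kept_weight / kept_weight.sum()
                )
                new_local = np.unique(draw)
            else:
                new_local = np.sort(kept_local)
            if new_local.size < 2:
                new_local = kept_local[:2]
                clamped = True
            retained = np.sort(retained[new_local])
            rmse, _ = cross_val_pls(
                X[:, retained], y, cv.max_latent_variables, kfold_splits(n, min(cv.k, n), rng)
            )
            counts.append(retained.size)
            rmsecv_trace.append(float(rmse.min()))
            lv_trace.append(int(np.argmin(rmse)) + 1)
            pools.append(retained.copy())
        best = int(np.argmin(rmsecv_trace))
        selected = pools[best]
        diagnostics = {
            "retained_counts": np.asarray(counts),
            "rmsecv": np.asarray(rmsecv_trace),
            "best_iteration": best,
            "n_components": lv_trace[best],
            "clamped": clamped,
        }
        return self._finalize(p, selected, diagnostics, self.random_state)


class SPASelector(_BandSelector):
    """Successive projections algorithm with exhaustive starting columns.

    From every starting band a chain grows by appending the unselected band of
    maximal residual norm after projection onto the orthogonal complement of
    the span already chosen (collinear bands therefore never co-occur).  Every
    (start, prefix-length) candidate subset is scored by the RMSE of an
    ordinary least-squares fit on a held-out validation fraction; the best
    subset wins, ties broken toward fewer bands then the lower starting index.
    """

    _method = "SPA"

    def __init__(
        self,
        max_vars: int = 30,
        val_fraction: float = 0.25,
        starts=None,
        wavelengths=None,
        random_state: int | None = 0,
    ):
        self.max_vars = max_vars
        self.val_fraction = val_fraction
        self.starts = starts  # restrict starting columns; None = all
        self.wavelengths = wavelengths
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate_xy(X, y, min_n=4)
        n, p = X.shape
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        rng = np.random.default_rng(self.random_state)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n)))
        val, tr = perm[:n_val], perm[n_val:]
        if tr.size < 2:
            raise ValueError("too few training samples after the validation split")
        max_vars = min(self.max_vars, tr.size - 1, p)
        if max_vars < 1:
            raise ValueError("max_vars must allow at least one band")
        Xtr, Xval = X[tr], X[val]
        ytr, yval = y[tr], y[val]
        col_norm0 = np.linalg.norm(Xtr, axis=0)
        tol = 1e-10 * max(col_norm0.max(), 1.0)

        def _val_rmse(cols):
            A = np.column_stack([np.ones(tr.size), Xtr[:, cols]])
            beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
            pred = np.column_stack([np.ones(val.size), Xval[:, cols]]) @ beta
            return float(np.sqrt(np.mean((pred - yval) ** 2)))

        best = None  # (rmse, k, start, chain)
        curves = {}
        start_pool = range(p) if self.starts is None else list(self.starts)
        for start in start_pool:
            if col_norm0[start] <= tol:
                continue
            residual = Xtr.copy()
            chain = [start]
            u = residual[:, start]
            residual = residual - np.outer(u, u @ residual) / (u @ u)
            rmses = [_val_rmse(chain)]
            while len(chain) < max_vars:
                norms = np.linalg.norm(residual, axis=0)
                norms[chain] = -1.0
                j = int(np.argmax(norms))  # ties -> lower band index
                if norms[j] <= tol:
                    break  # rank deficient: truncate the chain
                chain.append(j)
                u = residual[:, j]
                residual = residual - np.outer(u, u @ residual) / (u @ u)
                rmses.append(_val_rmse(chain))
            curves[start] = rmses
            for k, rmse in enumerate(rmses, start=1):
                key = (rmse, k, start)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (rmse, k, start, chain[:k])
        if best is None:
            raise ValueError("all columns are numerically zero; nothing to select")
        rmse, k, start, chain = best
        selected = np.asarray(chain)
        diagnostics = {
            "best_start": start,
            "projection_order": selected,
            "val_rmse": rmse,
            "rmse_curve_best_start": np.asarray(curves[start]),
            "effective_max_vars": max_vars,
        }
        return self._finalize(p, selected, diagnostics, self.random_state)


def _run(selector, X, y) -> SelectionResult:
    return selector.fit(X, y).result_


def uve_select(X, y, cv: CVConfig | None = None, cutoff_factor: float = 1.0,
               wavelengths=None, seed: int = 0) -> SelectionResult:
    return _run(UVESelector(cutoff_factor=cutoff_factor, cv=cv,
                            wavelengths=wavelengths, random_state=seed), X, y)


def cars_select(X, y, cv: CVConfig | None = None, n_runs: int = 50,
                mc_fraction: float = 0.8, wavelengths=None, seed: int = 0) -> SelectionResult:
    return _run(CARSSelector(n_runs=n_runs, mc_fraction=mc_fraction, cv=cv,
                             wavelengths=wavelengths, random_state=seed), X, y)


def spa_select(X, y, max_vars: int = 30, val_fraction: float = 0.25,
               wavelengths=None, seed: int = 0) -> SelectionResult:
    return _run(SPASelector(max_vars=max_vars, val_fraction=val_fraction,
                            wavelengths=wavelengths, random_state=seed), X, y)
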