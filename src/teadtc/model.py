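"""Train/test split, regression models, metrics and the evaluation grid.

The modeling stage regresses selected spectral bands against the drought
tolerance coefficient: a 3:1 random split, then PLSR / SVR (RBF) / random
forest with hyperparameters tuned by 5-fold cross-validation on the training
rows only, evaluated by R², RMSE and MAPE on both sets.  ``run_grid``
enumerates preprocessing-chain x band-selector x model combinations —
everything that touches held-out rows (the MSC reference, band selection,
tuning) is fitted on the training rows alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

from .preprocess import PreprocessChain
from .select import CARSSelector, CVConfig, SPASelector, UVESelector
from .spectra import SpectraMatrix

__all__ = [
    "SplitPlan",
    "ModelSpec",
    "EvalRecord",
    "Metrics",
    "split_train_test",
    "fit_model",
    "metrics",
    "run_grid",
    "select_best",
]


@dataclass(frozen=True)
class SplitPlan:
    train: np.ndarray
    test: np.ndarray
    ratio: tuple
    seed: int


def split_train_test(n: int, ratio: tuple = (3, 1), seed: int = 0) -> SplitPlan:
    """Uniformly random split; the first floor(n * a/(a+b)) permuted indices train."""
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ValueError("ratio parts must be positive")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(n * a / (a + b)))
    return SplitPlan(perm[:n_train], perm[n_train:], (a, b), seed)


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus (optionally) an explicit tuning grid overriding defaults."""

    family: str  # "plsr" | "svr" | "rf"
    grid: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("plsr", "svr", "rf"):
            raise ValueError("family must be 'plsr', 'svr' or 'rf'")


def _default_grid(family: str, X: np.ndarray) -> tuple:
    n, p = X.shape
    if family == "plsr":
        max_lv = max(1, min(15, p, n - 1))
        return PLSRegression(scale=False), {"n_components": list(range(1, max_lv + 1))}
    if family == "svr":
        var = X.var()
        gamma_scale = 1.0 / (p * var) if var > 0 else 1.0
        return (
            SVR(kernel="rbf", epsilon=0.01),
            {"C": [0.1, 1.0, 10.0, 100.0],
             "gamma": [gamma_scale * m for m in (0.1, 1.0, 10.0)]},
        )
    return (
        RandomForestRegressor(n_estimators=500),
        {"max_features": ["sqrt", 1.0 / 3.0]},
    )


def fit_model(spec: ModelSpec, X_train, y_train):
    """Fit one family with 5-fold inner-CV tuning on the training set only.

    Returns the fitted :class:`~sklearn.model_selection.GridSearchCV` (its
    ``predict`` maps a band matrix to responses; ``best_params_`` records the
    tuned hyperparameters).  Deterministic under a fixed ``spec.seed``.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X_train must be 2-D and match y_train in length")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: y has zero variance")
    estimator, grid = _default_grid(spec.family, X)
    if spec.family == "rf":
        estimator.set_params(random_state=spec.seed)
    if spec.grid is not None:
        grid = spec.grid
    n_folds = min(5, X.shape[0] // 2)
    search = GridSearchCV(
        estimator,
        grid,
        cv=KFold(n_splits=max(2, n_folds), shuffle=True, random_state=spec.seed),
        scoring="neg_root_mean_squared_error",
        refit=True,
        n_jobs=None,
    )
    search.fit(X, y)
    return search


class Metrics(NamedTuple):
    r2: float
    rmse: float
    mape_pct: float


def metrics(y_true, y_pred, r2_form: str = "standard") -> Metrics:
    """R², RMSE and MAPE (percent).

    ``r2_form='standard'`` uses 1 - SSres/SStot (can be negative on held-out
    data); ``'explained'`` uses the ratio sum(yhat - ybar)^2 / sum(y - ybar)^2,
    which coincides with the standard form only for in-sample least squares.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    yhat = np.asarray(y_pred, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("y_true and y_pred differ in length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if np.any(y == 0):
        raise ValueError("MAPE undefined: y_true contains zeros")
    sstot = ((y - y.mean()) ** 2).sum()
    if sstot == 0:
        raise ValueError("R^2 undefined: y_true has zero variance")
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    mape = float(100.0 * np.mean(np.abs((yhat - y) / y)))
    if r2_form == "standard":
        r2 = float(1.0 - ((y - yhat) ** 2).sum() / sstot)
    elif r2_form == "explained":
        r2 = float(((yhat - y.mean()) ** 2).sum() / sstot)
    else:
        raise ValueError("r2_form must be 'standard' or 'explained'")
    return Metrics(r2, rmse, mape)


@dataclass
class EvalRecord:
    """One chain x selector x model cell of the evaluation grid."""

    chain: str
    selector: str
    model: str
    n_bands: int
    train_r2: float = np.nan
    train_rmse: float = np.nan
    train_mape: float = np.nan
    test_r2: float = np.nan
    test_rmse: float = np.nan
    test_mape: float = np.nan
    seed: int = 0
    error: str | None = None
    details: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.error is None

    def to_dict(self) -> dict:
        d = {
            "chain": self.chain, "selector": self.selector, "model": self.model,
            "n_bands": self.n_bands,
            "train_r2": self.train_r2, "train_rmse": self.train_rmse,
            "train_mape_pct": self.train_mape,
            "test_r2": self.test_r2, "test_rmse": self.test_rmse,
            "test_mape_pct": self.test_mape,
            "seed": self.seed, "error": self.error,
        }
        return d


def _make_selector(name: str, seed: int, max_lv: int = 10):
    name = name.lower()
    if name == "none":
        return None
    if name == "uve":
        return UVESelector(cv=CVConfig(scheme="loo", max_latent_variables=max_lv),
                           random_state=seed)
    if name == "cars":
        return CARSSelector(cv=CVConfig(scheme="kfold", k=5, max_latent_variables=max_lv),
                            random_state=seed)
    if name == "spa":
        return SPASelector(random_state=seed)
    raise ValueError(f"unknown selector {name!r}; use none/uve/cars/spa")


def run_grid(
    spectra: SpectraMatrix,
    dtc: np.ndarray,
    chains,
    selectors,
    models,
    split: SplitPlan | None = None,
    seed: int = 0,
    selection_scope: str = "train",
) -> list:
    """Evaluate every chain x selector x model combination.

    ``chains`` are chain strings or :class:`PreprocessChain`; ``selectors`` are
    names (none/uve/cars/spa) or configured selector instances; ``models`` are
    family names or :class:`ModelSpec`.  Preprocessing references, band
    selection (unless ``selection_scope='all'``) and tuning see training rows
    only.  Failed combinations become records with ``error`` set; the returned
    list is sorted by descending test R², then ascending test RMSE and MAPE.
    """
    y = np.asarray(dtc, dtype=float).ravel()
    if y.size != spectra.n_samples:
        raise ValueError("response length does not match the spectra matrix")
    if not (chains and selectors and models):
        raise ValueError("chains, selectors and models must be non-empty")
    if split is None:
        split = split_train_test(spectra.n_samples, (3, 1), seed)
    tr, te = split.train, split.test

    ss = np.random.SeedSequence(seed)
    child_seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(
        len(chains) * len(selectors) + len(chains) * len(selectors) * len(models)
    ))

    records = []
    for chain_spec in chains:
        chain = (PreprocessChain.parse(chain_spec)
                 if isinstance(chain_spec, str) else chain_spec)
        chain.fit(spectra.values[tr], wavelengths=spectra.wavelengths)
        Xtr = chain.transform(spectra.values[tr])
        Xte = chain.transform(spectra.values[te])
        wl_out = chain.wavelengths_out_
        for selector_spec in selectors:
            sel_seed = int(next(child_seeds))
            sel_name = (selector_spec if isinstance(selector_spec, str)
                        else selector_spec._method.lower())
            try:
                if isinstance(selector_spec, str):
                    selector = _make_selector(selector_spec, sel_seed)
                else:
                    selector = selector_spec
                if selector is None:
                    cols = np.arange(Xtr.shape[1])
                else:
                    if selection_scope == "all":
                        X_sel = np.vstack([Xtr, Xte])
                        y_sel = np.concatenate([y[tr], y[te]])
                    else:
                        X_sel, y_sel = Xtr, y[tr]
                    selector.fit(X_sel, y_sel)
                    cols = np.flatnonzero(selector.support_)
                sel_err = None
            except Exception as err:  # noqa: BLE001 - grid keeps going
                cols, sel_err = None, f"{sel_name}: {err}"
            for model_spec in models:
                mdl_seed = int(next(child_seeds))
                spec = (ModelSpec(model_spec, seed=mdl_seed)
                        if isinstance(model_spec, str) else model_spec)
                rec = EvalRecord(
                    chain=chain.name, selector=sel_name, model=spec.family,
                    n_bands=0 if cols is None else int(len(cols)), seed=seed,
                )
                if sel_err is not None:
                    rec.error = sel_err
                    records.append(rec)
                    continue
                try:
                    fitted = fit_model(spec, Xtr[:, cols], y[tr])
                    pred_tr = np.asarray(fitted.predict(Xtr[:, cols])).ravel()
                    pred_te = np.asarray(fitted.predict(Xte[:, cols])).ravel()
                    m_tr = metrics(y[tr], pred_tr)
                    m_te = metrics(y[te], pred_te)
                    rec.train_r2, rec.train_rmse, rec.train_mape = m_tr
                    rec.test_r2, rec.test_rmse, rec.test_mape = m_te
                    rec.details = {
                        "best_params": fitted.best_params_,
                        "selected_bands": None if cols is None else cols,
                        "selected_nm": None if cols is None else wl_out[cols],
                    }
                except Exception as err:  # noqa: BLE001
                    rec.error = f"{spec.family}: {err}"
                records.append(rec)

    def _key(r: EvalRecord):
        return (not r.ok, -r.test_r2 if r.ok else np.inf,
                r.test_rmse if r.ok else np.inf, r.test_mape if r.ok else np.inf)

    records.sort(key=_key)
    return records


def select_best(records) -> EvalRecord:
    """Best record: maximal test R², ties by minimal test RMSE then MAPE."""
    good = [r for r in records if r.ok]
    if not good:
        raise ValueError("no successful evaluation records")
    return min(good, key=lambda r: (-r.test_r2, r.test_rmse, r.test_mape))
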