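"""Spectral pretreatments: SNV, MSC, Savitzky-Golay smoothing, finite-difference derivatives.

Each operation exists twice: a function on :class:`~teadtc.spectra.Spectrum` /
matrices matching the chemometric formulas, and an sklearn-style transformer
for pipeline composition.  A :class:`PreprocessChain` composes at most one
scatter step, one derivative step and one smoothing step, applied in that
order, and keeps the wavelength axis book-keeping explicit (derivatives shrink
the axis; smoothing leaves edge points untouched).

Formulas (x a spectrum of m points, x̄ its mean, Δλ the band spacing):

* SNV:  (x − x̄) / sd(x),  sd with m−1 in the denominator.
* MSC:  regress each sample on a reference spectrum, x ≈ m·ref + b (ordinary
  least squares); corrected = (x − b)/m.  The reference defaults to the
  training-set mean spectrum and is frozen at fit time.
* S-G:  local least-squares polynomial smoothing over an odd window.
* 1D:   forward difference (y_{i+1} − y_i)/Δλ, m−1 points on midpoint axis.
* 2D:   central second difference (y_{i+1} − 2y_i + y_{i−1})/Δλ², m−2 points.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import SpectraMatrix, Spectrum

__all__ = [
    "snv",
    "msc",
    "savgol",
    "derivative_1d",
    "derivative_2d",
    "apply_chain",
    "MSCFit",
    "StandardNormalVariate",
    "MultiplicativeScatterCorrection",
    "SavitzkyGolaySmoother",
    "SpectralDerivative",
    "PreprocessChain",
    "ChainStepError",
]


class ChainStepError(ValueError):
    """A preprocessing step failed; the message names the step."""


# ---------------------------------------------------------------- row kernels


def _snv_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 points")
    mean = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: SNV undefined (zero variance)")
    return (X - mean) / sd


def _msc_rows(X: np.ndarray, reference: np.ndarray):
    """OLS slope/intercept of each row against the reference; corrected = (x-b)/m."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("reference spectrum is constant; MSC undefined")
    slopes = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(slopes) < 1e-12):
        i = int(np.argmax(np.abs(slopes) < 1e-12))
        raise ValueError(f"degenerate MSC fit for sample {i}: slope ~ 0")
    intercepts = X.mean(axis=1) - slopes * ref.mean()
    corrected = (X - intercepts[:, None]) / slopes[:, None]
    return corrected, slopes, intercepts


def _savgol_rows(X: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[1]
    if window % 2 == 0:
        raise ValueError("S-G window must be odd")
    if not 3 <= window <= m:
        raise ValueError(f"S-G window must be in [3, {m}]")
    if polyorder >= window:
        raise ValueError("S-G polynomial order must be below the window width")
    out = savgol_filter(X, window, polyorder, axis=1, mode="interp")
    half = (window - 1) // 2
    # edge points pass through unchanged, preserving the band count without
    # inventing extrapolated values
    out[:, :half] = X[:, :half]
    out[:, m - half:] = X[:, m - half:]
    return out


def _check_uniform(wavelengths: np.ndarray) -> float:
    d = np.diff(wavelengths)
    if d.size == 0 or np.ptp(d) > 1e-9:
        raise ValueError("derivatives require a uniform wavelength axis")
    return float(d[0])


# ------------------------------------------------------------------ functions


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: centre and scale one spectrum to unit sample sd."""
    return Spectrum(_snv_rows(s.values[None, :])[0], s.wavelengths)


@dataclass
class MSCFit:
    """Frozen MSC state: the reference plus per-sample regression (slope, intercept)."""

    reference: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray


def msc(X, reference: np.ndarray | None = None):
    """Multiplicative scatter correction of a samples x bands matrix.

    Returns (corrected matrix, :class:`MSCFit`).  With no explicit reference the
    column-mean spectrum of ``X`` is used (requires >= 2 samples).
    """
    wavelengths = None
    ids = None
    if isinstance(X, SpectraMatrix):
        wavelengths, ids, X = X.wavelengths, X.sample_ids, X.values
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("MSC without an explicit reference needs >= 2 samples")
        reference = X.mean(axis=0)
    corrected, slopes, intercepts = _msc_rows(X, reference)
    fit = MSCFit(np.asarray(reference, dtype=float), slopes, intercepts)
    if wavelengths is not None:
        return SpectraMatrix(ids, wavelengths, corrected), fit
    return corrected, fit


def savgol(s: Spectrum, window: int, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing; edge points outside the first full window pass through."""
    return Spectrum(_savgol_rows(s.values[None, :], window, polyorder)[0], s.wavelengths)


def derivative_1d(s: Spectrum) -> Spectrum:
    """Forward-difference first derivative; m-1 points on the midpoint axis."""
    if s.n_bands < 2:
        raise ValueError("first derivative needs at least 2 points")
    step = _check_uniform(s.wavelengths)
    vals = np.diff(s.values) / step
    axis = (s.wavelengths[:-1] + s.wavelengths[1:]) / 2.0
    return Spectrum(vals, axis)


def derivative_2d(s: Spectrum) -> Spectrum:
    """Central second difference; m-2 points, axis trimmed one point each end."""
    if s.n_bands < 3:
        raise ValueError("second derivative needs at least 3 points")
    step = _check_uniform(s.wavelengths)
    vals = (s.values[2:] - 2 * s.values[1:-1] + s.values[:-2]) / step**2
    return Spectrum(vals, s.wavelengths[1:-1])


# --------------------------------------------------------------- transformers


class StandardNormalVariate(TransformerMixin, BaseEstimator):
    """Row-wise SNV; stateless."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return _snv_rows(np.atleast_2d(np.asarray(X, dtype=float)))


class MultiplicativeScatterCorrection(TransformerMixin, BaseEstimator):
    """MSC against a reference learned from the *training* matrix (its column mean).

    Freezing the reference at fit time means test samples are corrected against
    the training reference — no information flows back from held-out data.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.reference is not None:
            self.reference_ = np.asarray(self.reference, dtype=float)
        else:
            if X.shape[0] < 2:
                raise ValueError("MSC without an explicit reference needs >= 2 samples")
            self.reference_ = X.mean(axis=0)
        return self

    def transform(self, X):
        corrected, slopes, intercepts = _msc_rows(X, self.reference_)
        self.last_fit_ = MSCFit(self.reference_, slopes, intercepts)
        return corrected


class SavitzkyGolaySmoother(TransformerMixin, BaseEstimator):
    """Row-wise S-G smoothing with pass-through edges; stateless."""

    def __init__(self, window: int = 5, polyorder: int = 2):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return _savgol_rows(X, self.window, self.polyorder)


class SpectralDerivative(TransformerMixin, BaseEstimator):
    """Row-wise finite-difference derivative (order 1 or 2) over a uniform axis."""

    def __init__(self, order: int = 1, step: float = 1.0):
        self.order = order
        self.step = step

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.order == 1:
            return np.diff(X, axis=1) / self.step
        if self.order == 2:
            return (X[:, 2:] - 2 * X[:, 1:-1] + X[:, :-2]) / self.step**2
        raise ValueError("derivative order must be 1 or 2")


# ---------------------------------------------------------------------- chain

_CHAIN_RE = re.compile(
    r"^(?P<scatter>MSC|SNV|none)"
    r"-(?P<deriv>1D|2D|none)"
    r"-(?P<sg>S-?G\s*\((?P<w>\d+)(?:\s*,\s*(?P<p>\d+))?\)|none)$",
    re.IGNORECASE,
)


class PreprocessChain(BaseEstimator, TransformerMixin):
    """Ordered pretreatment chain: scatter -> derivative -> smoothing.

    Parameters mirror the chain-string grammar
    ``[MSC|SNV|none]-[1D|2D|none]-[SG(w[,p])|none]``; ``parse``/``name`` round-trip.
    ``fit`` learns the MSC reference (training rows only) and records the output
    wavelength axis in ``wavelengths_out_``.
    """

    def __init__(
        self,
        scatter: str | None = None,
        derivative: int | None = None,
        window: int | None = None,
        polyorder: int = 2,
    ):
        self.scatter = scatter
        self.derivative = derivative
        self.window = window
        self.polyorder = polyorder

    # ---------------------------------------------------------- construction

    @classmethod
    def parse(cls, text: str) -> "PreprocessChain":
        m = _CHAIN_RE.match(text.strip())
        if not m:
            raise ValueError(
                f"cannot parse chain {text!r}; expected "
                "'[MSC|SNV|none]-[1D|2D|none]-[SG(w[,p])|none]'"
            )
        scatter = m.group("scatter").lower()
        scatter = None if scatter == "none" else scatter
        deriv = m.group("deriv").lower()
        derivative = None if deriv == "none" else int(deriv[0])
        window = int(m.group("w")) if m.group("w") else None
        polyorder = int(m.group("p")) if m.group("p") else 2
        return cls(scatter=scatter, derivative=derivative, window=window, polyorder=polyorder)

    @property
    def name(self) -> str:
        scatter = (self.scatter or "none").upper() if self.scatter else "none"
        deriv = f"{self.derivative}D" if self.derivative else "none"
        if self.window:
            sg = f"SG({self.window})" if self.polyorder == 2 else f"SG({self.window},{self.polyorder})"
        else:
            sg = "none"
        return f"{scatter}-{deriv}-{sg}"

    def _validate(self):
        if self.scatter not in (None, "msc", "snv"):
            raise ValueError("scatter step must be 'msc', 'snv' or None")
        if self.derivative not in (None, 1, 2):
            raise ValueError("derivative step must be 1, 2 or None")
        if self.window is not None and self.window % 2 == 0:
            raise ChainStepError(f"step SG: window {self.window} is even")

    # --------------------------------------------------------------- fitting

    def fit(self, X, y=None, wavelengths: np.ndarray | None = None):
        self._validate()
        if isinstance(X, SpectraMatrix):
            wavelengths, X = X.wavelengths, X.values
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if wavelengths is None:
            wavelengths = np.arange(X.shape[1], dtype=float)
        wavelengths = np.asarray(wavelengths, dtype=float)
        if self.scatter == "msc":
            self._msc_ = MultiplicativeScatterCorrection().fit(X)
        wl = wavelengths
        if self.derivative == 1:
            if wl.size >= 2:
                _check_uniform(wl)
            wl = (wl[:-1] + wl[1:]) / 2.0
        elif self.derivative == 2:
            if wl.size >= 3:
                _check_uniform(wl)
            wl = wl[1:-1]
        self.wavelengths_in_ = wavelengths
        self.wavelengths_out_ = wl
        self.fitted_ = True
        return self

    def transform(self, X):
        if not getattr(self, "fitted_", False):
            raise ValueError("chain must be fitted before transform")
        if isinstance(X, SpectraMatrix):
            ids, X = X.sample_ids, X.values
        else:
            ids = None
        X = np.atleast_2d(np.asarray(X, dtype=float))
        step_name = "?"
        try:
            if self.scatter == "msc":
                step_name = "MSC"
                X = self._msc_.transform(X)
            elif self.scatter == "snv":
                step_name = "SNV"
                X = _snv_rows(X)
            if self.derivative:
                step_name = f"{self.derivative}D"
                delta = (
                    _check_uniform(self.wavelengths_in_)
                    if self.wavelengths_in_.size >= 2
                    else 1.0
                )
                X = SpectralDerivative(self.derivative, delta).transform(X)
            if self.window:
                step_name = f"SG({self.window})"
                X = _savgol_rows(X, self.window, self.polyorder)
        except ValueError as err:
            raise ChainStepError(f"step {step_name}: {err}") from err
        if ids is not None:
            return SpectraMatrix(ids, self.wavelengths_out_, X, name=self.name)
        return X

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def apply_chain(X: SpectraMatrix, chain: PreprocessChain | str) -> SpectraMatrix:
    """Fit the chain on ``X`` and apply it to ``X`` (single-matrix convenience)."""
    if isinstance(chain, str):
        chain = PreprocessChain.parse(chain)
    return chain.fit_transform(X)
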