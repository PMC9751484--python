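"""Core spectral containers.

A :class:`Spectrum` is one reflectance trace on an explicit wavelength axis;
a :class:`SpectraMatrix` stacks many samples sharing one axis (rows = samples,
columns = bands).  Both are thin, validated wrappers around numpy arrays; the
CSV layout (first column ``sample_id``, then one column per wavelength labeled
in nm to three decimals) is the package's on-disk exchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectraMatrix", "AxisMismatchError"]


class AxisMismatchError(ValueError):
    """Two spectra that should share a wavelength axis do not."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum with its wavelength axis (nm)."""

    values: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", _as_1d(self.values, "values"))
        object.__setattr__(self, "wavelengths", _as_1d(self.wavelengths, "wavelengths"))
        if self.values.shape != self.wavelengths.shape:
            raise ValueError(
                f"values ({self.values.size}) and wavelengths "
                f"({self.wavelengths.size}) differ in length"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        """Wavelength spacing; raises if the axis is not uniform (tol 1e-9 nm)."""
        d = np.diff(self.wavelengths)
        if d.size == 0:
            raise ValueError("a single-band spectrum has no step")
        if np.ptp(d) > 1e-9:
            raise ValueError("wavelength axis is not uniform")
        return float(d[0])


def _format_wavelength(wl: float) -> str:
    return f"{wl:.3f}"


@dataclass
class SpectraMatrix:
    """Samples x bands reflectance matrix on a shared wavelength axis."""

    sample_ids: list
    wavelengths: np.ndarray
    values: np.ndarray
    name: str = ""  # provenance tag, e.g. the preprocessing chain applied

    def __post_init__(self):
        self.wavelengths = _as_1d(self.wavelengths, "wavelengths")
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x bands array")
        if self.values.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} bands"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.values[i], self.wavelengths)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            columns=[_format_wavelength(w) for w in self.wavelengths],
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise ValueError("first column of a spectra CSV must be 'sample_id'")
        wl = np.array([float(c) for c in df.columns[1:]])
        return cls(df["sample_id"].tolist(), wl, df.iloc[:, 1:].to_numpy(float))
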