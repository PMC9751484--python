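"""Hyperspectral cube calibration and canopy mean-spectrum extraction.

The acquisition workflow this mirrors: a push-broom camera images the tea
canopy together with a white reference board and a dark background frame;
reflectance is recovered per pixel/band as ``R = (DN - dark)/(white - dark)``,
the canopy is segmented from the pot/soil background, and the per-band mean
over canopy pixels becomes the sample's spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import AxisMismatchError, SpectraMatrix, Spectrum

__all__ = [
    "HyperCube",
    "CanopyMask",
    "CalibrationError",
    "EmptyMaskError",
    "nearest_band",
    "calibrate_reflectance",
    "segment_canopy",
    "mean_spectrum",
    "stack_samples",
]


class CalibrationError(ValueError):
    """White and dark references coincide somewhere, so reflectance is undefined."""


class EmptyMaskError(ValueError):
    """Segmentation produced no canopy pixels."""


@dataclass
class HyperCube:
    """(height, width, bands) cube of digital numbers or reflectances."""

    values: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"  # "raw" | "reflectance"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be (height, width, bands)")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"{self.values.shape[2]} bands but {self.wavelengths.size} wavelengths"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError("kind must be 'raw' or 'reflectance'")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class CanopyMask:
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def nearest_band(wavelengths: np.ndarray, nm: float) -> int:
    """Index of the band closest to ``nm``; equidistant ties go to the lower index."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if not (wavelengths.min() <= nm <= wavelengths.max()):
        raise ValueError(
            f"requested {nm} nm outside axis range "
            f"[{wavelengths.min():.3f}, {wavelengths.max():.3f}]"
        )
    return int(np.argmin(np.abs(wavelengths - nm)))


def calibrate_reflectance(raw: HyperCube, white: np.ndarray, dark: np.ndarray) -> HyperCube:
    """Per-pixel, per-band reflectance ``(DN - dark)/(white - dark)``, clipped to [0, 1]."""
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if white.shape != raw.values.shape or dark.shape != raw.values.shape:
        raise ValueError("white/dark reference frames must match the raw cube shape")
    denom = white - dark
    bad = denom == 0
    if bad.any():
        r, c, b = (int(i) for i in np.argwhere(bad)[0])
        raise CalibrationError(
            f"white equals dark at pixel (row={r}, col={c}, band={b}); "
            "reflectance is undefined there"
        )
    refl = (raw.values.astype(float) - dark) / denom
    return HyperCube(np.clip(refl, 0.0, 1.0), raw.wavelengths, kind="reflectance")


def segment_canopy(
    cube: HyperCube,
    red_band_nm: float = 670.0,
    nir_band_nm: float = 800.0,
    index_threshold: float = 0.5,
) -> CanopyMask:
    """NDVI-threshold canopy segmentation: keep pixels with (NIR-red)/(NIR+red) > threshold."""
    if cube.kind != "reflectance":
        raise ValueError("segment_canopy expects a calibrated reflectance cube")
    red = cube.values[:, :, nearest_band(cube.wavelengths, red_band_nm)].astype(float)
    nir = cube.values[:, :, nearest_band(cube.wavelengths, nir_band_nm)].astype(float)
    total = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(total > 0, (nir - red) / total, 0.0)
    mask = ndvi > index_threshold
    if not mask.any():
        raise EmptyMaskError(
            f"NDVI threshold {index_threshold} left no canopy pixels; lower the threshold"
        )
    return CanopyMask(mask)


def mean_spectrum(cube: HyperCube, mask: CanopyMask) -> Spectrum:
    """Per-band arithmetic mean over the masked pixels."""
    if mask.mask.shape != cube.values.shape[:2]:
        raise ValueError("mask dimensions do not match the cube")
    if mask.pixel_count < 1:
        raise EmptyMaskError("cannot average over an empty mask")
    mean = cube.values[mask.mask].mean(axis=0)
    return Spectrum(mean, cube.wavelengths)


def stack_samples(spectra) -> SpectraMatrix:
    """Stack (sample_id, Spectrum) pairs into a samples x bands matrix, order preserved."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to stack")
    ids = [sid for sid, _ in spectra]
    axis = spectra[0][1].wavelengths
    rows = []
    for sid, s in spectra:
        if s.wavelengths.size != axis.size or not np.allclose(
            s.wavelengths, axis, rtol=0, atol=1e-9
        ):
            raise AxisMismatchError(f"sample {sid!r} is on a different wavelength axis")
        rows.append(s.values)
    return SpectraMatrix(ids, axis, np.vstack(rows))
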