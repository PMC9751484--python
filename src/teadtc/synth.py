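"""Synthetic drought–rehydration experiments with known ground truth.

The generator emulates a greenhouse screen of 10 tea cultivars sampled on 7
occasions (drought days 1, 5, 9, 13, 17, then rehydration days 4 and 8) with
4 canopy replicates each — 280 samples of a 360-band canopy mean spectrum
(400–1000 nm, 1.667 nm spacing) plus three physiological indicators.

Latent structure
----------------
Each occasion carries a base stress level tied to declining soil moisture;
each cultivar has a latent drought ``tolerance`` in [0, 1] that attenuates the
stress it actually experiences (severity).  Indicator means follow the field's
trend shapes: MDA and SS are unimodal in severity (``baseline +
amplitude * s * (1 - s^q)``), peaking at the day-13/day-17 occasions; TP falls
linearly with severity and recovers on rehydration.  Spectra are a smooth
vegetation template (green bump near 550 nm, red edge near 715 nm, NIR
plateau) shifted by severity — visible reflectance up, NIR amplitude down —
then distorted by a per-sample multiplicative gain and additive offset (the
scatter artifacts MSC/SNV exist to remove) and white noise.

A single integer seed expands into independent substreams (physiology noise,
scatter, spectral noise), so toggling one noise source leaves the others'
draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cube import HyperCube, CanopyMask
from .dtc import DroughtToleranceScorer
from .spectra import SpectraMatrix, Spectrum

__all__ = [
    "DEFAULT_VARIETIES",
    "DEFAULT_STAGES",
    "OCCASION_BASE_STRESS",
    "ExperimentDesign",
    "VarietyProfile",
    "SyntheticTruth",
    "CubeScene",
    "default_profiles",
    "severity_for",
    "indicator_means",
    "canopy_reflectance",
    "informative_bands",
    "generate_experiment",
    "generate_cube",
]

DEFAULT_VARIETIES = ["SCZ", "ZC108", "MS9", "QN1", "QN21", "QN36", "QN38", "JGY", "JX", "XY10"]

#: (stage label, day index within its phase): 5 drought + 2 rehydration occasions.
DEFAULT_STAGES = [
    ("d1", 1), ("d5", 5), ("d9", 9), ("d13", 13), ("d17", 17), ("r4", 4), ("r8", 8),
]

#: Base stress per occasion: rises over the 5 drought occasions, falls after rehydration.
OCCASION_BASE_STRESS = np.array([0.10, 0.30, 0.50, 0.75, 0.85, 0.45, 0.20])

#: Latent tolerance attenuates experienced severity: s = base * (1 - GAMMA * tolerance).
TOLERANCE_ATTENUATION = 0.5

#: Unimodal exponent for MDA/SS: f(s) = s * (1 - s**PEAK_EXPONENT) peaks at s ~ 0.72,
#: between the day-13 and day-17 base stress levels.
PEAK_EXPONENT = 6.0

_SOIL_MOISTURE_FULL = 80.0   # % relative water content at zero stress
_SOIL_MOISTURE_SPAN = 65.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout: varieties x occasions x replicates on a uniform band axis."""

    varieties: tuple = tuple(DEFAULT_VARIETIES)
    stages: tuple = tuple(DEFAULT_STAGES)
    replicates_per_cell: int = 4
    n_bands: int = 360
    wavelength_start: float = 400.0
    wavelength_step: float = 1.667
    seed: int = 0

    def __post_init__(self):
        if self.replicates_per_cell <= 0:
            raise ValueError("replicates_per_cell must be positive")
        if self.wavelength_step <= 0:
            raise ValueError("wavelength step must be positive")
        if self.n_bands <= 0:
            raise ValueError("n_bands must be positive")
        if len(self.stages) != len(OCCASION_BASE_STRESS):
            # designs may drop occasions; base stress is trimmed to match
            if len(self.stages) > len(OCCASION_BASE_STRESS):
                raise ValueError(
                    f"at most {len(OCCASION_BASE_STRESS)} occasions supported"
                )

    @property
    def n_samples(self) -> int:
        return len(self.varieties) * len(self.stages) * self.replicates_per_cell

    @property
    def wavelengths(self) -> np.ndarray:
        return self.wavelength_start + self.wavelength_step * np.arange(self.n_bands)

    @property
    def base_stress(self) -> np.ndarray:
        return OCCASION_BASE_STRESS[: len(self.stages)]

    @property
    def soil_moisture(self) -> np.ndarray:
        """Per-occasion soil relative water content (%), anti-monotone in base stress."""
        return _SOIL_MOISTURE_FULL - _SOIL_MOISTURE_SPAN * self.base_stress


@dataclass(frozen=True)
class VarietyProfile:
    """Latent tolerance plus the baseline/amplitude/noise parameters of one cultivar."""

    tolerance: float
    baseline_mda: float = 8.8    # nmol/g
    baseline_ss: float = 14.0    # mg/g
    baseline_tp: float = 5.5     # mg/g
    amp_mda: float = 22.0
    amp_ss: float = 48.0
    tp_depth: float = 0.65
    noise_sd_mda: float = 0.7
    noise_sd_ss: float = 1.5
    noise_sd_tp: float = 0.35
    scatter_gain_sd: float = 0.15
    scatter_offset_sd: float = 0.05
    spectral_noise_sd: float = 0.004

    def __post_init__(self):
        if not 0.0 <= self.tolerance <= 1.0:
            raise ValueError("tolerance must lie in [0, 1]")
        for name in ("baseline_mda", "baseline_ss", "baseline_tp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "noise_sd_mda", "noise_sd_ss", "noise_sd_tp",
            "scatter_gain_sd", "scatter_offset_sd", "spectral_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def noiseless(self) -> "VarietyProfile":
        return self.with_noise_scaled(0.0)

    def with_noise_scaled(self, factor: float) -> "VarietyProfile":
        """Scale every noise/scatter sd by ``factor`` (0 = fully deterministic)."""
        return replace(
            self,
            noise_sd_mda=factor * self.noise_sd_mda,
            noise_sd_ss=factor * self.noise_sd_ss,
            noise_sd_tp=factor * self.noise_sd_tp,
            scatter_gain_sd=factor * self.scatter_gain_sd,
            scatter_offset_sd=factor * self.scatter_offset_sd,
            spectral_noise_sd=factor * self.spectral_noise_sd,
        )


@dataclass
class SyntheticTruth:
    """Ground truth aligned with the generated sample order."""

    severity: np.ndarray          # per-sample latent stress in [0, 1]
    soil_moisture: np.ndarray     # per-occasion %
    true_dtc: np.ndarray          # per-sample tolerance-oriented composite
    tolerance: dict               # variety -> latent tolerance
    informative_bands: np.ndarray # band indices where severity moves reflectance


class CubeScene(NamedTuple):
    raw: HyperCube
    white: np.ndarray
    dark: np.ndarray
    true_mask: CanopyMask
    true_mean: Spectrum


def default_profiles(varieties=None) -> dict:
    """One profile per cultivar; tolerances spread over [0.05, 0.95].

    The spread follows the published strong-to-weak tolerance ranking so that
    ranking-recovery tests compare like with like.
    """
    from .reference import REPORTED_TOLERANCE_ORDER

    varieties = list(varieties) if varieties is not None else list(DEFAULT_VARIETIES)
    ranked = [v for v in REPORTED_TOLERANCE_ORDER if v in varieties]
    extras = [v for v in varieties if v not in ranked]
    order = ranked + extras
    n = len(order)
    tol = {v: 0.95 - 0.9 * i / max(n - 1, 1) for i, v in enumerate(order)}
    return {v: VarietyProfile(tolerance=tol[v]) for v in varieties}


def severity_for(tolerance: float, base_stress) -> np.ndarray:
    """Experienced severity: base stress attenuated by latent tolerance."""
    return np.asarray(base_stress, dtype=float) * (1.0 - TOLERANCE_ATTENUATION * tolerance)


def indicator_means(profile: VarietyProfile, severity) -> np.ndarray:
    """Noiseless (MDA, SS, TP) means at the given severities; shape (len(severity), 3)."""
    s = np.asarray(severity, dtype=float)
    bump = s * (1.0 - s**PEAK_EXPONENT)
    mda = profile.baseline_mda + profile.amp_mda * bump
    ss = profile.baseline_ss + profile.amp_ss * bump
    tp = profile.baseline_tp * (1.0 - profile.tp_depth * s)
    return np.column_stack([mda, ss, tp])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _template(wl: np.ndarray) -> np.ndarray:
    """Healthy-canopy reflectance: visible plateau, green bump, red edge, NIR plateau."""
    return (
        0.05
        + 0.04 * np.exp(-(((wl - 550.0) / 35.0) ** 2))
        + 0.40 * _sigmoid((wl - 715.0) / 18.0)
    )


def _severity_effect(wl: np.ndarray) -> np.ndarray:
    """d(reflectance)/d(severity): visible rises (pigment loss), NIR falls (structure)."""
    vis = 0.10 * np.exp(-(((wl - 600.0) / 80.0) ** 2)) * (1.0 - _sigmoid((wl - 705.0) / 12.0))
    nir = 0.12 * _sigmoid((wl - 760.0) / 20.0)
    return vis - nir


def canopy_reflectance(wavelengths, severity) -> np.ndarray:
    """Clean severity-dependent canopy spectra; shape (len(severity), n_bands)."""
    wl = np.asarray(wavelengths, dtype=float)
    s = np.atleast_1d(np.asarray(severity, dtype=float))
    return _template(wl)[None, :] + s[:, None] * _severity_effect(wl)[None, :]


def informative_bands(wavelengths, threshold: float = 0.02) -> np.ndarray:
    """Band indices whose reflectance responds to severity by more than ``threshold``."""
    return np.flatnonzero(np.abs(_severity_effect(np.asarray(wavelengths, float))) > threshold)


def generate_experiment(design: ExperimentDesign, profiles: dict | None = None):
    """Generate one synthetic experiment.

    Returns ``(spectra, physio, truth)``: a :class:`SpectraMatrix` (values
    clipped to [0, 1]), a physiology table (sample_id, variety, stage, day,
    mda, ss, tp) and a :class:`SyntheticTruth`.  Same seed -> bit-identical
    outputs.
    """
    profiles = profiles if profiles is not None else default_profiles(design.varieties)
    missing = [v for v in design.varieties if v not in profiles]
    if missing:
        raise ValueError(f"no profile for varieties: {missing}")

    ss_root = np.random.SeedSequence(design.seed)
    rng_physio, rng_scatter, rng_spectral = (
        np.random.default_rng(s) for s in ss_root.spawn(3)
    )

    wl = design.wavelengths
    base = design.base_stress
    rows, sample_ids, severities = [], [], []
    means = []
    noise_sds = []
    scatter_sds = []
    for variety in design.varieties:
        prof = profiles[variety]
        sev_occ = severity_for(prof.tolerance, base)
        mu_occ = indicator_means(prof, sev_occ)  # (n_stages, 3)
        for t, (stage, day) in enumerate(design.stages):
            for rep in range(design.replicates_per_cell):
                sample_ids.append(f"{variety}_{stage}_r{rep + 1}")
                rows.append((variety, stage, day))
                severities.append(sev_occ[t])
                means.append(mu_occ[t])
                noise_sds.append((prof.noise_sd_mda, prof.noise_sd_ss, prof.noise_sd_tp))
                scatter_sds.append(
                    (prof.scatter_gain_sd, prof.scatter_offset_sd, prof.spectral_noise_sd)
                )
    n = len(sample_ids)
    severity = np.array(severities)
    means = np.vstack(means)
    noise_sds = np.array(noise_sds)
    scatter_sds = np.array(scatter_sds)

    physio_vals = means + rng_physio.standard_normal((n, 3)) * noise_sds
    physio_vals = np.maximum(physio_vals, 1e-6)  # indicator concentrations stay positive

    clean = canopy_reflectance(wl, severity)
    gains = 1.0 + rng_scatter.standard_normal(n) * scatter_sds[:, 0]
    offsets = rng_scatter.standard_normal(n) * scatter_sds[:, 1]
    noise = rng_spectral.standard_normal((n, wl.size)) * scatter_sds[:, 2][:, None]
    spectra_vals = np.clip(clean * gains[:, None] + offsets[:, None] + noise, 0.0, 1.0)

    physio = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "variety": [r[0] for r in rows],
            "stage": [r[1] for r in rows],
            "day": [r[2] for r in rows],
            "mda": physio_vals[:, 0],
            "ss": physio_vals[:, 1],
            "tp": physio_vals[:, 2],
        }
    )
    spectra = SpectraMatrix(sample_ids, wl, spectra_vals, name="raw")

    # tolerance-oriented composite from the noiseless means (larger = more tolerant);
    # flipping every indicator leaves the CRITIC weights unchanged
    scorer = DroughtToleranceScorer(tolerance_oriented=True)
    true_dtc = scorer.fit_transform(pd.DataFrame(means, columns=["mda", "ss", "tp"]))

    truth = SyntheticTruth(
        severity=severity,
        soil_moisture=design.soil_moisture,
        true_dtc=true_dtc,
        tolerance={v: profiles[v].tolerance for v in design.varieties},
        informative_bands=informative_bands(wl),
    )
    return spectra, physio, truth


def generate_cube(
    height: int,
    width: int,
    design: ExperimentDesign,
    canopy_fraction: float = 0.4,
    seed: int = 0,
    severity: float = 0.5,
) -> CubeScene:
    """Synthesize a raw cube + white/dark references with known mask and mean spectrum.

    Canopy pixels (a centred blob covering ``canopy_fraction`` of the frame)
    carry the severity-dependent plant spectrum with mild per-pixel gain
    variation; background pixels carry a flat low-NIR spectrum.  The raw cube
    is constructed as ``dark + R * (white - dark)`` so calibration inverts it
    exactly.
    """
    if not 0.0 < canopy_fraction <= 1.0:
        raise ValueError("canopy_fraction must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    wl = design.wavelengths
    n_px = height * width

    # centred blob of exactly round(fraction * n_px) pixels
    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    dist = (rr - (height - 1) / 2.0) ** 2 + (cc - (width - 1) / 2.0) ** 2
    k = max(1, int(round(canopy_fraction * n_px)))
    order = np.argsort(dist.ravel(), kind="stable")
    mask_flat = np.zeros(n_px, dtype=bool)
    mask_flat[order[:k]] = True
    mask = mask_flat.reshape(height, width)

    plant = canopy_reflectance(wl, np.array([severity]))[0]
    background = np.full(wl.size, 0.15)
    refl = np.empty((height, width, wl.size))
    refl[:] = background
    pixel_gain = 1.0 + 0.02 * rng.standard_normal(k)
    refl[mask] = np.clip(plant[None, :] * pixel_gain[:, None], 0.0, 1.0)

    white = np.broadcast_to(
        2500.0 + 1000.0 * np.exp(-(((wl - 700.0) / 200.0) ** 2)), (height, width, wl.size)
    ).copy()
    dark = np.full((height, width, wl.size), 100.0)
    raw = dark + refl * (white - dark)

    true_mean = Spectrum(refl[mask].mean(axis=0), wl)
    return CubeScene(
        raw=HyperCube(raw, wl, kind="raw"),
        white=white,
        dark=dark,
        true_mask=CanopyMask(mask),
        true_mean=true_mean,
    )
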