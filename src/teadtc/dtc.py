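"""Drought tolerance coefficient (DTC): range normalization, CRITIC weights, scoring, ranking.

Three physiological indicators summarize a tea plant's drought response:
malondialdehyde (MDA, nmol/g — lipid peroxidation, rises under stress),
soluble sugar (SS, mg/g — osmolyte, rises under stress) and total polyphenol
(TP, mg/g — quality component, falls under stress).  The range method maps
each indicator onto [0, 1] oriented so that larger means more
stress-responsive; CRITIC then weights the indicators objectively by
combining each column's contrast strength (its standard deviation) with its
conflict against the other columns (one minus the pairwise Pearson
correlation):

    C_j = sd_j * sum_k (1 - r_jk),     w_j = C_j / sum_m C_m

and a sample's DTC is the weighted sum of its normalized indicators.  Note
the convention this inherits: with stress-positive orientation the composite
*rises* with stress, so varieties whose samples sit mostly below the overall
mean are the drought-tolerant ones; ``1 - dtc`` is the equivalent
tolerance-oriented score (the CRITIC weights are identical either way, since
flipping every column changes neither standard deviations nor correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "INDICATORS",
    "OrientationSpec",
    "CriticResult",
    "DTCTable",
    "RankingTable",
    "summarize_physiology",
    "relative_difference",
    "orient_and_normalize",
    "critic_weights",
    "compute_dtc",
    "rank_varieties",
    "DroughtToleranceScorer",
]

INDICATORS = ("mda", "ss", "tp")

#: Biology-given orientations: MDA and SS rise with stress, TP falls.
DEFAULT_ORIENTATION = {"mda": "+", "ss": "+", "tp": "-"}


@dataclass(frozen=True)
class OrientationSpec:
    """Per-indicator direction: '+' = larger means more stress-responsive, '-' = smaller."""

    directions: dict

    def __post_init__(self):
        for name, d in self.directions.items():
            if d not in ("+", "-"):
                raise ValueError(f"direction for {name!r} must be '+' or '-', got {d!r}")

    @classmethod
    def default(cls) -> "OrientationSpec":
        return cls(dict(DEFAULT_ORIENTATION))

    def flipped(self) -> "OrientationSpec":
        return OrientationSpec(
            {k: ("-" if d == "+" else "+") for k, d in self.directions.items()}
        )


@dataclass
class CriticResult:
    indicators: list
    contrast: np.ndarray      # sd_j of the normalized columns (ddof=1)
    correlation: np.ndarray   # Pearson r_jk
    info_content: np.ndarray  # C_j = sd_j * sum_k (1 - r_jk)
    weights: np.ndarray       # w_j = C_j / sum C
    shares_pct: np.ndarray    # w_j as percentages

    def to_dict(self) -> dict:
        return {
            "indicators": list(self.indicators),
            "contrast": self.contrast.tolist(),
            "correlation": self.correlation.tolist(),
            "info_content": self.info_content.tolist(),
            "weights": self.weights.tolist(),
            "shares_pct": self.shares_pct.tolist(),
        }


@dataclass
class DTCTable:
    """Per-sample normalized indicators and DTC, plus overall mean and median."""

    table: pd.DataFrame  # columns: sample metadata, x'_<ind> ..., dtc
    mean: float
    median: float


@dataclass
class RankingTable:
    table: pd.DataFrame  # per variety: counts/percentages beyond mean and median, rank


def summarize_physiology(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(variety, stage) mean and standard error for each indicator.

    SEM = sample sd / sqrt(n); a single-replicate cell gets SEM 0 with
    ``sem_defined = False``.
    """
    required = {"variety", "stage", *INDICATORS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"physiology table missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("physiology table is empty")
    grouped = table.groupby(["variety", "stage"], sort=False)
    out = []
    for (variety, stage), cell in grouped:
        n = len(cell)
        row = {"variety": variety, "stage": stage, "n": n, "sem_defined": n > 1}
        for ind in INDICATORS:
            vals = cell[ind].to_numpy(float)
            row[f"{ind}_mean"] = vals.mean()
            row[f"{ind}_sem"] = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)


def relative_difference(a: float, b: float, basis: str = "smaller") -> float:
    """Percent difference between the larger value ``a`` and smaller ``b``.

    ``basis='smaller'`` divides by ``b`` (how much bigger a is than b);
    ``basis='larger'`` divides by ``a``.  Both conventions occur in field
    reports, so both are exposed.
    """
    if a <= 0 or b <= 0:
        raise ValueError("relative_difference requires positive inputs")
    if a < b:
        raise ValueError("first argument must be the larger value")
    if basis == "smaller":
        return (a - b) / b * 100.0
    if basis == "larger":
        return (a - b) / a * 100.0
    raise ValueError("basis must be 'smaller' or 'larger'")


def orient_and_normalize(
    table: pd.DataFrame, spec: OrientationSpec | None = None
) -> pd.DataFrame:
    """Range-normalize each indicator over ALL samples jointly, oriented per ``spec``.

    positive direction -> (x - min)/(max - min); negative -> (max - x)/(max - min).
    """
    spec = spec or OrientationSpec.default()
    out = {}
    for ind, direction in spec.directions.items():
        if ind not in table.columns:
            raise ValueError(f"indicator column {ind!r} missing from table")
        x = table[ind].to_numpy(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError(f"indicator {ind!r} is constant; range normalization undefined")
        out[ind] = (x - lo) / (hi - lo) if direction == "+" else (hi - x) / (hi - lo)
    return pd.DataFrame(out, index=table.index)


def critic_weights(normalized) -> CriticResult:
    """CRITIC objective weights from a jointly normalized samples x indicators matrix."""
    if isinstance(normalized, pd.DataFrame):
        names = list(normalized.columns)
        X = normalized.to_numpy(float)
    else:
        X = np.asarray(normalized, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 indicator columns")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise ValueError(f"indicator {names[j]!r} has zero variance")
    r = np.corrcoef(X, rowvar=False)
    C = sd * (1.0 - r).sum(axis=1)
    w = C / C.sum()
    return CriticResult(names, sd, r, C, w, w * 100.0)


def compute_dtc(
    normalized: pd.DataFrame,
    weights: CriticResult,
    meta: pd.DataFrame | None = None,
) -> DTCTable:
    """Score every sample: dtc_i = sum_j w_j * x'_ij, with overall mean/median attached."""
    if list(normalized.columns) != list(weights.indicators):
        raise ValueError("normalized columns do not match the weighted indicators")
    if not np.isclose(weights.weights.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    dtc = normalized.to_numpy(float) @ weights.weights
    parts = []
    if meta is not None:
        if len(meta) != len(normalized):
            raise ValueError("meta and normalized row counts differ")
        parts.append(meta.reset_index(drop=True))
    parts.append(
        normalized.rename(columns={c: f"x_{c}" for c in normalized.columns}).reset_index(
            drop=True
        )
    )
    table = pd.concat(parts, axis=1)
    table["dtc"] = dtc
    return DTCTable(table, float(dtc.mean()), float(np.median(dtc)))


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def rank_varieties(dtc: DTCTable, total_n: int | None = None) -> RankingTable:
    """Per-variety counts of samples whose DTC exceeds the overall mean / median.

    Percentages are count/total*100, rounded half-up to 2 decimals.  Rank is by
    descending beyond-mean count, ties broken by beyond-median count, then label.
    Because DTC here is stress-oriented, a LOW rank position (few samples beyond
    the mean) indicates the more drought-tolerant variety.
    """
    if "variety" not in dtc.table.columns:
        raise ValueError("every sample must carry a variety label")
    total_n = len(dtc.table) if total_n is None else total_n
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    rows = []
    for variety, cell in dtc.table.groupby("variety", sort=False):
        above_mean = int((cell["dtc"] > dtc.mean).sum())
        above_median = int((cell["dtc"] > dtc.median).sum())
        rows.append(
            {
                "variety": variety,
                "n_beyond_mean": above_mean,
                "pct_beyond_mean": _round_half_up(above_mean / total_n * 100.0),
                "n_beyond_median": above_median,
                "pct_beyond_median": _round_half_up(above_median / total_n * 100.0),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        by=["n_beyond_mean", "n_beyond_median", "variety"],
        ascending=[False, False, True],
        kind="stable",
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return RankingTable(out.reset_index(drop=True))


class DroughtToleranceScorer(BaseEstimator, TransformerMixin):
    """sklearn-style scorer: fit learns ranges + CRITIC weights, transform yields DTC.

    Parameters
    ----------
    orientation : dict mapping indicator name -> '+'/'-'; default MDA +, SS +, TP -.
    tolerance_oriented : if True, emit ``1 - dtc`` so that larger = more tolerant.
    """

    def __init__(self, orientation: dict | None = None, tolerance_oriented: bool = False):
        self.orientation = orientation
        self.tolerance_oriented = tolerance_oriented

    def _spec(self) -> OrientationSpec:
        return OrientationSpec(dict(self.orientation or DEFAULT_ORIENTATION))

    def _frame(self, X) -> pd.DataFrame:
        spec = self._spec()
        if isinstance(X, pd.DataFrame):
            return X[list(spec.directions)]
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=list(spec.directions))

    def fit(self, X, y=None):
        frame = self._frame(X)
        spec = self._spec()
        self.mins_ = frame.min(axis=0).to_numpy(float)
        self.maxs_ = frame.max(axis=0).to_numpy(float)
        if np.any(self.maxs_ == self.mins_):
            raise ValueError("constant indicator column; range normalization undefined")
        normalized = orient_and_normalize(frame, spec)
        self.critic_ = critic_weights(normalized)
        self.weights_ = self.critic_.weights
        self.info_content_ = self.critic_.info_content
        self.shares_pct_ = self.critic_.shares_pct
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "critic_")
        frame = self._frame(X)
        spec = self._spec()
        cols = []
        for j, (ind, direction) in enumerate(spec.directions.items()):
            x = frame[ind].to_numpy(float)
            span = self.maxs_[j] - self.mins_[j]
            z = (x - self.mins_[j]) / span
            cols.append(z if direction == "+" else 1.0 - z)
        dtc = np.column_stack(cols) @ self.weights_
        return 1.0 - dtc if self.tolerance_oriented else dtc
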