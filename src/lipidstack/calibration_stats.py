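"""Cross-validation statistics for the imaging pipeline.

Two statistics tie image-derived lipid volumes to independent measurements:

* Ordinary least squares of Oil-Red-O optical density (absorbance at 500 nm,
  blank-subtracted) on image-derived lipid volume. OD is proportional to, but
  not 1:1 with, lipid volume, so converting an OD reading into an absolute
  volume requires this regression (or another standard); prediction is by
  analytic inversion of the fitted line.

* The intraclass correlation coefficient between two measurement procedures
  of the same samples (e.g., semi-automated vs. manual registration of total
  lipid volume). The default is ICC(2,1): two-way random effects, absolute
  agreement, single measure — the form that speaks to interchangeability of
  the two procedures. The consistency form ICC(3,1) is available behind a
  flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "CalibrationPair",
    "RaterPair",
    "RegressionResult",
    "od_volume_regression",
    "icc_absolute_agreement",
    "read_calibration_csv",
    "read_rater_csv",
]


@dataclass(frozen=True)
class CalibrationPair:
    """(OD at 500 nm, image-derived volume) for one muscle sample."""

    sample_id: str
    od: float
    volume: float

    def __post_init__(self) -> None:
        if self.od < 0:
            raise ValueError("od must be >= 0 (blank-subtracted absorbance)")
        if self.volume < 0:
            raise ValueError("volume must be >= 0")


@dataclass(frozen=True)
class RaterPair:
    """Total lipid volume of one sample measured by two procedures/raters."""

    sample_id: str
    value_a: float
    value_b: float

    def __post_init__(self) -> None:
        for v in (self.value_a, self.value_b):
            if not np.isfinite(v) or v < 0:
                raise ValueError("rater values must be finite and >= 0")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    predict_volume: Callable[[float], float]

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
        }


def _aggregate_duplicates(pairs: Sequence[CalibrationPair]) -> tuple[np.ndarray, np.ndarray]:
    """Average duplicate OD well readings per sample before regression."""
    df = pd.DataFrame(
        {"sample_id": [p.sample_id for p in pairs],
         "od": [p.od for p in pairs],
         "volume": [p.volume for p in pairs]}
    )
    agg = df.groupby("sample_id", sort=False).mean(numeric_only=True)
    return agg["volume"].to_numpy(), agg["od"].to_numpy()


def od_volume_regression(pairs: Sequence[CalibrationPair]) -> RegressionResult:
    """OLS of OD on volume; returns slope, intercept, r^2 and an inverse predictor.

    Duplicate readings of the same sample are averaged first. Requires >= 3
    distinct samples and non-degenerate volumes.
    """
    if len(pairs) < 3:
        raise ValueError("regression needs >= 3 calibration pairs")
    volume, od = _aggregate_duplicates(pairs)
    if len(volume) < 3:
        raise ValueError("regression needs >= 3 distinct samples")
    if np.allclose(volume, volume[0]):
        raise ValueError("degenerate predictor: all volumes equal")
    fit = linregress(volume, od)
    slope, intercept = float(fit.slope), float(fit.intercept)

    def predict_volume(od_value: float) -> float:
        """Estimated volume for a new OD reading (inverse regression).

        The OD-volume relationship is proportional but not 1:1; absolute
        volumes are only meaningful through this calibration line.
        """
        if slope == 0:
            raise ValueError("zero slope: volume cannot be inferred from OD")
        return (od_value - intercept) / slope

    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=float(fit.rvalue) ** 2,
        n=len(volume),
        predict_volume=predict_volume,
    )


def icc_absolute_agreement(pairs: Sequence[RaterPair], form: str = "ICC2") -> float:
    """Single-measure intraclass correlation between two measurement columns.

    ``form="ICC2"`` (default): two-way random effects, absolute agreement —
    ICC(2,1) from the mean-squares decomposition. ``form="ICC3"``: two-way
    mixed, consistency — ICC(3,1), insensitive to a fixed offset between
    raters. Deterministic; requires >= 3 samples and nonzero total variance.
    """
    if len(pairs) < 3:
        raise ValueError("ICC needs >= 3 sample pairs")
    data = np.array([[p.value_a, p.value_b] for p in pairs], dtype=float)
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined for identical data")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = (
        np.sum((data - grand) ** 2)
        - k * np.sum((row_means - grand) ** 2)
        - n * np.sum((col_means - grand) ** 2)
    )
    mse = sse / ((n - 1) * (k - 1))
    if form == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"form must be ICC2|ICC3, got {form!r}")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def read_calibration_csv(path: str | Path) -> list[CalibrationPair]:
    """Read (sample_id, od, volume) rows."""
    df = pd.read_csv(path)
    required = ["sample_id", "od", "volume"]
    if [c for c in required if c not in df.columns]:
        raise ValueError(f"calibration CSV must have columns {required}")
    return [
        CalibrationPair(str(r.sample_id), float(r.od), float(r.volume))
        for r in df.itertuples()
    ]


def read_rater_csv(path: str | Path) -> list[RaterPair]:
    """Read (sample_id, value_a, value_b) rows."""
    df = pd.read_csv(path)
    required = ["sample_id", "value_a", "value_b"]
    if [c for c in required if c not in df.columns]:
        raise ValueError(f"rater CSV must have columns {required}")
    return [
        RaterPair(str(r.sample_id), float(r.value_a), float(r.value_b))
        for r in df.itertuples()
    ]
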