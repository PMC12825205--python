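"""Assay-level statistics: fold-change normalization, EMT score, TRAIL
sensitization, endpoint regressions and cohort summaries.

Flow-cytometry readouts are mean fluorescence intensities (MFI).  Protein
expression is normalized to the untreated t = 0 baseline after background
(unstained-control) subtraction:

    fold = (F_protein - F_background) / (F_baseline - F_background)

The EMT score is the ratio of the mean normalized vimentin fold-change to
the mean normalized E-cadherin fold-change (ratio of means, not mean of
ratios).  TRAIL sensitization compares treated to control viability:

    sensitization = (pct_control - pct_treated) / pct_control
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError

__all__ = [
    "ExpressionMeasurement",
    "ViabilityRecord",
    "CohortRecord",
    "normalized_expression",
    "emt_score",
    "trail_sensitization",
    "endpoint_regression",
    "cohort_summary",
    "flag_outliers_mad",
    "printed_1dp",
]


@dataclass(frozen=True)
class ExpressionMeasurement:
    """One flow-cytometry measurement with its normalization anchors."""

    f_protein: float
    f_baseline: float
    f_background: float
    protein: str = ""
    dose_ng_ml: float = float("nan")
    time_h: float = float("nan")
    replicate: int = 0

    def __post_init__(self):
        for name in ("f_protein", "f_baseline", "f_background"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class ViabilityRecord:
    """Percent viable/apoptotic/necrotic cells for one treatment group."""

    treatment: str
    pct_viable: float
    pct_apoptotic: float
    pct_necrotic: float
    prl_pre_exposed: bool = False
    shear: bool = False
    trail_dose_ng_ml: float = 0.0

    def __post_init__(self):
        for name in ("pct_viable", "pct_apoptotic", "pct_necrotic"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{name} must be in [0, 100], got {v}")


@dataclass(frozen=True)
class CohortRecord:
    """One patient row of the clinical cohort table."""

    patient_id: str
    age: Optional[float]
    pregnant: bool
    trimester: Optional[str] = None
    tumor_location: str = "CL"           # R, CR or CL
    tumor_size_cm: Optional[float] = None
    stage: str = ""
    procedures: tuple[str, ...] = ()
    systemic_treatments: tuple[str, ...] = ()
    vital_status: str = "A"

    def __post_init__(self):
        if self.tumor_size_cm is not None and self.tumor_size_cm <= 0:
            raise ValidationError(
                f"tumor size must be > 0 cm, got {self.tumor_size_cm}")
        if self.tumor_location not in ("R", "CR", "CL"):
            raise ValidationError(
                f"tumor location must be R, CR or CL, "
                f"got {self.tumor_location!r}")

    @property
    def n_interventions(self) -> int:
        """Listed procedures plus listed systemic agents, once each."""
        return len(self.procedures) + len(self.systemic_treatments)


def normalized_expression(m: ExpressionMeasurement) -> float:
    """Background-subtracted fold-change relative to the untreated baseline.

    Values above/below 1 indicate up-/down-regulation; a value below 0
    (protein MFI under the unstained background) is permitted but warned
    about, as it usually indicates a staining problem.
    """
    denom = m.f_baseline - m.f_background
    if denom == 0:
        raise ZeroDivisionError(
            "baseline MFI equals background MFI; fold-change undefined")
    if m.f_protein < m.f_background:
        warnings.warn(
            f"protein MFI ({m.f_protein}) below background "
            f"({m.f_background}); negative fold-change", stacklevel=2)
    return (m.f_protein - m.f_background) / denom


def emt_score(vim_folds: Sequence[float], ecad_folds: Sequence[float]) -> float:
    """EMT score: mean vimentin fold over mean E-cadherin fold."""
    if len(vim_folds) == 0 or len(ecad_folds) == 0:
        raise ValidationError("EMT score requires nonempty replicate lists")
    ecad_mean = float(np.mean(ecad_folds))
    if ecad_mean == 0:
        raise ZeroDivisionError("mean E-cadherin fold-change is zero")
    return float(np.mean(vim_folds)) / ecad_mean


def trail_sensitization(pct_viable: float, pct_viable_control: float) -> float:
    """Fractional viability loss of a treated group versus its control.

    0 when viabilities are equal, 1 when no treated cells remain, negative
    when the treatment protected the cells.
    """
    if pct_viable_control <= 0:
        raise ZeroDivisionError("control viability must be positive")
    return (pct_viable_control - pct_viable) / pct_viable_control


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def endpoint_regression(x: Sequence[float], y: Sequence[float]
                        ) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    if len(x) < 3:
        raise ValidationError(
            f"regression needs at least 3 paired points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in x; regression degenerate")
    with warnings.catch_warnings():
        # a perfectly constant y triggers a harmless divide warning in the
        # p-value computation
        warnings.simplefilter("ignore")
        res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    if math.isnan(r2):  # constant y: slope 0, no explained variance
        r2 = 0.0
    p = float(res.pvalue) if not math.isnan(res.pvalue) else 1.0
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=r2, p_value=p, n=len(x))


def printed_1dp(x: float) -> float:
    """One-decimal display value, truncating toward zero.

    Matches the convention of the cohort summary's printed values (e.g. a
    mean of 3.66 cm is displayed as 3.6).
    """
    return math.trunc(x * 10) / 10


@dataclass
class GroupSummary:
    group: str
    n: int
    n_with_size: int
    mean_size_cm: Optional[float]
    sd_size_cm: Optional[float]
    mean_interventions: float
    location_counts: dict = field(default_factory=dict)
    empty: bool = False


def _summarize_group(label: str, records: Sequence[CohortRecord]
                     ) -> GroupSummary:
    if not records:
        return GroupSummary(group=label, n=0, n_with_size=0,
                            mean_size_cm=None, sd_size_cm=None,
                            mean_interventions=float("nan"), empty=True)
    sizes = [r.tumor_size_cm for r in records if r.tumor_size_cm is not None]
    mean = float(np.mean(sizes)) if sizes else None
    # sample SD (ddof=1); undefined for a single size
    sd = float(np.std(sizes, ddof=1)) if len(sizes) > 1 else None
    locs: dict[str, int] = {}
    for r in records:
        locs[r.tumor_location] = locs.get(r.tumor_location, 0) + 1
    return GroupSummary(
        group=label, n=len(records), n_with_size=len(sizes),
        mean_size_cm=mean, sd_size_cm=sd,
        mean_interventions=float(np.mean([r.n_interventions
                                          for r in records])),
        location_counts=locs)


def cohort_summary(records: Iterable[CohortRecord]
                   ) -> dict[str, GroupSummary]:
    """Per-group tumor-size mean ± sample SD, intervention counts and
    tumor-location distribution, grouped by pregnancy status.

    Missing tumor sizes are excluded, never imputed.  An empty group
    yields an empty-summary marker rather than an exception.
    """
    records = list(records)
    groups = {
        "pregnant": [r for r in records if r.pregnant],
        "non_pregnant": [r for r in records if not r.pregnant],
    }
    return {label: _summarize_group(label, rs)
            for label, rs in groups.items()}


def flag_outliers_mad(values: Sequence[float], threshold: float = 3.5
                      ) -> np.ndarray:
    """Median-absolute-deviation outlier screen (flag-only, off by default
    in every pipeline step).  Returns a boolean mask of flagged points."""
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return np.zeros(v.shape, dtype=bool)
    # 0.6745 scales the MAD to an SD-equivalent under normality
    return np.abs(v - med) / (mad / 0.6745) > threshold
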