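"""Assay-validation statistics: precision, detection limits, linearity,
reference intervals, QC charting, stability, and cohort distribution tables.

Conventions used throughout (documented in the result objects):

* CV = 100 × sample SD (n−1 denominator) / mean; undefined at mean 0, in
  which case the absolute SD is the reportable quantity.
* Nonparametric percentiles use the rank-(n+1)p convention with linear
  interpolation between order statistics, clamped to the observed range.
* LoB is the 95th percentile of blank replicates; LoD = LoB + 1.6 × SD of a
  low-level sample; LoQ is the lowest level whose replicate CV < 25%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import round_half_up
from .errors import InsufficientDataError

PERCENTILE_METHOD = "nonparametric rank (n+1)p, linear interpolation"


class PrecisionScope(str, Enum):
    WITHIN_RUN = "within_run"
    BETWEEN_RUN = "between_run"


@dataclass(frozen=True)
class PrecisionResult:
    level_label: str
    n: int
    mean: float
    sd: float
    cv_percent: Optional[float]  # None (flagged) when mean == 0
    scope: PrecisionScope = PrecisionScope.WITHIN_RUN


@dataclass(frozen=True)
class DetectionLimits:
    lob: float
    lod: float
    loq: Optional[float]
    lod_sd: float
    loq_cv_threshold: float = 25.0


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class ReferenceInterval:
    n: int
    percentile_p: float
    cutoff_value: float
    method: str = PERCENTILE_METHOD
    reliable: bool = True  # False when n < 120


def compute_cv(
    values: Sequence[float],
    level_label: str = "",
    scope: PrecisionScope = PrecisionScope.WITHIN_RUN,
) -> PrecisionResult:
    """Replicate precision: mean, sample SD, and CV%.

    At mean 0 (e.g. a zero-copy level) the CV is undefined and flagged
    None; the SD remains the reportable imprecision.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("CV needs at least 2 replicates")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else None
    return PrecisionResult(level_label, int(x.size), mean, sd, cv, scope)


def _percentile_np1(sorted_x: np.ndarray, p: float) -> float:
    """Rank-(n+1)p percentile with linear interpolation, clamped to range."""
    n = sorted_x.size
    rank = (n + 1) * p  # 1-based
    if rank <= 1:
        return float(sorted_x[0])
    if rank >= n:
        return float(sorted_x[-1])
    lo = int(math.floor(rank))
    frac = rank - lo
    return float(sorted_x[lo - 1] + frac * (sorted_x[lo] - sorted_x[lo - 1]))


def limit_of_blank(blank_values: Sequence[float], n_required: int = 20) -> float:
    """LoB as the nonparametric 95th percentile of blank replicates.

    Reduces to 0 when all blanks measure 0.
    """
    x = np.sort(np.asarray(blank_values, dtype=float))
    if x.size < n_required:
        raise InsufficientDataError(
            f"LoB needs >= {n_required} blank replicates, got {x.size}"
        )
    return _percentile_np1(x, 0.95)


def limit_of_detection(lob: float, sd_low_level: float) -> float:
    """LoD = LoB + 1.6 × SD of a low-level replicate series."""
    if sd_low_level < 0:
        raise ValueError("sd must be >= 0")
    return lob + 1.6 * sd_low_level


def limit_of_quantification(
    levels: Sequence[tuple[float, Sequence[float]]], cv_threshold: float = 25.0
) -> Optional[float]:
    """Lowest tested concentration whose replicate CV is below the threshold.

    Returns None (not determined) when no level qualifies.
    """
    qualifying = []
    for conc, reps in levels:
        res = compute_cv(reps, level_label=str(conc))
        if res.cv_percent is not None and res.cv_percent < cv_threshold:
            qualifying.append(conc)
    return min(qualifying) if qualifying else None


def linearity_fit(
    expected: Sequence[float], measured: Sequence[float]
) -> LinearityResult:
    """Ordinary least squares of measured on expected concentration."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("linearity needs >= 3 paired points")
    if np.allclose(x, x[0]):
        raise ValueError("expected concentrations are constant: fit degenerate")
    fit = stats.linregress(x, y)
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def reference_interval(
    values: Sequence[float],
    p: float = 0.025,
    gestational_weeks: Optional[Sequence[float]] = None,
    min_weeks: float = 34.0,
) -> ReferenceInterval:
    """Lower reference percentile of a screening marker.

    When gestational ages are given, only full-term samples (>= min_weeks)
    enter the estimate. Fewer than 120 samples makes the nonparametric
    percentile unreliable; the result is then flagged rather than refused.
    """
    x = np.asarray(values, dtype=float)
    if gestational_weeks is not None:
        weeks = np.asarray(gestational_weeks, dtype=float)
        if weeks.size != x.size:
            raise ValueError("gestational_weeks must align with values")
        x = x[weeks >= min_weeks]
    if x.size == 0:
        raise InsufficientDataError("no samples left after gestational-age filter")
    return ReferenceInterval(
        n=int(x.size),
        percentile_p=p,
        cutoff_value=_percentile_np1(np.sort(x), p),
        reliable=bool(x.size >= 120),
    )


def levey_jennings_flags(
    qc_values: Sequence[float], mean: float, sd: float
) -> pd.DataFrame:
    """Control-chart evaluation against mean ± 2SD.

    Columns: value, z, out_of_control (|z| > 2, the 1-2s acceptance rule)
    and advisory_22s (this and the previous point beyond 2SD on the same
    side — reported as advisory only).
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    x = np.asarray(qc_values, dtype=float)
    z = (x - mean) / sd
    out = np.abs(z) > 2.0
    same_side = np.zeros_like(out)
    same_side[1:] = out[1:] & out[:-1] & (np.sign(z[1:]) == np.sign(z[:-1]))
    return pd.DataFrame(
        {"value": x, "z": z, "out_of_control": out, "advisory_22s": same_side}
    )


def stability_recovery(
    day0_values: Sequence[float],
    dayn_values: Sequence[float],
    tolerance_percent: float = 10.0,
) -> tuple[float, bool]:
    """Mean recovery (%) of a stored specimen versus baseline, and whether it
    falls within ±tolerance of 100%."""
    d0 = np.asarray(day0_values, dtype=float)
    dn = np.asarray(dayn_values, dtype=float)
    if d0.size < 1 or dn.size < 1:
        raise InsufficientDataError("recovery needs >= 1 value per timepoint")
    m0 = float(np.mean(d0))
    if m0 == 0:
        raise ValueError("baseline mean is zero: recovery undefined")
    recovery = 100.0 * float(np.mean(dn)) / m0
    return recovery, abs(recovery - 100.0) <= tolerance_percent


def cn_distribution_table(cn_calls: dict[str, Sequence[int]]) -> pd.DataFrame:
    """Copy-number frequency table per gene.

    Columns: gene, copy_number, count, percent (half-up to one decimal).
    """
    rows = []
    for gene, calls in cn_calls.items():
        arr = np.asarray(list(calls), dtype=int)
        if arr.size == 0:
            raise InsufficientDataError(f"no calls for {gene}")
        total = arr.size
        for cn in sorted(set(arr.tolist())):
            count = int(np.sum(arr == cn))
            rows.append(
                {
                    "gene": gene,
                    "copy_number": cn,
                    "count": count,
                    "percent": round_half_up(100.0 * count / total, 1),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "copy_number", "count", "percent"])
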