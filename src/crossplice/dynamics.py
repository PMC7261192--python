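"""Reference-normalized expression dynamics: fold changes, decay fits, induction.

mRNA half-life is estimated from a transcription-shutoff (e.g. actinomycin D)
time course under a single-exponential model: abundance is normalized to a
reference gene (e.g. actin) and to its own t=0 value, then ln(abundance) is
regressed on time by ordinary least squares; the decay rate k is the negated
slope and the half-life is ln2 / k.  Induction time courses (e.g. PMA
stimulation) are expressed as fold induction relative to t=0 per condition
and compared between genotypes.

Below-detection measurements are encoded as NaN (missing), never as zero,
and are excluded from fits; the number of exclusions is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DecaySeries:
    """Target and reference abundance over a shutoff time course (hours)."""

    timepoints: np.ndarray
    target: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if not (len(self.timepoints) == len(self.target) == len(self.reference)):
            raise ValueError("timepoints, target and reference must have equal length")
        if 0.0 not in self.timepoints:
            raise ValueError("series must include t = 0")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")


@dataclass(frozen=True)
class HalfLifeEstimate:
    decay_rate: float  # per hour; negated slope of the log-linear fit
    half_life: float  # hours; NaN when no measurable decay (k <= 0)
    r_squared: float
    n_points: int
    n_excluded: int = 0

    @property
    def defined(self) -> bool:
        return self.decay_rate > 0


def normalize_to_reference(series: DecaySeries) -> np.ndarray:
    """target/reference per timepoint, rescaled so the t=0 value is 1."""
    bad = np.where(~(series.reference > 0))[0]
    if len(bad):
        t = series.timepoints[bad[0]]
        raise ValueError(f"reference is not positive at t = {t} h")
    ratio = series.target / series.reference
    i0 = int(np.where(series.timepoints == 0.0)[0][0])
    if not ratio[i0] > 0:
        raise ValueError("normalized abundance at t = 0 must be positive")
    return ratio / ratio[i0]


def estimate_half_life(series: DecaySeries, min_points: int = 3) -> HalfLifeEstimate:
    """Log-linear OLS fit of the single-exponential decay model.

    Missing (NaN) or non-positive normalized abundances are excluded from
    the fit and counted in n_excluded.  A non-positive fitted decay rate
    yields half_life = NaN (no measurable decay), not an error.
    """
    norm = normalize_to_reference(series)
    ok = np.isfinite(norm) & (norm > 0)
    n_excluded = int((~ok).sum())
    t = series.timepoints[ok]
    y = np.log(norm[ok])
    if len(t) < min_points:
        raise ValueError(
            f"need >= {min_points} usable timepoints for the decay fit, have {len(t)}"
        )
    res = stats.linregress(t, y)
    k = -float(res.slope)
    half_life = float(np.log(2.0) / k) if k > 0 else float("nan")
    return HalfLifeEstimate(
        decay_rate=k,
        half_life=half_life,
        r_squared=float(res.rvalue**2),
        n_points=len(t),
        n_excluded=n_excluded,
    )


def fold_change(measure_a, measure_b, reference_a, reference_b) -> float:
    """Reference-normalized fold change of condition b relative to condition a."""
    vals = {
        "measure_a": measure_a,
        "measure_b": measure_b,
        "reference_a": reference_a,
        "reference_b": reference_b,
    }
    for name, v in vals.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (measure_b / reference_b) / (measure_a / reference_a)


@dataclass
class ExpressionSeries:
    """Target/reference abundance over a stimulation time course for one condition."""

    timepoints: np.ndarray
    target: np.ndarray
    reference: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if 0.0 not in self.timepoints:
            raise ValueError("series must include t = 0")

    def fold_induction(self) -> np.ndarray:
        """(target/reference) relative to its own t=0 value; 1 at t=0 by construction."""
        bad = np.where(~(self.reference > 0))[0]
        if len(bad):
            raise ValueError(
                f"reference is not positive at t = {self.timepoints[bad[0]]} h"
            )
        ratio = self.target / self.reference
        i0 = int(np.where(self.timepoints == 0.0)[0][0])
        return ratio / ratio[i0]


@dataclass
class InductionComparison:
    table: pd.DataFrame  # time, fold_wt, fold_kd, ratio_kd_over_wt
    max_induction_wt: float
    max_induction_kd: float
    induction_lost: bool
    loss_threshold: float


def compare_induction(
    series_wt: ExpressionSeries,
    series_kd: ExpressionSeries,
    loss_threshold: float = 0.5,
) -> InductionComparison:
    """Compare fold-induction time courses between two genotypes.

    Flags 'induction lost' when the knockdown's maximal fold induction is
    below loss_threshold times the wildtype's maximal fold induction.
    """
    if not np.array_equal(series_wt.timepoints, series_kd.timepoints):
        raise ValueError("time courses have mismatched timepoints")
    fold_wt = series_wt.fold_induction()
    fold_kd = series_kd.fold_induction()
    table = pd.DataFrame(
        {
            "time": series_wt.timepoints,
            "fold_wt": fold_wt,
            "fold_kd": fold_kd,
            "ratio_kd_over_wt": fold_kd / fold_wt,
        }
    )
    max_wt = float(np.nanmax(fold_wt))
    max_kd = float(np.nanmax(fold_kd))
    return InductionComparison(
        table=table,
        max_induction_wt=max_wt,
        max_induction_kd=max_kd,
        induction_lost=max_kd < loss_threshold * max_wt,
        loss_threshold=loss_threshold,
    )
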