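"""Overlap, regression, classification and rescue logic for two knockdowns.

Given per-event splicing calls from two knockdown-vs-control comparisons
(factors A and B) computed on a common universe of testable events, this
module answers: do the two factors regulate the same events (hypergeometric
overlap test), how similar are the effects on shared events (OLS of dPSI_B
on dPSI_A), which events are truly factor-specific versus merely trending,
and what do rescue (re-expression) experiments say about the mode of
co-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OverlapStats:
    n_universe: int
    n_A: int
    n_B: int
    n_shared: int
    p_two_tailed: float
    pct_of_A: float
    pct_of_B: float


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


EVENT_CLASSES = (
    "shared",
    "A_specific",
    "B_specific",
    "A_trend_in_B",
    "B_trend_in_A",
    "discordant",
    "nonresponsive",
)

RESCUE_CALLS = ("no_rescue", "partial_rescue", "full_rescue", "untestable")
RESCUE_MODELS = ("antagonistic_direct", "saturated_single", "cooperative")


@dataclass(frozen=True)
class RescueOutcome:
    mean_psi_wt: float
    mean_psi_kd: float
    mean_psi_rescue: float
    rescue_fraction: float  # NaN when untestable
    call: str
    model: str | None = None


def _check_overlap_counts(n_universe, n_A, n_B, n_shared) -> None:
    for name, v in (("n_universe", n_universe), ("n_A", n_A), ("n_B", n_B), ("n_shared", n_shared)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if n_A > n_universe or n_B > n_universe:
        raise ValueError("set sizes cannot exceed the universe")
    if n_shared > min(n_A, n_B):
        raise ValueError("shared count cannot exceed the smaller set")
    if n_shared < max(0, n_A + n_B - n_universe):
        raise ValueError("shared count below the forced minimum overlap")


def hypergeometric_two_tailed(
    n_universe: int, n_A: int, n_B: int, n_shared: int, method: str = "double"
) -> float:
    """Two-tailed hypergeometric test of the overlap between two sets.

    Under the null, the overlap of a fixed set of size n_A with a random
    set of size n_B drawn without replacement from n_universe items is
    hypergeometric.  ``method='double'`` (default) doubles the smaller of
    the enrichment tail P[X >= n_shared] and the depletion tail
    P[X <= n_shared], capped at 1.  ``method='minlike'`` sums the
    probabilities of all outcomes no more likely than the observed one
    (the construction used by exact tests such as Fisher's).
    """
    _check_overlap_counts(n_universe, n_A, n_B, n_shared)
    dist = stats.hypergeom(M=n_universe, n=n_A, N=n_B)
    if method == "double":
        enrich = dist.sf(n_shared - 1)
        deplete = dist.cdf(n_shared)
        return float(min(1.0, 2.0 * min(enrich, deplete)))
    if method == "minlike":
        lo = max(0, n_A + n_B - n_universe)
        hi = min(n_A, n_B)
        ks = np.arange(lo, hi + 1)
        pmf = dist.pmf(ks)
        observed = dist.pmf(n_shared)
        p = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
        return min(1.0, p)
    raise ValueError(f"unknown method {method!r}")


def overlap_stats(
    calls_A: pd.DataFrame, calls_B: pd.DataFrame, method: str = "double"
) -> OverlapStats:
    """Overlap of the significant-event sets of two comparisons.

    The universe is the intersection of events testable in both
    comparisons; it is always reported so the sensitivity of the p-value
    to the universe definition can be checked.  Percentages are on the
    0-100 scale.
    """
    universe = np.intersect1d(calls_A["event_id"], calls_B["event_id"])
    if len(universe) == 0:
        raise ValueError("empty universe: the two call sets share no events")
    a = calls_A.set_index("event_id").loc[universe]
    b = calls_B.set_index("event_id").loc[universe]
    sig_a = set(a.index[a["significant"]])
    sig_b = set(b.index[b["significant"]])
    shared = sig_a & sig_b
    n_a, n_b, n_s = len(sig_a), len(sig_b), len(shared)
    p = hypergeometric_two_tailed(len(universe), n_a, n_b, n_s, method=method)
    return OverlapStats(
        n_universe=len(universe),
        n_A=n_a,
        n_B=n_b,
        n_shared=n_s,
        p_two_tailed=p,
        pct_of_A=100.0 * n_s / n_a if n_a else float("nan"),
        pct_of_B=100.0 * n_s / n_b if n_b else float("nan"),
    )


def shared_event_regression(delta_psi_A, delta_psi_B) -> RegressionFit:
    """OLS of dPSI_B (y) on dPSI_A (x) for events shared by both knockdowns."""
    x = np.asarray(delta_psi_A, dtype=float)
    y = np.asarray(delta_psi_B, dtype=float)
    if x.shape != y.shape:
        raise ValueError("delta_psi_A and delta_psi_B must have equal length")
    if len(x) < 3:
        raise ValueError(f"regression needs >= 3 shared events, got {len(x)}")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


def classify_events(
    calls_A: pd.DataFrame, calls_B: pd.DataFrame, trend_threshold: float = 5.0
) -> pd.DataFrame:
    """Partition the common universe into cross-regulation classes.

    shared        : significant in both, same direction.
    discordant    : significant in both, opposite directions (surfaced as an
                    anomaly class; such predictions failed orthogonal
                    validation in practice).
    A_trend_in_B  : significant in A only, with a same-direction dPSI
                    strictly above trend_threshold in B.
    A_specific    : significant in A only, B's dPSI at or below
                    trend_threshold or of opposite sign.
    B_trend_in_A / B_specific : symmetric.
    nonresponsive : significant in neither.

    The classes are mutually exclusive and exhaustive over the universe.
    """
    merged = calls_A.merge(
        calls_B, on="event_id", suffixes=("_A", "_B"), how="inner"
    )
    da = merged["delta_psi_A"].to_numpy()
    db = merged["delta_psi_B"].to_numpy()
    sa = merged["significant_A"].to_numpy(dtype=bool)
    sb = merged["significant_B"].to_numpy(dtype=bool)
    same_sign = np.sign(da) * np.sign(db) > 0

    cls = np.full(len(merged), "nonresponsive", dtype=object)
    cls[sa & sb & same_sign] = "shared"
    cls[sa & sb & ~same_sign] = "discordant"
    only_a = sa & ~sb
    only_b = sb & ~sa
    trend_b = same_sign & (np.abs(db) > trend_threshold)
    trend_a = same_sign & (np.abs(da) > trend_threshold)
    cls[only_a & trend_b] = "A_trend_in_B"
    cls[only_a & ~trend_b] = "A_specific"
    cls[only_b & trend_a] = "B_trend_in_A"
    cls[only_b & ~trend_a] = "B_specific"

    out = merged[
        ["event_id", "delta_psi_A", "p_value_A", "significant_A",
         "delta_psi_B", "p_value_B", "significant_B"]
    ].copy()
    out["event_class"] = cls
    return out


def classify_rescue(
    psi_wt,
    psi_kd,
    psi_rescue,
    partial_band: tuple[float, float] = (0.25, 0.75),
    min_effect: float = 10.0,
    depleted: str | None = None,
    reexpressed: str | None = None,
    both_sensitive: bool | None = None,
) -> RescueOutcome:
    """Interpret a re-expression (rescue) experiment on one splicing event.

    rescue_fraction = (PSI_rescue - PSI_kd) / (PSI_wt - PSI_kd) from group
    means; defined only when the knockdown moved PSI by more than
    ``min_effect`` points, otherwise the outcome is 'untestable'.  The call
    is no_rescue below the partial band, full_rescue above it, partial
    in between.

    When the experimental context is given, a mode-of-action model is
    inferred: no rescue by the *partner* of the depleted factor indicates
    the partner is already active (antagonistic_direct, for events produced
    by depleting B while A opposes it) or already saturating
    (saturated_single, for events produced by depleting A); partial rescue
    by either factor on an event sensitive to both knockdowns indicates
    cooperative regulation.
    """
    lo, hi = partial_band
    if not 0 <= lo <= hi <= 1:
        raise ValueError("partial_band must satisfy 0 <= lo <= hi <= 1")
    m_wt = float(np.mean(psi_wt))
    m_kd = float(np.mean(psi_kd))
    m_rescue = float(np.mean(psi_rescue))
    if abs(m_wt - m_kd) <= min_effect:
        return RescueOutcome(m_wt, m_kd, m_rescue, float("nan"), "untestable")
    frac = (m_rescue - m_kd) / (m_wt - m_kd)
    if frac < lo:
        call = "no_rescue"
    elif frac > hi:
        call = "full_rescue"
    else:
        call = "partial_rescue"

    model = None
    if depleted is not None and reexpressed is not None and reexpressed != depleted:
        if call == "no_rescue":
            model = "antagonistic_direct" if depleted == "B" else "saturated_single"
        elif call == "partial_rescue" and both_sensitive:
            model = "cooperative"
    elif both_sensitive and call == "partial_rescue":
        model = "cooperative"
    return RescueOutcome(m_wt, m_kd, m_rescue, float(frac), call, model)
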