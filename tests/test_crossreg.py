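"""Tests for overlap statistics, regression, classification and rescue logic."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossplice.crossreg import (
    classify_events,
    classify_rescue,
    hypergeometric_two_tailed,
    overlap_stats,
    shared_event_regression,
)

# ---------------------------------------------------------------------------
# exact enumeration oracle (independent of scipy): distribution of |A ∩ B|
# over all unordered pairs of subsets of given sizes from a universe of size N.


def overlap_pmf_exact(n_universe, n_a, n_b):
    """P(|A ∩ B| = k) by counting subset pairs with exact rational arithmetic."""
    total = Fraction(comb(n_universe, n_a) * comb(n_universe, n_b))
    pmf = {}
    for k in range(max(0, n_a + n_b - n_universe), min(n_a, n_b) + 1):
        ways = comb(n_universe, n_a) * comb(n_a, k) * comb(n_universe - n_a, n_b - k)
        pmf[k] = Fraction(ways) / total
    return pmf


def two_tailed_exact(n_universe, n_a, n_b, k):
    pmf = overlap_pmf_exact(n_universe, n_a, n_b)
    upper = sum(p for kk, p in pmf.items() if kk >= k)
    lower = sum(p for kk, p in pmf.items() if kk <= k)
    return float(min(Fraction(1), 2 * min(upper, lower)))


def test_hypergeometric_matches_enumeration_small_grid():
    for n in range(1, 9):
        for n_a in range(n + 1):
            for n_b in range(n + 1):
                for k in range(max(0, n_a + n_b - n), min(n_a, n_b) + 1):
                    got = hypergeometric_two_tailed(n, n_a, n_b, k)
                    want = two_tailed_exact(n, n_a, n_b, k)
                    assert got == pytest.approx(want, abs=1e-12), (n, n_a, n_b, k)


def test_hypergeometric_worked_example():
    # universe 10, sets of 4 and 5, overlap 4: only overlap-4 draws are as extreme
    assert hypergeometric_two_tailed(10, 4, 5, 4) == pytest.approx(
        two_tailed_exact(10, 4, 5, 4), abs=1e-15
    )


def test_hypergeometric_symmetry_and_cap():
    assert hypergeometric_two_tailed(30, 8, 12, 4) == hypergeometric_two_tailed(30, 12, 8, 4)
    # overlap at its expectation in a tiny universe: p large but never above 1
    p = hypergeometric_two_tailed(8, 4, 4, 2)  # E[X] = 2
    assert 0.5 < p <= 1.0


def test_hypergeometric_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        hypergeometric_two_tailed(10, 4, 5, 5)  # shared > min set
    with pytest.raises(ValueError):
        hypergeometric_two_tailed(10, 11, 5, 2)  # set > universe
    with pytest.raises(ValueError):
        hypergeometric_two_tailed(10, 8, 8, 2)  # below forced overlap of 6


def test_two_tailed_p_super_uniform_under_null():
    """Random independent label assignment: P[p <= alpha] <= alpha + MC error."""
    rng = np.random.default_rng(0)
    n, n_a, n_b, reps = 60, 15, 20, 2000
    pvals = np.empty(reps)
    for i in range(reps):
        a = set(rng.choice(n, n_a, replace=False))
        b = set(rng.choice(n, n_b, replace=False))
        pvals[i] = hypergeometric_two_tailed(n, n_a, n_b, len(a & b))
    for alpha in (0.01, 0.05, 0.1):
        rate = np.mean(pvals <= alpha)
        mc = 3 * np.sqrt(alpha * (1 - alpha) / reps)
        assert rate <= alpha + mc


# ---------------------------------------------------------------------------
# overlap stats on call tables


def _calls(event_ids, sig_ids, deltas=None):
    deltas = deltas if deltas is not None else np.zeros(len(event_ids))
    return pd.DataFrame(
        {
            "event_id": event_ids,
            "delta_psi": deltas,
            "p_value": 0.01,
            "significant": [e in sig_ids for e in event_ids],
        }
    )


def test_overlap_identical_sets():
    events = [f"e{i}" for i in range(50)]
    sig = set(events[:10])
    stats_ = overlap_stats(_calls(events, sig), _calls(events, sig))
    assert stats_.n_shared == stats_.n_A == stats_.n_B == 10
    assert stats_.pct_of_A == 100.0 and stats_.pct_of_B == 100.0
    assert stats_.p_two_tailed < 1e-9
    assert stats_.n_universe == 50


def test_overlap_disjoint_sets():
    events = [f"e{i}" for i in range(200)]
    stats_ = overlap_stats(_calls(events, set(events[:5])), _calls(events, set(events[5:10])))
    assert stats_.n_shared == 0


def test_overlap_universe_is_intersection_of_testable():
    a = _calls([f"e{i}" for i in range(30)], {"e1"})
    b = _calls([f"e{i}" for i in range(20, 50)], {"e21"})
    stats_ = overlap_stats(a, b)
    assert stats_.n_universe == 10  # e20..e29


def test_overlap_empty_universe_errors():
    a = _calls(["e1"], set())
    b = _calls(["e2"], set())
    with pytest.raises(ValueError, match="empty universe"):
        overlap_stats(a, b)


# ---------------------------------------------------------------------------
# shared-event regression


def test_regression_exact_line():
    x = np.array([-20.0, -5.0, 10.0, 25.0])
    fit = shared_event_regression(x, 0.8 * x)
    assert fit.slope == pytest.approx(0.8)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_regression_zero_covariance():
    x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
    y = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])  # symmetric in x, cov = 0
    fit = shared_event_regression(x, y)
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(0.0, abs=1e-12)


def test_regression_needs_three_points():
    with pytest.raises(ValueError, match=">= 3"):
        shared_event_regression([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# event classification


def _pair(delta_a, p_a, sig_a, delta_b, p_b, sig_b, event_id="e"):
    a = pd.DataFrame(
        {"event_id": [event_id], "delta_psi": [delta_a], "p_value": [p_a],
         "significant": [sig_a]}
    )
    b = pd.DataFrame(
        {"event_id": [event_id], "delta_psi": [delta_b], "p_value": [p_b],
         "significant": [sig_b]}
    )
    return a, b


@pytest.mark.parametrize(
    "delta_a, sig_a, delta_b, sig_b, expected",
    [
        (+25, True, +2, False, "A_specific"),
        (+25, True, +8, False, "A_trend_in_B"),
        (+25, True, +20, True, "shared"),
        (+25, True, -8, False, "A_specific"),  # opposite-sign trend does not count
        (+2, False, +25, True, "B_specific"),
        (+8, False, +25, True, "B_trend_in_A"),
        (+25, True, -20, True, "discordant"),
        (+2, False, +3, False, "nonresponsive"),
    ],
)
def test_classification_rules(delta_a, sig_a, delta_b, sig_b, expected):
    a, b = _pair(delta_a, 0.01 if sig_a else 0.3, sig_a, delta_b, 0.01 if sig_b else 0.3, sig_b)
    out = classify_events(a, b, trend_threshold=5.0)
    assert out["event_class"].iloc[0] == expected


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_classification_partitions_universe(seed):
    rng = np.random.default_rng(seed)
    n = 40
    events = [f"e{i}" for i in range(n)]
    def rand_calls():
        return pd.DataFrame(
            {
                "event_id": events,
                "delta_psi": rng.uniform(-30, 30, n),
                "p_value": rng.uniform(0, 1, n),
                "significant": rng.random(n) < 0.3,
            }
        )
    out = classify_events(rand_calls(), rand_calls())
    assert len(out) == n
    counts = out["event_class"].value_counts()
    assert counts.sum() == n  # mutually exclusive and exhaustive


def test_classification_recovers_generator_labels(default_sim):
    """On synthetic data, classified shared events are dominated by true shared/trend events."""
    from crossplice import compare_conditions, compute_psi, filter_events

    _, table, truth = default_sim
    table = filter_events(table)
    psi = compute_psi(table)
    ra = compare_conditions(psi, table.samples, "knockdownA", "control")
    rb = compare_conditions(psi, table.samples, "knockdownB", "control")
    out = classify_events(ra.calls, rb.calls)
    merged = out.merge(truth, on="event_id")
    shared_called = merged[merged["event_class"] == "shared"]
    if len(shared_called):
        frac_true = (shared_called["class_label"] != "null").mean()
        assert frac_true >= 0.8


# ---------------------------------------------------------------------------
# rescue


@pytest.mark.parametrize(
    "rescue_psi, exp_fraction, exp_call",
    [
        ([80, 80, 80], 0.0, "no_rescue"),
        ([65, 65, 65], 0.5, "partial_rescue"),
        ([50, 50, 50], 1.0, "full_rescue"),
    ],
)
def test_rescue_fraction_and_call(rescue_psi, exp_fraction, exp_call):
    out = classify_rescue([50, 50, 50], [80, 80, 80], rescue_psi)
    assert out.rescue_fraction == pytest.approx(exp_fraction)
    assert out.call == exp_call


def test_rescue_untestable_without_knockdown_effect():
    out = classify_rescue([50, 50], [55, 55], [52, 52])
    assert out.call == "untestable"
    assert np.isnan(out.rescue_fraction)


def test_rescue_invariant_to_isoform_role_swap():
    """Relabeling long/short (PSI -> 100 - PSI) leaves the rescue fraction unchanged."""
    wt, kd, rescue = [42.0, 48.0], [75.0, 81.0], [60.0, 64.0]
    a = classify_rescue(wt, kd, rescue)
    flip = lambda v: [100 - x for x in v]
    b = classify_rescue(flip(wt), flip(kd), flip(rescue))
    assert a.rescue_fraction == pytest.approx(b.rescue_fraction)
    assert a.call == b.call


def test_rescue_model_inference():
    # partner re-expression fails to rescue a B-knockdown effect: partner already active
    out = classify_rescue([50] * 3, [80] * 3, [79] * 3, depleted="B", reexpressed="A")
    assert out.model == "antagonistic_direct"
    # partner re-expression fails to rescue an A-knockdown effect: partner saturating
    out = classify_rescue([50] * 3, [80] * 3, [79] * 3, depleted="A", reexpressed="B")
    assert out.model == "saturated_single"
    # partial rescue of a both-sensitive event by either factor: cooperative
    out = classify_rescue(
        [50] * 3, [80] * 3, [65] * 3, depleted="A", reexpressed="B", both_sensitive=True
    )
    assert out.model == "cooperative"
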