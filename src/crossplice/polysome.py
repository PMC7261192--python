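"""Spike-in-normalized polysome profile analysis and CHX-shift classification.

A polysome profile is the distribution of an mRNA across sucrose-gradient
fractions ordered light (free mRNPs, monosomes) to heavy (polysomes).  A
known quantity of an exogenous spike-in RNA is added to every fraction
before RNA isolation; dividing the target signal by the spike-in signal
cancels fraction-specific recovery differences, and renormalizing gives a
distribution over fractions.

Efficiently elongating mRNAs are polysome-associated when ribosomes are
frozen with cycloheximide (CHX) but run off without it; CHX-independent
polysome association marks poor elongation efficiency.  The classifier
reduces a +/-CHX profile pair to a single shift statistic,
proportion(+CHX) - proportion(-CHX) of mass in the polysomal fractions,
and calls efficient_elongation when the shift exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import default_polysome_boundary  # noqa: F401  (re-exported)


@dataclass
class PolysomeProfile:
    """One gradient run: per-fraction target and spike-in signal.

    Fractions are ordered 1..F light to heavy; polysome_boundary is the
    first (1-based) fraction index counted as polysomal.
    """

    target_signal: np.ndarray
    spikein_signal: np.ndarray
    chx: bool
    genotype: str = ""
    polysome_boundary: int | None = None

    def __post_init__(self) -> None:
        self.target_signal = np.asarray(self.target_signal, dtype=float)
        self.spikein_signal = np.asarray(self.spikein_signal, dtype=float)
        f = len(self.target_signal)
        if f < 6:
            raise ValueError(f"need >= 6 fractions, got {f}")
        if len(self.spikein_signal) != f:
            raise ValueError("target and spike-in tracks differ in length")
        if self.polysome_boundary is None:
            self.polysome_boundary = default_polysome_boundary(f)
        if not 1 < self.polysome_boundary <= f:
            raise ValueError(f"polysome_boundary {self.polysome_boundary} out of range (2..{f})")

    @property
    def n_fractions(self) -> int:
        return len(self.target_signal)


@dataclass(frozen=True)
class TranslationCall:
    proportion_plus_chx: float
    proportion_minus_chx: float
    chx_shift: float
    call: str  # efficient_elongation | impaired_elongation
    shift_threshold: float
    polysome_boundary: int


def spike_normalize(profile: PolysomeProfile) -> np.ndarray:
    """Per-fraction target/spike-in ratios renormalized to a distribution.

    Fraction-specific recovery factors multiply both channels equally, so
    the output is invariant to them; it always sums to 1.
    """
    bad = np.where(~(profile.spikein_signal > 0))[0]
    if len(bad):
        raise ValueError(f"spike-in signal is not positive in fraction {bad[0] + 1}")
    ratio = profile.target_signal / profile.spikein_signal
    total = ratio.sum()
    if not total > 0:
        raise ValueError("profile carries no target signal")
    return ratio / total


def polysome_proportion(distribution, polysome_boundary: int) -> float:
    """Mass of the distribution in fractions >= polysome_boundary (1-based)."""
    dist = np.asarray(distribution, dtype=float)
    if not 1 <= polysome_boundary <= len(dist):
        raise ValueError(
            f"polysome_boundary {polysome_boundary} out of range (1..{len(dist)})"
        )
    return float(dist[polysome_boundary - 1 :].sum())


def classify_translation(
    profile_plus_chx: PolysomeProfile,
    profile_minus_chx: PolysomeProfile,
    shift_threshold: float = 0.15,
) -> TranslationCall:
    """Classify elongation efficiency from a matched +/-CHX profile pair.

    chx_shift = polysome proportion(+CHX) - polysome proportion(-CHX);
    efficient_elongation when the shift is strictly above shift_threshold,
    impaired_elongation otherwise (CHX-independent polysome retention).
    """
    if profile_plus_chx.n_fractions != profile_minus_chx.n_fractions:
        raise ValueError("profiles have different fraction counts")
    if profile_plus_chx.polysome_boundary != profile_minus_chx.polysome_boundary:
        raise ValueError("profiles have different polysome boundaries")
    if not profile_plus_chx.chx or profile_minus_chx.chx:
        raise ValueError("expected a (+CHX, -CHX) pair in that order")
    boundary = profile_plus_chx.polysome_boundary
    p_plus = polysome_proportion(spike_normalize(profile_plus_chx), boundary)
    p_minus = polysome_proportion(spike_normalize(profile_minus_chx), boundary)
    shift = p_plus - p_minus
    call = "efficient_elongation" if shift > shift_threshold else "impaired_elongation"
    return TranslationCall(
        proportion_plus_chx=p_plus,
        proportion_minus_chx=p_minus,
        chx_shift=shift,
        call=call,
        shift_threshold=shift_threshold,
        polysome_boundary=boundary,
    )
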