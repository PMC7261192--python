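"""Synthetic data generators with known ground truth for every pipeline stage.

The count-table generator emulates a targeted splicing screen of roughly
5000 alternative events measured in two RNA-binding-protein knockdowns
(A and B) against a common control, three replicates each.  Events belong
to one of six ground-truth classes:

* ``shared``      — true dPSI in both knockdowns, with dPSI_B =
                    shared_slope * dPSI_A (default slope 0.83), i.e. nearly
                    identical direction and extent of effect;
* ``A_specific`` / ``B_specific`` — true effect in one knockdown only;
* ``A_trend`` / ``B_trend``      — significant-magnitude effect in one
                    knockdown and a same-sign sub-threshold shift (3–9 pp)
                    in the other, mimicking events that look specific but
                    trend with the partner knockdown;
* ``null``        — no effect.

Counts follow a negative-binomial total per (event, sample) with a binomial
long/short split at the replicate-level true PSI; replicate noise is normal
on the PSI scale (percentage points, clamped to [0, 100]) so that effect
sizes are stated in dPSI units throughout.

All randomness flows from the single ``seed`` in the config through one
numpy Generator, so equal seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .splicing import EventCountTable

CONDITION_CONTROL = "control"
CONDITION_KD_A = "knockdownA"
CONDITION_KD_B = "knockdownB"

CLASS_LABELS = ("shared", "A_specific", "B_specific", "A_trend", "B_trend", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic splicing screen.

    Defaults describe the emulated study: ~5000 events, 3 knockdown vs 3
    control replicates, class fractions sized so the expected counts of
    shared (~71), A-specific (~45) and B-specific (~37) events and the
    ~23%/33% overlap percentages of the responsive sets are realistic;
    shared events couple the two knockdowns with slope 0.83.
    """

    n_events: int = 5000
    n_replicates_per_group: int = 3
    mean_depth: float = 200.0
    depth_dispersion: float = 10.0
    frac_shared: float = 0.0142
    frac_A_specific: float = 0.009
    frac_B_specific: float = 0.0074
    frac_trending: float = 0.06
    shared_slope: float = 0.83
    delta_psi_magnitude_range: tuple[float, float] = (12.0, 40.0)
    trend_magnitude_range: tuple[float, float] = (3.0, 9.0)
    psi_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_shared,
            self.frac_A_specific,
            self.frac_B_specific,
            self.frac_trending,
        )
        if any(f < 0 for f in fracs):
            raise ValueError("class proportions must be >= 0")
        if sum(fracs) > 1 + 1e-12:
            raise ValueError(f"class proportions sum to {sum(fracs)} > 1")
        for name in ("delta_psi_magnitude_range", "trend_magnitude_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is inverted: ({lo}, {hi})")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.n_replicates_per_group < 1:
            raise ValueError("n_replicates_per_group must be >= 1")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be > 0")
        if self.psi_noise_sd < 0:
            raise ValueError("psi_noise_sd must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    n = config.n_events
    counts = {
        "shared": round(config.frac_shared * n),
        "A_specific": round(config.frac_A_specific * n),
        "B_specific": round(config.frac_B_specific * n),
        "A_trend": round(config.frac_trending * n / 2),
        "B_trend": round(config.frac_trending * n / 2),
    }
    assigned = sum(counts.values())
    if assigned > n:
        raise ValueError("rounded class counts exceed n_events")
    counts["null"] = n - assigned
    return counts


def _draw_magnitudes(rng, n, lo, hi):
    mags = rng.uniform(lo, hi, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    return mags * signs


def simulate_count_table(config: SimulationConfig) -> tuple[EventCountTable, pd.DataFrame]:
    """Simulate a full isoform count table plus its ground truth.

    Returns (EventCountTable, ground_truth) where ground_truth has one row
    per event: event_id, class_label, baseline_psi, delta_psi_A,
    delta_psi_B.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    counts_by_class = _class_counts(config)

    labels = np.concatenate(
        [np.repeat(lab, k) for lab, k in counts_by_class.items()]
    )
    rng.shuffle(labels)

    delta_a = np.zeros(n)
    delta_b = np.zeros(n)
    lo, hi = config.delta_psi_magnitude_range
    tlo, thi = config.trend_magnitude_range

    idx = labels == "shared"
    d = _draw_magnitudes(rng, idx.sum(), lo, hi)
    delta_a[idx] = d
    # event-level scatter around the coupling line, vanishing with psi_noise_sd
    delta_b[idx] = config.shared_slope * d + rng.normal(
        0.0, config.psi_noise_sd, size=idx.sum()
    )

    idx = labels == "A_specific"
    delta_a[idx] = _draw_magnitudes(rng, idx.sum(), lo, hi)

    idx = labels == "B_specific"
    delta_b[idx] = _draw_magnitudes(rng, idx.sum(), lo, hi)

    idx = labels == "A_trend"
    d = _draw_magnitudes(rng, idx.sum(), lo, hi)
    delta_a[idx] = d
    delta_b[idx] = np.sign(d) * rng.uniform(tlo, thi, size=idx.sum())

    idx = labels == "B_trend"
    d = _draw_magnitudes(rng, idx.sum(), lo, hi)
    delta_b[idx] = d
    delta_a[idx] = np.sign(d) * rng.uniform(tlo, thi, size=idx.sum())

    # baseline PSI chosen so baseline and baseline+delta stay inside [5, 95]
    low = 5.0 - np.minimum(0.0, np.minimum(delta_a, delta_b))
    high = 95.0 - np.maximum(0.0, np.maximum(delta_a, delta_b))
    baseline = rng.uniform(low, high)

    event_ids = np.array([f"event_{i:05d}" for i in range(n)])
    truth = pd.DataFrame(
        {
            "event_id": event_ids,
            "class_label": labels,
            "baseline_psi": baseline,
            "delta_psi_A": delta_a,
            "delta_psi_B": delta_b,
        }
    )

    reps = config.n_replicates_per_group
    sample_rows = []
    for cond, shift in (
        (CONDITION_CONTROL, None),
        (CONDITION_KD_A, delta_a),
        (CONDITION_KD_B, delta_b),
    ):
        for r in range(1, reps + 1):
            sample_rows.append((f"{cond}_{r}", cond, r, shift))
    sheet = pd.DataFrame(
        [(sid, cond, r) for sid, cond, r, _ in sample_rows],
        columns=["sample_id", "condition", "replicate"],
    )
    sheet["stimulation"] = "PMA"

    # negative binomial total: var = m + m^2/dispersion
    r_nb = config.depth_dispersion
    p_nb = r_nb / (r_nb + config.mean_depth)

    frames = []
    for sid, cond, rep, shift in sample_rows:
        true_psi = baseline if shift is None else baseline + shift
        psi = true_psi + rng.normal(0.0, config.psi_noise_sd, size=n)
        psi = np.clip(psi, 0.0, 100.0)
        total = rng.negative_binomial(r_nb, p_nb, size=n)
        long = rng.binomial(total, psi / 100.0)
        frames.append(
            pd.DataFrame(
                {
                    "event_id": event_ids,
                    "sample_id": sid,
                    "long_count": long,
                    "short_count": total - long,
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    table = EventCountTable(counts=counts, samples=sheet)
    return table, truth


# ---------------------------------------------------------------------------
# mRNA decay


@dataclass
class DecaySeriesSim:
    """Simulated transcription-shutoff time course (target + constant reference)."""

    timepoints: np.ndarray
    target: np.ndarray
    reference: np.ndarray
    true_half_life: float


def simulate_decay_series(
    half_life: float,
    timepoints,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> DecaySeriesSim:
    """Exponential decay with multiplicative lognormal noise.

    abundance(t) = exp(-ln2 * t / half_life) * lognormal noise whose
    coefficient of variation is noise_cv (mean-one).  A constant
    reference-gene track is emitted alongside.
    """
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    t = np.asarray(timepoints, dtype=float)
    if 0.0 not in t:
        raise ValueError("timepoints must include 0")
    rng = np.random.default_rng(seed)
    clean = np.exp(-np.log(2.0) * t / half_life)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=t.shape)
    else:
        noise = np.ones_like(t)
    return DecaySeriesSim(
        timepoints=t,
        target=clean * noise,
        reference=np.ones_like(t),
        true_half_life=half_life,
    )


# ---------------------------------------------------------------------------
# polysome profiles

SHIFT_CLASSES = ("efficient", "impaired")


@dataclass
class PolysomeProfileSim:
    """Simulated gradient fractions with fraction-specific recovery distortion.

    true_distribution is the pre-distortion distribution over fractions;
    spike-in normalization of (target_signal, spikein_signal) recovers it
    exactly up to global scale.
    """

    target_signal: np.ndarray
    spikein_signal: np.ndarray
    chx: bool
    shift_class: str
    polysome_boundary: int
    true_distribution: np.ndarray


def default_polysome_boundary(n_fractions: int) -> int:
    """First fraction index (1-based) counted as polysomal: ceil(F/2) + 1."""
    return int(np.ceil(0.5 * n_fractions)) + 1


def simulate_polysome_profiles(
    n_fractions: int,
    shift_class: str,
    chx: bool,
    seed: int = 0,
    recovery_sd: float = 0.4,
    weight_jitter_sd: float = 0.02,
) -> PolysomeProfileSim:
    """Simulate one gradient profile for an mRNA of known elongation class.

    Efficiently elongating mRNAs sit in heavy (polysomal) fractions when
    ribosomes are frozen with cycloheximide (chx=True) but run off to light
    fractions without it; elongation-impaired mRNAs stay polysomal either
    way.  Each fraction's two channels share a lognormal recovery factor
    (sd of log = recovery_sd), emulating fraction-to-fraction RNA recovery
    differences that spike-in normalization cancels.
    """
    if n_fractions < 6:
        raise ValueError("n_fractions must be >= 6")
    if shift_class not in SHIFT_CLASSES:
        raise ValueError(f"shift_class must be one of {SHIFT_CLASSES}, got {shift_class!r}")
    rng = np.random.default_rng(seed)
    boundary = default_polysome_boundary(n_fractions)

    if shift_class == "efficient":
        heavy_weight = 0.75 if chx else 0.15
    else:  # impaired: polysome-retained regardless of CHX
        heavy_weight = 0.70
    heavy_weight = float(np.clip(heavy_weight + rng.normal(0.0, weight_jitter_sd), 0.02, 0.98))

    frac_idx = np.arange(1, n_fractions + 1)
    light = np.where(frac_idx < boundary, np.exp(-0.5 * (frac_idx - 1)), 0.0)
    light /= light.sum()
    center = (boundary + n_fractions) / 2.0
    width = max((n_fractions - boundary) / 3.0, 0.75)
    heavy = np.where(
        frac_idx >= boundary, np.exp(-0.5 * ((frac_idx - center) / width) ** 2), 0.0
    )
    heavy /= heavy.sum()
    dist = (1.0 - heavy_weight) * light + heavy_weight * heavy

    recovery = rng.lognormal(mean=0.0, sigma=recovery_sd, size=n_fractions)
    total_material = 1000.0
    spike_amount = 1.0  # same known quantity added to every fraction
    return PolysomeProfileSim(
        target_signal=total_material * dist * recovery,
        spikein_signal=spike_amount * recovery,
        chx=chx,
        shift_class=shift_class,
        polysome_boundary=boundary,
        true_distribution=dist,
    )


# ---------------------------------------------------------------------------
# IO helpers for the CLI


def write_simulation(table: EventCountTable, truth: pd.DataFrame, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table.write_tsv(out / "counts.tsv", out / "samples.tsv")
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)


def config_from_yaml(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("delta_psi_magnitude_range", "trend_magnitude_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)
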