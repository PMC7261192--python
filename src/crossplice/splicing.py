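"""PSI quantification and knockdown-vs-control splicing calls from targeted isoform counts.

The input is a long-format count table from a targeted splicing assay
(RASL-seq style): for every alternative-splicing event and every sample,
a read count supporting the long (exon-included) isoform and one supporting
the short (exon-skipped) isoform.  Percent spliced in (PSI) is the percent
of reads supporting the long isoform,

    PSI = 100 * long / (long + short),

and a knockdown-vs-control comparison reports dPSI = mean PSI(knockdown) -
mean PSI(control) in percentage points, with a two-sided unpaired Student's
t-test on per-replicate PSI values.  An event is called significant when
|dPSI| > dpsi_threshold (strict) AND p < alpha.  No multiple-testing
correction is applied by default: the calling rule is the raw
|dPSI| > 10 / p < 0.05 filter, reproduced deliberately; apply an FDR step
downstream if your design needs one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

COUNT_COLUMNS = ["event_id", "sample_id", "long_count", "short_count"]
SHEET_COLUMNS = ["sample_id", "condition", "replicate"]


class CountTableError(ValueError):
    """Raised when a count table or sample sheet violates its contract."""


@dataclass
class EventCountTable:
    """Validated isoform counts plus sample metadata.

    counts : long-format frame with columns event_id, sample_id,
        long_count, short_count (non-negative integers; each
        (event, sample) pair at most once).
    samples : sample sheet with columns sample_id, condition, replicate
        (plus optional extras such as stimulation).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_counts(self.counts)
        _validate_samples(self.samples)
        unknown = set(self.counts["sample_id"]) - set(self.samples["sample_id"])
        if unknown:
            raise CountTableError(
                f"samples present in counts but absent from sample sheet: {sorted(unknown)}"
            )

    @property
    def event_ids(self) -> list[str]:
        return list(pd.unique(self.counts["event_id"]))

    @property
    def n_events(self) -> int:
        return self.counts["event_id"].nunique()

    def write_tsv(self, counts_path, sheet_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index=False)
        self.samples.to_csv(sheet_path, sep="\t", index=False)


def _validate_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise CountTableError(f"count table is missing columns: {missing}")
    for col in ("long_count", "short_count"):
        vals = counts[col]
        if not np.issubdtype(vals.dtype, np.integer):
            # allow float columns that are exactly integral (common after IO)
            if not np.all(np.asarray(vals) == np.floor(np.asarray(vals))):
                bad = counts.index[np.asarray(vals) != np.floor(np.asarray(vals))]
                raise CountTableError(
                    f"non-integer values in {col} at rows {list(bad[:5])} (0-based data rows)"
                )
        neg = counts.index[vals < 0]
        if len(neg):
            rows = ", ".join(str(i) for i in neg[:5])
            raise CountTableError(
                f"negative values in {col} at data rows [{rows}] "
                f"(file lines {[i + 2 for i in neg[:5]]} counting the header)"
            )
    dup = counts.duplicated(subset=["event_id", "sample_id"])
    if dup.any():
        rows = list(counts.index[dup][:5])
        raise CountTableError(f"duplicate (event_id, sample_id) pairs at data rows {rows}")


def _validate_samples(samples: pd.DataFrame) -> None:
    missing = [c for c in SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise CountTableError(f"sample sheet is missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        raise CountTableError("duplicate sample_id in sample sheet")


def read_count_table(path, sample_sheet_path) -> EventCountTable:
    """Read and validate a count table TSV and its sample sheet.

    Malformed rows (negative or non-integer counts, duplicated
    (event, sample) pairs, samples missing from the sheet) raise
    CountTableError naming the offending rows.
    """
    counts = pd.read_csv(path, sep="\t")
    samples = pd.read_csv(sample_sheet_path, sep="\t")
    table = EventCountTable(counts=counts, samples=samples)
    table.counts["long_count"] = table.counts["long_count"].astype(np.int64)
    table.counts["short_count"] = table.counts["short_count"].astype(np.int64)
    return table


def filter_events(table: EventCountTable, min_mean_reads: float = 10.0) -> EventCountTable:
    """Keep events whose mean total reads across ALL samples is strictly > threshold.

    The comparison is strict: an event whose mean equals min_mean_reads is
    dropped.  Lowering the threshold can only add events back (monotone).
    """
    totals = table.counts["long_count"] + table.counts["short_count"]
    mean_per_event = totals.groupby(table.counts["event_id"]).mean()
    keep = set(mean_per_event.index[mean_per_event > min_mean_reads])
    kept = table.counts[table.counts["event_id"].isin(keep)].reset_index(drop=True)
    return EventCountTable(counts=kept, samples=table.samples)


def compute_psi(table: EventCountTable) -> pd.DataFrame:
    """PSI matrix (events x samples) in percent; NaN where total reads are zero.

    Cells with zero total reads are undefined and are excluded from group
    means and t-tests downstream, never imputed.
    """
    df = table.counts.copy()
    total = df["long_count"] + df["short_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["psi"] = 100.0 * df["long_count"] / total
    df.loc[total == 0, "psi"] = np.nan
    mat = df.pivot(index="event_id", columns="sample_id", values="psi")
    # preserve first-appearance event order
    mat = mat.reindex(index=pd.unique(table.counts["event_id"]))
    return mat


@dataclass
class ComparisonResult:
    """Per-event calls for one knockdown-vs-control comparison.

    calls : frame with event_id, mean_psi_ctrl, mean_psi_kd, delta_psi,
        p_value, significant, direction (sign of delta_psi).
    untestable : event_ids with fewer than 2 defined PSI replicates in
        either group.
    """

    calls: pd.DataFrame
    untestable: list = field(default_factory=list)
    group_kd: str = ""
    group_ctrl: str = ""


def _group_columns(samples: pd.DataFrame, condition: str) -> list:
    ids = samples.loc[samples["condition"] == condition, "sample_id"].tolist()
    if not ids:
        raise ValueError(f"condition {condition!r} absent from sample sheet")
    return ids


def compare_conditions(
    psi: pd.DataFrame,
    samples: pd.DataFrame,
    group_kd: str,
    group_ctrl: str,
    dpsi_threshold: float = 10.0,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> ComparisonResult:
    """Call differential splicing between a knockdown and a control group.

    Per event: dPSI = mean PSI(kd) - mean PSI(ctrl) on defined replicates;
    two-sided Student's t-test (equal variance by default; set
    equal_var=False for Welch).  significant <=> |dPSI| > dpsi_threshold
    (strict) and p < alpha.  Events with fewer than 2 defined replicates
    in either group are returned as untestable, not called.
    """
    kd_cols = _group_columns(samples, group_kd)
    ctrl_cols = _group_columns(samples, group_ctrl)
    kd = psi[kd_cols].to_numpy(dtype=float)
    ctrl = psi[ctrl_cols].to_numpy(dtype=float)

    n_kd = np.sum(~np.isnan(kd), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    testable = (n_kd >= 2) & (n_ctrl >= 2)

    mean_kd = np.nanmean(np.where(np.isnan(kd), np.nan, kd), axis=1)
    mean_ctrl = np.nanmean(np.where(np.isnan(ctrl), np.nan, ctrl), axis=1)
    delta = mean_kd - mean_ctrl

    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(
            kd, ctrl, axis=1, equal_var=equal_var, nan_policy="omit"
        )
    pvals = np.asarray(t_res.pvalue, dtype=float)
    # zero pooled variance: identical groups -> p = 1; any difference -> p -> 0
    degenerate = np.isnan(pvals) & testable
    pvals[degenerate & (delta == 0)] = 1.0
    pvals[degenerate & (delta != 0)] = 0.0

    significant = testable & (np.abs(delta) > dpsi_threshold) & (pvals < alpha)
    calls = pd.DataFrame(
        {
            "event_id": psi.index,
            "mean_psi_ctrl": mean_ctrl,
            "mean_psi_kd": mean_kd,
            "delta_psi": delta,
            "p_value": pvals,
            "significant": significant,
            "direction": np.sign(delta).astype(int),
        }
    )
    untestable = calls.loc[~testable, "event_id"].tolist()
    calls = calls[testable].reset_index(drop=True)
    return ComparisonResult(
        calls=calls, untestable=untestable, group_kd=group_kd, group_ctrl=group_ctrl
    )


def validate_concordance(
    rasl_delta_psi: float,
    rtpcr_psi_ctrl,
    rtpcr_psi_kd,
    dpsi_threshold: float = 10.0,
    alpha: float = 0.05,
) -> str:
    """Check an orthogonal RT-PCR measurement against a sequencing-based call.

    Returns 'validated' when the RT-PCR dPSI has the same sign as the
    sequencing call, |dPSI| > dpsi_threshold and the RT-PCR t-test gives
    p < alpha; 'not_validated' otherwise; 'untestable' when either
    condition has fewer than 2 replicates.
    """
    ctrl = np.asarray(rtpcr_psi_ctrl, dtype=float)
    kd = np.asarray(rtpcr_psi_kd, dtype=float)
    ctrl = ctrl[~np.isnan(ctrl)]
    kd = kd[~np.isnan(kd)]
    if len(ctrl) < 2 or len(kd) < 2:
        return "untestable"
    delta = kd.mean() - ctrl.mean()
    if delta == 0:
        return "not_validated"
    p = stats.ttest_ind(kd, ctrl, equal_var=True).pvalue
    if np.isnan(p):
        p = 0.0  # zero-variance groups with a nonzero difference
    same_sign = np.sign(delta) == np.sign(rasl_delta_psi)
    if same_sign and abs(delta) > dpsi_threshold and p < alpha:
        return "validated"
    return "not_validated"


def write_calls_tsv(result: ComparisonResult, path) -> None:
    result.calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t")
    calls["significant"] = calls["significant"].astype(bool)
    return calls
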