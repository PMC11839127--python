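"""Barcode-, element- and replicate-level filtering and aggregation.

The fixed QC order is: count floor (DNA or RNA < 5 drops the barcode in
that replicate) -> Tukey-fence outlier removal on barcode-level
log2(RNA/DNA) within each (element, replicate, condition) -> aggregation
to element sums with depth normalization -> replicate correlation QC ->
element availability filters (>= 5 retained barcodes per replicate,
element present in >= 10 retained replicates per condition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    min_reads: int = 5            # count floor on DNA and RNA
    min_barcodes: int = 5         # retained barcodes per element-replicate
    min_replicates: int = 10      # retained replicates per element-condition
    replicate_r_threshold: float = 0.7
    min_dna_size_factor: float = 0.10
    pseudocount: float = 0.5
    tukey_coef: float = 1.5
    attrition: dict = field(default_factory=dict)


def filter_low_counts(counts: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Drop (barcode, replicate, condition) rows with DNA or RNA below the floor.

    The floor is strict ("less than"): dna == min_reads is retained.
    """
    keep = (counts["dna"] >= min_reads) & (counts["rna"] >= min_reads)
    return counts[keep].reset_index(drop=True)


def tukey_hinges(x: np.ndarray) -> tuple[float, float]:
    """Lower and upper Tukey hinges (the fivenum convention).

    Hinges are medians of the lower/upper half of the sorted data with
    the overall median included in both halves when n is odd.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty vector")
    n4 = np.floor((n + 3) / 2) / 2
    lo = 0.5 * (x[int(np.floor(n4)) - 1] + x[int(np.ceil(n4)) - 1])
    hi = 0.5 * (x[n - int(np.floor(n4))] + x[n - int(np.ceil(n4))])
    return float(lo), float(hi)


def tukey_outliers(x: np.ndarray, coef: float = 1.5) -> np.ndarray:
    """Boolean mask of values outside the Tukey fences [H1-c*IQR, H3+c*IQR]."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.zeros(len(x), dtype=bool)
    h1, h3 = tukey_hinges(x)
    iqr = h3 - h1
    return (x < h1 - coef * iqr) | (x > h3 + coef * iqr)


def flag_outlier_barcodes(counts: pd.DataFrame,
                          coef: float = 1.5) -> pd.Series:
    """Flag outlier barcodes on log2(rna/dna) within (element, replicate, condition).

    Counts must already have passed the count floor so ratios are finite.
    Returns a boolean Series aligned with ``counts``.
    """
    ratio = np.log2(counts["rna"].to_numpy(float) /
                    counts["dna"].to_numpy(float))
    work = counts[["element_id", "replicate", "condition"]].copy()
    work["_ratio"] = ratio
    flags = (
        work.groupby(["element_id", "replicate", "condition"],
                     sort=False, observed=True)["_ratio"]
        .transform(lambda v: tukey_outliers(v.to_numpy(), coef))
    )
    return flags.astype(bool)


def library_size_factors(counts: pd.DataFrame) -> pd.DataFrame:
    """Per (replicate, condition) DNA/RNA totals scaled to mean 1."""
    tot = counts.groupby(["replicate", "condition"], observed=True)[
        ["dna", "rna"]].sum()
    out = pd.DataFrame({
        "dna_factor": tot["dna"] / tot["dna"].mean(),
        "rna_factor": tot["rna"] / tot["rna"].mean(),
    }).reset_index()
    return out


def aggregate_elements(counts: pd.DataFrame,
                       flags: pd.Series | None = None,
                       size_factors: pd.DataFrame | None = None,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """Sum retained barcode counts per (element, replicate, condition).

    Depth-normalized log2 ratio uses the configured pseudocount on both
    scaled sums: log2((rna_sum/s_rna + c) / (dna_sum/s_dna + c)).
    """
    work = counts if flags is None else counts[~flags.to_numpy()]
    agg = (
        work.groupby(["element_id", "replicate", "condition"],
                     sort=True, observed=True)
        .agg(dna_sum=("dna", "sum"), rna_sum=("rna", "sum"),
             n_barcodes_retained=("barcode", "nunique"))
        .reset_index()
    )
    if size_factors is None:
        size_factors = library_size_factors(work)
    agg = agg.merge(size_factors, on=["replicate", "condition"], how="left")
    agg["log2_ratio"] = np.log2(
        (agg["rna_sum"] / agg["rna_factor"] + pseudocount) /
        (agg["dna_sum"] / agg["dna_factor"] + pseudocount))
    return agg


def qc_replicates(summaries: pd.DataFrame,
                  r_threshold: float = 0.7
                  ) -> tuple[pd.DataFrame, dict]:
    """Drop replicates poorly correlated with the others within a condition.

    Pairwise Pearson correlations are computed on the per-element
    log2-ratio vectors; a replicate is dropped when its median
    correlation to the other replicates falls below the threshold.
    Returns the filtered summaries and a report with the correlation
    matrices and dropped replicates per condition.
    """
    report: dict = {"dropped": {}, "correlations": {}}
    keep_frames = []
    for cond, sub in summaries.groupby("condition", observed=True):
        reps = sorted(sub["replicate"].unique())
        if len(reps) < 3:
            log.warning("condition %s: <3 replicates, replicate QC skipped", cond)
            keep_frames.append(sub)
            continue
        mat = sub.pivot_table(index="element_id", columns="replicate",
                              values="log2_ratio")
        corr = mat.corr(method="pearson")
        med = corr.where(~np.eye(len(corr), dtype=bool)).median()
        dropped = [int(r) for r in med.index[med < r_threshold]]
        report["correlations"][str(cond)] = corr.round(4).to_dict()
        report["dropped"][str(cond)] = dropped
        for r in dropped:
            log.info("condition %s: replicate %s dropped (median r=%.3f)",
                     cond, r, med[r])
        keep_frames.append(sub[~sub["replicate"].isin(dropped)])
    return pd.concat(keep_frames, ignore_index=True), report


def filter_elements(summaries: pd.DataFrame,
                    min_barcodes: int = 5,
                    min_replicates: int = 10) -> pd.DataFrame:
    """Apply element availability filters.

    Keeps (element, replicate) rows backed by at least ``min_barcodes``
    retained barcodes, then keeps elements present in at least
    ``min_replicates`` retained replicates within each condition.
    """
    out = summaries[summaries["n_barcodes_retained"] >= min_barcodes]
    n_reps = out.groupby(["element_id", "condition"], observed=True)[
        "replicate"].transform("nunique")
    return out[n_reps >= min_replicates].reset_index(drop=True)


def run_qc(counts: pd.DataFrame, config: QCConfig | None = None
           ) -> tuple[pd.DataFrame, dict]:
    """Full QC chain; returns analysis-ready summaries and an attrition report."""
    cfg = config or QCConfig()
    report: dict = {"input_rows": int(len(counts))}

    filtered = filter_low_counts(counts, cfg.min_reads)
    report["after_count_floor"] = int(len(filtered))

    flags = flag_outlier_barcodes(filtered, cfg.tukey_coef)
    report["outlier_barcodes_flagged"] = int(flags.sum())

    retained = filtered[~flags.to_numpy()]
    factors = library_size_factors(retained)
    low_dna = factors[factors["dna_factor"] < cfg.min_dna_size_factor]
    if len(low_dna):
        bad = set(map(tuple, low_dna[["replicate", "condition"]].to_numpy()))
        log.info("excluding %d replicate(s) with DNA size factor < %.2f",
                 len(bad), cfg.min_dna_size_factor)
        keep = ~retained.set_index(["replicate", "condition"]).index.isin(bad)
        retained = retained[keep]
        factors = library_size_factors(retained)
    report["low_dna_factor_replicates"] = int(len(low_dna))

    summaries = aggregate_elements(retained, None, factors, cfg.pseudocount)
    summaries, rep_report = qc_replicates(summaries, cfg.replicate_r_threshold)
    report["replicate_qc"] = rep_report

    final = filter_elements(summaries, cfg.min_barcodes, cfg.min_replicates)
    report["final_rows"] = int(len(final))
    report["final_elements"] = int(final["element_id"].nunique())
    return final, report
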