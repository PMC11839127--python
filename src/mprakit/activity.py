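"""Element activity estimation and calling against scrambled negatives.

The transcription-rate estimate alpha for an element is the ratio of
depth-normalized summed RNA to summed DNA across retained replicates.
Activity is called with a robust z-score (MAD score) of log2(alpha)
against the distribution of the scrambled negative controls, one-sided
(activity above the null), followed by Benjamini-Hochberg adjustment at
FDR < 0.1.  Condition-differential activity uses a Welch two-sample t
test on replicate-level log2 ratios for elements measured in both
conditions and active in at least one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss

from .stats import bh_adjust

MAD_CONSTANT = 1.4826  # normal-consistency scale factor


@dataclass
class ActivityConfig:
    fdr_threshold: float = 0.1
    pseudocount: float = 0.5
    min_negative_controls: int = 20


def estimate_alpha(summaries: pd.DataFrame,
                   pseudocount: float = 0.5) -> pd.DataFrame:
    """Per (element, condition) transcription-rate estimate.

    alpha = (sum_r rna_sum_r / s_rna_r) / (sum_r dna_sum_r / s_dna_r);
    log2_alpha adds the pseudocount to numerator and denominator.
    Elements with a zero DNA denominator are excluded with a reason code.
    """
    work = summaries.copy()
    work["rna_norm"] = work["rna_sum"] / work["rna_factor"]
    work["dna_norm"] = work["dna_sum"] / work["dna_factor"]
    agg = (
        work.groupby(["element_id", "condition"], sort=True, observed=True)
        .agg(rna_total=("rna_norm", "sum"), dna_total=("dna_norm", "sum"),
             n_replicates=("replicate", "nunique"))
        .reset_index()
    )
    bad = agg["dna_total"] <= 0
    agg.loc[bad, "exclusion_reason"] = "zero_dna_denominator"
    agg = agg[~bad].copy()
    agg["alpha"] = agg["rna_total"] / agg["dna_total"]
    agg["log2_alpha"] = np.log2((agg["rna_total"] + pseudocount) /
                                (agg["dna_total"] + pseudocount))
    return agg.drop(columns=["rna_total", "dna_total"])


def mad_test(results: pd.DataFrame, negative_control_ids,
             min_negatives: int = 20) -> pd.DataFrame:
    """Robust z (MAD score) and one-sided p against the negative-control null.

    z = (log2_alpha - median_neg) / (1.4826 * MAD_neg) per condition;
    p is the upper tail of the standard normal.
    """
    neg_ids = set(negative_control_ids)
    out = []
    for cond, sub in results.groupby("condition", observed=True):
        neg = sub[sub["element_id"].isin(neg_ids)]["log2_alpha"].to_numpy()
        if len(neg) < min_negatives:
            raise ValueError(
                f"condition {cond}: {len(neg)} negative controls with alpha "
                f"estimates, need >= {min_negatives}")
        med = float(np.median(neg))
        mad = float(np.median(np.abs(neg - med)))
        if mad == 0:
            raise ValueError(
                f"condition {cond}: MAD of negative controls is 0; "
                "review negative controls or add jitter")
        sub = sub.copy()
        sub["mad_z"] = (sub["log2_alpha"] - med) / (MAD_CONSTANT * mad)
        sub["p"] = np.clip(ss.norm.sf(sub["mad_z"]), np.nextafter(0, 1), 1.0)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def call_active(results: pd.DataFrame, library: pd.DataFrame | None = None,
                fdr_threshold: float = 0.1
                ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """BH-adjust per condition and flag active elements.

    An element is active when FDR < threshold and its MAD z is positive.
    When the library is given, a variant-level table is also returned:
    a variant counts as active in a condition if either allele's element
    is active there.
    """
    out = []
    for _, sub in results.groupby("condition", observed=True):
        sub = sub.copy()
        sub["fdr"] = bh_adjust(sub["p"].to_numpy())
        sub["active"] = (sub["fdr"] < fdr_threshold) & (sub["mad_z"] > 0)
        out.append(sub)
    res = pd.concat(out, ignore_index=True)

    variant_level = None
    if library is not None:
        merged = res.merge(
            library[["element_id", "variant_id", "allele"]],
            on="element_id", how="left")
        paired = merged[merged["variant_id"].fillna("") != ""]
        variant_level = (
            paired.groupby(["variant_id", "condition"], observed=True)
            .agg(active=("active", "any"), n_alleles=("allele", "nunique"),
                 best_p=("p", "min"))
            .reset_index()
        )
    return res, variant_level


def differential_activity(summaries: pd.DataFrame,
                          activity: pd.DataFrame,
                          fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Welch t test of replicate log2 ratios between conditions.

    Tested only for elements measured in both conditions and active in
    at least one; delta is stimulated minus vehicle.  Elements with
    fewer than two replicates in a condition are skipped with a reason.
    """
    act = activity.pivot_table(index="element_id", columns="condition",
                               values="active", aggfunc="first")
    if act.shape[1] < 2:
        return pd.DataFrame(columns=["element_id", "delta_log2_alpha",
                                     "t", "df", "p", "fdr"])
    conditions = list(act.columns)
    veh = "vehicle" if "vehicle" in conditions else conditions[0]
    stim = next(c for c in conditions if c != veh)
    eligible = act.index[act.fillna(False).any(axis=1) & act.notna().all(axis=1)]

    rows, skipped = [], []
    grouped = summaries[summaries["element_id"].isin(eligible)].groupby(
        "element_id", observed=True)
    for eid, sub in grouped:
        x = sub.loc[sub["condition"] == stim, "log2_ratio"].to_numpy()
        y = sub.loc[sub["condition"] == veh, "log2_ratio"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            skipped.append((eid, "lt2_replicates"))
            continue
        if np.var(x) == 0 and np.var(y) == 0:
            t, p, df = 0.0, 1.0, float(len(x) + len(y) - 2)
            if not np.isclose(x.mean(), y.mean()):
                t, p = np.inf, 0.0
        else:
            tt = ss.ttest_ind(x, y, equal_var=False)
            t, p, df = float(tt.statistic), float(tt.pvalue), float(tt.df)
        rows.append(dict(element_id=eid,
                         delta_log2_alpha=float(x.mean() - y.mean()),
                         t=t, df=df, p=p))
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_threshold
    out.attrs["skipped"] = skipped
    return out
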