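"""Shared exact and adjustment statistics.

Small wrappers with fixed conventions used throughout the pipeline:
two-sided Fisher's exact test (probability-ordering rule) with both the
conditional-MLE and the sample odds ratio, Benjamini-Hochberg step-up
adjustment, the one-sided exact binomial sign test, and the 2x2
feature-enrichment harness used for all active-vs-inactive comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table [[a, b], [c, d]]."""

    odds_ratio: float  # conditional MLE (NaN when a margin is zero)
    sample_or: float  # a*d / (b*c); inf when b*c == 0 and a*d > 0
    p: float


def fisher_exact(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test.

    The two-sided p-value sums hypergeometric probabilities of all tables
    with the same margins whose probability does not exceed that of the
    observed table.  The primary odds ratio is the conditional maximum
    likelihood estimate under the noncentral hypergeometric model; the
    plain cross-product ratio is reported alongside.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    # degenerate margin: only one table is possible, nothing to test
    if min(a + b, c + d, a + c, b + d) == 0:
        return FisherResult(math.nan, _sample_or(a, b, c, d), 1.0)
    p = float(ss.fisher_exact(table, alternative="two-sided")[1])
    cmle = float(ss.contingency.odds_ratio(table, kind="conditional").statistic)
    return FisherResult(cmle, _sample_or(a, b, c, d), min(p, 1.0))


def _sample_or(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_sign_test(k: int, n: int, p0: float = 0.5,
                       alternative: str = "greater") -> float:
    """Exact binomial test of k concordant outcomes among n.

    Defaults to the one-sided upper tail P(X >= k | n, p0) used to ask
    whether directional concordance exceeds chance.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return float(ss.binomtest(k, n, p0, alternative=alternative).pvalue)


def enrich_features(
    units: pd.DataFrame,
    feature_cols: list[str],
    group_col: str = "group",
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Fisher enrichment of boolean features in a two-group unit table.

    ``units`` has one row per analysis unit with boolean feature columns
    and a ``group_col`` taking exactly the values {"target", "background"}.
    Returns one row per feature with both odds-ratio variants, the
    two-sided p, BH FDR across features and a significance flag.
    """
    groups = set(units[group_col].unique())
    if not groups <= {"target", "background"}:
        raise ValueError("group column must contain only 'target'/'background'")
    rows = []
    tgt = units[units[group_col] == "target"]
    bkg = units[units[group_col] == "background"]
    for feat in feature_cols:
        a = int(tgt[feat].sum())
        b = int(len(tgt) - a)
        c = int(bkg[feat].sum())
        d = int(len(bkg) - c)
        res = fisher_exact(a, b, c, d)
        rows.append(
            {"feature": feat, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": res.odds_ratio, "sample_or": res.sample_or,
             "p": res.p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_threshold
    return out


def dedup_variants(results: pd.DataFrame) -> pd.DataFrame:
    """Reduce an element-level activity table to one row per variant.

    Keeps, per variant, the element with the smaller activity p-value
    (higher activity); ties keep the reference allele's element.  Rows
    without a variant id (controls) are kept as-is.
    """
    res = results.copy()
    has_var = res["variant_id"].notna() & (res["variant_id"] != "")
    controls = res[~has_var]
    paired = res[has_var].copy()
    # stable tie-break: ref sorts before alt
    allele_rank = paired["allele"].map({"ref": 0, "alt": 1}).fillna(2)
    paired = paired.assign(_rank=allele_rank)
    paired = paired.sort_values(["variant_id", "p", "_rank"], kind="mergesort")
    best = paired.groupby("variant_id", sort=False).head(1).drop(columns="_rank")
    return pd.concat([best, controls], ignore_index=True)
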