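"""Allelic-effect (emVar) and genotype-by-condition interaction tests.

Allelic effects are tested on replicate-paired differences of element
log2 ratios (alt minus ref), optionally with empirical-Bayes variance
moderation: per-variant sample variances are shrunk toward a common
prior fitted as a scaled-F hyperprior, the moderated t gaining the prior
degrees of freedom.  Interactions are ordinary least squares on
replicate-level log2 ratios with allele, condition and product terms,
tested on the product coefficient.

Gating follows the analysis design: allelic tests run only for variants
where at least one allele was called active in some condition, and
interaction tests only for variants that are emVars in at least one
condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as ss
from scipy.special import polygamma, psi

from .stats import bh_adjust


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, df: int
                       ) -> tuple[float, float, np.ndarray]:
    """Fit a scaled-F hyperprior to sample variances and shrink them.

    Moment fit on log variances: with z = log(s2), the excess of
    var(z) over trigamma(df/2) identifies the prior degrees of freedom
    d0 via the trigamma function, and the centered mean of z identifies
    the prior variance s0^2.  Returns (d0, s0_sq, s2_post) where
    s2_post = (d0*s0^2 + df*s2) / (d0 + df); d0 = inf shrinks fully.
    """
    s2 = np.asarray(s2, dtype=float)
    if len(s2) < 2:
        raise ValueError("need at least 2 variances to fit the hyperprior")
    if df <= 0:
        raise ValueError("df must be positive")
    z = np.log(np.maximum(s2, 1e-12))
    e = z - float(psi(df / 2)) + np.log(df / 2)
    ebar = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2))
    if evar <= 0:
        # no excess spread over sampling noise: shrink fully; when the
        # variances are literally identical the prior is that common value
        s0_sq = float(s2[0]) if np.ptp(s2) == 0 else float(np.exp(ebar))
        return np.inf, s0_sq, np.full_like(s2, s0_sq)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(ebar + psi(d0 / 2) - np.log(d0 / 2)))
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return float(d0), s0_sq, s2_post


def test_allelic(summaries: pd.DataFrame, library: pd.DataFrame,
                 variant_activity: pd.DataFrame, condition: str,
                 moderation: bool = True,
                 fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Paired allelic test per variant within one condition.

    For each variant with both alleles retained, compute per-replicate
    differences d_r = log2_ratio(alt) - log2_ratio(ref) over common
    replicates; logFC is their mean and the t statistic uses the sample
    variance, or the moderated posterior variance when moderation is on
    (and at least 10 variants are testable).  Two-sided p from the t
    distribution; BH across tested variants; emVar at FDR < threshold.

    Variants failing the gate or missing one allele are reported with a
    reason code and no test.
    """
    lib = library[["element_id", "variant_id", "allele"]]
    sub = summaries[summaries["condition"] == condition].merge(
        lib, on="element_id")
    sub = sub[sub["variant_id"].fillna("") != ""]

    gate = variant_activity.groupby("variant_id", observed=True)["active"].any()
    active_variants = set(gate.index[gate])

    tested, untestable = [], []
    for vid, v in sub.groupby("variant_id", observed=True):
        if vid not in active_variants:
            untestable.append((vid, "no_active_allele"))
            continue
        wide = v.pivot_table(index="replicate", columns="allele",
                             values="log2_ratio")
        if "ref" not in wide.columns or "alt" not in wide.columns:
            untestable.append((vid, "allele_missing_after_qc"))
            continue
        d = (wide["alt"] - wide["ref"]).dropna().to_numpy()
        if len(d) < 2:
            untestable.append((vid, "lt2_common_replicates"))
            continue
        tested.append(dict(
            variant_id=vid, condition=condition, n=len(d),
            logFC=float(np.mean(d)), s2=float(np.var(d, ddof=1)),
        ))

    out = pd.DataFrame(tested)
    out.attrs["untestable"] = untestable
    if not len(out):
        return out

    df_resid = out["n"].to_numpy() - 1
    if moderation and len(out) >= 10:
        # hyperprior fitted at the median residual df; shrinkage applied
        # with each variant's own df
        d_fit = int(np.median(df_resid))
        d0, s0_sq, _ = moderate_variances(out["s2"].to_numpy(), d_fit)
        if np.isfinite(d0):
            s2_post = ((d0 * s0_sq + df_resid * out["s2"].to_numpy())
                       / (d0 + df_resid))
            df_total = df_resid + d0
        else:
            s2_post = np.full(len(out), s0_sq)
            df_total = np.full(len(out), np.inf)
        out["s2_post"] = s2_post
        use_s2 = s2_post
    else:
        out["s2_post"] = out["s2"]
        df_total = df_resid.astype(float)
        use_s2 = out["s2"].to_numpy()

    se = np.sqrt(use_s2 / out["n"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, out["logFC"].to_numpy() / se, 0.0)
    finite_df = np.where(np.isfinite(df_total), df_total, 1e9)
    p = 2.0 * ss.t.sf(np.abs(t), finite_df)
    zero_spread = (se == 0) & (out["logFC"].to_numpy() == 0)
    p = np.where(zero_spread, 1.0, np.clip(p, np.nextafter(0, 1), 1.0))
    out["t"] = t
    out["df_total"] = df_total
    out["p"] = p
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["emvar"] = out["fdr"] < fdr_threshold
    return out


def test_interaction(summaries: pd.DataFrame, library: pd.DataFrame,
                     emvar_calls: pd.DataFrame,
                     fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Genotype x condition interaction on replicate-level log2 ratios.

    Model: log2_ratio ~ allele + condition + allele:condition with
    allele and condition coded 0/1 (alt = 1, stimulated = 1); the t test
    is on the product coefficient.  Tested only for variants that are
    emVars in at least one condition, with both alleles measured in both
    conditions; rank-deficient designs (an empty cell) are skipped.
    """
    gate = emvar_calls.groupby("variant_id", observed=True)["emvar"].any()
    emvars = set(gate.index[gate])

    lib = library[["element_id", "variant_id", "allele"]]
    sub = summaries.merge(lib, on="element_id")
    sub = sub[sub["variant_id"].isin(emvars)]

    rows, skipped = [], []
    for vid, v in sub.groupby("variant_id", observed=True):
        g = (v["allele"] == "alt").to_numpy(float)
        c = (v["condition"] == "stim").to_numpy(float)
        y = v["log2_ratio"].to_numpy(float)
        cells = {(int(gi), int(ci)) for gi, ci in zip(g, c)}
        if len(cells) < 4:
            skipped.append((vid, "missing_design_cell"))
            continue
        X = np.column_stack([np.ones_like(g), g, c, g * c])
        n, k = X.shape
        if n <= k:
            skipped.append((vid, "insufficient_replicates"))
            continue
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < k:
            skipped.append((vid, "rank_deficient"))
            continue
        resid = y - X @ coef
        dof = n - k
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
        beta = float(coef[3])
        if se == 0:
            t, p = (0.0, 1.0) if beta == 0 else (np.inf, 0.0)
        else:
            t = beta / se
            p = float(2.0 * ss.t.sf(abs(t), dof))
        rows.append(dict(variant_id=vid, beta_interaction=beta, se=se,
                         t=t, df=dof, p=max(p, np.nextafter(0, 1))))
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_threshold
    return out
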