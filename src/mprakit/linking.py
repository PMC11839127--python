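"""Gene linking, concordance with condition-dependent expression, and
regional TF-expression regression.

Elements link to genes either through promoter windows (2 kb upstream of
the TSS, closed at the far edge and open at the TSS) or through
chromatin-loop anchors (element in one anchor, gene TSS in the mate
anchor, symmetric in anchor order).  Concordance between
condition-differential element activity and differential gene
expression is tested with the one-sided binomial sign test.  Regional
analysis regresses per-region association z-scores (signed toward the
motif-matching allele) on mean regional TF expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats as ss
from intervaltree import IntervalTree

from .stats import bh_adjust, binomial_sign_test

log = logging.getLogger(__name__)

PROMOTER_BP = 2000


def read_gtf_tss(path) -> pd.DataFrame:
    """Extract per-gene TSS from a GTF (1-based closed coordinates).

    TSS is the start of a + strand gene and the end of a - strand gene,
    taken from ``gene`` records (or the minimum feature span per gene).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "source", "feature", "start", "end",
                            "score", "strand", "frame", "attrs"])
    df["gene_id"] = df["attrs"].str.extract(r'gene_id "([^"]+)"')
    rows = []
    for gid, g in df.groupby("gene_id", observed=True):
        g0 = g[g["feature"] == "gene"]
        g0 = g0 if len(g0) else g
        strand = g0.iloc[0]["strand"]
        if strand not in "+-":
            log.info("gene %s has no strand; skipped", gid)
            continue
        tss = int(g0["start"].min()) if strand == "+" else int(g0["end"].max())
        rows.append(dict(gene_id=gid, chrom=g0.iloc[0]["chrom"],
                         strand=strand, tss=tss))
    return pd.DataFrame(rows)


def promoter_window(tss: int, strand: str,
                    size: int = PROMOTER_BP) -> tuple[int, int]:
    """Promoter interval in 0-based half-open coordinates.

    A + strand gene with 1-based TSS t has promoter [t-1-size, t-1); on
    the - strand the window is the mirror image (t, t+size] in 1-based
    closed terms, i.e. [t, t+size) half-open.
    """
    t0 = tss - 1  # 0-based TSS position
    if strand == "+":
        return max(t0 - size, 0), t0
    return t0 + 1, t0 + 1 + size


def link_promoters(elements: pd.DataFrame, genes: pd.DataFrame,
                   size: int = PROMOTER_BP) -> pd.DataFrame:
    """Link elements overlapping any gene's promoter window."""
    trees: dict[str, IntervalTree] = {}
    for _, g in genes.iterrows():
        lo, hi = promoter_window(int(g["tss"]), g["strand"], size)
        if hi <= lo:
            continue
        trees.setdefault(str(g["chrom"]), IntervalTree()).addi(
            lo, hi, g["gene_id"])
    rows = []
    for _, el in elements.iterrows():
        tree = trees.get(str(el["chrom"]))
        if tree is None:
            continue
        for iv in sorted(tree.overlap(int(el["start"]), int(el["end"]))):
            rows.append(dict(element_id=el["element_id"], gene_id=iv.data,
                             mechanism="promoter"))
    return pd.DataFrame(rows, columns=["element_id", "gene_id", "mechanism"])


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :6]
    df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    bad = (df["end1"] <= df["start1"]) | (df["end2"] <= df["start2"])
    if bad.any():
        log.info("skipped %d malformed BEDPE row(s)", int(bad.sum()))
    return df[~bad].reset_index(drop=True)


def link_loops(elements: pd.DataFrame, loops: pd.DataFrame,
               genes: pd.DataFrame, tissue_zone: str = "") -> pd.DataFrame:
    """Link elements to genes through loop anchors (symmetric, deduped)."""
    def overlaps(chrom, start, end, row, side):
        return (str(row[f"chrom{side}"]) == str(chrom)
                and int(row[f"start{side}"]) < end
                and start < int(row[f"end{side}"]))

    pairs = set()
    for _, loop in loops.iterrows():
        for el_side, gene_side in ((1, 2), (2, 1)):
            hit_elems = [
                el["element_id"] for _, el in elements.iterrows()
                if overlaps(el["chrom"], int(el["start"]), int(el["end"]),
                            loop, el_side)]
            if not hit_elems:
                continue
            for _, g in genes.iterrows():
                t0 = int(g["tss"]) - 1
                if overlaps(g["chrom"], t0, t0 + 1, loop, gene_side):
                    for eid in hit_elems:
                        pairs.add((eid, g["gene_id"]))
    rows = [dict(element_id=e, gene_id=g, mechanism="loop",
                 tissue_zone=tissue_zone)
            for e, g in sorted(pairs)]
    return pd.DataFrame(rows, columns=["element_id", "gene_id", "mechanism",
                                       "tissue_zone"])


def concordance_test(diff_activity: pd.DataFrame, de_table: pd.DataFrame,
                     links: pd.DataFrame,
                     de_fdr: float = 0.1) -> dict:
    """Directional concordance of element activity change and gene DE.

    For linked (element, gene) pairs where the element shows significant
    condition-differential activity and the gene is differentially
    expressed (FDR < ``de_fdr``), concordance means same sign of the two
    effects; tested one-sided against 0.5.
    """
    de = de_table[de_table["fdr"] < de_fdr]
    sig = diff_activity[diff_activity["significant"]] \
        if "significant" in diff_activity.columns else diff_activity
    merged = (links.merge(sig[["element_id", "delta_log2_alpha"]],
                          on="element_id")
              .merge(de[["gene_id", "log2fc"]], on="gene_id"))
    n = len(merged)
    if n == 0:
        return dict(n_pairs=0, n_concordant=0, percent_concordant=np.nan,
                    p=np.nan, note="no testable pairs")
    conc = int((np.sign(merged["delta_log2_alpha"])
                == np.sign(merged["log2fc"])).sum())
    return dict(n_pairs=n, n_concordant=conc,
                percent_concordant=100.0 * conc / n,
                p=binomial_sign_test(conc, n), note="")


def gwas_z(beta: float, se: float, matched_is_effect_allele: bool) -> float:
    """Association z-score signed toward the motif-matching allele."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = beta / se
    return z if matched_is_effect_allele else -z


def map_regions(dk_values: pd.DataFrame, region_map: pd.DataFrame
                ) -> pd.DataFrame:
    """Average fine-parcellation (DK) values within macroscale regions.

    ``region_map`` maps dk_region -> macro_region (many-to-one).
    ``dk_values`` has columns (dk_region, value).
    """
    merged = dk_values.merge(region_map, on="dk_region")
    return (merged.groupby("macro_region", observed=True)["value"]
            .mean().reset_index())


def regional_regression(expression: pd.DataFrame,
                        gwas_regional: pd.DataFrame,
                        min_regions: int = 3) -> pd.DataFrame:
    """Regress regional z on mean regional TF expression per (variant, TF).

    ``expression`` is region x TF-gene (already averaged over ages);
    ``gwas_regional`` has columns (variant_id, tf_gene, region, z).
    Pairs with fewer than ``min_regions`` shared regions or constant
    expression are skipped; BH is applied across all fitted pairs.
    """
    rows = []
    for (vid, tf), g in gwas_regional.groupby(["variant_id", "tf_gene"],
                                              observed=True):
        if tf not in expression.columns:
            rows.append(dict(variant_id=vid, tf_gene=tf, n_regions=0,
                             slope=np.nan, intercept=np.nan, r=np.nan,
                             p=np.nan, note="tf_not_in_expression"))
            continue
        common = g[g["region"].isin(expression.index)]
        if len(common) < min_regions:
            rows.append(dict(variant_id=vid, tf_gene=tf,
                             n_regions=len(common), slope=np.nan,
                             intercept=np.nan, r=np.nan, p=np.nan,
                             note="too_few_regions"))
            continue
        x = expression.loc[common["region"], tf].to_numpy(float)
        y = common["z"].to_numpy(float)
        if np.std(x) == 0:
            rows.append(dict(variant_id=vid, tf_gene=tf,
                             n_regions=len(common), slope=np.nan,
                             intercept=np.nan, r=np.nan, p=np.nan,
                             note="constant_expression"))
            continue
        fit = ss.linregress(x, y)
        rows.append(dict(variant_id=vid, tf_gene=tf, n_regions=len(common),
                         slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r=float(fit.rvalue), p=float(fit.pvalue), note=""))
    out = pd.DataFrame(rows)
    fitted = out["note"] == ""
    if fitted.any():
        out.loc[fitted, "fdr"] = bh_adjust(out.loc[fitted, "p"].to_numpy())
    return out
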