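"""Planted-effect recovery evaluation on the synthetic study.

Runs the full statistical chain (QC -> activity -> allelic ->
interaction) on a generated study with known truth and measures how well
the planted effects are recovered: sensitivity and empirical FDR of
activity calls, bias of the allelic log-fold-change estimate, and
detection power for condition interactions.  The default study
conditions are 200 variants (400 allele elements) plus 50 scrambled
negatives, 14 replicates per condition, negative-binomial dispersion
0.1, with multiplicative activity log2 alpha = 2 planted for 10% of
variants, allelic log2 fold-change 1 for 10%, and interaction
coefficient 1 for 5%.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import activity as act
from . import allelic as allelic_mod
from . import qc, simulate

RECOVERY_CONDITIONS = dict(
    n_variants=200, n_negative_controls=50,
    n_replicates_per_condition=14, nb_dispersion=0.1,
    frac_active=0.10, frac_emvar=0.10, frac_interaction=0.05,
    active_log2_alpha=2.0, allelic_lfc=1.0, interaction_beta=1.0)


def evaluate_recovery(seed: int,
                      config: simulate.SimulationConfig | None = None,
                      n_runs: int = 1) -> dict:
    """Score planted-effect recovery, averaged over ``n_runs`` studies.

    A single run yields a false discovery *proportion*; the false
    discovery *rate* is its expectation, so with ``n_runs > 1`` the
    study is regenerated with seeds derived from ``seed`` and each
    metric is the mean over runs (an ``<metric>_mc_se`` entry gives the
    Monte Carlo standard error of that mean).
    """
    if n_runs > 1:
        runs = [evaluate_recovery((int(seed) + 9973 * k) % 2 ** 31, config)
                for k in range(n_runs)]
        out: dict = {}
        for key in runs[0]:
            vals = np.array([r[key]["value"] for r in runs], dtype=float)
            out[key] = {"value": float(np.nanmean(vals)),
                        "n": int(sum(r[key]["n"] for r in runs))}
            out[key]["mc_se"] = float(np.nanstd(vals, ddof=1)
                                      / np.sqrt(n_runs))
        return out

    if config is None:
        config = simulate.SimulationConfig(**RECOVERY_CONDITIONS)
    config = dataclasses.replace(config, rng_seed=int(seed))

    library, truth = simulate.generate_library(config)
    counts = simulate.generate_counts(library, truth, config)
    summaries, report = qc.run_qc(counts)

    negatives = library.loc[library["category"] == "negative_control",
                            "element_id"]
    alphas = act.estimate_alpha(summaries)
    tested = act.mad_test(alphas, negatives)
    results, variant_activity = act.call_active(tested, library)

    # activity recovery, scored on variant elements in the vehicle condition
    merged = results.merge(truth, on="element_id")
    veh = merged[(merged["condition"] == "vehicle")
                 & (merged["variant_id"] != "")]
    tp = int((veh["active"] & veh["is_active"]).sum())
    fp = int((veh["active"] & ~veh["is_active"]).sum())
    fn = int((~veh["active"] & veh["is_active"]).sum())
    sensitivity = tp / (tp + fn) if tp + fn else np.nan
    empirical_fdr = fp / (tp + fp) if tp + fp else 0.0

    # allelic recovery in the vehicle condition
    emv_veh = allelic_mod.test_allelic(summaries, library, variant_activity,
                                       "vehicle", moderation=True)
    emv_stim = allelic_mod.test_allelic(summaries, library, variant_activity,
                                        "stim", moderation=True)
    var_truth = truth[truth["element_id"].str.endswith("_ref")][
        ["variant_id", "true_allelic_lfc", "is_emvar", "is_interaction"]]
    em = emv_veh.merge(var_truth, on="variant_id")
    planted = em[em["true_allelic_lfc"] != 0]
    logfc_mean = float(planted["logFC"].mean()) if len(planted) else np.nan
    emvar_power = float(planted["emvar"].mean()) if len(planted) else np.nan

    # interaction recovery
    inter = allelic_mod.test_interaction(
        summaries, library, pd.concat([emv_veh, emv_stim],
                                      ignore_index=True))
    im = inter.merge(var_truth, on="variant_id")
    pl = im[im["is_interaction"]]
    interaction_power = float(pl["significant"].mean()) if len(pl) else np.nan

    n_variant_elements = int(len(veh))
    return {
        "active_call_sensitivity": {
            "value": float(sensitivity), "n": n_variant_elements},
        "active_call_empirical_fdr": {
            "value": float(empirical_fdr), "n": n_variant_elements},
        "allelic_logfc_mean_planted": {
            "value": logfc_mean, "n": int(len(planted))},
        "allelic_logfc_abs_bias": {
            "value": float(abs(logfc_mean - config.allelic_lfc)),
            "n": int(len(planted))},
        "emvar_detection_power": {
            "value": emvar_power, "n": int(len(planted))},
        "interaction_detection_power": {
            "value": interaction_power, "n": int(len(pl))},
        "elements_retained_after_qc": {
            "value": float(summaries["element_id"].nunique()),
            "n": int(len(library))},
        "mean_barcodes_per_element_after_qc": {
            "value": float(summaries["n_barcodes_retained"].mean()),
            "n": int(len(summaries))},
    }
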