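"""Allelic (emVar) tests, variance moderation, and interaction model."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from conftest import make_summaries
from mprakit import allelic


def paired_setup(d_by_variant, conditions=("vehicle",), active=None):
    """Build (summaries, library, variant_activity) from per-replicate
    alt-ref differences; ref log-ratio is 0 in every replicate."""
    rows, lib_rows, act_rows = [], [], []
    for vid, d in d_by_variant.items():
        for allele in ("ref", "alt"):
            lib_rows.append(dict(element_id=f"{vid}_{allele}",
                                 variant_id=vid, allele=allele))
        for cond in conditions:
            for r, dv in enumerate(d, start=1):
                rows.append((f"{vid}_ref", r, cond, 0.0))
                rows.append((f"{vid}_alt", r, cond, float(dv)))
            act_rows.append(dict(variant_id=vid, condition=cond,
                                 active=(active is None or vid in active)))
    return (make_summaries(rows), pd.DataFrame(lib_rows),
            pd.DataFrame(act_rows))


class TestAllelic:
    def test_closed_form_paired_t(self):
        summ, lib, act = paired_setup({"v1": [0.9, 1.0, 1.1]})
        res = allelic.test_allelic(summ, lib, act, "vehicle",
                                   moderation=False)
        row = res.iloc[0]
        assert row["logFC"] == pytest.approx(1.0)
        assert row["t"] == pytest.approx(17.3205, abs=1e-3)
        assert row["p"] == pytest.approx(2 * ss.t.sf(17.3205, 2), rel=1e-3)
        assert row["p"] == pytest.approx(3.32e-3, rel=0.01)

    def test_zero_differences_null(self):
        summ, lib, act = paired_setup({"v1": [0.0, 0.0, 0.0, 0.0]})
        res = allelic.test_allelic(summ, lib, act, "vehicle",
                                   moderation=False)
        assert res.iloc[0]["logFC"] == 0.0
        assert res.iloc[0]["p"] == 1.0

    def test_gating_excludes_inactive_variants(self):
        summ, lib, act = paired_setup({"v1": [1.0, 1.0], "v2": [1.0, 1.0]},
                                      active={"v1"})
        res = allelic.test_allelic(summ, lib, act, "vehicle",
                                   moderation=False)
        assert set(res["variant_id"]) == {"v1"}
        assert ("v2", "no_active_allele") in res.attrs["untestable"]

    def test_missing_allele_reported_untestable(self):
        summ, lib, act = paired_setup({"v1": [1.0, 1.0, 1.0]})
        summ = summ[summ["element_id"] != "v1_ref"]
        res = allelic.test_allelic(summ, lib, act, "vehicle")
        assert len(res) == 0
        assert ("v1", "allele_missing_after_qc") in res.attrs["untestable"]

    def test_label_swap_negates_logfc(self):
        summ, lib, act = paired_setup({"v1": [0.8, 1.2, 1.0]})
        swapped_lib = lib.copy()
        swapped_lib["allele"] = swapped_lib["allele"].map(
            {"ref": "alt", "alt": "ref"})
        r1 = allelic.test_allelic(summ, lib, act, "vehicle", moderation=False)
        r2 = allelic.test_allelic(summ, swapped_lib, act, "vehicle",
                                  moderation=False)
        assert r1.iloc[0]["logFC"] == pytest.approx(-r2.iloc[0]["logFC"])

    def test_type_one_error_under_null(self):
        rng = np.random.default_rng(17)
        n_var, n_rep, n_sim = 60, 8, 5
        rejections, total = 0, 0
        for _ in range(n_sim):
            d = {f"v{i}": rng.normal(0, 0.3, n_rep) for i in range(n_var)}
            summ, lib, act = paired_setup(d)
            res = allelic.test_allelic(summ, lib, act, "vehicle",
                                       moderation=False)
            rejections += (res["p"] < 0.05).sum()
            total += len(res)
        rate = rejections / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 3 * se + 1e-9

    def test_planted_lfc_recovered_with_moderation(self):
        rng = np.random.default_rng(23)
        d = {f"v{i}": 1.0 + rng.normal(0, 0.2, 10) for i in range(100)}
        summ, lib, act = paired_setup(d)
        res = allelic.test_allelic(summ, lib, act, "vehicle", moderation=True)
        assert abs(res["logFC"].mean() - 1.0) < 0.1
        assert res["emvar"].mean() > 0.9


class TestModeration:
    def test_equal_variances_fixed_point(self):
        d0, s0, post = allelic.moderate_variances(np.full(20, 4.0), 6)
        assert np.allclose(post, 4.0)
        assert np.isinf(d0)

    def test_limits_of_shrinkage_formula(self):
        s2 = np.array([1.0, 2.0, 4.0])
        d = 5
        # d0 = 0: no shrinkage by the posterior formula
        assert np.allclose((0 * 1.0 + d * s2) / (0 + d), s2)

    def test_hyperprior_recovery(self):
        rng = np.random.default_rng(31)
        d0_true, s0_sq, d = 4.0, 1.0, 6
        true_var = s0_sq * d0_true / rng.chisquare(d0_true, size=1000)
        s2 = true_var * rng.chisquare(d, size=1000) / d
        d0_hat, s0_hat, _ = allelic.moderate_variances(s2, d)
        assert abs(d0_hat - d0_true) / d0_true < 0.5
        assert abs(s0_hat - s0_sq) / s0_sq < 0.5


class TestInteraction:
    def _setup(self, cell_means, noise_sd=0.05, n=14, seed=2):
        rng = np.random.default_rng(seed)
        rows, lib_rows = [], []
        for allele in ("ref", "alt"):
            lib_rows.append(dict(element_id=f"v1_{allele}", variant_id="v1",
                                 allele=allele))
            for cond in ("vehicle", "stim"):
                mu = cell_means[(allele, cond)]
                for r in range(1, n + 1):
                    rows.append((f"v1_{allele}", r, cond,
                                 mu + rng.normal(0, noise_sd)))
        emv = pd.DataFrame([dict(variant_id="v1", condition="vehicle",
                                 emvar=True)])
        return make_summaries(rows), pd.DataFrame(lib_rows), emv

    def test_planted_interaction_recovered(self):
        summ, lib, emv = self._setup({("ref", "vehicle"): 0,
                                      ("alt", "vehicle"): 0,
                                      ("ref", "stim"): 0,
                                      ("alt", "stim"): 1.0})
        res = allelic.test_interaction(summ, lib, emv)
        assert res.iloc[0]["beta_interaction"] == pytest.approx(1.0, abs=0.1)
        assert res.iloc[0]["p"] < 1e-3

    def test_equal_allelic_effect_gives_null_beta(self):
        summ, lib, emv = self._setup({("ref", "vehicle"): 0,
                                      ("alt", "vehicle"): 0.5,
                                      ("ref", "stim"): 0.3,
                                      ("alt", "stim"): 0.8})
        res = allelic.test_interaction(summ, lib, emv)
        assert abs(res.iloc[0]["beta_interaction"]) < 0.1

    def test_beta_equals_difference_of_per_condition_logfc_noiseless(self):
        summ, lib, emv = self._setup({("ref", "vehicle"): 0,
                                      ("alt", "vehicle"): 0.4,
                                      ("ref", "stim"): 0,
                                      ("alt", "stim"): 1.1}, noise_sd=0.0)
        res = allelic.test_interaction(summ, lib, emv)
        assert res.iloc[0]["beta_interaction"] == pytest.approx(1.1 - 0.4)

    def test_label_swap_negates_beta(self):
        summ, lib, emv = self._setup({("ref", "vehicle"): 0,
                                      ("alt", "vehicle"): 0,
                                      ("ref", "stim"): 0,
                                      ("alt", "stim"): 1.0})
        swapped = lib.copy()
        swapped["allele"] = swapped["allele"].map({"ref": "alt", "alt": "ref"})
        b1 = allelic.test_interaction(summ, lib, emv).iloc[0]["beta_interaction"]
        b2 = allelic.test_interaction(summ, swapped, emv).iloc[0][
            "beta_interaction"]
        assert b1 == pytest.approx(-b2)

    def test_missing_cell_skipped_with_reason(self):
        summ, lib, emv = self._setup({("ref", "vehicle"): 0,
                                      ("alt", "vehicle"): 0,
                                      ("ref", "stim"): 0,
                                      ("alt", "stim"): 1.0})
        summ = summ[~((summ["element_id"] == "v1_alt")
                      & (summ["condition"] == "stim"))]
        res = allelic.test_interaction(summ, lib, emv)
        assert len(res) == 0
        assert ("v1", "missing_design_cell") in res.attrs["skipped"]

    def test_non_emvar_not_tested(self):
        summ, lib, emv = self._setup({("ref", "vehicle"): 0,
                                      ("alt", "vehicle"): 0,
                                      ("ref", "stim"): 0,
                                      ("alt", "stim"): 1.0})
        emv["emvar"] = False
        res = allelic.test_interaction(summ, lib, emv)
        assert len(res) == 0
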