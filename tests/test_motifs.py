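"""PWM scanning, exact p-values, disruption scoring, entropy."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mprakit import motifs
from mprakit.motifs import (PWM, ExactScoreDistribution, correlate_disruption,
                            disruption_score, scan_pwm, score_word,
                            sequence_entropy)


def poly_a_pwm(width=2):
    m = np.zeros((4, width))
    m[0, :] = 1.0
    return PWM("polyA", m, pseudocount=0.0)


def enumeration_pvalue(pwm, observed_score, tol=1e-9):
    """Independent oracle: exact tail mass over all 4^w words."""
    w = pwm.width
    total = 0.0
    for word in itertools.product("ACGT", repeat=w):
        s = score_word(pwm, "".join(word))
        prob = np.prod([pwm.background["ACGT".index(b)] for b in word])
        if s >= observed_score - tol:
            total += prob
    return total


class TestScoring:
    def test_consensus_score_two_bits_per_position(self):
        pwm = poly_a_pwm()
        # pseudocount 0 -> exact 2 bits per matched A against uniform bg
        assert score_word(pwm, "AA") == pytest.approx(4.0)

    def test_best_hit_p_is_one_sixteenth(self):
        pwm = poly_a_pwm()
        hits = scan_pwm("AACC", pwm)
        best = hits.loc[hits["score"].idxmax()]
        assert best["p"] == pytest.approx(1 / 16)

    def test_additivity_against_naive_scorer(self):
        rng = np.random.default_rng(5)
        mat = rng.dirichlet(np.ones(4), size=6).T
        pwm = PWM("m", mat)
        word = "ACGTAC"
        naive = sum(np.log2(pwm.probs["ACGT".index(b), j] / 0.25)
                    for j, b in enumerate(word))
        assert score_word(pwm, word) == pytest.approx(naive)

    def test_reverse_strand_symmetry(self):
        rng = np.random.default_rng(8)
        mat = rng.dirichlet(np.ones(4), size=5).T
        pwm = PWM("m", mat)
        seq = "ACGTACGTAAGG"
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        fwd = scan_pwm(seq, pwm)
        rev = scan_pwm(rc, pwm)
        assert (np.sort(fwd["score"].to_numpy())
                == pytest.approx(np.sort(rev["score"].to_numpy())))

    def test_sequence_shorter_than_motif_yields_no_hits(self):
        assert len(scan_pwm("ACG", poly_a_pwm(5))) == 0


class TestExactPvalues:
    @pytest.mark.parametrize("width", [2, 3, 4, 5, 6])
    def test_exact_tail_matches_enumeration(self, width):
        rng = np.random.default_rng(width)
        mat = rng.dirichlet(np.ones(4) * 0.7, size=width).T
        pwm = PWM(f"w{width}", mat)
        dist = ExactScoreDistribution(pwm)
        words = ["".join(w) for w in
                 itertools.islice(itertools.product("ACGT", repeat=width),
                                  40)]
        for word in words:
            idx = np.array(["ACGT".index(c) for c in word])
            p_dp = float(dist.pvalues(idx)[0])
            p_enum = enumeration_pvalue(pwm, score_word(pwm, word))
            assert p_dp == pytest.approx(p_enum, rel=1e-9, abs=1e-12)

    def test_grid_mode_halving_step_stable_to_three_figures(self):
        rng = np.random.default_rng(3)
        mat = rng.dirichlet(np.ones(4), size=10).T  # width 10 -> grid DP
        pwm = PWM("m", mat)
        seq = "ACGTACGTAAGGCCTTACGT"
        p1 = scan_pwm(seq, pwm, step=0.01)["p"].to_numpy()
        p2 = scan_pwm(seq, pwm, step=0.005)["p"].to_numpy()
        assert np.allclose(p1, p2, rtol=5e-3)

    def test_grid_mode_close_to_exact_enumeration(self):
        rng = np.random.default_rng(6)
        width = 4
        mat = rng.dirichlet(np.ones(4), size=width).T
        pwm = PWM("m", mat)
        exact = ExactScoreDistribution(pwm)
        grid = ExactScoreDistribution(pwm, exact=False)
        words = np.array([[0, 1, 2, 3], [0, 0, 0, 0], [3, 3, 3, 3]])
        assert np.allclose(grid.pvalues(words), exact.pvalues(words),
                           rtol=2e-2, atol=1e-4)

    def test_bh_threshold_monotone(self, small_study):
        _, library, _, _ = small_study
        rng = np.random.default_rng(1)
        pwm = PWM("m", rng.dirichlet(np.ones(4) * 0.3, size=8).T)
        sub = library.head(30)
        h1 = motifs.scan_elements(sub, [pwm], p_threshold=1e-3,
                                  fdr_threshold=0.1)
        h2 = motifs.scan_elements(sub, [pwm], p_threshold=1e-3,
                                  fdr_threshold=0.2)
        assert h2["significant"].sum() >= h1["significant"].sum()


class TestDisruption:
    def _consensus_pwm(self, core="ACGTACG"):
        w = len(core)
        m = np.full((4, w), 0.02)
        for j, b in enumerate(core):
            m["ACGT".index(b), j] = 0.94
        return PWM("tf", m)

    def test_variant_outside_motif_span_none(self):
        pwm = self._consensus_pwm()
        ref = "A" * 40
        alt = ref[:35] + "C" + ref[36:]
        res = disruption_score(ref, alt, 2, pwm)  # window far from pos 35?
        # variant offset given is 2; alleles identical inside the window
        assert res["delta"] == 0.0
        assert res["strength"] == "none"

    def test_alt_completing_consensus_scores_positive(self):
        core = "ACGTACG"
        pwm = self._consensus_pwm(core)
        flank = "TTTTTTTTTT"
        # ref carries a mismatch at the center of the core; alt restores it
        broken = core[:3] + ("A" if core[3] != "A" else "C") + core[4:]
        ref = flank + broken + flank
        alt = flank + core + flank
        off = len(flank) + 3
        res = disruption_score(ref, alt, off, pwm)
        assert res["delta"] > 0
        assert res["matched_allele"] == "alt"
        assert res["strength"] in ("strong", "weak")

    def test_antisymmetry_under_allele_swap(self):
        pwm = self._consensus_pwm()
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=31))
        alt = seq[:15] + ("A" if seq[15] != "A" else "G") + seq[16:]
        r1 = disruption_score(seq, alt, 15, pwm)
        r2 = disruption_score(alt, seq, 15, pwm)
        assert r1["delta"] == pytest.approx(-r2["delta"])


class TestEntropy:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAAAA", 0.0), ("ACGTACGT", 2.0), ("AACC", 1.0)])
    def test_known_values(self, seq, expected):
        assert sequence_entropy(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sequence_entropy("")


class TestCorrelation:
    def test_proportional_gives_r_one(self):
        dis = pd.DataFrame({"variant_id": [f"v{i}" for i in range(5)],
                            "motif_id": "m", "delta": [1, 2, 3, 4, 5.0]})
        al = pd.DataFrame({"variant_id": [f"v{i}" for i in range(5)],
                           "logFC": [2, 4, 6, 8, 10.0]})
        res = correlate_disruption(dis, al)
        assert res.iloc[0]["r"] == pytest.approx(1.0)
        assert res.iloc[0]["slope"] == pytest.approx(2.0)

    def test_constant_delta_reported_missing(self):
        dis = pd.DataFrame({"variant_id": [f"v{i}" for i in range(4)],
                            "motif_id": "m", "delta": [1.0] * 4})
        al = pd.DataFrame({"variant_id": [f"v{i}" for i in range(4)],
                           "logFC": [1, 2, 3, 4.0]})
        res = correlate_disruption(dis, al)
        assert np.isnan(res.iloc[0]["r"])
        assert res.iloc[0]["note"] == "degenerate_or_small"

    def test_too_few_points_skipped(self):
        dis = pd.DataFrame({"variant_id": ["v0", "v1"], "motif_id": "m",
                            "delta": [1.0, 2.0]})
        al = pd.DataFrame({"variant_id": ["v0", "v1"], "logFC": [1.0, 2.0]})
        assert correlate_disruption(dis, al).iloc[0]["note"] != ""


class TestReaders:
    def test_jaspar_roundtrip(self, tmp_path, small_study):
        cfg, library, truth, _ = small_study
        from mprakit import simulate
        ann = simulate.generate_annotations(library, cfg, truth=truth)
        p = tmp_path / "pwms.jaspar"
        simulate.write_jaspar_pwms(ann.pwms, p)
        pwms = motifs.read_jaspar(p)
        assert {m.motif_id for m in pwms} == set(ann.pwms)
        planted = next(m for m in pwms if m.motif_id == "PLANTED_TF")
        orig = PWM("PLANTED_TF", ann.pwms["PLANTED_TF"])
        assert planted.consensus() == orig.consensus()

    def test_meme_reader(self, tmp_path):
        text = ("MEME version 4\n\nALPHABET= ACGT\n\n"
                "strands: + -\n\n"
                "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
                "MOTIF test_motif\n"
                "letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0\n"
                " 0.7 0.1 0.1 0.1\n 0.1 0.7 0.1 0.1\n 0.1 0.1 0.7 0.1\n")
        p = tmp_path / "m.meme"
        p.write_text(text)
        pwms = motifs.read_meme(p)
        assert len(pwms) == 1
        assert pwms[0].width == 3
        assert pwms[0].consensus() == "ACG"

    def test_cluster_gating_by_expressed_tfs(self):
        rng = np.random.default_rng(2)
        pwms = [PWM(f"M{i}", rng.dirichlet(np.ones(4), size=4).T)
                for i in range(3)]
        clusters = pd.DataFrame({
            "motif_id": ["M0", "M1", "M2"],
            "cluster_id": ["c1", "c1", "c2"],
            "tf_name": ["TF0", "TF1", "TF2"]})
        kept = motifs.assign_clusters(pwms, clusters, expressed_tfs={"TF1"})
        assert {m.motif_id for m in kept} == {"M0", "M1"}  # cluster c1 only
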