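"""Repeat annotation, Alu box scanning, and age binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mprakit import repeats, simulate
from mprakit.repeats import (A_BOX, B_BOX, age_bin, overlap_repeats,
                             relative_position, scan_boxes, t4_termination)


def naive_edit1_scan(sequence, motif):
    """Brute-force comparator: offsets where an edit-distance<=1 match
    of the motif starts (substitution, single deletion or insertion)."""
    def lev(a, b):
        m, n = len(a), len(b)
        dp = list(range(n + 1))
        for i in range(1, m + 1):
            prev, dp[0] = dp[0], i
            for j in range(1, n + 1):
                cur = dp[j]
                dp[j] = min(dp[j] + 1, dp[j - 1] + 1,
                            prev + (a[i - 1] != b[j - 1]))
                prev = cur
        return dp[n]

    hits = set()
    for start in range(len(sequence)):
        for L in (len(motif) - 1, len(motif), len(motif) + 1):
            window = sequence[start:start + L]
            if len(window) == L and lev(motif, window) <= 1:
                hits.add(start)
    return hits


def repeat_row(chrom="chr1", start=0, end=300, strand="+", name="AluY",
               cls="SINE", fam="Alu", millidiv=50):
    return dict(chrom=chrom, start=start, end=end, strand=strand,
                repeat_name=name, repeat_class=cls, repeat_family=fam,
                milliDiv=millidiv)


def element_row(eid="e1", chrom="chr1", start=100, end=250, seq="A" * 150):
    return dict(element_id=eid, chrom=chrom, start=start, end=end,
                sequence=seq)


class TestOverlap:
    def test_overlap_bp_arithmetic(self):
        out = overlap_repeats(pd.DataFrame([element_row(start=100, end=250)]),
                              pd.DataFrame([repeat_row(start=0, end=300)]))
        assert out.iloc[0]["overlap_bp"] == 150

    def test_adjacent_half_open_no_overlap(self):
        out = overlap_repeats(pd.DataFrame([element_row(start=300, end=450)]),
                              pd.DataFrame([repeat_row(start=0, end=300)]))
        assert len(out) == 0

    def test_minus_strand_reverse_orientation(self):
        out = overlap_repeats(pd.DataFrame([element_row()]),
                              pd.DataFrame([repeat_row(strand="-")]))
        assert out.iloc[0]["orientation"] == "reverse"

    def test_chromosome_name_normalization(self):
        out = overlap_repeats(pd.DataFrame([element_row(chrom="chr1")]),
                              pd.DataFrame([repeat_row(chrom="1")]))
        assert len(out) == 1

    def test_multiple_overlapping_alus_all_kept(self):
        reps = pd.DataFrame([repeat_row(start=0, end=300),
                             repeat_row(start=200, end=600, name="AluSx")])
        ctx = repeats.annotate_alu_context(
            pd.DataFrame([element_row(start=100, end=250)]), reps)
        assert len(ctx) == 2


class TestRelativePosition:
    def test_midpoint_arithmetic(self):
        # Alu [1000,1300)+, element overlap [1100,1250) -> midpoint 1175
        assert relative_position(1100, 1250, 1000, 1300, "+") == 175

    def test_minus_strand_measured_from_alu_end(self):
        assert relative_position(1100, 1250, 1000, 1300, "-") == 1300 - 1175

    def test_short_alu_excluded(self):
        assert relative_position(1000, 1100, 1000, 1240, "+") is None

    @given(st.integers(-10**6, 10**6))
    def test_translation_invariance(self, k):
        base = relative_position(1100, 1250, 1000, 1300, "+")
        assert relative_position(1100 + k, 1250 + k,
                                 1000 + k, 1300 + k, "+") == base

    def test_left_arm_classification(self):
        assert repeats.classify_arm(40) == "left_arm"
        assert repeats.classify_arm(200) == "right_arm"


class TestBoxScanning:
    def test_exact_a_box_at_offset(self):
        seq = "C" * 10 + A_BOX + "C" * 20
        hits = [h for h in scan_boxes(seq) if h.exact and h.box == "a_box"]
        assert [h.offset for h in hits] == [10]

    def test_b_box_like_edit_distance_one(self):
        seq = "C" * 30 + "GTTCGAGC" + "C" * 30  # B-box with one deletion
        hits = scan_boxes(seq)
        assert any(h.box == "b_box" and not h.exact for h in hits)
        assert not any(h.exact for h in hits)

    def test_motif_free_sequence_has_no_hits(self):
        # GC-balanced 150-mer verified motif-free by the brute comparator
        rng = np.random.default_rng(0)
        while True:
            seq = "".join(rng.permutation(list("ACGT" * 38))[:150])
            if not (naive_edit1_scan(seq, A_BOX)
                    or naive_edit1_scan(seq, B_BOX)):
                break
        assert scan_boxes(seq) == []

    def test_agrees_with_brute_force_comparator(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            if trial % 3 == 0:  # spike in real boxes sometimes
                pos = int(rng.integers(0, 60))
                seq = seq[:pos] + (A_BOX if trial % 2 else B_BOX) + seq[pos + 11:]
            got = {(h.box, h.offset) for h in scan_boxes(seq)}
            want = {("a_box", o) for o in naive_edit1_scan(seq, A_BOX)}
            want |= {("b_box", o) for o in naive_edit1_scan(seq, B_BOX)}
            assert got == want


class TestT4Termination:
    def test_t4_downstream_of_box_fires(self):
        seq = "C" * 10 + B_BOX + "CCC" + "TTTT" + "C" * 10
        assert t4_termination(seq, scan_boxes(seq)) is True

    def test_no_t4_after_box(self):
        seq = "C" * 10 + B_BOX + "C" * 30
        assert t4_termination(seq, scan_boxes(seq)) is False

    def test_t4_only_upstream_does_not_fire(self):
        seq = "TTTT" + "C" * 10 + B_BOX + "C" * 10
        assert t4_termination(seq, scan_boxes(seq)) is False


class TestAgeBin:
    @pytest.mark.parametrize("md,expected", [
        (50, "<100"), (99, "<100"), (100, "100-150"), (150, "100-150"),
        (151, ">150"), (200, ">150")])
    def test_bins(self, md, expected):
        assert age_bin(md) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            age_bin(-1)


class TestParsers:
    def test_repeatmasker_out_roundtrip(self, tmp_path):
        reps = pd.DataFrame([repeat_row(start=1000, end=1300, millidiv=120),
                             repeat_row(chrom="chr2", start=5, end=400,
                                        strand="-", name="L1PA", cls="LINE",
                                        fam="L1", millidiv=87)])
        p = tmp_path / "test.out"
        simulate.write_repeatmasker_out(reps, p)
        back = repeats.read_repeatmasker_out(p)
        for col in ("chrom", "start", "end", "strand", "repeat_name",
                    "repeat_class", "repeat_family", "milliDiv"):
            assert back[col].tolist() == reps[col].tolist()

    def test_bed_roundtrip(self, tmp_path):
        reps = pd.DataFrame([repeat_row()])
        p = tmp_path / "test.bed"
        simulate.write_repeats_bed(reps, p)
        back = repeats.read_repeats_bed(p)
        assert back.iloc[0]["repeat_family"] == "Alu"
        assert back.iloc[0]["milliDiv"] == 50


class TestEndToEndContext:
    def test_every_alu_embedded_element_gets_context(self, small_study):
        cfg, library, truth, _ = small_study
        ann = simulate.generate_annotations(library, cfg, truth=truth)
        ctx = repeats.annotate_alu_context(library, ann.repeats)
        flagged = library[(library["alu_mode"] != "")
                          & (library["allele"] == "ref")]
        assert set(flagged["element_id"]) <= set(ctx["element_id"])
        withA = flagged[flagged["alu_mode"].str.contains("A")]
        sub = ctx[ctx["element_id"].isin(withA["element_id"])]
        assert sub["a_box"].all()
        assert set(ctx["age_bin"]) <= {"<100", "100-150", ">150"}
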