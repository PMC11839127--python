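"""Transposable-element context and Alu internal structure.

Annotates elements with overlapping RepeatMasker features (SINE/LINE/LTR
class flags, Alu subfamily and orientation), computes the element's
relative position within forward-oriented Alu elements of length >= 250
bp, scans for the Pol III promoter boxes (A-box TGGCTCACGCC, B-box
GTTCGAGAC) exactly and within edit distance 1, checks for the TTTT
(T4) Pol III termination signal downstream of a box, and bins repeat
age by milliDiv (<100, 100-150 inclusive, >150).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import edlib
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

A_BOX = "TGGCTCACGCC"
B_BOX = "GTTCGAGAC"
T4 = "TTTT"

# Approximate consensus landmark offsets within a full-length Alu
# (left arm with A- and B-box, A5TACA6 linker, poly-A tail).  These are
# literature-informed configuration defaults, used only for the
# approximate positional classification of elements inside an Alu.
ALU_LANDMARKS = {"a_box": 6, "b_box": 72, "linker": 130, "left_arm_end": 132}


@dataclass(frozen=True)
class BoxHit:
    box: str          # "a_box" | "b_box"
    offset: int       # 0-based start within the element
    exact: bool       # False for edit-distance-1 ("box-like") hits


def read_repeatmasker_out(path) -> pd.DataFrame:
    """Parse the RepeatMasker .out column dialect to a repeat table.

    Output coordinates are 0-based half-open; milliDiv is the divergence
    column times 10 rounded to an integer (mismatches per 1,000 bases).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].replace(".", "").isdigit():
                continue
            chrom = parts[4]
            start = int(parts[5]) - 1
            end = int(parts[6])
            strand = "+" if parts[8] == "+" else "-"
            name = parts[9]
            cls_fam = parts[10]
            cls, _, fam = cls_fam.partition("/")
            rows.append(dict(chrom=chrom, start=start, end=end, strand=strand,
                             repeat_name=name, repeat_class=cls,
                             repeat_family=fam or cls,
                             milliDiv=int(round(float(parts[1]) * 10))))
    return pd.DataFrame(rows)


def read_repeats_bed(path) -> pd.DataFrame:
    """BED6+2 alternative: name, score=milliDiv, strand, class, family."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "repeat_name",
                            "milliDiv", "strand", "repeat_class",
                            "repeat_family"])
    return df


_CHR_RE = re.compile(r"^chr", re.IGNORECASE)


def _norm_chrom(c: str) -> str:
    return _CHR_RE.sub("", str(c))


def overlap_repeats(elements: pd.DataFrame,
                    repeats: pd.DataFrame) -> pd.DataFrame:
    """All element/repeat overlaps with class flags (BED half-open).

    Chromosome names are normalized ("chr1" vs "1") before matching;
    adjacency (element end == repeat start) is not an overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, r in repeats.iterrows():
        trees.setdefault(_norm_chrom(r["chrom"]), IntervalTree()).addi(
            int(r["start"]), int(r["end"]), idx)
    rows = []
    for _, el in elements.iterrows():
        tree = trees.get(_norm_chrom(el["chrom"]))
        if tree is None:
            continue
        for iv in sorted(tree.overlap(int(el["start"]), int(el["end"]))):
            r = repeats.loc[iv.data]
            ov_start = max(int(el["start"]), int(r["start"]))
            ov_end = min(int(el["end"]), int(r["end"]))
            rows.append(dict(
                element_id=el["element_id"], repeat_name=r["repeat_name"],
                repeat_class=r["repeat_class"], repeat_family=r["repeat_family"],
                strand=r["strand"],
                orientation="forward" if r["strand"] == "+" else "reverse",
                overlap_bp=ov_end - ov_start,
                overlap_start=ov_start, overlap_end=ov_end,
                repeat_start=int(r["start"]), repeat_end=int(r["end"]),
                milliDiv=int(r["milliDiv"]),
                is_alu=r["repeat_family"] == "Alu",
            ))
    out = pd.DataFrame(rows, columns=[
        "element_id", "repeat_name", "repeat_class", "repeat_family",
        "strand", "orientation", "overlap_bp", "overlap_start",
        "overlap_end", "repeat_start", "repeat_end", "milliDiv", "is_alu"])
    return out


def relative_position(overlap_start: int, overlap_end: int,
                      alu_start: int, alu_end: int, strand: str = "+",
                      min_alu_length: int = 250) -> int | None:
    """Distance from the Alu start to the midpoint of the overlap.

    The positional analysis follows the forward-oriented convention:
    for minus-strand Alus the distance is taken from the element's 5'
    (alu_end).  Alus shorter than ``min_alu_length`` are excluded
    (returns None).
    """
    if alu_end - alu_start < min_alu_length:
        return None
    midpoint = (overlap_start + overlap_end) // 2
    rel = midpoint - alu_start if strand == "+" else alu_end - midpoint
    if rel < 0:
        raise ValueError("overlap midpoint outside the Alu interval")
    return int(rel)


def classify_arm(relative_midpoint: int,
                 left_arm_end: int = ALU_LANDMARKS["left_arm_end"]) -> str:
    """Approximate left/right arm classification from consensus landmarks."""
    return "left_arm" if relative_midpoint < left_arm_end else "right_arm"


def _within_one_edit(window: str, motif: str) -> bool:
    """Edit distance <= 1 check for |len(window) - len(motif)| <= 1."""
    if len(window) == len(motif):
        return sum(a != b for a, b in zip(window, motif)) <= 1
    short, long_ = sorted((window, motif), key=len)
    if len(long_) - len(short) != 1:
        return False
    return edlib.align(short, long_, mode="NW", k=1)["editDistance"] >= 0


def _edit1_hits(sequence: str, motif: str) -> list[int]:
    """Start offsets of approximate occurrences within edit distance 1.

    Every start offset where a window of length w-1, w or w+1 matches
    the motif within one substitution, deletion or insertion is
    reported, independently of whether a better (exact) match exists at
    another offset.
    """
    w = len(motif)
    starts = []
    for s in range(len(sequence)):
        for L in (w - 1, w, w + 1):
            window = sequence[s:s + L]
            if len(window) == L and _within_one_edit(window, motif):
                starts.append(s)
                break
    return starts


def scan_boxes(sequence: str) -> list[BoxHit]:
    """Exact and edit-distance-1 hits of the Pol III A- and B-boxes."""
    sequence = sequence.upper()
    hits: list[BoxHit] = []
    for name, motif in (("a_box", A_BOX), ("b_box", B_BOX)):
        exact = set()
        start = sequence.find(motif)
        while start != -1:
            exact.add(start)
            hits.append(BoxHit(name, start, True))
            start = sequence.find(motif, start + 1)
        for s in _edit1_hits(sequence, motif):
            if s not in exact:
                hits.append(BoxHit(name, s, False))
    return sorted(hits, key=lambda h: (h.offset, h.box, not h.exact))


def t4_termination(sequence: str, box_hits: list[BoxHit],
                   exact_only: bool = True) -> bool:
    """True iff TTTT occurs 3' of (after the end of) any box hit."""
    sequence = sequence.upper()
    for hit in box_hits:
        if exact_only and not hit.exact:
            continue
        motif_len = len(A_BOX) if hit.box == "a_box" else len(B_BOX)
        if sequence.find(T4, hit.offset + motif_len) != -1:
            return True
    return False


def age_bin(millidiv: int) -> str:
    """Three-way Alu age bin; the middle bin is closed on both ends."""
    if millidiv < 0:
        raise ValueError("milliDiv must be non-negative")
    if millidiv < 100:
        return "<100"
    if millidiv <= 150:
        return "100-150"
    return ">150"


def annotate_alu_context(elements: pd.DataFrame,
                         repeats: pd.DataFrame,
                         min_alu_length: int = 250) -> pd.DataFrame:
    """One AluContext row per (element, overlapping Alu).

    Combines overlap, relative position (forward Alus >= 250 bp only),
    box scanning of the element sequence, T4 termination and age bin.
    """
    overlaps = overlap_repeats(elements, repeats)
    alus = overlaps[overlaps["is_alu"]]
    seqs = elements.set_index("element_id")["sequence"]
    rows = []
    for _, ov in alus.iterrows():
        seq = seqs[ov["element_id"]]
        hits = scan_boxes(seq)
        exact = [h for h in hits if h.exact]
        rel = relative_position(ov["overlap_start"], ov["overlap_end"],
                                ov["repeat_start"], ov["repeat_end"],
                                ov["strand"], min_alu_length)
        rows.append(dict(
            element_id=ov["element_id"], alu_name=ov["repeat_name"],
            orientation=ov["orientation"], overlap_bp=ov["overlap_bp"],
            relative_midpoint=rel if ov["orientation"] == "forward" else None,
            age_bin=age_bin(ov["milliDiv"]), milliDiv=ov["milliDiv"],
            a_box=any(h.box == "a_box" for h in exact),
            b_box=any(h.box == "b_box" for h in exact),
            box_like_hits=sum(1 for h in hits if not h.exact),
            t4_after_box=t4_termination(seq, hits),
            arm=(classify_arm(rel) if rel is not None else None),
        ))
    return pd.DataFrame(rows, columns=[
        "element_id", "alu_name", "orientation", "overlap_bp",
        "relative_midpoint", "age_bin", "milliDiv", "a_box", "b_box",
        "box_like_hits", "t4_after_box", "arm"])
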