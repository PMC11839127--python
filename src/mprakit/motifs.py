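"""PWM scanning with exact p-values and variant motif-disruption scoring.

Scores are base-2 log-odds of the position probability matrix (with a
small pseudocount) against an i.i.d. background.  P-values are exact
tail masses of the score distribution over background-generated words,
computed by dynamic programming on scores discretized to 0.01-bit
steps; the scanned word's score is discretized on the same grid so the
DP tail is exact for the discretized score.  Disruption scores compare
the best hit of each allele in the window covering the variant; the
delta is antisymmetric under allele swap by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss
from Bio import motifs as bio_motifs

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}
DEFAULT_STEP = 0.01      # bits, grid mode
SCORE_FLOOR = -100.0     # bits, stands in for log2(0) cells
EXACT_MAX_WIDTH = 8      # exact convolution up to 4^8 distinct words


@dataclass
class PWM:
    """Position probability matrix over ACGT with background model."""

    motif_id: str
    probs: np.ndarray                        # 4 x w, columns sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    cluster_id: str = ""
    pseudocount: float = 0.001

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape[0] != 4 or probs.shape[1] < 2:
            raise ValueError("matrix must be 4 x w with width >= 2")
        probs = probs + self.pseudocount
        self.probs = probs / probs.sum(axis=0, keepdims=True)
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background[:, None])
        # zero-probability cells (pseudocount 0) get a finite floor so
        # scores and the null distribution stay well defined
        return np.where(np.isneginf(lo), SCORE_FLOOR, lo)

    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))


def _encode(sequence: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in sequence.upper()], dtype=np.int64)


def score_word(pwm: PWM, word: str) -> float:
    """Additive log-odds score of a single width-w word."""
    idx = _encode(word)
    if len(idx) != pwm.width:
        raise ValueError("word length must equal motif width")
    return float(pwm.log_odds[idx, np.arange(pwm.width)].sum())


class ExactScoreDistribution:
    """Exact null distribution of PWM scores under the background model.

    For motifs up to width ``EXACT_MAX_WIDTH`` the distribution of the
    exact (float) total score is built by convolution over columns,
    merging equal sums, so tail p-values equal exhaustive enumeration
    over all 4^w words.  Wider motifs fall back to a dynamic program on
    scores discretized to ``step``-bit integers; halving the step does
    not change reported p-values at three significant figures.
    """

    def __init__(self, pwm: PWM, step: float = DEFAULT_STEP,
                 exact: bool | None = None):
        self.step = step
        lo = pwm.log_odds
        self.lo = lo
        self.exact = pwm.width <= EXACT_MAX_WIDTH if exact is None else exact
        if self.exact:
            scores = np.zeros(1)
            probs = np.ones(1)
            bmask = pwm.background > 0
            for j in range(pwm.width):
                cand = (scores[:, None] + lo[bmask, j][None, :]).ravel()
                candp = (probs[:, None]
                         * pwm.background[bmask][None, :]).ravel()
                cand = np.round(cand, 9)  # merge float-equal sums
                scores, inverse = np.unique(cand, return_inverse=True)
                probs = np.bincount(inverse, weights=candp)
            self._scores = scores
            self._survival = np.cumsum(probs[::-1])[::-1]
        else:
            self.scaled = np.round(lo / step).astype(np.int64)
            col_min = self.scaled.min(axis=0)
            self.total_min = int(col_min.sum())
            size = int(self.scaled.max(axis=0).sum()) - self.total_min + 1
            dist = np.zeros(size)
            dist[0] = 1.0
            for j in range(pwm.width):
                new = np.zeros(size)
                for b in range(4):
                    if pwm.background[b] <= 0:
                        continue
                    shift = int(self.scaled[b, j] - col_min[j])
                    new[shift:] += pwm.background[b] * dist[:size - shift]
                dist = new
            self._survival = np.cumsum(dist[::-1])[::-1]

    def pvalues(self, word_idx: np.ndarray) -> np.ndarray:
        """Tail p-values for an (n, w) array of encoded words."""
        word_idx = np.atleast_2d(word_idx)
        cols = np.arange(word_idx.shape[1])
        if self.exact:
            scores = self.lo[word_idx, cols].sum(axis=1)
            k = np.searchsorted(self._scores, scores - 1e-6, side="left")
            k = np.minimum(k, len(self._survival) - 1)
            return np.minimum(self._survival[k], 1.0)
        totals = self.scaled[word_idx, cols].sum(axis=1)
        k = np.clip(totals - self.total_min, 0, len(self._survival))
        out = np.where(k >= len(self._survival), 0.0,
                       self._survival[np.minimum(k, len(self._survival) - 1)])
        return np.minimum(np.where(k <= 0, 1.0, out), 1.0)


def scan_pwm(sequence: str, pwm: PWM, step: float = DEFAULT_STEP,
             p_threshold: float | None = None,
             dist: ExactScoreDistribution | None = None) -> pd.DataFrame:
    """Score every offset of both strands; exact p per hit.

    Returns a table (offset, strand, score, p), optionally restricted to
    p <= ``p_threshold``.  Sequences shorter than the motif yield no
    hits.
    """
    if dist is None:
        dist = ExactScoreDistribution(pwm, step)
    w = pwm.width
    idx = _encode(sequence)
    n = len(idx) - w + 1
    if n <= 0:
        return pd.DataFrame(columns=["offset", "strand", "score", "p"])
    lo = pwm.log_odds
    rows = []
    rc = np.array([_COMPLEMENT[b] for b in idx[::-1]], dtype=np.int64)
    for strand, enc in (("+", idx), ("-", rc)):
        windows = np.lib.stride_tricks.sliding_window_view(enc, w)
        scores = lo[windows, np.arange(w)].sum(axis=1)
        pvals = dist.pvalues(windows)
        for off in range(n):
            p = float(pvals[off])
            if p_threshold is not None and p > p_threshold:
                continue
            offset = off if strand == "+" else len(idx) - w - off
            rows.append(dict(offset=offset, strand=strand,
                             score=float(scores[off]), p=p))
    return pd.DataFrame(rows, columns=["offset", "strand", "score", "p"])


def scan_elements(elements: pd.DataFrame, pwms: list[PWM],
                  p_threshold: float = 1e-4, fdr_threshold: float = 0.1,
                  step: float = DEFAULT_STEP) -> pd.DataFrame:
    """Scan every element with every motif; BH across the whole scan run.

    The q-value uses the total number of scored positions (all offsets,
    strands, motifs and sequences) as the test count, so the adjustment
    is identical whether or not sub-threshold p-values were materialized.
    """
    all_hits = []
    m_total = 0
    for pwm in pwms:
        dist = ExactScoreDistribution(pwm, step)
        for _, el in elements.iterrows():
            seq = el["sequence"]
            n_pos = max(len(seq) - pwm.width + 1, 0)
            m_total += 2 * n_pos
            hits = scan_pwm(seq, pwm, step, p_threshold, dist)
            if len(hits):
                hits.insert(0, "element_id", el["element_id"])
                hits.insert(1, "motif_id", pwm.motif_id)
                if pwm.cluster_id:
                    hits["cluster_id"] = pwm.cluster_id
                all_hits.append(hits)
    if not all_hits:
        return pd.DataFrame(columns=["element_id", "motif_id", "offset",
                                     "strand", "score", "p", "q"])
    out = pd.concat(all_hits, ignore_index=True)
    out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    ranks = np.arange(1, len(out) + 1)
    q = out["p"].to_numpy() * m_total / ranks
    out["q"] = np.minimum.accumulate(q[::-1])[::-1].clip(max=1.0)
    out["significant"] = out["q"] < fdr_threshold
    return out


def disruption_score(ref_seq: str, alt_seq: str, variant_offset: int,
                     pwm: PWM, strong_threshold: float = 0.4,
                     step: float = DEFAULT_STEP,
                     dist: ExactScoreDistribution | None = None) -> dict:
    """Allele motif-disruption score in the window covering the variant.

    Scores every motif placement whose span covers the variant position
    (a window of width 2w-1 centered on it), on both strands, for each
    allele; ``delta = score_alt - score_ref`` of the best placements.
    Strength is "strong" when |delta| normalized by the PWM score range
    exceeds the threshold, "none" when the variant lies outside every
    placement or the alleles score identically.
    """
    if len(ref_seq) != len(alt_seq):
        raise ValueError("alleles must be length-matched")
    w = pwm.width
    lo_off = max(variant_offset - w + 1, 0)
    hi_off = min(variant_offset, len(ref_seq) - w)
    if hi_off < lo_off:
        return dict(motif_id=pwm.motif_id, score_ref=np.nan,
                    score_alt=np.nan, delta=0.0, strength="none",
                    matched_allele="na")
    if dist is None:
        dist = ExactScoreDistribution(pwm, step)
    window_ref = ref_seq[lo_off:hi_off + w]
    window_alt = alt_seq[lo_off:hi_off + w]
    best = {}
    for allele, window in (("ref", window_ref), ("alt", window_alt)):
        hits = scan_pwm(window, pwm, step, dist=dist)
        best[allele] = float(hits["score"].max()) if len(hits) else np.nan
    delta = best["alt"] - best["ref"]
    smin, smax = pwm.score_range()
    norm = abs(delta) / (smax - smin) if smax > smin else 0.0
    if delta == 0:
        strength = "none"
    elif norm > strong_threshold:
        strength = "strong"
    else:
        strength = "weak"
    return dict(motif_id=pwm.motif_id, score_ref=best["ref"],
                score_alt=best["alt"], delta=float(delta), strength=strength,
                matched_allele="alt" if delta > 0 else
                ("ref" if delta < 0 else "na"))


def disruption_table(library: pd.DataFrame, pwms: list[PWM],
                     strong_threshold: float = 0.4,
                     expressed_tfs: set[str] | None = None) -> pd.DataFrame:
    """Disruption scores for every (variant, motif) pair in the library.

    ``expressed_tfs`` restricts motifs to transcription factors expressed
    in the assayed cells (either condition), mirroring the analysis gate.
    """
    from .simulate import VARIANT_OFFSET  # local to avoid cycle at import

    use = [p for p in pwms
           if expressed_tfs is None or p.motif_id in expressed_tfs]
    dists = {p.motif_id: ExactScoreDistribution(p) for p in use}
    pairs = library[library["variant_id"].fillna("") != ""]
    rows = []
    for vid, v in pairs.groupby("variant_id", observed=True, sort=True):
        alleles = v.set_index("allele")["sequence"]
        if "ref" not in alleles.index or "alt" not in alleles.index:
            continue
        off = VARIANT_OFFSET
        if "variant_pos" in v.columns and "start" in v.columns:
            off = int(v.iloc[0]["variant_pos"]) - int(v.iloc[0]["start"]) - 1
        for pwm in use:
            rec = disruption_score(alleles["ref"], alleles["alt"], off, pwm,
                                   strong_threshold,
                                   dist=dists[pwm.motif_id])
            rec["variant_id"] = vid
            rows.append(rec)
    return pd.DataFrame(rows)


def sequence_entropy(sequence: str) -> float:
    """Shannon entropy (bits) of the mononucleotide composition."""
    if not sequence:
        raise ValueError("empty sequence")
    _, counts = np.unique(list(sequence.upper()), return_counts=True)
    f = counts / counts.sum()
    return float(-(f * np.log2(f)).sum())


def correlate_disruption(disruptions: pd.DataFrame,
                         allelic: pd.DataFrame,
                         per_motif: bool = False) -> pd.DataFrame:
    """Pearson correlation and linear fit of allelic logFC on delta."""
    merged = disruptions.merge(allelic[["variant_id", "logFC"]],
                               on="variant_id")
    groups = merged.groupby("motif_id") if per_motif else [("pooled", merged)]
    rows = []
    for name, g in groups:
        x = g["delta"].to_numpy(float)
        y = g["logFC"].to_numpy(float)
        if len(g) < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append(dict(motif_id=name, n=len(g), slope=np.nan,
                             r=np.nan, p=np.nan, note="degenerate_or_small"))
            continue
        fit = ss.linregress(x, y)
        rows.append(dict(motif_id=name, n=len(g), slope=float(fit.slope),
                         r=float(fit.rvalue), p=float(fit.pvalue), note=""))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers


def read_jaspar(path, background=None) -> list[PWM]:
    """Read JASPAR-text PWMs (count matrices) into PWM objects."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        probs = counts / counts.sum(axis=0, keepdims=True)
        out.append(PWM(m.matrix_id or m.name, probs,
                       background if background is not None
                       else np.full(4, 0.25)))
    return out


def read_meme(path, background=None) -> list[PWM]:
    """Read minimal MEME-format motifs into PWM objects."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        pwm_rows = np.array([list(m.pwm[b]) for b in "ACGT"], dtype=float)
        out.append(PWM(m.name, pwm_rows,
                       background if background is not None
                       else np.full(4, 0.25)))
    return out


def assign_clusters(pwms: list[PWM], clusters: pd.DataFrame,
                    expressed_tfs: set[str] | None = None) -> list[PWM]:
    """Attach cluster ids and keep clusters with an expressed member TF.

    ``clusters`` maps motif_id -> (cluster_id, tf_name).  When an
    expressed-gene set is supplied, a cluster is retained only if at
    least one member TF is expressed.
    """
    lookup = clusters.set_index("motif_id")
    if expressed_tfs is not None:
        expressed_clusters = set(
            lookup.loc[lookup["tf_name"].isin(expressed_tfs), "cluster_id"])
    else:
        expressed_clusters = set(lookup["cluster_id"])
    out = []
    for pwm in pwms:
        if pwm.motif_id not in lookup.index:
            continue
        cid = lookup.loc[pwm.motif_id, "cluster_id"]
        if cid in expressed_clusters:
            pwm.cluster_id = str(cid)
            out.append(pwm)
    return out
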