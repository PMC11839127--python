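"""Barcode-to-element dictionary construction and barcode counting.

Mapping reads carry the 150 bp element followed by its random 20 bp
barcode (offsets configurable).  The element segment must match a
library sequence exactly (the default policy); barcodes of the wrong
length are discarded, and barcodes observed with more than one element
are removed entirely rather than resolved by vote.  Counting accepts
only exact 20-mer matches against the final map.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

BARCODE_LEN = 20


@dataclass
class MappingPolicy:
    element_start: int = 0
    element_length: int = 150
    barcode_start: int = 150          # immediately after the element
    barcode_length: int = BARCODE_LEN
    reverse_complement: bool = False  # reads sequenced as reverse complements
    max_mismatches: int = 0           # exact element match by default


def _open_fastq(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _matches(seq: str, ref: str, max_mismatches: int) -> bool:
    if max_mismatches == 0:
        return seq == ref
    if len(seq) != len(ref):
        return False
    mm = sum(a != b for a, b in zip(seq, ref))
    return mm <= max_mismatches


def build_barcode_map(fastq_paths, library: pd.DataFrame,
                      policy: MappingPolicy | None = None) -> pd.DataFrame:
    """Build the barcode -> element assignment table from mapping reads.

    Returns columns (barcode, element_id, support_reads).  Barcodes seen
    with more than one element are dropped; reads whose extracted
    barcode is not exactly 20 bp are discarded.
    """
    policy = policy or MappingPolicy()
    if isinstance(fastq_paths, (str, bytes)) or hasattr(fastq_paths, "__fspath__"):
        fastq_paths = [fastq_paths]
    by_seq = dict(zip(library["sequence"], library["element_id"]))
    support: dict[tuple[str, str], int] = Counter()
    barcode_elements: dict[str, set] = defaultdict(set)
    n_reads = n_matched = 0
    for path in fastq_paths:
        with _open_fastq(path) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                n_reads += 1
                if policy.reverse_complement:
                    seq = reverse_complement(seq)
                elem = seq[policy.element_start:
                           policy.element_start + policy.element_length]
                bc = seq[policy.barcode_start:
                         policy.barcode_start + policy.barcode_length]
                if len(bc) != policy.barcode_length:
                    continue
                if policy.max_mismatches == 0:
                    eid = by_seq.get(elem)
                else:
                    eid = next((e for s, e in by_seq.items()
                                if _matches(elem, s, policy.max_mismatches)),
                               None)
                if eid is None:
                    continue
                n_matched += 1
                support[(bc, eid)] += 1
                barcode_elements[bc].add(eid)
    if n_matched == 0:
        log.warning("no mapping read matched any library element "
                    "(%d reads examined)", n_reads)
    rows = [
        dict(barcode=bc, element_id=eid, support_reads=n)
        for (bc, eid), n in sorted(support.items())
        if len(barcode_elements[bc]) == 1
    ]
    n_multi = sum(1 for v in barcode_elements.values() if len(v) > 1)
    if n_multi:
        log.info("dropped %d barcode(s) observed with multiple elements",
                 n_multi)
    return pd.DataFrame(rows, columns=["barcode", "element_id",
                                       "support_reads"])


def count_barcodes(fastq_by_sample: dict[tuple[int, str], object],
                   barcode_map: pd.DataFrame,
                   assay: str,
                   reverse_complement_reads: bool = False,
                   barcode_start: int = 0) -> pd.DataFrame:
    """Count exact barcode matches per (replicate, condition) FASTQ.

    ``fastq_by_sample`` maps (replicate, condition) to a FASTQ path;
    registering the same (replicate, condition) twice is a configuration
    error handled at dict construction by the caller.  Returns the long
    count table with a column named after ``assay`` ("dna" or "rna");
    unmatched-read fractions are logged.  Barcodes never observed get
    count 0.
    """
    if assay not in ("dna", "rna"):
        raise ValueError("assay must be 'dna' or 'rna'")
    known = set(barcode_map["barcode"])
    frames = []
    for (replicate, condition), path in sorted(fastq_by_sample.items()):
        counts: Counter = Counter()
        n_reads = 0
        with _open_fastq(path) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                n_reads += 1
                if reverse_complement_reads:
                    seq = reverse_complement(seq)
                bc = seq[barcode_start:barcode_start + BARCODE_LEN]
                if bc in known:
                    counts[bc] += 1
        matched = sum(counts.values())
        if n_reads == 0:
            log.warning("empty FASTQ for replicate %s %s", replicate, condition)
        else:
            log.info("replicate %s %s: %d/%d reads matched (%.1f%%)",
                     replicate, condition, matched, n_reads,
                     100.0 * matched / n_reads)
        frame = barcode_map[["barcode", "element_id"]].copy()
        frame["replicate"] = replicate
        frame["condition"] = condition
        frame[assay] = frame["barcode"].map(counts).fillna(0).astype(int)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def register_count_files(entries) -> dict[tuple[int, str], object]:
    """Validate (replicate, condition, path) registrations.

    Raises on duplicate (replicate, condition) pairs.
    """
    out: dict[tuple[int, str], object] = {}
    for replicate, condition, path in entries:
        key = (int(replicate), str(condition))
        if key in out:
            raise ValueError(f"duplicate registration for replicate "
                             f"{replicate} condition {condition}")
        out[key] = path
    return out
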