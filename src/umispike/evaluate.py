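"""Scoring call sets: truth concordance, replicate summaries, intersections.

On spike-in datasets the truth is known, so sensitivity is true-positive
count against the truth VCF; because the template itself is real-ish data,
specificity is inferred as *putative false positives* — total calls minus
true positives — rather than from unknowable true negatives.  On truth-free
data, the fraction of calls present in the somatic catalogue and the
UpSet-style exclusive intersections across callers stand in for precision.

The module also ships a deliberately naive pileup caller (call the dominant
non-reference base where alt reads >= k and alt fraction >= f).  It exists
so the downstream filtering and scoring stages can be exercised end-to-end
without any third-party caller; it is not a competitive variant caller.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from .model import Fragment, SyntheticReference, TruthSet, VariantRecord

__all__ = [
    "match_truth", "summarize_replicates", "cosmic_fraction", "intersections",
    "pileup_counts", "alt_fraction_at", "naive_pileup_caller",
]

Key = tuple[str, int, str, str]


# ----------------------------------------------------------------- scoring

def match_truth(calls: list[VariantRecord], truth: TruthSet,
                ) -> tuple[set[Key], set[Key]]:
    """Split calls into true positives and putative false positives.

    A call is a true positive iff its (contig, pos, ref, alt) key exactly
    matches a truth record; keys are sets, so each truth record matches at
    most once.  Everything else is a putative false positive.
    """
    truth_keys = truth.keys()
    if not truth_keys:
        raise ValueError("truth set is empty")
    call_keys = {c.key() for c in calls}
    tp = call_keys & truth_keys
    return tp, call_keys - tp


def summarize_replicates(per_dataset: pd.DataFrame) -> pd.DataFrame:
    """Mean TP and putative FP per (depth, vaf) cell over replicates.

    Expects columns depth, vaf, replicate, tp, putative_fp.
    """
    grouped = (per_dataset
               .groupby(["depth", "vaf"], as_index=False)
               .agg(mean_tp=("tp", "mean"),
                    mean_putative_fp=("putative_fp", "mean"),
                    n_replicates=("replicate", "count")))
    return grouped


def cosmic_fraction(records: list[VariantRecord]) -> tuple[float | None, int]:
    """Percentage of calls flagged in the somatic catalogue, with the total.

    Zero calls gives (None, 0): the fraction is undefined, not zero.
    """
    total = len(records)
    if total == 0:
        return None, 0
    flagged = sum(1 for r in records if r.cosmic)
    return round(100.0 * flagged / total, 1), total


def intersections(callsets: dict[str, set[Key]],
                  ) -> tuple[dict[frozenset, int], dict[str, float]]:
    """UpSet-style exclusive intersection counts and private fractions.

    For every non-empty caller subset S, counts the variant keys called by
    exactly the callers in S.  The private fraction of caller c is the
    percentage of the union called by c alone — the usual indicator of
    caller-specific (likely false positive) discovery.
    """
    if len(callsets) < 2:
        raise ValueError("intersections need at least two call sets")
    union: set[Key] = set().union(*callsets.values())
    table: Counter = Counter()
    for key in union:
        members = frozenset(c for c, keys in callsets.items() if key in keys)
        table[members] += 1
    n_union = len(union)
    private = {}
    for caller in callsets:
        alone = table.get(frozenset([caller]), 0)
        private[caller] = round(100.0 * alone / n_union, 1) if n_union else 0.0
    return dict(table), private


# ------------------------------------------------------------------ pileup

_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T byte values


def pileup_counts(fragments: list[Fragment],
                  ref: SyntheticReference) -> dict[str, np.ndarray]:
    """Per-contig (4, L) base-count matrices from aligned read pairs.

    Rows index A/C/G/T; both mates contribute (bases stored in reference
    orientation, so no strand handling is needed).
    """
    counts = {name: np.zeros((4, len(seq)), dtype=np.int32)
              for name, seq in ref.contigs.items()}
    for frag in fragments:
        mat = counts[frag.contig]
        for start, seq in ((frag.frag_start, frag.r1_seq),
                           (frag.r2_start, frag.r2_seq)):
            codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            rows = np.empty(codes.size, dtype=np.int8)
            for byte, row in _BASE_INDEX.items():
                rows[codes == byte] = row
            np.add.at(mat, (rows, np.arange(start, start + codes.size)), 1)
    return counts


def alt_fraction_at(fragments: list[Fragment], ref: SyntheticReference,
                    variant: VariantRecord) -> tuple[float | None, int]:
    """Alt fraction and depth at one locus, by direct per-read counting."""
    pos0 = variant.pos - 1
    alt_reads = depth = 0
    for frag in fragments:
        if frag.contig != variant.contig:
            continue
        for start, seq in ((frag.frag_start, frag.r1_seq),
                           (frag.r2_start, frag.r2_seq)):
            if start <= pos0 < start + len(seq):
                depth += 1
                if seq[pos0 - start] == variant.alt:
                    alt_reads += 1
    if depth == 0:
        return None, 0
    return alt_reads / depth, depth


def naive_pileup_caller(fragments: list[Fragment], ref: SyntheticReference,
                        min_alt_reads: int = 3, min_alt_fraction: float = 0.004,
                        targets: list[tuple[str, int, int]] | None = None,
                        error_rate: float = 0.001) -> list[VariantRecord]:
    """Call SNVs wherever a non-reference base clears simple thresholds.

    At every target position, the most frequent non-reference base is
    called iff its read count >= ``min_alt_reads`` and its fraction of the
    depth >= ``min_alt_fraction``.  QUAL is the PHRED-scaled binomial tail
    probability of seeing that many alt reads from sequencing error alone,
    capped at 999 — enough structure for the quality filter to act on.
    """
    counts = pileup_counts(fragments, ref)
    bases = "ACGT"
    calls: list[VariantRecord] = []
    regions = targets if targets is not None else [
        (name, 0, len(seq)) for name, seq in ref.contigs.items()]
    for contig, start, end in regions:
        mat = counts[contig][:, start:end]
        depth = mat.sum(axis=0)
        seq = ref.contigs[contig]
        ref_rows = np.array([_BASE_INDEX[ord(seq[p])] for p in range(start, end)])
        cols = np.arange(end - start)
        alt_mat = mat.copy()
        alt_mat[ref_rows, cols] = -1  # mask the reference base
        best_row = alt_mat.argmax(axis=0)
        best_count = alt_mat[best_row, cols]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, best_count / np.maximum(depth, 1), 0.0)
        hit = (best_count >= min_alt_reads) & (frac >= min_alt_fraction)
        for off in np.nonzero(hit)[0]:
            pos0 = start + int(off)
            n, k = int(depth[off]), int(best_count[off])
            # error model: any specific wrong base appears at rate e/3
            p_tail = stats.binom.sf(k - 1, n, error_rate / 3.0)
            qual = min(999.0, -10.0 * math.log10(max(p_tail, 1e-100)))
            calls.append(VariantRecord(
                contig=contig, pos=pos0 + 1, ref=seq[pos0],
                alt=bases[int(best_row[off])], dp=n, qual=round(qual, 1),
                info={"DP": n}))
    return calls


def brute_force_intersections(callsets: dict[str, set[Key]],
                              ) -> dict[frozenset, int]:
    """Independent oracle: enumerate every caller subset explicitly."""
    callers = list(callsets)
    union: set[Key] = set().union(*callsets.values())
    table: dict[frozenset, int] = {}
    for r in range(1, len(callers) + 1):
        for combo in itertools.combinations(callers, r):
            inside = set(combo)
            n = sum(
                1 for key in union
                if all(key in callsets[c] for c in inside)
                and all(key not in callsets[c] for c in callers if c not in inside))
            if n:
                table[frozenset(combo)] = n
    return table
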