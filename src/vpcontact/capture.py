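"""Capture-C read processing: junction decomposition and reporter profiles.

A Capture-C read carries ligation junctions between the viewpoint fragment
and distal partners; every junction coincides with a restriction motif, so
in-silico digestion of the read recovers the constituent sub-fragments.
Each mapped sub-fragment falls in exactly one of three classes:

* ``capture`` — inside the viewpoint restriction fragment;
* ``proximity_exclusion`` — inside the flank (1 kb by default) extended
  from the viewpoint in both directions: near-viewpoint religation noise;
* ``reporter`` — anywhere else: evidence of a genuine distal contact.

Reads with identical ordered sub-fragment compositions (coordinates and
strand) are PCR duplicates; after deduplication, reporter sub-fragments of
reads that retain a capture sub-fragment are tallied per restriction
fragment into a bedGraph interaction profile.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .digest import RestrictionMap, find_sites
from .io import revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ViewpointSpec:
    """The viewpoint restriction fragment and its proximity-exclusion flank."""

    chrom: str
    start: int
    end: int
    flank: int = 1000

    def __post_init__(self):
        if self.flank < 0:
            raise ValueError("exclusion flank must be >= 0")
        if self.end <= self.start:
            raise ValueError("viewpoint fragment must be a non-empty interval")


@dataclass(frozen=True)
class SubFragment:
    """One digested piece of a read, mapped (or not) to the genome."""

    read_id: str
    ordinal: int
    chrom: str | None
    start: int
    end: int
    strand: str
    klass: str = "unmapped"  # capture | proximity_exclusion | reporter | unmapped


@dataclass
class ReadRecord:
    """A processed read (merged single read or mate pair) with its sub-fragments."""

    read_id: str
    subfragments: list[SubFragment]
    merged: bool = True

    def composition(self):
        """Ordered (chrom, start, end, strand) tuples of mapped sub-fragments."""
        return tuple(
            (f.chrom, f.start, f.end, f.strand)
            for f in self.subfragments
            if f.chrom is not None
        )

    def has_capture(self) -> bool:
        return any(f.klass == "capture" for f in self.subfragments)


def filter_pairs(pairs, min_len: int = 20, min_quality: float = 20.0):
    """Drop pairs with a short mate or a low mean base quality.

    A pair is discarded if either mate is shorter than ``min_len`` bp or
    either mate's mean Phred score (Phred+33) is below ``min_quality``.
    Returns ``(kept_pairs, stats)``.
    """
    kept = []
    total = 0
    for pair in pairs:
        name, s1, q1, s2, q2 = pair
        total += 1
        if len(q1) != len(s1) or len(q2) != len(s2):
            raise ValueError(f"read {name}: sequence/quality length mismatch")
        if not s1 or not s2:
            raise ValueError(f"read {name}: empty mate")
        if len(s1) < min_len or len(s2) < min_len:
            continue
        mq1 = sum(ord(c) - 33 for c in q1) / len(q1)
        mq2 = sum(ord(c) - 33 for c in q2) / len(q2)
        if mq1 < min_quality or mq2 < min_quality:
            continue
        kept.append(pair)
    return kept, {"kept": len(kept), "total": total}


def merge_pair(pair, min_overlap: int = 10):
    """Reconstruct a centrally overlapping pair into a single read.

    Searches for the longest exact overlap (>= ``min_overlap``) between the
    3' end of mate 1 and the reverse complement of mate 2; non-overlapping
    pairs pass through unmerged. Returns ``(merged, sequences)`` where
    ``sequences`` is ``[merged_read]`` or ``[mate1, mate2]``.
    """
    _, s1, _, s2, _ = pair
    s2r = revcomp(s2)
    max_k = min(len(s1), len(s2r))
    for k in range(max_k, min_overlap - 1, -1):
        if s1[-k:] == s2r[:k]:
            return True, [s1 + s2r[k:]]
    return False, [s1, s2]


def split_at_motif(seq: str, motif: str) -> list[str]:
    """Digest a read in silico: split at internal motif occurrences.

    The motif is retained at the start of the following piece, mirroring the
    cut-at-motif-start convention of the genome digest, so each piece after
    the first begins with the motif. A read without an internal motif is
    returned whole.
    """
    cuts = [p for p in find_sites(seq, motif) if p > 0]
    if not cuts:
        return [seq]
    pieces, prev = [], 0
    for c in cuts:
        if c <= prev:
            continue
        pieces.append(seq[prev:c])
        prev = c
    pieces.append(seq[prev:])
    return pieces


def map_subfragment(seq: str, genome: dict[str, str], read_id: str = "", ordinal: int = 0) -> SubFragment:
    """Exact-match a sub-fragment against the genome (both strands).

    A sequence matching exactly once (forward or reverse complement) is
    mapped; zero or multiple matches yield an unmapped sub-fragment.
    """
    hits: list[tuple[str, int, str]] = []
    rc = revcomp(seq)
    for chrom, chromseq in genome.items():
        for probe, strand in ((seq, "+"), (rc, "-")):
            if probe == seq and seq == rc and strand == "-":
                continue  # palindromic sequence: count one orientation only
            i = chromseq.find(probe)
            while i != -1:
                hits.append((chrom, i, strand))
                if len(hits) > 1:
                    break
                i = chromseq.find(probe, i + 1)
            if len(hits) > 1:
                break
        if len(hits) > 1:
            break
    if len(hits) != 1:
        return SubFragment(read_id, ordinal, None, -1, -1, ".", "unmapped")
    chrom, start, strand = hits[0]
    return SubFragment(read_id, ordinal, chrom, start, start + len(seq), strand)


def classify_subfragment(frag: SubFragment, vp: ViewpointSpec) -> str:
    """Assign one of the three sub-fragment classes.

    ``capture`` if the interval intersects the viewpoint fragment; else
    ``proximity_exclusion`` if it intersects the flank-extended viewpoint
    ``[start - flank, end + flank)``; else ``reporter``. Unmapped
    sub-fragments keep the ``unmapped`` class and are excluded from
    profiles.
    """
    if frag.chrom is None:
        return "unmapped"
    if frag.chrom == vp.chrom:
        if frag.start < vp.end and frag.end > vp.start:
            return "capture"
        if frag.start < vp.end + vp.flank and frag.end > vp.start - vp.flank:
            return "proximity_exclusion"
    return "reporter"


def process_pairs(
    pairs,
    genome: dict[str, str],
    vp: ViewpointSpec,
    motif: str,
    min_len: int = 20,
    min_quality: float = 20.0,
    min_overlap: int = 10,
) -> tuple[list[ReadRecord], dict]:
    """Run the read-processing chain: filter, merge, digest, map, classify.

    Pairs failing the central-overlap merge are analyzed as two independent
    mates within one record (flagged ``merged=False``). Mapping results are
    memoized per sequence, so PCR duplicates cost one lookup.
    """
    kept, fstats = filter_pairs(pairs, min_len=min_len, min_quality=min_quality)
    memo: dict[str, SubFragment] = {}
    records = []
    n_merged = 0
    for pair in kept:
        merged, seqs = merge_pair(pair, min_overlap=min_overlap)
        n_merged += merged
        frags: list[SubFragment] = []
        ordinal = 0
        for seq in seqs:
            for piece in split_at_motif(seq, motif):
                proto = memo.get(piece)
                if proto is None:
                    proto = map_subfragment(piece, genome)
                    memo[piece] = proto
                frag = SubFragment(
                    pair[0], ordinal, proto.chrom, proto.start, proto.end, proto.strand
                )
                klass = classify_subfragment(frag, vp)
                frags.append(
                    SubFragment(
                        pair[0], ordinal, frag.chrom, frag.start, frag.end, frag.strand, klass
                    )
                )
                ordinal += 1
        records.append(ReadRecord(pair[0], frags, merged=merged))
    stats = dict(fstats)
    stats["merged"] = n_merged
    return records, stats


def dedup_reads(records: list[ReadRecord]) -> list[ReadRecord]:
    """Collapse PCR duplicates by sub-fragment composition.

    Two reads are duplicates iff their ordered tuples of mapped
    ``(chrom, start, end, strand)`` sub-fragments are identical. One
    representative survives per duplicate class; the surviving set is
    independent of input order (representatives are returned in
    composition-sorted order). Idempotent.
    """
    by_key: dict[tuple, ReadRecord] = {}
    for rec in records:
        key = rec.composition()
        if key not in by_key:
            by_key[key] = rec
    return [by_key[k] for k in sorted(by_key, key=repr)]


def class_counts(records: list[ReadRecord]) -> dict[str, int]:
    """Sub-fragment counts per class across all records."""
    out = {"capture": 0, "proximity_exclusion": 0, "reporter": 0, "unmapped": 0}
    for rec in records:
        for f in rec.subfragments:
            out[f.klass] += 1
    return out


def reporter_profile(records: list[ReadRecord], rmap: RestrictionMap):
    """Per-restriction-fragment reporter counts.

    Only reads containing at least one capture-class sub-fragment contribute
    (a reporter is evidence of contact only in cis-ligation with the
    captured viewpoint). Each reporter sub-fragment increments the fragment
    containing its midpoint. Returns ``(counts, n_reporters)``; the counts
    sum equals the number of counted reporter sub-fragments.
    """
    counts = {c: np.zeros(rmap.n_fragments(c), dtype=np.int64) for c in rmap.chroms}
    n_reporters = 0
    for rec in records:
        if not rec.has_capture():
            continue
        for f in rec.subfragments:
            if f.klass != "reporter":
                continue
            mid = (f.start + f.end) // 2
            if f.chrom not in counts or not 0 <= mid < rmap.chrom_lengths[f.chrom]:
                logger.warning("reporter midpoint outside map: %s:%d", f.chrom, mid)
                continue
            b = rmap.boundaries[f.chrom]
            j = int(np.searchsorted(b, mid, side="right")) - 1
            counts[f.chrom][j] += 1
            n_reporters += 1
    return counts, n_reporters


def profile_to_bedgraph(counts: dict[str, np.ndarray], rmap: RestrictionMap):
    """Yield ``(chrom, start, end, value)`` rows for nonzero fragments."""
    for chrom in rmap.chroms:
        b = rmap.boundaries[chrom]
        vals = counts[chrom]
        for j in np.nonzero(vals)[0].tolist():
            yield (chrom, int(b[j]), int(b[j + 1]), int(vals[j]))


def _flatten(profiles: list[dict[str, np.ndarray]], rmap: RestrictionMap) -> np.ndarray:
    rows = []
    for profile in profiles:
        rows.append(np.concatenate([profile[c] for c in rmap.chroms]))
    return np.sum(rows, axis=0)


def differential_sites(
    profiles_a: list[dict[str, np.ndarray]],
    profiles_b: list[dict[str, np.ndarray]],
    rmap: RestrictionMap,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential interacting fragments between two conditions.

    Replicates are pooled per condition; for each fragment a 2x2 table
    (fragment count vs rest-of-library count, condition A vs B) is tested
    with two-sided Fisher's exact, and Benjamini-Hochberg correction is
    applied across tested fragments (those with any count). Returns the
    fragments with adjusted p < ``fdr``, with the direction column naming
    the condition with the higher relative frequency.
    """
    if not profiles_a or not profiles_b:
        raise ValueError("each condition needs at least one replicate profile")
    a = _flatten(profiles_a, rmap)
    b = _flatten(profiles_b, rmap)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("a condition has no reporter counts")
    frag_meta = []
    for chrom in rmap.chroms:
        bd = rmap.boundaries[chrom]
        for j in range(rmap.n_fragments(chrom)):
            frag_meta.append((chrom, int(bd[j]), int(bd[j + 1])))
    tested = np.nonzero((a + b) > 0)[0]
    pvals, odds = [], []
    for j in tested.tolist():
        table = [[int(a[j]), na - int(a[j])], [int(b[j]), nb - int(b[j])]]
        res = sps.fisher_exact(table, alternative="two-sided")
        odds.append(res.statistic)
        pvals.append(res.pvalue)
    pvals = np.asarray(pvals)
    qvals = sps.false_discovery_control(pvals, method="bh") if len(pvals) else pvals
    rows = []
    for j, p, q, o in zip(tested.tolist(), pvals, qvals, odds):
        if q >= fdr:
            continue
        chrom, start, end = frag_meta[j]
        direction = "A" if a[j] / na > b[j] / nb else "B"
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "count_a": int(a[j]),
                "count_b": int(b[j]),
                "odds_ratio": float(o),
                "p": float(p),
                "adj_p": float(q),
                "direction": direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "count_a", "count_b", "odds_ratio", "p", "adj_p", "direction"],
    )
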