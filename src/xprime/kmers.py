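"""Canonical k-mer counting, two-sample spectrum clouds, and read binning.

The classification follows the ploidy-cloud logic of a two-genotype
k-mer frequency heatmap: k-mers present only in the target read set at
around haploid depth are chromosome-specific markers; k-mers haploid in
the other set but diploid in the target are shared sex-linked sequence;
k-mers diploid in both are autosomal; low-count k-mers are read errors.
Reads carrying enough marker k-mers are binned as target-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .io import read_fastq, revcomp


@dataclass
class KmerTable:
    """Counts of canonical k-mers (lexicographic min of k-mer and its RC)."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_distinct(self) -> int:
        return len(self.counts)


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError("k must be odd (even k allows palindromic self-complements)")
    if not (3 <= k <= 31):
        raise ValueError("k must lie in [3, 31]")


def count_kmers_in_seqs(seqs: Iterable[str], k: int) -> KmerTable:
    """Count every canonical k-window; windows containing N are skipped."""
    _check_k(k)
    counts: dict[str, int] = {}
    n_short = 0
    for seq in seqs:
        n = len(seq)
        if n < k:
            n_short += 1
            continue
        rc = revcomp(seq)
        if "N" in seq:
            for i in range(n - k + 1):
                f = seq[i : i + k]
                if "N" in f:
                    continue
                r = rc[n - k - i : n - i]
                kmer = f if f <= r else r
                counts[kmer] = counts.get(kmer, 0) + 1
        else:
            for i in range(n - k + 1):
                f = seq[i : i + k]
                r = rc[n - k - i : n - i]
                kmer = f if f <= r else r
                counts[kmer] = counts.get(kmer, 0) + 1
    if n_short:
        import logging

        logging.getLogger("xprime").info(
            "skipped %d reads shorter than k=%d", n_short, k
        )
    return KmerTable(k=k, counts=counts)


def count_kmers(fastq_paths: Iterable[str | Path], k: int) -> KmerTable:
    def reads() -> Iterator[str]:
        for path in fastq_paths:
            for _rid, seq in read_fastq(path):
                yield seq

    return count_kmers_in_seqs(reads(), k)


def genome_kmer_set(seq: str, k: int) -> set[str]:
    """Exact canonical k-mer set of a sequence (oracle helper)."""
    return set(count_kmers_in_seqs([seq], k).counts)


# ---------------------------------------------------------------------------
# joint spectrum
# ---------------------------------------------------------------------------


@dataclass
class JointSpectrum:
    """Distinct-k-mer counts by (count in other, count in target), capped."""

    matrix: np.ndarray
    cap: int

    @property
    def n_distinct(self) -> int:
        return int(self.matrix.sum())


def joint_spectrum(
    table_target: KmerTable, table_other: KmerTable, cap: int = 100
) -> JointSpectrum:
    if table_target.k != table_other.k:
        raise ValueError("k-mer tables have mismatched k")
    matrix = np.zeros((cap + 1, cap + 1), dtype=np.int64)
    other = table_other.counts
    for kmer, ct in table_target.counts.items():
        co = other.get(kmer, 0)
        matrix[min(co, cap), min(ct, cap)] += 1
    for kmer, co in other.items():
        if kmer not in table_target.counts:
            matrix[min(co, cap), 0] += 1
    return JointSpectrum(matrix=matrix, cap=cap)


# ---------------------------------------------------------------------------
# coverage peaks
# ---------------------------------------------------------------------------


class PeakError(ValueError):
    """Coverage histogram too degenerate to resolve ploidy peaks."""


def estimate_coverage_peaks(
    table: KmerTable, error_max: int = 2
) -> tuple[int, int | None]:
    """Locate the haploid and (if present) diploid peaks of a count histogram.

    The histogram is smoothed with a width-3 moving average; local maxima
    at counts beyond the error cloud (> error_max) are candidate peaks.
    The tallest candidate is taken as the haploid peak unless a
    substantial companion peak sits near half its location, in which case
    the pair is read as (haploid, diploid).
    """
    if not table.counts:
        raise PeakError("empty k-mer table")
    values = np.fromiter(table.counts.values(), dtype=np.int64)
    hist = np.bincount(np.minimum(values, 1000))
    if len(hist) < error_max + 3:
        raise PeakError("coverage too low to resolve peaks")
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    maxima = [
        i
        for i in range(error_max + 1, len(smooth) - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > 0
    ]
    if not maxima:
        raise PeakError("coverage too low to resolve peaks")
    tallest = max(maxima, key=lambda i: smooth[i])
    # companion near half the tallest location => tallest is the diploid cloud
    companions = [
        i
        for i in maxima
        if 0.35 * tallest <= i <= 0.65 * tallest
        and smooth[i] >= 0.05 * smooth[tallest]
    ]
    if companions:
        haploid = max(companions, key=lambda i: smooth[i])
        return haploid, tallest
    haploid = tallest
    diploids = [i for i in maxima if i > 1.5 * haploid]
    diploid = max(diploids, key=lambda i: smooth[i]) if diploids else None
    return haploid, diploid


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

LABELS = (
    "error",
    "target_specific",
    "shared_haploid_in_other",
    "shared_diploid_both",
    "unclassified",
)


@dataclass
class KmerThresholds:
    error_max: int = 2
    other_absent_max: int = 2
    target_min: float = 0.0
    target_max: float = float("inf")
    target_haploid: int | None = None
    target_diploid: int | None = None
    other_haploid: int | None = None
    other_diploid: int | None = None

    def __post_init__(self) -> None:
        if self.error_max >= self.target_min:
            raise ValueError(
                "overlapping thresholds: error_max must be below target_min"
            )


def default_thresholds(
    table_target: KmerTable,
    table_other: KmerTable,
    error_max: int = 2,
    target_window: tuple[float, float] = (0.25, 2.5),
) -> KmerThresholds:
    """Thresholds anchored on the estimated target haploid peak."""
    t_hap, t_dip = estimate_coverage_peaks(table_target, error_max)
    try:
        o_hap, o_dip = estimate_coverage_peaks(table_other, error_max)
    except PeakError:
        o_hap, o_dip = None, None
    return KmerThresholds(
        error_max=error_max,
        other_absent_max=error_max,
        target_min=target_window[0] * t_hap,
        target_max=target_window[1] * t_hap,
        target_haploid=t_hap,
        target_diploid=t_dip,
        other_haploid=o_hap,
        other_diploid=o_dip,
    )


@dataclass
class KmerClassification:
    """Partition of the joint k-mer set into ploidy clouds."""

    k: int
    thresholds: KmerThresholds
    sets: dict[str, set[str]]

    @property
    def target_specific(self) -> set[str]:
        return self.sets["target_specific"]

    def summary(self) -> dict[str, int]:
        return {label: len(self.sets[label]) for label in LABELS}


def classify_kmers(
    table_target: KmerTable,
    table_other: KmerTable,
    thresholds: KmerThresholds,
) -> KmerClassification:
    if table_target.k != table_other.k:
        raise ValueError("k-mer tables have mismatched k")
    th = thresholds
    t_dip = th.target_diploid or (2 * th.target_haploid if th.target_haploid else None)
    o_dip = th.other_diploid or (2 * th.other_haploid if th.other_haploid else None)
    sets: dict[str, set[str]] = {label: set() for label in LABELS}
    other = table_other.counts
    target = table_target.counts
    for kmer in target.keys() | other.keys():
        ct = target.get(kmer, 0)
        co = other.get(kmer, 0)
        if ct <= th.error_max and co <= th.error_max:
            sets["error"].add(kmer)
        elif co <= th.other_absent_max and th.target_min <= ct <= th.target_max:
            sets["target_specific"].add(kmer)
        elif (
            th.target_haploid is not None
            and t_dip is not None
            and th.other_haploid is not None
            and o_dip is not None
        ):
            near_t_dip = abs(ct - t_dip) <= abs(ct - th.target_haploid)
            near_o_hap = abs(co - th.other_haploid) < abs(co - o_dip)
            if near_t_dip and near_o_hap and co > th.other_absent_max:
                sets["shared_haploid_in_other"].add(kmer)
            elif near_t_dip and not near_o_hap and co > th.other_absent_max:
                sets["shared_diploid_both"].add(kmer)
            else:
                sets["unclassified"].add(kmer)
        else:
            sets["unclassified"].add(kmer)
    return KmerClassification(k=table_target.k, thresholds=th, sets=sets)


# ---------------------------------------------------------------------------
# read binning
# ---------------------------------------------------------------------------


@dataclass
class BinningResult:
    binned_ids: list[str]
    unbinned_ids: list[str]
    hit_counts: dict[str, int]

    @property
    def n_pairs(self) -> int:
        return len(self.binned_ids) + len(self.unbinned_ids)


def _count_hits(seq: str, kmer_set: set[str], k: int) -> int:
    n = len(seq)
    if n < k:
        return 0
    rc = revcomp(seq)
    hits = 0
    for i in range(n - k + 1):
        f = seq[i : i + k]
        r = rc[n - k - i : n - i]
        if (f if f <= r else r) in kmer_set:
            hits += 1
    return hits


def bin_reads(
    pairs: Iterable[tuple[str, str, str]],
    target_kmers: set[str],
    k: int,
    min_hits: int = 1,
) -> BinningResult:
    """Bin read pairs containing >= min_hits marker k-mers in either mate.

    Pair-level semantics: a single hitting mate bins both mates, so
    pairing is preserved for downstream assembly.  Input order is
    preserved in both output lists.
    """
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    _check_k(k)
    binned: list[str] = []
    unbinned: list[str] = []
    hit_counts: dict[str, int] = {}
    for rid, s1, s2 in pairs:
        hits = _count_hits(s1, target_kmers, k) + _count_hits(s2, target_kmers, k)
        hit_counts[rid] = hits
        (binned if hits >= min_hits else unbinned).append(rid)
    return BinningResult(binned, unbinned, hit_counts)


def expected_error_free_kmer_fraction(
    read_len: int, error_rate: float, k: int
) -> tuple[float, float]:
    """Probability a k-mer is error-free and expected clean k-mers per read.

    With per-base error e, a k-mer survives with (1-e)^k; at the ~11-16%
    error rates of uncorrected long reads this collapses to a few percent
    for k=27, which is why k-mer binning only works for short reads.
    """
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must lie in [0, 1)")
    if read_len < k:
        raise ValueError("read_len must be >= k")
    p_clean = (1.0 - error_rate) ** k
    return p_clean, (read_len - k + 1) * p_clean
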