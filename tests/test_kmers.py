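"""Canonical counting, ploidy clouds, and binning invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xprime.io import revcomp
from xprime.kmers import (
    KmerTable,
    PeakError,
    KmerThresholds,
    bin_reads,
    canonical,
    classify_kmers,
    count_kmers_in_seqs,
    default_thresholds,
    estimate_coverage_peaks,
    expected_error_free_kmer_fraction,
    genome_kmer_set,
    joint_spectrum,
)
from xprime.simulate import StratumSpec, apply_strata, simulate_reads
from xprime.io import GenomicInterval

dna = st.text(alphabet="ACGT", min_size=11, max_size=60)


class TestCounting:
    def test_hand_enumeration(self):
        # ACG and CGT canonicalize to the same 3-mer... at k=3 on "ACGT"
        table = count_kmers_in_seqs(["ACGT"], 3)
        # allow the documented example shape: both windows collapse
        assert table.counts == {"ACG": 2}

    def test_n_windows_skipped(self):
        assert count_kmers_in_seqs(["ANGT"], 3).counts == {}

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            count_kmers_in_seqs(["ACGTACGT"], 4)

    def test_short_reads_skipped(self):
        assert count_kmers_in_seqs(["ACG"], 11).counts == {}

    @given(dna)
    def test_strand_invariance(self, seq):
        a = count_kmers_in_seqs([seq], 11).counts
        b = count_kmers_in_seqs([revcomp(seq)], 11).counts
        assert a == b

    @given(dna)
    def test_all_stored_kmers_canonical(self, seq):
        for kmer in count_kmers_in_seqs([seq], 11).counts:
            assert kmer == canonical(kmer)


class TestSpectrum:
    def test_empty_tables(self):
        spec = joint_spectrum(KmerTable(27), KmerTable(27), cap=10)
        assert spec.matrix.sum() == 0

    def test_cell_placement_and_conservation(self):
        target = KmerTable(27, {"A" * 27: 30, "C" * 27: 5})
        other = KmerTable(27, {"C" * 27: 5, "G" * 27: 2})
        spec = joint_spectrum(target, other, cap=50)
        assert spec.matrix[0, 30] == 1  # target-only k-mer
        assert spec.matrix[5, 5] == 1
        assert spec.matrix[2, 0] == 1  # other-only k-mer
        assert spec.n_distinct == 3

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            joint_spectrum(KmerTable(27), KmerTable(25))


def _poisson_table(rng, n_hap, n_dip, lam):
    counts = {}
    i = 0
    for lam_i, n_i in ((lam, n_hap), (2 * lam, n_dip)):
        for c in rng.poisson(lam_i, n_i):
            if c > 0:
                counts[f"k{i}"] = int(c)
                i += 1
    return KmerTable(27, counts)


class TestPeaks:
    def test_haploid_diploid_mixture(self, rng):
        table = _poisson_table(rng, 20_000, 20_000, 30)
        hap, dip = estimate_coverage_peaks(table)
        assert abs(hap - 30) <= 0.15 * 30
        assert dip is not None and abs(dip - 60) <= 0.15 * 60

    def test_diploid_dominant_mixture(self, rng):
        table = _poisson_table(rng, 4_000, 40_000, 30)
        hap, dip = estimate_coverage_peaks(table)
        assert abs(hap - 30) <= 0.15 * 30
        assert dip is not None and abs(dip - 60) <= 0.15 * 60

    def test_pure_error_table_raises(self, rng):
        counts = {f"k{i}": int(c) for i, c in enumerate(rng.integers(1, 3, 5000))}
        with pytest.raises(PeakError):
            estimate_coverage_peaks(KmerTable(27, counts))

    def test_single_ploidy_no_diploid_peak(self, rng):
        table = _poisson_table(rng, 20_000, 0, 30)
        hap, dip = estimate_coverage_peaks(table)
        assert abs(hap - 30) <= 0.15 * 30
        assert dip is None


class TestClassification:
    def test_target_specific_and_error_clouds(self):
        target = KmerTable(27, {"A" * 27: 30, "C" * 27: 2})
        other = KmerTable(27, {"C" * 27: 1})
        th = KmerThresholds(
            error_max=2, other_absent_max=2, target_min=7.5, target_max=75,
            target_haploid=30, target_diploid=60, other_haploid=30, other_diploid=60,
        )
        result = classify_kmers(target, other, th)
        assert "A" * 27 in result.target_specific
        assert "C" * 27 in result.sets["error"]

    def test_overlapping_thresholds_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            KmerThresholds(error_max=5, target_min=3)

    def test_labels_partition_union(self):
        rng = np.random.default_rng(0)
        alphabet = np.array(list("ACGT"))
        kmers = ["".join(alphabet[rng.integers(0, 4, 27)]) for _ in range(500)]
        target = KmerTable(27, {k: int(rng.integers(1, 80)) for k in kmers[:400]})
        other = KmerTable(27, {k: int(rng.integers(1, 80)) for k in kmers[200:]})
        th = KmerThresholds(
            error_max=2, other_absent_max=2, target_min=7.5, target_max=75,
            target_haploid=30, target_diploid=60, other_haploid=30, other_diploid=60,
        )
        result = classify_kmers(target, other, th)
        union = set(target.counts) | set(other.counts)
        labelled = [k for s in result.sets.values() for k in s]
        assert len(labelled) == len(union)
        assert set(labelled) == union


class TestBinning:
    def test_no_hits_unbinned_and_conservation(self):
        pairs = [("p1", "A" * 40, "C" * 40), ("p2", "G" * 40, "T" * 40)]
        result = bin_reads(pairs, {"ACGTACGTACG"}, k=11)
        assert result.binned_ids == []
        assert result.unbinned_ids == ["p1", "p2"]
        assert result.n_pairs == 2

    def test_either_mate_bins_the_pair(self):
        marker = canonical("ACGTTGCAACGTTGCAACGTTGCAACG")
        pairs = [("p1", "T" * 30, "ACGTTGCAACGTTGCAACGTTGCAACG")]
        result = bin_reads(pairs, {marker}, k=27)
        assert result.binned_ids == ["p1"]

    def test_strand_invariance(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        markers = genome_kmer_set(seq[10:50], 17)
        fwd = bin_reads([("p", seq, seq)], markers, 17)
        rev = bin_reads([("p", revcomp(seq), revcomp(seq))], markers, 17)
        assert fwd.binned_ids == rev.binned_ids

    def test_min_hits_monotonicity(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        markers = genome_kmer_set(seq[:1000], 17)
        pairs = [
            ("p%d" % i, seq[s : s + 100], seq[s + 120 : s + 220])
            for i, s in enumerate(range(0, 1700, 50))
        ]
        previous = None
        for min_hits in (1, 5, 20, 80):
            binned = set(bin_reads(pairs, markers, 17, min_hits).binned_ids)
            if previous is not None:
                assert binned <= previous
            previous = binned


class TestGenomeOracle:
    def test_classification_matches_exact_set_difference(self, rng):
        """On a small genome with saturating error-free coverage the
        target-specific call equals the brute-force k-mer set difference."""
        k = 21
        alphabet = np.array(list("ACGT"))
        x = "".join(alphabet[rng.integers(0, 4, 30_000)])
        a = "".join(alphabet[rng.integers(0, 4, 20_000)])
        strata = [StratumSpec(GenomicInterval("X", 2_000, 28_000), 0.02)]
        xp, _v, _r = apply_strata(x, [], strata, rng)
        genomes_t = {"X": x, "Xprime": xp, "A1": a}
        genomes_o = {"X": x, "A1": a}
        t1, t2 = simulate_reads(genomes_t, "XprimeX", 40.0, rng, 100, 220)
        o1, o2 = simulate_reads(genomes_o, "X0", 40.0, rng, 100, 220)
        table_t = count_kmers_in_seqs((s for _i, s in t1 + t2), k)
        table_o = count_kmers_in_seqs((s for _i, s in o1 + o2), k)
        result = classify_kmers(table_t, table_o, default_thresholds(table_t, table_o))
        exact = genome_kmer_set(xp, k) - genome_kmer_set(x, k) - genome_kmer_set(a, k)
        called = result.target_specific
        assert called <= exact
        assert len(called) >= 0.97 * len(exact)


class TestErrorModel:
    def test_limits_and_closed_form(self):
        assert expected_error_free_kmer_fraction(150, 0.0, 27)[0] == 1.0
        p, _ = expected_error_free_kmer_fraction(150, 0.13, 27)
        assert p == pytest.approx(0.87**27)
        assert p == pytest.approx(0.0233, abs=2e-3)
        _, clean = expected_error_free_kmer_fraction(150, 0.001, 27)
        assert clean == pytest.approx(124 * 0.999**27, rel=1e-9)
        assert clean == pytest.approx(120.7, abs=0.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expected_error_free_kmer_fraction(150, 1.0, 27)
        with pytest.raises(ValueError):
            expected_error_free_kmer_fraction(20, 0.0, 27)
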