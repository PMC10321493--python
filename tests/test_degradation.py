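"""Variant consensus, expression calls, status rules, DC and chi-square."""

import numpy as np
import pandas as pd
import pytest

from xprime.degradation import (
    chisq_2x2,
    classify_status,
    consensus_variants,
    dosage_compensation_test,
    expressed_call,
    percent,
    subtract_background,
    tpm,
)
from xprime.io import Genotype, VariantRecord
from xprime.simulate import emit_replicate_vcfs
from xprime.io import read_vcf


def _v(pos, gt=Genotype.HET, alt="T"):
    return VariantRecord("X", pos, "A", alt, gt)


class TestVariantSets:
    def test_rep1_only_excluded(self):
        assert consensus_variants([_v(10)], []) == []

    def test_identical_replicates_idempotent(self):
        reps = [_v(10), _v(20)]
        out = consensus_variants(reps, list(reps))
        assert [v.key for v in out] == [v.key for v in reps]

    def test_genotype_mismatch_and_missing_excluded(self):
        assert consensus_variants([_v(10, Genotype.HET)], [_v(10, Genotype.HOM_ALT)]) == []
        assert consensus_variants([_v(10, Genotype.MISSING)], [_v(10, Genotype.MISSING)]) == []

    def test_subtract_background(self):
        target = [_v(10), _v(20)]
        assert [v.pos for v in subtract_background(target, [_v(10)])] == [20]
        assert subtract_background(target, []) == target

    def test_consensus_suppresses_fp_noise(self, tmp_path, rng):
        """Independent false positives rarely survive the intersection."""
        x = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        paths = emit_replicate_vcfs(
            {}, [], x, tmp_path, rng, fn_rate=0.0, fp_rate=1e-3
        )
        rep1 = read_vcf(paths[("XprimeX", 1)])
        rep2 = read_vcf(paths[("XprimeX", 2)])
        assert len(rep1) > 50
        consensus = consensus_variants(rep1, rep2)
        # expectation ~ n1*n2/L = 0.1 collisions
        assert len(consensus) <= 3

    def test_subtract_consensus_order_stable(self):
        reps = [[_v(p) for p in (10, 20, 30)], [_v(p) for p in (10, 30, 40)]]
        bg = [_v(30)]
        a = subtract_background(consensus_variants(*reps), bg)
        b = consensus_variants(
            subtract_background(reps[0], bg), subtract_background(reps[1], bg)
        )
        assert [v.key for v in a] == [v.key for v in b]


class TestTpm:
    def test_single_gene_full_million(self):
        counts = pd.DataFrame({"s1": [7]}, index=["g1"])
        out = tpm(counts, pd.Series({"g1": 500}))
        assert out.loc["g1", "s1"] == pytest.approx(1e6)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [10, 30]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 100, "g2": 300})
        assert tpm(counts * 2, lengths).equals(tpm(counts, lengths))

    def test_length_normalization_closed_form(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        out = tpm(counts, pd.Series({"g1": 1000, "g2": 2000}))
        assert out.loc["g1", "s1"] == pytest.approx(2e6 / 3)
        assert out.loc["g2", "s1"] == pytest.approx(1e6 / 3)

    def test_columns_sum_to_million(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, (30, 4)), columns=list("abcd")
        )
        lengths = pd.Series(rng.integers(200, 3000, 30), index=counts.index)
        sums = tpm(counts, lengths).sum(axis=0)
        assert np.allclose(sums, 1e6)

    def test_all_zero_sample_warned(self, caplog):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with caplog.at_level("WARNING", logger="xprime"):
            out = tpm(counts, pd.Series({"g1": 100, "g2": 100}))
        assert (out["s1"] == 0).all()
        assert "all-zero" in caplog.text


class TestExpressedCall:
    def test_zero_is_nonexpressed(self):
        m = pd.DataFrame({"s": [0.0, 5.0]}, index=["g1", "g2"])
        flags = expressed_call(m)
        assert not flags.loc["g1", "s"] and flags.loc["g2", "s"]

    def test_equal_nonzero_none_removed(self):
        m = pd.DataFrame({"s": [3.0] * 50})
        assert expressed_call(m)["s"].all()

    def test_bottom_permille_flagged(self, rng):
        vals = rng.lognormal(3, 1, 10_000) + 0.001
        m = pd.DataFrame({"s": vals})
        flags = expressed_call(m)
        n_off = (~flags["s"]).sum()
        assert 5 <= n_off <= 15
        # the flagged genes are exactly the smallest ones
        assert vals[~flags["s"].to_numpy()].max() < np.quantile(vals, 0.002)


class TestStatusRules:
    def _expr(self, frame):
        return pd.DataFrame(frame).T  # genes x stages

    def test_four_way_classification_and_partition(self):
        pairs = {"g1": "g1x", "g2": "g2x", "g3": "g3x", "g4": "g4x"}
        expr_x = pd.DataFrame(
            {"s1": [True, True, True, False], "s2": [True, True, True, False]},
            index=["g1", "g2", "g3", "g4"],
        )
        expr_xp = pd.DataFrame(
            {"s1": [True, False, False, False], "s2": [True, False, False, False]},
            index=["g1x", "g2x", "g3x", "g4x"],
        )
        report = classify_status(
            pairs, {"g3"}, {"X": expr_x, "Xprime": expr_xp}
        )
        assert report.status["g1"].value == "functional"
        assert report.status["g2"].value == "silenced"
        assert report.status["g3"].value == "silenced_and_disrupted"
        # g4: ancestral copy never expressed, so silencing cannot be called
        assert report.status["g4"].value == "functional"
        assert sum(report.counts.values()) == len(pairs)

    def test_xprime_expressed_at_other_stage_not_silenced(self):
        pairs = {"g1": "g1x"}
        expr_x = pd.DataFrame({"s1": [True], "s2": [False]}, index=["g1"])
        expr_xp = pd.DataFrame({"s1": [False], "s2": [True]}, index=["g1x"])
        report = classify_status(pairs, set(), {"X": expr_x, "Xprime": expr_xp})
        # expressed only at a stage where the X copy is silent: still silenced
        assert report.status["g1"].value == "silenced"

    def test_missing_expression_excluded(self):
        pairs = {"g1": "g1x", "g2": "g2x"}
        expr_x = pd.DataFrame({"s1": [True]}, index=["g1"])
        expr_xp = pd.DataFrame({"s1": [True]}, index=["g1x"])
        report = classify_status(pairs, set(), {"X": expr_x, "Xprime": expr_xp})
        assert report.excluded_pairs == ["g2"]
        assert sum(report.counts.values()) == 1

    def test_percent_formatter(self):
        assert percent(123, 2321) == 5.3
        assert percent(4.2, 54.7) == 7.7
        assert percent(4.9, 58.8) == 8.3
        with pytest.raises(ValueError):
            percent(1, 0)


class TestDosageCompensation:
    def _counts(self, rng, n_genes=60, n_samples=4, scale=1.0):
        return pd.DataFrame(
            rng.poisson(500 * scale, (n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_identical_means_not_upregulated(self, rng):
        a = self._counts(rng)
        b = self._counts(rng).rename(columns=lambda c: c + "_ref")
        out = dosage_compensation_test(a, b, set())
        assert not out["upregulated"].any()
        assert out["log2fc"].abs().max() < 0.3

    def test_doubled_mean_upregulated(self, rng):
        a = self._counts(rng, scale=2.0)
        b = self._counts(rng).rename(columns=lambda c: c + "_ref")
        out = dosage_compensation_test(a, b, set())
        # library-size normalization absorbs a global doubling...
        # so double only a subset of genes instead
        a2 = self._counts(rng)
        a2.iloc[:10] *= 4
        out = dosage_compensation_test(a2, b, {"g1"})
        assert out["upregulated"].iloc[:10].all()
        assert not out["upregulated"].iloc[10:].any()

    def test_no_reference_samples_rejected(self, rng):
        a = self._counts(rng)
        with pytest.raises(ValueError, match="reference"):
            dosage_compensation_test(a, a.iloc[:, :0], set())

    def test_null_overlap_with_degraded_is_empty(self, rng):
        """Without any true compensation, degraded genes are not called up."""
        a = self._counts(rng)
        b = self._counts(rng).rename(columns=lambda c: c + "_ref")
        degraded = {f"g{i}" for i in range(0, 60, 7)}
        out = dosage_compensation_test(a, b, degraded, n_permutations=200,
                                       rng=np.random.default_rng(5))
        assert not (out["upregulated"] & out["degraded_homolog"]).any()
        assert (out.loc[sorted(degraded), "q_perm"] > 0.05).all()


class TestChiSquare:
    def test_independence(self):
        stat, df, p = chisq_2x2(10, 10, 10, 10)
        assert stat == 0 and df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        stat, _df, p = chisq_2x2(20, 5, 5, 20)
        assert stat == pytest.approx(18.0)
        assert p < 0.001

    def test_transposition_invariance(self):
        assert chisq_2x2(12, 7, 3, 9)[0] == pytest.approx(chisq_2x2(12, 3, 7, 9)[0])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_2x2(0, 0, 5, 10)


def test_degradation_recovery_under_call_noise():
    """With 5% false-negative call noise, disrupted recall stays >= 0.9."""
    from xprime.recovery import degradation_recovery_check
    from xprime.simulate import StudyConfig, simulate_study
    import tempfile
    from xprime.degradation import classify_disruption
    from xprime.effects import annotate_variants

    config = StudyConfig(
        x_length=300_000, autosome_length=0, n_genes=180, mean_cds_codons=150,
        fn_rate=0.05, fp_rate=0.0, n_background=20, seed=21,
    )
    study = simulate_study(config)
    rng = np.random.default_rng(22)
    with tempfile.TemporaryDirectory() as tmp:
        paths = study.write_vcfs(tmp, rng)
        xp = [read_vcf(paths[("XprimeX", r)], "XprimeX", r) for r in (1, 2)]
        x0 = [read_vcf(paths[("X0", r)], "X0", r) for r in (1, 2)]
    specific = subtract_background(
        consensus_variants(*xp), consensus_variants(*x0)
    )
    annotated = annotate_variants(study.genes, study.genome, specific)
    called = classify_disruption(annotated)
    truth = study.truth.disrupted_genes
    recall = len(called & truth) / len(truth)
    assert recall >= 0.9
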