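"""Generator invariants: construction properties, noise levels, determinism."""

import numpy as np
import pytest

from xprime.effects import annotate_variants
from xprime.degradation import classify_disruption
from xprime.io import GenomeSequence, GenomicInterval, Genotype, read_vcf, revcomp
from xprime.oracles import translate
from xprime.simulate import (
    StratumSpec,
    StudyConfig,
    TruthSet,
    apply_strata,
    default_strata,
    draw_background,
    emit_replicate_vcfs,
    inject_disruptions,
    parse_read_id,
    simulate_expression,
    simulate_genome,
    simulate_reads,
    simulate_study,
)


class TestGenome:
    def test_genes_translatable(self, tiny_genome_and_genes):
        genome, genes = tiny_genome_and_genes
        assert len(genes) == 25
        for g in genes:
            cds = g.cds_sequence(genome)
            assert cds[:3] == "ATG"
            prot = translate(cds)
            assert prot.endswith("*")
            assert "*" not in prot[:-1]

    def test_both_strands_used(self, tiny_genome_and_genes):
        _genome, genes = tiny_genome_and_genes
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}

    def test_determinism(self):
        a = simulate_genome(np.random.default_rng(5), {"X": 30_000}, 5, 60)
        b = simulate_genome(np.random.default_rng(5), {"X": 30_000}, 5, 60)
        assert a[0].records == b[0].records
        assert [g.cds_segments for g in a[1]] == [g.cds_segments for g in b[1]]

    def test_zero_genes(self, rng):
        genome, genes = simulate_genome(rng, {"X": 5_000}, 0)
        assert genes == [] and len(genome["X"]) == 5_000

    def test_overcrowded_chromosome_rejected(self, rng):
        with pytest.raises(ValueError, match="density"):
            simulate_genome(rng, {"X": 3_000}, n_genes=20, mean_cds_codons=100)


class TestStrata:
    def test_zero_divergence_identity(self, rng):
        x = "ACGT" * 2500
        strata = [StratumSpec(GenomicInterval("X", 0, 10_000), 0.0)]
        xp, variants, realized = apply_strata(x, [], strata, rng)
        assert xp == x and variants == {} and realized == [0.0]

    def test_outside_strata_untouched(self, rng):
        x = "ACGT" * 5000
        strata = [StratumSpec(GenomicInterval("X", 5_000, 15_000), 0.02)]
        xp, variants, _ = apply_strata(x, [], strata, rng)
        assert xp[:5_000] == x[:5_000] and xp[15_000:] == x[15_000:]
        assert all(5_000 <= p < 15_000 for p in variants)

    def test_realized_fraction_binomial_bound(self, rng):
        n, d = 200_000, 0.01
        x = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        strata = [StratumSpec(GenomicInterval("X", 0, n), d)]
        _xp, _v, realized = apply_strata(x, [], strata, rng)
        se = np.sqrt(d * (1 - d) / n)
        assert abs(realized[0] - d) < 3 * se

    def test_variants_match_sequence_diff(self, rng):
        x = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20_000)])
        strata = [StratumSpec(GenomicInterval("X", 0, 20_000), 0.01)]
        xp, variants, _ = apply_strata(x, [], strata, rng)
        diffs = {i for i in range(len(x)) if x[i] != xp[i]}
        assert diffs == set(variants)
        for p, (ref, alt) in variants.items():
            assert x[p] == ref and xp[p] == alt

    def test_default_layout_contrasts(self):
        strata = default_strata()
        assert len(strata) == 16
        for a, b in zip(strata, strata[1:]):
            assert a.interval.end <= b.interval.start or a.interval.end == b.interval.start
            ratio = max(a.divergence, b.divergence) / min(a.divergence, b.divergence)
            assert ratio >= 3.0


class TestDisruptions:
    def test_fraction_zero_noop(self, tiny_genome_and_genes, rng):
        genome, genes = tiny_genome_and_genes
        xp, disrupted, events, variants = inject_disruptions(
            genome["X"], genome["X"], genes, 0.0, rng
        )
        assert xp == genome["X"] and disrupted == set() and events == []

    def test_events_disrupt_translation(self, tiny_genome_and_genes, rng):
        """Every injected event must be recoverable by effect annotation."""
        genome, genes = tiny_genome_and_genes
        _xp, disrupted, events, variants = inject_disruptions(
            genome["X"], genome["X"], genes, 0.5, rng
        )
        assert len(disrupted) >= 10
        kinds = {e["kind"] for e in events}
        assert kinds >= {"frameshift_del", "premature_stop", "start_loss"} or len(kinds) >= 3
        from xprime.io import VariantRecord

        records = [
            VariantRecord("X", p + 1, ref, alt)
            for p, (ref, alt) in sorted(variants.items())
        ]
        annotated = annotate_variants(genes, genome, records)
        assert classify_disruption(annotated) == disrupted

    def test_frameshift_shifts_downstream_frame(self, tiny_genome_and_genes):
        genome, genes = tiny_genome_and_genes
        rng = np.random.default_rng(99)
        # force frameshifts only by retrying until one lands
        for _ in range(50):
            xp, disrupted, events, _ = inject_disruptions(
                genome["X"], genome["X"], genes, 0.3, rng
            )
            dels = [e for e in events if e["kind"] == "frameshift_del"]
            if dels:
                break
        event = dels[0]
        gene = next(g for g in genes if g.gene_id == event["gene_id"])
        mutated = GenomeSequence({"X": xp})
        # the edited chromosome no longer ends this CDS cleanly in frame
        span = gene.span
        removed = len(event["ref"]) - len(event["alt"])
        shifted = xp[span.start : span.end - removed]
        original = genome["X"][span.start : span.end]
        assert shifted != original[: len(shifted)]


class TestReads:
    def test_pair_count_arithmetic(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        r1, r2 = simulate_reads({"A1": seq}, "X0", 30.0, rng, 150, 350)
        # two copies of the autosome at per-copy coverage 30
        assert len(r1) == round(2 * 30 * 100_000 / (2 * 150))
        assert len(r1) == len(r2)

    def test_error_free_reads_match_template(self, rng):
        x = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20_000)])
        a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20_000)])
        genomes = {"X": x, "A1": a}
        r1, r2 = simulate_reads(genomes, "X0", 3.0, rng, 100, 250)
        for (rid, s1), (_rid, s2) in list(zip(r1, r2))[:200]:
            _serial, template, start, end = parse_read_id(rid)
            frag = genomes[template][start:end]
            assert s1 == frag[:100]
            assert s2 == revcomp(frag)[:100]

    def test_xprime_specific_depth_is_haploid(self, rng):
        """Carrier X'-only positions get ~half the autosomal depth."""
        x = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50_000)])
        a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50_000)])
        r1, _ = simulate_reads({"X": x, "Xprime": x, "A1": a}, "XprimeX", 20.0, rng)
        depth = {"Xprime": 0, "A1": 0}
        probe = 25_000
        for rid, _s in r1:
            _serial, template, start, end = parse_read_id(rid)
            if template in depth and start <= probe < end:
                depth[template] += 1
        assert 0.3 < depth["Xprime"] / depth["A1"] < 0.75

    def test_read_longer_than_template_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_reads({"X": "ACGT" * 10}, "X0", 5.0, rng, read_len=100, insert=120)


class TestReplicateVcfs:
    def test_noise_free_replicates_equal_truth(self, tmp_path, rng):
        x = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50_000)])
        strata = [StratumSpec(GenomicInterval("X", 0, 50_000), 0.005)]
        _xp, variants, _ = apply_strata(x, [], strata, rng)
        paths = emit_replicate_vcfs(
            variants, [], x, tmp_path, rng, fn_rate=0.0, fp_rate=0.0
        )
        for rep in (1, 2):
            recs = read_vcf(paths[("XprimeX", rep)], "XprimeX", rep)
            assert {(r.pos - 1, r.ref, r.alt) for r in recs} == {
                (p, ref, alt) for p, (ref, alt) in variants.items()
            }
            assert all(r.genotype is Genotype.HET for r in recs)
            assert read_vcf(paths[("X0", rep)]) == []

    def test_background_in_all_four_files(self, tmp_path, rng):
        x = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        background = draw_background(x, 5, rng)
        paths = emit_replicate_vcfs(
            {}, background, x, tmp_path, rng, fn_rate=0.0, fp_rate=0.0
        )
        expected = {(p + 1, ref, alt) for p, ref, alt in background}
        for key, path in paths.items():
            recs = read_vcf(path)
            assert {(r.pos, r.ref, r.alt) for r in recs} == expected


class TestExpression:
    def test_silenced_zero_and_ploidy_ratio(self, tiny_genome_and_genes, rng):
        _genome, genes = tiny_genome_and_genes
        pairs = {g.gene_id: g.gene_id + "_xp" for g in genes}
        silenced = {genes[0].gene_id, genes[1].gene_id}
        counts, lengths, meta = simulate_expression(genes, pairs, silenced, rng)
        xp_cols = meta[meta["origin"] == "Xprime"]["sample"]
        for g in silenced:
            assert (counts.loc[pairs[g], xp_cols] == 0).all()
        # XX samples are diploid: about twice the carrier's X-origin counts
        x_cols = meta[(meta["genotype"] == "XprimeX") & (meta["origin"] == "X")]["sample"]
        xx_cols = meta[meta["genotype"] == "XX"]["sample"]
        gene_ids = [g.gene_id for g in genes]
        ratio = (
            counts.loc[gene_ids, xx_cols].to_numpy().mean()
            / counts.loc[gene_ids, x_cols].to_numpy().mean()
        )
        assert 1.7 < ratio < 2.3

    def test_determinism(self, tiny_genome_and_genes):
        _genome, genes = tiny_genome_and_genes
        pairs = {g.gene_id: g.gene_id + "_xp" for g in genes}
        a = simulate_expression(genes, pairs, set(), np.random.default_rng(3))[0]
        b = simulate_expression(genes, pairs, set(), np.random.default_rng(3))[0]
        assert a.equals(b)


class TestStudy:
    def test_end_to_end_determinism_and_truth_round_trip(self, tmp_path):
        cfg = StudyConfig(
            x_length=60_000, autosome_length=0, n_genes=20, mean_cds_codons=60,
            strata=[StratumSpec(GenomicInterval("X", 5_000, 55_000), 0.01)],
            n_background=5, seed=11,
        )
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        assert a.xprime_seq == b.xprime_seq
        assert a.counts.equals(b.counts)
        assert a.truth.variants == b.truth.variants
        path = tmp_path / "truth.json"
        a.truth.to_json(path)
        back = TruthSet.from_json(path)
        assert back.variants == a.truth.variants
        assert back.disrupted_genes == a.truth.disrupted_genes
        assert back.silenced_genes == a.truth.silenced_genes

    def test_disrupted_and_silenced_disjoint(self):
        cfg = StudyConfig(
            x_length=120_000, autosome_length=0, n_genes=60, mean_cds_codons=60,
            strata=[], seed=2,
        )
        study = simulate_study(cfg)
        assert not (study.truth.disrupted_genes & study.truth.silenced_genes)
        n = len(study.genes)
        assert len(study.truth.disrupted_genes) in (int(0.053 * n), int(0.053 * n) + 1)
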