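"""End-to-end truth-recovery evaluations on synthetic data.

Each function builds a seeded synthetic data set, runs the relevant
slice of the pipeline on the emitted files (never on the in-memory
truth), and measures how well the truth is recovered.  They back both
the test suite and the reproduction script.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .degradation import (
    classify_disruption,
    classify_status,
    consensus_variants,
    stage_expression,
    subtract_background,
    tpm,
)
from .effects import annotate_variants, classify_snv
from .io import GenomeSequence, VariantRecord, read_vcf
from .kmers import (
    bin_reads,
    classify_kmers,
    count_kmers_in_seqs,
    default_thresholds,
)
from .oracles import snv_effect_by_translation
from .simulate import (
    StudyConfig,
    apply_strata,
    default_strata,
    draw_background,
    emit_replicate_vcfs,
    parse_read_id,
    simulate_genome,
    simulate_study,
)
from .strata import (
    ChangePointConfig,
    bcp_segment,
    call_strata,
    evaluate_strata_recovery,
    exact_change_probabilities,
    segment_density_series,
    window_density,
)


def changepoint_oracle_check(
    seed: int, n: int = 10, iterations: int = 2500, burnin: int = 500
) -> dict:
    """Max |MCMC - exact| over boundary change probabilities, short series.

    The exact values come from exhaustive enumeration of all 2^(n-1)
    partitions under the identical model, so any systematic discrepancy
    is a sampler defect rather than Monte Carlo noise.
    """
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0.0, 1.0, n // 2), rng.normal(2.0, 1.0, n - n // 2)])
    exact = exact_change_probabilities(x)
    posterior = bcp_segment(
        x, ChangePointConfig(iterations=iterations, burnin=burnin, seed=seed + 1)
    )
    return {
        "max_abs_error": float(np.max(np.abs(posterior.change_probability - exact))),
        "n": n,
    }


def strata_recovery_check(
    seed: int,
    x_length: int = 2_000_000,
    window_bp: int = 5_000,
    fn_rate: float = 0.02,
    fp_rate: float = 1e-6,
) -> dict:
    """Recover the 16-stratum layout from noisy replicate VCFs.

    A stratum counts as recovered when a called stratum matches both of
    its boundaries within two windows.  The two strata whose scaled
    lengths fall below one window are physically unresolvable at this
    window size.
    """
    rng = np.random.default_rng(seed)
    from .simulate import _random_sequence

    x_seq = _random_sequence(rng, x_length)
    strata = default_strata(x_length)
    _xprime, variants, _realized = apply_strata(x_seq, [], strata, rng)
    background = draw_background(x_seq, 50, rng, exclude=set(variants))
    with tempfile.TemporaryDirectory() as tmp:
        paths = emit_replicate_vcfs(
            variants, background, x_seq, tmp, rng, fn_rate=fn_rate, fp_rate=fp_rate
        )
        rep1 = read_vcf(paths[("XprimeX", 1)], "XprimeX", 1)
        rep2 = read_vcf(paths[("XprimeX", 2)], "XprimeX", 2)
    consensus = consensus_variants(rep1, rep2)
    series = window_density(consensus, "X", x_length, window_bp, genome_seq=x_seq)
    posterior, kept = segment_density_series(
        series, ChangePointConfig(iterations=500, burnin=50, seed=seed + 1)
    )
    calls = call_strata(posterior, series, kept, prob_threshold=0.5, min_windows=1)
    recovered = evaluate_strata_recovery(
        [s.interval for s in strata], calls, tol_bp=2 * window_bp
    )
    return {
        "recovered": recovered,
        "n_truth": len(strata),
        "n_called": len(calls),
        "n": x_length,
    }


def kmer_binning_check(
    seed: int,
    x_length: int = 300_000,
    autosome_length: int = 300_000,
    coverage: float = 15.0,
    k: int = 27,
) -> dict:
    """Bin carrier reads with marker k-mers learned from read spectra.

    Recall is measured over X'-template pairs that carry at least one
    true X-X' difference (pairs identical to the ancestral X are not
    markable even in principle); the false rate over autosomal pairs.
    """
    config = StudyConfig(
        x_length=x_length,
        autosome_length=autosome_length,
        n_genes=0,
        strata=default_strata(x_length),
        disrupted_fraction=0.0,
        silenced_fraction=0.0,
        coverage=coverage,
        error_rate=0.0,
        n_background=0,
        seed=seed,
    )
    study = simulate_study(config)
    rng = np.random.default_rng(seed + 1)
    t1, t2 = study.reads("XprimeX", rng)
    o1, o2 = study.reads("X0", rng)
    table_target = count_kmers_in_seqs((s for _i, s in t1 + t2), k)
    table_other = count_kmers_in_seqs((s for _i, s in o1 + o2), k)
    thresholds = default_thresholds(table_target, table_other)
    classification = classify_kmers(table_target, table_other, thresholds)
    pairs = [(rid, s1, s2) for (rid, s1), (_r, s2) in zip(t1, t2)]
    result = bin_reads(pairs, classification.target_specific, k, min_hits=1)
    binned = set(result.binned_ids)

    var_pos = np.fromiter(study.truth.variants.keys(), dtype=np.int64)
    var_pos.sort()
    read_len = config.read_len

    def has_variant(start: int, end: int) -> bool:
        intervals = ((start, start + read_len), (end - read_len, end))
        for lo, hi in intervals:
            i = np.searchsorted(var_pos, lo)
            if i < len(var_pos) and var_pos[i] < hi:
                return True
        return False

    labelled = auto = labelled_binned = auto_binned = 0
    for rid, _s1, _s2 in pairs:
        _serial, template, start, end = parse_read_id(rid)
        if template == "Xprime" and has_variant(start, end):
            labelled += 1
            labelled_binned += rid in binned
        elif template not in ("X", "Xprime"):
            auto += 1
            auto_binned += rid in binned
    return {
        "recall_pct": 100.0 * labelled_binned / labelled,
        "false_pct": 100.0 * auto_binned / auto,
        "n_marked_pairs": labelled,
        "n_autosomal_pairs": auto,
        "n_marker_kmers": len(classification.target_specific),
        "n": len(pairs),
    }


def effects_agreement_check(seed: int, n_cases: int = 1000) -> dict:
    """Agreement of codon-arithmetic SNV effects with the translation oracle."""
    rng = np.random.default_rng(seed)
    genome, genes = simulate_genome(
        rng, {"X": 200_000}, n_genes=60, mean_cds_codons=150
    )
    chrom = genome["X"]
    agree = 0
    for _ in range(n_cases):
        gene = genes[rng.integers(0, len(genes))]
        span = gene.span
        pos0 = int(
            rng.integers(max(0, span.start - 20), min(len(chrom), span.end + 20))
        )
        ref = chrom[pos0]
        alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
        variant = VariantRecord("X", pos0 + 1, ref, alt)
        impl = classify_snv(gene, genome, variant).effect
        oracle = snv_effect_by_translation(gene, genome, pos0, alt)
        agree += impl == oracle
    return {"agreement_pct": 100.0 * agree / n_cases, "n": n_cases}


def degradation_recovery_check(seed: int, n_genes: int = 250) -> dict:
    """Recover planted disrupted and silenced gene sets at zero call noise."""
    config = StudyConfig(
        x_length=400_000,
        autosome_length=0,
        n_genes=n_genes,
        mean_cds_codons=150,
        fn_rate=0.0,
        fp_rate=0.0,
        n_background=30,
        seed=seed,
    )
    study = simulate_study(config)
    rng = np.random.default_rng(seed + 1)
    with tempfile.TemporaryDirectory() as tmp:
        paths = study.write_vcfs(tmp, rng)
        xp = [read_vcf(paths[("XprimeX", r)], "XprimeX", r) for r in (1, 2)]
        x0 = [read_vcf(paths[("X0", r)], "X0", r) for r in (1, 2)]
    xp_consensus = consensus_variants(*xp)
    x0_consensus = consensus_variants(*x0)
    specific = subtract_background(xp_consensus, x0_consensus)
    annotated = annotate_variants(study.genes, study.genome, specific)
    disrupted_called = classify_disruption(annotated)

    tpm_matrix = tpm(study.counts, study.gene_lengths)
    expressed = stage_expression(tpm_matrix, study.sample_meta)
    report = classify_status(
        study.truth.ortholog_pairs, disrupted_called, expressed
    )

    def pr(called: set[str], truth: set[str]) -> tuple[float, float]:
        tp = len(called & truth)
        precision = tp / len(called) if called else 1.0
        recall = tp / len(truth) if truth else 1.0
        return precision, recall

    dis_p, dis_r = pr(report.disrupted_genes, study.truth.disrupted_genes)
    sil_p, sil_r = pr(report.silenced_genes, study.truth.silenced_genes)
    return {
        "disruption_precision": dis_p,
        "disruption_recall": dis_r,
        "silencing_precision": sil_p,
        "silencing_recall": sil_r,
        "degraded_fraction_pct": report.degraded_fraction_pct,
        "n": n_genes,
    }
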