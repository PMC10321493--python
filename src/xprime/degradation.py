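"""Functional-degradation classification of single-copy homolog pairs.

A nonrecombining homolog's gene copy can decay by pseudogenizing
mutations (frameshifts, start/stop gains and losses) or by
transcriptional silencing.  This module intersects replicate variant
calls, subtracts the shared background seen in the reference genotype,
flags disrupted genes from annotated effects, calls expression from
TPM with a within-sample noise floor, and combines both axes into a
per-pair status.  A log2 fold-change screen between karyotypes tests
whether intact copies of degraded genes are dosage compensated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .effects import DISRUPTIVE, AnnotatedVariant
from .io import Genotype, VariantRecord


# ---------------------------------------------------------------------------
# variant set algebra
# ---------------------------------------------------------------------------

VariantKey = tuple[str, int, str, str]


def consensus_variants(
    rep1: list[VariantRecord], rep2: list[VariantRecord]
) -> list[VariantRecord]:
    """Variants called identically (allele and genotype) in both replicates.

    Missing genotypes never form a consensus.
    """
    by_key = {
        v.key: v.genotype
        for v in rep2
        if v.genotype is not Genotype.MISSING
    }
    return [
        v
        for v in rep1
        if v.genotype is not Genotype.MISSING and by_key.get(v.key) == v.genotype
    ]


def subtract_background(
    target: list[VariantRecord], background: list[VariantRecord]
) -> list[VariantRecord]:
    """Remove variants also present in the background genotype's calls."""
    bg_keys = {v.key for v in background}
    return [v for v in target if v.key not in bg_keys]


def classify_disruption(annotated: list[AnnotatedVariant]) -> set[str]:
    """Gene ids carrying at least one pseudogenizing effect."""
    return {
        a.gene_id for a in annotated if a.gene_id and a.effect in DISRUPTIVE
    }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: rate = count/length, scaled to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every gene needs a positive length")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero_cols = totals[totals == 0].index
    if len(zero_cols):
        import logging

        logging.getLogger("xprime").warning(
            "all-zero sample column(s): %s", ", ".join(map(str, zero_cols))
        )
        totals = totals.replace(0, np.nan)
    out = rate.div(totals, axis=1) * 1e6
    return out.fillna(0.0)


def expressed_call(tpm_matrix: pd.DataFrame, quantile: float = 0.001) -> pd.DataFrame:
    """Per-gene, per-sample expressed flags.

    A gene is nonexpressed in a sample if its TPM is zero or falls below
    the within-sample ``quantile`` of nonzero TPMs (a floor absorbing
    stochastic read mismapping).
    """
    if not (0 < quantile < 1):
        raise ValueError("quantile must lie in (0, 1)")
    flags = pd.DataFrame(False, index=tpm_matrix.index, columns=tpm_matrix.columns)
    for col in tpm_matrix.columns:
        vals = tpm_matrix[col]
        nonzero = vals[vals > 0]
        if nonzero.empty:
            continue
        # the empirical (lower) order statistic: in a sample of 10,000
        # nonzero TPMs the bottom ~10 fall below it and are flagged
        floor = float(np.quantile(nonzero.to_numpy(), quantile, method="lower"))
        flags[col] = (vals > 0) & (vals >= floor)
    return flags


def stage_expression(
    tpm_matrix: pd.DataFrame,
    sample_meta: pd.DataFrame,
    quantile: float = 0.001,
    genotype: str = "XprimeX",
) -> dict[str, pd.DataFrame]:
    """Stage-level expressed flags per chromosome of origin.

    Replicate samples of the same (stage, origin) are aggregated by mean
    TPM before thresholding.  Returns {origin: genes x stages flags}.
    """
    meta = sample_meta[sample_meta["genotype"] == genotype]
    out: dict[str, pd.DataFrame] = {}
    for origin, group in meta.groupby("origin"):
        stage_cols = {}
        for stage, sub in group.groupby("stage"):
            stage_cols[stage] = tpm_matrix[sub["sample"].tolist()].mean(axis=1)
        stage_tpm = pd.DataFrame(stage_cols)
        out[origin] = expressed_call(stage_tpm, quantile)
    return out


# ---------------------------------------------------------------------------
# per-pair status
# ---------------------------------------------------------------------------


class GeneStatus(str, Enum):
    FUNCTIONAL = "functional"
    DISRUPTED = "disrupted"
    SILENCED = "silenced"
    SILENCED_AND_DISRUPTED = "silenced_and_disrupted"


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Report-style percentage, half-up rounded (123/2321 -> 5.3)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    q = Decimal(10) ** -decimals
    return float(
        Decimal(100.0 * numerator / denominator).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass
class DegradationReport:
    status: dict[str, GeneStatus]
    counts: dict[str, int]
    fractions_pct: dict[str, float]
    degraded_fraction_pct: float
    per_stage_expressed: pd.DataFrame
    excluded_pairs: list[str] = field(default_factory=list)

    @property
    def disrupted_genes(self) -> set[str]:
        return {
            g
            for g, s in self.status.items()
            if s in (GeneStatus.DISRUPTED, GeneStatus.SILENCED_AND_DISRUPTED)
        }

    @property
    def silenced_genes(self) -> set[str]:
        return {
            g
            for g, s in self.status.items()
            if s in (GeneStatus.SILENCED, GeneStatus.SILENCED_AND_DISRUPTED)
        }


def classify_status(
    ortholog_pairs: dict[str, str],
    disrupted: set[str],
    expressed_by_origin: dict[str, pd.DataFrame],
) -> DegradationReport:
    """Combine disruption flags and expression into a per-pair status.

    A pair (keyed by the ancestral-copy gene id) is silenced when the
    ancestral copy is expressed in at least one stage and the derived
    copy is expressed in none of those stages.  Pairs without expression
    rows are excluded and tallied.
    """
    expr_x = expressed_by_origin.get("X")
    expr_xp = expressed_by_origin.get("Xprime")
    status: dict[str, GeneStatus] = {}
    excluded: list[str] = []
    for x_id, xp_id in ortholog_pairs.items():
        if (
            expr_x is None
            or expr_xp is None
            or x_id not in expr_x.index
            or xp_id not in expr_xp.index
        ):
            excluded.append(x_id)
            continue
        x_stages = expr_x.loc[x_id]
        xp_stages = expr_xp.loc[xp_id]
        x_on = x_stages[x_stages].index
        silenced = len(x_on) > 0 and not xp_stages[x_on].any()
        is_disrupted = x_id in disrupted
        if silenced and is_disrupted:
            status[x_id] = GeneStatus.SILENCED_AND_DISRUPTED
        elif silenced:
            status[x_id] = GeneStatus.SILENCED
        elif is_disrupted:
            status[x_id] = GeneStatus.DISRUPTED
        else:
            status[x_id] = GeneStatus.FUNCTIONAL
    counts = {s.value: 0 for s in GeneStatus}
    for s in status.values():
        counts[s.value] += 1
    total = len(status)
    fractions = {k: percent(v, total) if total else 0.0 for k, v in counts.items()}
    degraded = total - counts[GeneStatus.FUNCTIONAL.value]
    per_stage = _per_stage_counts(expr_x, expr_xp, ortholog_pairs)
    return DegradationReport(
        status=status,
        counts=counts,
        fractions_pct=fractions,
        degraded_fraction_pct=percent(degraded, total) if total else 0.0,
        per_stage_expressed=per_stage,
        excluded_pairs=excluded,
    )


def _per_stage_counts(
    expr_x: pd.DataFrame | None,
    expr_xp: pd.DataFrame | None,
    pairs: dict[str, str],
) -> pd.DataFrame:
    if expr_x is None or expr_xp is None:
        return pd.DataFrame(columns=["stage", "x_expressed", "xprime_expressed"])
    x_ids = [x for x in pairs if x in expr_x.index]
    xp_ids = [pairs[x] for x in pairs if pairs[x] in expr_xp.index]
    rows = []
    for stage in expr_x.columns:
        rows.append(
            {
                "stage": stage,
                "x_expressed": int(expr_x.loc[x_ids, stage].sum()),
                "xprime_expressed": int(expr_xp.loc[xp_ids, stage].sum())
                if stage in expr_xp.columns
                else 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dosage compensation
# ---------------------------------------------------------------------------


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Library-size factors from the median of per-gene count ratios."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has positive counts in every sample")
    log_geo = np.log(positive).mean(axis=1)
    factors = np.exp(np.log(positive).sub(log_geo, axis=0).median(axis=0))
    return factors


def dosage_compensation_test(
    counts_carrier: pd.DataFrame,
    counts_reference: pd.DataFrame,
    degraded_genes: set[str],
    log2fc_threshold: float = 0.5,
    pseudocount: float = 1.0,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Screen sex-linked genes for upregulation in the carrier karyotype.

    Both matrices are genes x samples of counts over the same gene set;
    library sizes are equalized by median-of-ratios before means are
    compared.  A gene is upregulated when
    log2((mean_carrier + c) / (mean_reference + c)) exceeds the
    threshold.  With ``n_permutations`` > 0 a sample-label permutation
    p-value (BH-adjusted) is added.
    """
    if counts_reference.shape[1] == 0:
        raise ValueError("no reference-karyotype samples")
    joint = pd.concat([counts_carrier, counts_reference], axis=1)
    factors = median_of_ratios_size_factors(joint)
    norm = joint.div(factors, axis=1)
    carrier_cols = list(counts_carrier.columns)
    reference_cols = list(counts_reference.columns)

    def log2fc(frame: pd.DataFrame, cols_a: list, cols_b: list) -> pd.Series:
        mean_a = frame[cols_a].mean(axis=1)
        mean_b = frame[cols_b].mean(axis=1)
        return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    fc = log2fc(norm, carrier_cols, reference_cols)
    out = pd.DataFrame(
        {
            "mean_carrier": norm[carrier_cols].mean(axis=1),
            "mean_reference": norm[reference_cols].mean(axis=1),
            "log2fc": fc,
            "upregulated": fc > log2fc_threshold,
            "degraded_homolog": [g in degraded_genes for g in norm.index],
        }
    )
    if n_permutations > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        all_cols = carrier_cols + reference_cols
        n_a = len(carrier_cols)
        exceed = np.zeros(len(norm), dtype=np.int64)
        obs = np.abs(fc.to_numpy())
        for _ in range(n_permutations):
            perm = rng.permutation(all_cols)
            perm_fc = log2fc(norm, list(perm[:n_a]), list(perm[n_a:]))
            exceed += (np.abs(perm_fc.to_numpy()) >= obs).astype(np.int64)
        pvals = (exceed + 1) / (n_permutations + 1)
        out["p_perm"] = pvals
        out["q_perm"] = _benjamini_hochberg(pvals)
    return out


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.clip(ranked, 0, 1)
    return out


# ---------------------------------------------------------------------------
# contingency comparison
# ---------------------------------------------------------------------------


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)
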