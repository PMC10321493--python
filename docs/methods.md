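# Methods

This note documents the models, parameter choices and numerical decisions
behind `xprime`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate and format conventions

All internal intervals are 0-based half-open; VCF (1-based, indel-anchored on
the preceding base) and GFF3 (1-based inclusive) are converted at the I/O
boundary only. Multi-allelic VCF sites are split into biallelic records, the
genotype of each split record evaluated against its own ALT. N bases are
excluded from every callable-site denominator. Sequences are restricted to
A/C/G/T/N and uppercased on read.

## k-mer classification and read binning

Canonical k-mers are the lexicographic minimum of a k-mer and its reverse
complement; k must be odd so no k-mer is its own complement. The default
k = 27 matches the marker length used for short-read chromosome assignment in
this system. Joint spectra of two read sets separate into ploidy clouds:
error k-mers near the origin, carrier-specific k-mers at haploid depth on the
carrier axis only, shared X-linked k-mers haploid in the reference male but
diploid in the carrier female, and autosomal k-mers diploid in both.

Peak finding smooths the count histogram with a width-3 moving average and
takes local maxima beyond the error cutoff (counts > 2). The tallest maximum
is read as the haploid peak unless a companion peak sits near half its
location with at least 5% of its mass, in which case the pair is read as
(haploid, diploid) — necessary because in a carrier read set most k-mers are
shared between the two homologs and the diploid cloud dominates.

Classification thresholds are deliberate choices, config-exposed, not taken
from any external source: a k-mer is an error if both counts ≤ 2,
carrier-specific if its reference count ≤ 2 and its carrier count lies in
[0.25, 2.5] × the carrier haploid peak, and shared classes are assigned by
nearest ploidy peak per axis. Binning is pair-level — one mate containing
≥ `min_hits` (default 1) marker k-mers bins both mates — preserving pairing
for downstream assembly. The closed form (1 − e)^k for the error-free k-mer
probability quantifies why this works for short reads only: at the ~13%
error rate of uncorrected long reads, barely 2% of 27-mers are intact.

## Windowed divergence and change-point segmentation

Heterozygous SNV sites per window, divided by the window's non-N length,
proxy the carrier-vs-ancestral divergence D_xy. The window default is
100 kb for chromosome-scale data; the bundled desk-scale analyses use 5-kb
windows because a 2-Mb synthetic X must still contain ~400 windows for a
16-block segmentation to be meaningful. Whether invariant sites were
genotyped is not observable from a variants-only VCF, so the non-N
denominator is the default; an all-sites VCF changes the D_xy scale but not
the segmentation geometry.

Segmentation implements the Barry–Hartigan product-partition Gaussian model:
given change indicators ρ with b changes, the marginal partition score is

    P(ρ | x) ∝ ∫₀^p0 p^b (1−p)^(n−1−b) dp · ∫₀^w0 w^(b/2) / (W + Bw)^((n−1)/2) dw

with W the within-block and B the between-block sum of squares. The p
integral is an incomplete beta function; the w integral is evaluated by
100-node Gauss–Legendre quadrature in log space (data are standardized
first, and W is floored at 1e-12 to guard the degenerate all-equal-blocks
case). A Gibbs sweep resamples every indicator from its conditional odds,
maintaining W and B incrementally. Priors and run lengths follow the
reference defaults for this model family: p0 = w0 = 0.2, 500 iterations, 50
burn-in, fully seeded. Post-burn-in indicator frequencies are the change
probabilities; the average of block means is the posterior mean.

Correctness is checked against exhaustive enumeration of all 2^(n−1)
partitions under the same score for short series (max marginal discrepancy
≤ 0.05 with 2,500 iterations), a constant-series null, a permutation null,
and two-segment simulations.

Stratum calling cuts at local maxima of the change probability above 0.5
(the probability threshold and local-maximum rule are this package's
decisions), merges blocks shorter than `min_windows` into the more similar
neighbor, attaches missing windows to the stratum on their left so strata
tile the analyzed interval, and labels S1… left to right.

## Dating

Generations since divergence: T = D_xy/(2r), or V/(2rS) from V synonymous
variants over S synonymous sites. The clock bracket pairs the fast mutation
rate (4.9×10⁻⁹ per site per generation) with the short generation time
(24 days) for the lowest estimate and the slow rate (2.8×10⁻⁹) with 40-day
generations for the highest; the midpoint is their mean; years use 365
days/year (365.25 breaks third-decimal agreement with the published table).
Report values are half-up rounded to 3 decimals in Ma; full precision is
kept alongside. In the bundled published table the "highest" column is the
slow-clock age of the *neutral* (synonymous) divergence — reproduced by
rescaling the neutral midpoint by 2·f_slow/(f_slow+f_fast) ≈ 1.489 — with
the D_xy-based slow-clock age as fallback for the stratum without homologs.
No multiple-hit correction is applied; divergences here are far below
saturation.

Synonymous sites use fractional (Nei–Gojobori-style) counting: each CDS site
contributes (synonymous alternatives)/3, cross-checked by exhaustive
single-mutation enumeration; a `fourfold_only` switch counts strictly 4-fold
sites instead. Stop-retaining changes at stop codons count as synonymous.

## Variant effects

SNVs map to CDS coordinates honoring strand (alleles complemented on −),
codons are recomputed, and one effect is assigned per (variant, gene) under
the fixed severity order start_loss > stop_gain > stop_loss > missense >
synonymous (only the disrupted/intact dichotomy matters downstream; the
order exists for determinism). Indels classify by the net CDS-overlapping
length change L: frameshift iff L mod 3 ≠ 0, in-frame otherwise, noncoding
if L = 0. Splice effects are out of scope (genes are modeled per-CDS). The
production classifier is validated against an independent oracle that edits
the coding sequence, translates both versions and reads the effect off the
protein diff — 100% agreement over 1,000 random gene × variant cases.

## Degradation classification

Only variant calls identical (position, alleles, genotype, non-missing) in
both replicates are kept; carrier-specific variants are the consensus set
minus the reference-genotype (X0) consensus, removing ancestral X
polymorphisms and reference errors. A gene is disrupted if it carries ≥ 1
frameshift or start/stop gain/loss.

TPM is computed per sample; a gene is expressed when its TPM is nonzero and
at or above the within-sample 0.1% quantile of nonzero TPMs. The quantile is
the lower empirical order statistic, so in a sample of ~10,000 nonzero genes
the bottom ~10 are floored — absorbing stochastic read mismapping without
discarding the minimum of small gene sets. Stage-level calls aggregate
replicates by mean TPM first. A homolog pair is silenced when the ancestral
copy is expressed in ≥ 1 stage and the derived copy in none of those stages;
silenced ∧ disrupted is its own class; the four statuses partition the pairs.

Dosage compensation: X-linked totals of carrier (X′X) and reference (XX)
females are library-size normalized by median-of-ratios (a fully specified
stand-in for TMM), and a gene is upregulated when
log2((mean_carrier + 1)/(mean_reference + 1)) > 0.5 (pseudocount 1 is this
package's choice). An optional sample-label permutation p-value
(≥ 1,000 permutations, BH-adjusted) provides the significance layer, since
the exact test behind the original screen is unspecified. Group counts are
compared with Pearson chi-square on 2×2 tables without continuity
correction.

## Synthetic data: what it emulates, and what it does not

The generator produces, from one seed, a byte-identical study: random
chromosomes with non-overlapping translatable genes (ATG start, stop end, no
internal stops, ~half on the minus strand); an X′ derived by per-site
substitution at stratum-specific probabilities; disruption events (1–2-bp
frameshift indels, premature stops, start/stop losses, one per selected
gene, 5.3% of genes by default) and a disjoint 2% silenced set; paired-end
reads with per-genotype ploidy (X0: X+2A, XX: 2X+2A, X′X: X+X′+2A; coverage
is per template copy, so X′-specific positions show half the autosomal
depth); replicate VCFs with independent false-negative dropout (default
0.02) and Poisson false positives (default 1e-6/bp — caller error rates are
not published, so both are exposed placeholders), plus shared background
polymorphisms present in every genotype; and negative-binomial counts
(dispersion 0.1, lognormal gene means, 4 stages mirroring
embryo/larva/pupa/adult) with origin-binned carrier columns and diploid XX
columns.

Two deliberate idealizations keep ground truth exact: background stratum
substitutions inside CDS are constrained to changes that neither create nor
destroy start/stop codons (so the disrupted truth set is exactly the
injected events), and sequencing errors are substitution-only. The default
stratum layout scales the published 16 relative lengths 1:30 onto a 2-Mb X;
its divergence values lie in the observed range (0.0006–0.016) and are
arranged so adjacent contrasts — including across the two strata whose
scaled lengths (~3.3 kb) fall below one 5-kb window — are ≥ 3×. Those two
sub-window strata are unresolvable by construction, which is why the
recovery check targets ≥ 14/16. A recovered stratum is one whose two
boundaries are each matched by a called boundary within ±2 windows; a
spurious interior cut is thus a precision error (an excess of calls), not a
recall failure.

Passing these recovery tests shows the pipeline's stages are correct and
well-calibrated under the generator's assumptions — independent sites, no
TEs or repeats, no mapping bias, clean ploidy, known gene models. It does
not show that the real chromosome segments into exactly 16 strata, nor
validate alignment, variant calling or assembly, all of which are upstream
of this package.

## Problem sizes

Desk-scale defaults keep every analysis in seconds to a couple of minutes on
one core: 2-Mb chromosomes for segmentation (≈ 400 windows × 500 Gibbs
sweeps), 300-kb chromosomes at 15× per-copy coverage for k-mer work (~26M
k-mer lookups), 250–300 genes for degradation. All sizes are configurable
through `StudyConfig`.
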