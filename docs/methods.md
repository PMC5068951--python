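# Methods

`barseqfit` implements the analysis stack for pooled-fitness screening by
barcode sequencing (Bar-seq): a library of deletion mutants, each carrying
two strain-specific barcodes (an *uptag* and a *dntag*), is grown
competitively for *d* generations with and without a toxicant; barcode
abundances read out each mutant's fitness. This note records the models,
estimators and numerical choices, and what the synthetic-data generator
does and does not emulate.

## Pool growth model

Mutant *i* starts at abundance `a_i0` and doubles at relative rate `g_i`
(1.0 = wild-type-like). After `d` pool doublings its expected abundance is

    a_i(d) = a_i0 * 2^(g_i * d)

Under treatment `g_i` is scaled by the *treatment fitness* `f_i ∈ [0, 1]`,
the fraction of its own baseline doublings the mutant still achieves.
Sequencing observes a multinomial draw of the per-sample read depth over
the normalized abundances. Initial abundances default to equal; a
log-normal spread (`lognormal_abundance`, σ configurable) models uneven
pooling.

## Growth-inhibition (GI) score

Counts are library-size normalized to counts-per-million after adding a
pseudocount (default 1; configurable). For a screen with `d` doublings
(default 5):

    GI_i = log2(c_i / t_i) / d

with `c`, `t` the normalized control and treatment values. An unaffected
mutant scores ≈ 0; a mutant that stops dividing entirely scores ≈ 1,
because it misses all `d` doublings (a 2^5 = 32-fold relative depletion at
d = 5). Constitutively slow growers are handled by the structure of the
ratio itself — slow growth depresses both arms equally and cancels — not
by an extra per-mutant correction. Uptag and dntag counts of the same
sample are summed before scoring (configurable: sum, one tag only, or
keep separate); summing maximizes effective depth and is common Bar-seq
practice.

GI is *compositional*: strongly depleted mutants shrink the treatment pool,
which inflates every other mutant's share and offsets all GI values by
`-log2(renormalization)/d`. The robust-Z centering below absorbs this
offset, which is why parameter-recovery tests compare *median-centered*
GI to the planted `1 - f`.

Mutants missing from a sample propagate NaN through GI, Z and FDR; they
are never imputed.

## Robust Z and tail-area FDR

Within a screen, each mutant's deviation from the median GI is expressed
in units of the normalized interquartile range:

    Z_i = (GI_i − median(GI)) / NIQR,   NIQR = IQR / 1.349

1.349 is the IQR of a standard normal, so NIQR is a robust σ estimate that
true hits (tail outliers) cannot inflate. A screen where NIQR = 0 (≥ 75%
of scores identical) is rejected as degenerate.

The tail-area false discovery rate is an empirical-null re-implementation
in the fdrtool style (half-normal empirical null):

1. Fit a half-normal scale σ₀ to the central bulk of |Z| — the values
   below the 0.75 quantile — by truncated maximum likelihood (1-D bounded
   scalar minimization on log σ).
2. Estimate the null fraction π₀ as the observed central mass divided by
   the null mass below the cutoff, capped at 1.
3. Fdr(z) = min(1, π₀ · P₀(|Z| ≥ |z|) / F̂(|Z| ≥ |z|)), with F̂ the
   empirical exceedance, then enforced non-increasing in |z| by a running
   maximum from the largest |z| down.

Guards: ≥ 100 finite Z values required; the fit is rejected when the
implied π₀ < 0.5 (more than half the mass in the tail) or when the central
bulk misfits the truncated half-normal grossly (Kolmogorov–Smirnov
distance > 0.2), both signs that the score distribution is not
null-dominated. This is a deliberate re-implementation, not a binding of
the original fdrtool software; outputs may differ in the second decimal.

## Hit calling and expressivity

A mutant is called sensitive to a compound iff in *every* screen where it
was assayed: FDR ≤ cutoff (default 0.1) **and** GI > 0 (depletion
direction; enrichment never qualifies). Mutants significant in at least
one but not all of their screens form the *rescreen-candidate* list — the
set a bench follow-up (spot dilution assay) would retest. Mutants missing
from some screens are judged on the screens where they are present.

Expressivity grades the effect size from mean GI: high ≥ 0.6,
medium ≥ 0.25, low otherwise. The cutoffs are configuration, spanning the
planted-class expectations (GI 0.1 / 0.4 / 1.0 for f = 0.9 / 0.6 / 0.0);
published screens describe their own cutoffs as arbitrary and do not print
them.

## Growth assay and dose selection

Screening doses are those inhibiting the wild-type growth *rate* by
10–20% (rates, not endpoint OD). The rate estimator is the slope of
log2(OD) over the contiguous window (≥ 6 points) maximizing the R² of a
log-linear fit. Exact R² ties — noiseless or saturated curves, where
several segments fit perfectly — are broken toward the larger slope, then
the longer window, then the earlier start, so a stationary plateau never
outranks the exponential phase. A constant window is treated as a perfect
zero-slope fit (R² = 1); windows containing non-positive ODs are excluded,
and a curve with no valid window is an error.

The curve generator emulates the dose-finding assay: mid-log cultures at
OD600 ≈ 0.2, readings every 30 min for 16 h, each reported value the mean
of three technical repeats with Gaussian read noise per repeat
(`noise_sd`, default 0). Growth is exponential until a carrying-capacity
plateau (default 1.5). The saturation is a hard cap rather than a smooth
logistic bend: the exponential phase is then exactly log-linear, so the
window estimator's closed-form recovery can be verified to numerical
precision. Lag phases, smooth logistic shoulders, and evaporation drift
are not modelled; passing tests bound estimator behavior only under
exponential-plus-plateau kinetics.

## Overlap and clustering

Hit-list overlap uses the two-sided Fisher exact test (point-probability
criterion, via `scipy.stats.fisher_exact`) on the 2×2 table
(both, A-only, B-only, neither) over a configurable gene universe, plus
exact Venn partition counts.

GI profiles (mutants × screens) are clustered by unweighted average
linkage (UPGMA, `scipy.cluster.hierarchy`) on the uncentered correlation
distance

    d(x, y) = 1 − Σxᵢyᵢ / √(Σxᵢ² · Σyᵢ²) ∈ [0, 2]

the Cluster 3.0 pairing for expression heat maps. Means are not
subtracted, so profiles must agree in sign and magnitude. Missing values
are dropped pairwise with at least 2 complete positions required — the
distance step resolves all missingness, and the linkage step rejects NaN.
Note the uncentered correlation distance violates the triangle inequality;
it is a dissimilarity, not a metric. Clustering is gene-axis by default,
restricted to the union hit list; scipy's tie-breaking is deterministic,
so dendrograms are reproducible. Dendrograms export as Newick plus an
ordered matrix TSV for heat-map rendering.

## Enrichment

For a hit list of `n` genes and a term annotating `K` of `N` background
genes with `k` in the list: fold enrichment `(k/n)/(K/N)` (reported raw
and integer-rounded as screening tables print it), upper-tail
hypergeometric p (over-representation only), Benjamini–Hochberg q across
terms, significance at α = 0.01 by default. Term members outside the
universe are dropped with a count. Two backgrounds matter in the
fission-yeast setting and are both supported: 5135 protein-coding genes
(default) or the 2902 mutants that actually received a score; the table
records which was used. GO-graph ancestor propagation and annotation
retrieval are out of scope — the collection is whatever GMT is supplied.

## Synthetic reads

Reads are `sample index (3–4 nt) + constant spacer + barcode (20 nt)`,
padded with A to 42 nt, with substitution errors i.i.d. per base across
the whole read. This layout is the package's own convention, recorded in
the run manifest and shared by the counter; it is a stand-in, not a claim
about any archived sequencing run's primer scheme. Synthetic barcode sets
enforce pairwise Hamming distance ≥ 3 within a tag class by rejection
sampling, making one-mismatch matching provably unambiguous; the counter
nevertheless handles real-world ties by refusing to assign them
(`ambiguous` QC category). Demultiplexing is exact on the index (a 3–4 nt
index cannot absorb a mismatch without sample collisions), so with
error rate *e* the expected assignable fraction is
`(1−e)^L_idx · [(1−e)^20 + 20e(1−e)^19]` — about 97.6% at e = 0.005 —
and read loss is uniform across mutants, leaving shares unbiased.
Indel and quality-score error models, PCR amplification bias, and
paired-tag chimeras are not simulated.

## Reproducibility and problem sizes

Every stochastic step runs off an explicit seed; identical configs produce
byte-identical FASTQ and tables. Seed streams derive from
`(seed, stage, row-position)` so a sample's draw does not depend on how
units are grouped into files.

The test suite exercises the study-scale conditions directly where they
are cheap (3000 mutants at depth 10⁶ for estimator consistency and hit
recovery; 10⁵ draws for NIQR calibration) and smaller casts elsewhere
(30–300 mutants, depths 2×10⁴–10⁵) chosen so that sampling-noise bounds
derived analytically still discriminate real defects. The acceptance
script reports the infinite-depth GI of a fully inhibited mutant in a
3000-strain pool from expected endpoint abundances (0.9999; the 1/3000
share the dead mutant retains keeps it just below 1 exactly).

## Known limitations

- The tail-area FDR differs numerically from the original fdrtool
  (different truncation-point selection and no Grenander smoothing of the
  empirical CDF); ranks and cutoff decisions agree in simulation, exact
  FDR values need not.
- GI assumes a common doubling count `d` for the whole pool; per-mutant
  doubling counts (e.g. density-dependent effects) are not modelled.
- The 0-h time point sample that real screens harvest is accepted in
  manifests but unused: the score compares control vs treatment endpoints
  only.
- Index assignment trusts the sample sheet; index hopping between samples
  is not modelled or detected.
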