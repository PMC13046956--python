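# Methods

This note documents the statistical model behind each `mcc` pipeline stage,
the synthetic cohort generator's assumptions, the numerical choices taken
where behaviour had to be pinned down, and the known limitations of the
approach.

## Study design assumed by the pipeline

The pipeline targets a paired longitudinal case–control design: donors come
in matched pairs (one case who progresses to disease, one control matched
on birth date within a year), each sampled at three timepoints — T1 before
seroconversion, T2 soon after, T3 near diagnosis — and profiled in three
single-cell data layers: cytosolic scRNA, single-nucleus RNA (snRNA) and
single-nucleus open chromatin (snATAC), the latter two captured jointly as
a multiome on the same nuclei. Cell-type labels are taken as input and are
assumed to be already collapsed to five parent lineages (Monocyte, B, CD4T,
CD8T, NK) plus `not_assigned`; upstream processing (demultiplexing,
clustering, label transfer, peak calling) is outside the package's scope.

## Pseudobulk and normalization

Counts are summed over cells per donor × timepoint × lineage sample.
`not_assigned` cells are excluded; donors with no cells in a stratum are
absent rather than zero-filled. Per-million values scale each sample row to
1e6 within the tested feature universe; RPKM further divides by feature
length in kb. A sample with zero total reads has undefined normalizations
(NaN, flagged) rather than zeros. The representation filter keeps
(lineage, timepoint) strata where a configurable fraction of donors
(default 0.75) contribute at least a minimum number of cells (default 10),
which guards interpretability of pooled tests; both knobs are configurable
because the appropriate floor depends on capture depth.

## The observed/expected Fisher test

For each feature in a stratum the test compares pooled group reads in the
feature against pooled group reads in all other features of that layer,
i.e. it tests equality of the feature's *fraction* of the group's read
pool. Assumptions: reads within a group are exchangeable multinomial draws
— donors are pooled, not modelled. Consequences, both demonstrated in the
test suite:

- under a pure multinomial null the test is calibrated to slightly
  conservative (discrete p-values; P(p ≤ a) ≤ a);
- with donor-level biological variability (overdispersion) the pooled test
  is **anti-conservative** — the suite plants gamma overdispersion 0.2 on a
  no-effect cohort and records a null rejection rate many times the nominal
  level. Significant hits should therefore be read together with the
  replication layer, which is the design's guard against this inflation;
- because the read pool is closed, a genuine change in one feature dilutes
  all others ("compositional" echo), so large planted effects induce weak
  opposite-direction associations in unaffected features.

Numerical choices: the two-sided p-value uses the probability-mass rule
(sum of hypergeometric probabilities ≤ the observed table's, with 1e-7
relative slack to make the inclusion boundary reproducible across float
implementations). The implementation enumerates the support with log-gamma
arithmetic and normalizes by the summed support mass; it matches an exact
rational-arithmetic oracle to better than 1e-9 relative error over all
tables with total ≤ 40 and sampled larger tables, and scipy's
`fisher_exact` to ~1e-14. Effects are E = (control fraction)/(case
fraction): E < 1 ⇔ up in cases. Zero fractions yield 0/∞ sentinels, never
pseudocounts. BH q-values are computed within each layer × lineage ×
timepoint stratum (the reported per-timepoint discovery rates imply
stratified families); q is the standard step-up cumulative minimum, clipped
at 1.

The discreteness of exact p-values matters for calibration studies: the
null distribution has an atom at p = 1 of order 1.6/√(feature reads), so a
Kolmogorov–Smirnov comparison against the continuous uniform is only
meaningful when per-feature counts are large. The calibration tests run in
that regime (≈8k reads per feature per group) and pass KS in 20/20 seeds;
at low depth KS fails on the atom alone even though tail calibration is
exact.

## Replication across data layers

The orthogonal "data layers" for an association discovered at one
(layer, timepoint) cell are all other {scRNA, snRNA, snATAC} × {T1, T2, T3}
cells. Evidence requires q < 0.1 and concordant direction; each cell
contributes at most one evidence unit, whether reached directly (same
feature id) or through a peak–gene link (cross-modality), where a
negative-correlation link flips the required direction. Only links that
themselves passed independent replication may carry evidence (configurable)
— nominal links would otherwise manufacture replication. An association is
"replicated" when evidence cells ≥ required_layers − 1 (default 2 total
layers). Same-timepoint/other-modality and other-timepoint/same-modality
evidence are weighted equally.

Overlap enrichment between two significant sets uses expected overlap
|A||B|/U and an upper hypergeometric tail. The adjacency statistic counts
consecutive same-chromosome peak pairs that are both significant; its null
permutes significance labels uniformly over the tested peaks (default 1000
seeded permutations) and is cross-checked against the closed form
Σ_chrom (n_c − 1)·k(k−1)/(n(n−1)), which reduces to k(k−1)/n on a single
chromosome.

## Peak–gene links

Candidate pairs are all peaks within 1 Mb of a gene TSS; distance is 0 if
the TSS lies inside the peak, otherwise the distance to the nearest peak
edge (edge rather than centre makes "TSS inside ⇒ 0" exact). Distance
classes are half-open: [0, 5 kb) promoter, [5, 20 kb) proximal,
[20, 500 kb) distal, [0.5, 1 Mb] long-range. Correlation is Pearson across
pseudobulk samples shared by the two tables (per-million scale), with the
t-transform p-value on n−2 df; pairs with <3 shared samples or zero
variance are skipped with a reason code, and replication failures due to
missing data are marked untestable rather than failed. Correlation is
computed at the sample level, not per cell: the replication pairing
(standalone chromatin × independent scRNA) shares no cells, so samples are
the only common currency; this also keeps discovery deterministic and
desk-scale. No GC-matched background correction is applied — discovery is
by the stated nominal thresholds (p < 0.05, |r| > 0.05) and the burden of
multiplicity is carried by independent replication (|r| > 0.65, same sign).
Link densities divide per-class link counts by the searchable space
(2 × class width × number of genes with a TSS), in links per kb.

## QTL scan

For each index variant, features within 1 Mb (genes anchored at the TSS,
peaks at the interval) are tested per lineage × timepoint: Spearman rank
correlation between donors' alternate-allele dosage and per-million signal.
Missing dosages drop the donor; tests with <5 informative donors or
constant input are skipped. Midranks handle ties; the p-value uses the
t-approximation t = ρ√((n−2)/(1−ρ²)) except for n ≤ 9 where the exact
permutation distribution is enumerated. Bonferroni correction multiplies by
the number of completed tests in the (lineage × modality) family. The
locus-overlap summary counts, per variant, Bonferroni-significant QTL
features and case–control-significant features within a closed 100 kb
window, and their intersection.

## Age trajectories and endotypes

Per donor group (cases or controls), each feature's per-million signal
(optionally log1p-transformed; untransformed is the default as the response
specification names the pseudobulk expression itself) is regressed on age
at draw across donor × timepoint samples by closed-form simple OLS; BH is
applied within group × lineage × layer. A trait is *shared* when q < 0.1 in
both groups with the same slope sign, group-specific when significant in
exactly one, discordant when significant in both with opposite signs.
Summary medians of q and r² are pooled over the class-defining group
records. When recovering planted log-linear trends, the log1p response
makes the OLS slope directly comparable to the planted per-year log-fold
slope; coverage of the 95% t-interval is verified in simulation at depths
where the log-count noise is approximately Gaussian (≥30 reads per feature
per sample) — at very low counts the t-interval's assumptions fail and
coverage is not guaranteed.

Endotype analyses subset to the labelled cases (strict IAA-first, default
21 of 49; loose GADA-first, default 11 of 49, scaled proportionally for
smaller synthetic cohorts) and *their pair-matched controls only*,
preserving the age matching; statistics and FDR are bit-identical to the
full analysis restricted to that donor set. The endotype overlap reports,
per lineage × timepoint × direction, the fraction of replicated full-cohort
signals that are also significant with the same direction in the endotype
run; direction matching uses the E-orientation, not effect magnitude.

## The synthetic cohort generator

What it emulates: matched pairs (default 49) with strictly increasing ages
per donor (T1/T2/T3 means ≈1.6/3.0/6.0 years, truncated normal gaps,
control within ±0.9 years of its case at every timepoint); three data
layers with the multiome layers drawn from the same nuclei (shared
barcodes) and scRNA from independent cells; five-lineage composition
(defaults Monocyte 0.25, B 0.15, CD4T 0.30, CD8T 0.15, NK 0.15); per-cell
depth Poisson around the configured layer mean; a heavy-tailed lognormal
baseline abundance shared across donors; `cells_per_sample_mean` (default
2278) counts measurements per sample summed over configured layers, so each
capture pool draws mean/len(layers) cells.

Planted-effect channels, all multiplicative on expected feature
proportions: case-restricted fold changes per lineage/timepoint/layer;
peak–gene links driven by a shared per-(donor, timepoint) standard-normal
latent mapped through exp with log-scale loading s (default 0.8), with the
latent correlation analytically pre-compensated for lognormal attenuation
(ρ = log(1 + |r|·(e^{s²}−1))/s²) so the realized level correlation targets
`target_r`; negative targets load the gene with opposite sign, and
`target_r = 0` yields matched decoys (same marginal variance, independent
latents); per-allele log-fold QTL effects on Hardy–Weinberg genotypes at
configurable MAF (missing dosages are masked after effects are applied —
the biology happened, the call is missing); log-linear age trends centred
at 3 years with both/case-only/control-only scope; endotype-restricted fold
changes affecting only labelled cases, never their controls; optional
donor-level gamma overdispersion (mean 1, variance = `overdispersion`)
shared across timepoints, the knob used to demonstrate the pooled test's
anti-conservativeness.

What it does not emulate: raw reads, doublets, ambient RNA, batch effects,
cluster substructure within lineages, per-cell coupling of multiome
modalities (links are donor-level latents, so cell-level co-accessibility
methods cannot be validated against it), linkage disequilibrium between
variants, and the study's standalone snATAC capture (link replication pairs
the snATAC pseudobulk with the independent scRNA layer instead). A green
recovery test therefore establishes that the statistics recover the stated
generative signals at the stated scales — not robustness to the artefacts
above.

Determinism: one seeded `numpy` Generator drives all draws in a fixed
order; identical configs give byte-identical written cohorts.

## Known limitations

- The pooled Fisher test ignores donor-level variance; its significance
  under real biological overdispersion is inflated by construction, and the
  replication framework — not the p-value — is the robustness claim.
- The closed read pool makes effects compositional: strong signals induce
  opposite-sign echoes in unaffected features.
- Fisher p-values are discrete; calibration diagnostics against continuous
  references need large counts.
- Sample-level link correlations cannot separate cell-intrinsic
  co-activity from donor-level composition shifts; with few samples the
  |r| > 0.65 replication bar is the effective multiplicity control.
- The age regression is a two-parameter OLS per feature; it does not model
  within-donor correlation across timepoints, so its p-values are mildly
  optimistic when donor random effects are present.
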