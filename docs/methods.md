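# Methods

This note documents the statistical models behind `gcprofiler`, the
synthetic-data generator that exercises them, the numerical choices made
where the design was genuinely open, and the limits of what passing tests
demonstrate.

## Cohort definitions

Samples carry two independent labels: a Lauren histopathology type
(diffuse / intestinal / mixed / unknown) and a molecular subtype
(EBV / MSI / GS / CIN). Four analysis cohorts are derived from the sequenced
samples:

- **diffuse** — Lauren diffuse;
- **non-diffuse** — Lauren intestinal *only*; mixed and unknown samples are
  excluded from the comparator rather than lumped into it, so the contrast
  is histologically clean;
- **GS** — molecular genomically-stable;
- **non-GS** — every other sequenced sample.

Note the asymmetry: diffuse + non-diffuse does not cover the cohort, while
GS + non-GS does. Diffuse and GS overlap heavily by construction of the
biology (the default simulated cohort puts 39 of 55 GS samples in the
diffuse type); much of the downstream design deals with the consequences of
that overlap.

## Significantly mutated genes

### Counting

Protein-altering classes are missense, nonsense, frameshift indel, in-frame
indel, and splice site; silent and non-coding classes are excluded. Counting
is per (sample, gene, position, ref, alt) event with exact duplicates
removed — a hotspot recurrent in *k* samples contributes *k*. This keeps
per-cohort rates comparable across cohort sizes. A `unit="unique_site"` mode
collapses identical sites across samples for sensitivity analyses; whether
hypermutators should be capped is left to the caller (no capping is
applied).

### Background model and test

The background is a single global rate: *r = M / L*<sub>tot</sub>, where *M*
sums counted mutations over all genes and *L*<sub>tot</sub> sums coding
lengths over the entire gene-length table, including genes with zero
mutations. No covariates (expression, replication timing) enter the model.

Genes with *x<sub>g</sub> > e<sub>g</sub>* = *r L<sub>g</sub>* are tested
right-tailed. The default `conditional_exact` method conditions on the total
count: under the null that the gene shares the global per-bp rate, its count
is Binomial(*M*, *L<sub>g</sub>*/*L*<sub>tot</sub>), and
*p = P(X ≥ x<sub>g</sub>)*. This is the conditional construction that exact
two-sample rate-ratio tests reduce to, with the comparator arm being all
other genes. The `poisson_tail` alternative uses the unconditional
Poisson(*e<sub>g</sub>*) tail; the two agree closely whenever
*L<sub>g</sub> ≪ L*<sub>tot</sub> and *M* is large (binomial→Poisson limit,
asserted to 10% relative in tests at *e<sub>g</sub>* ≤ 1, *M* = 20 000).

P-values are computed for *all* genes (the `tested` flag gates significance
calls only), so counterpart p-values are always defined for the differential
step.

### Storey q-values

π̂₀(λ) = #{p > λ} / (m(1 − λ)) is evaluated on λ = 0.05, 0.10, …, 0.95 and
smoothed with a cubic polynomial fit evaluated at λ = 0.95, capped into
[0, 1]. The fit is weighted by the inverse standard deviation of π̂₀(λ)
(∝ √((1−λ)/λ)), because the high-λ grid points are both the most informative
about the null proportion and by far the noisiest — at m = 2000 the raw
π̂₀(0.95) has binomial sd ≈ 0.097, and an unweighted endpoint evaluation
inherits most of that variance. With the weights the estimator is unbiased
to within a few percent on a uniform null (mean ≈ 0.97 across seeds) with
per-seed sd ≈ 0.05; any single-λ or spline estimator of π̂₀ at this m has
spread of that order, which is why the calibration check asserts the mean
across seeds, not each seed. Below m = 100 the single-point plug-in at
λ = 0.5 is used. q-values are the usual step-up cumulative minimum
q(p₍ᵢ₎) = min₍ⱼ≥ᵢ₎ π̂₀ m p₍ⱼ₎ / j, computed with a stable sort so ties and
permutations behave predictably.

q-values are computed over all genes in the length table (not only the
`tested` subset), which is the more conservative and order-independent
contract.

### Significance and differential extraction

A gene is significant when tested ∧ p < 0.01 ∧ q < 0.25. The differential
set at fold *k* contains genes significant in the target cohort with
*p*<sub>out</sub>/*p*<sub>in</sub> ≥ *k*; both p-values are floored at
1e-300 before the ratio so the statistic log₁₀ *p*<sub>out</sub> −
log₁₀ *p*<sub>in</sub> is always finite. For fold > 1 the two directions of
extraction are disjoint by construction.

### Null calibration and discreteness

An exact test on counts is discrete: its attained level at the nominal 0.01
is always ≤ 0.01, and at per-gene expectations of a few events it sits
around 0.5–0.8 of nominal. The calibration check therefore brackets the
pooled fraction of null genes at p < 0.01 with the 99% binomial band of a
single 1000-gene cohort ([0.0019, 0.0181]) — wide enough to admit the
inherent conservatism of any exact test, tight enough to catch a broken one
(measured pooled fraction ≈ 0.006–0.007). No exact test can match nominal
size to pooled-across-seeds precision, so that stricter reading would be
unfalsifiable-by-design rather than informative.

## Network partition

Edges come from a STRING-style table; `combined_score` on the 0–1000 scale
is rescaled to [0, 1] and the default confidence cutoff is 0.4 (the usual
medium-confidence convention). Self-loops are dropped and duplicate pairs
keep the maximum score.

Within the subgraph induced by A ∪ B, the four counters — in-A, in-B, inter,
and shared-incident — are disjoint, so they sum to the number of retained
edges. The per-gene fraction series applies the shared-gene policy: an
exclusive gene's edge to a shared (A ∩ B) gene counts as within-set, since
shared genes are the connectors of the two sub-networks; shared genes
themselves contribute no fraction row (their "own set" is ambiguous). With
that policy *f*<sub>in</sub> + *f*<sub>inter</sub> = 1 for every counted
gene.

The paired t-test runs per set on *d<sub>g</sub>* = *f*<sub>in</sub> −
*f*<sub>inter</sub> over genes with at least one counted edge, two-sided
(the original report does not state sidedness; two-sided is the conservative
choice). When the sample variance is exactly zero the test is degenerate and
is reported as p = 0 with a warning if the common difference is non-zero,
else (t, p) = (0, 1). Which pairing unit the original analysis used is
ambiguous; per-gene fractions are one defensible reading and are stated as
such, not claimed as the only one. Label-swapping A and B swaps the
statistics exactly.

## Mutational signatures

### Context classification

SNVs are classified into the 96 trinucleotide categories on the pyrimidine
strand: purine-reference records are reverse-complemented (alleles and
flanks) first. Contexts are taken from an input column rather than a
reference genome lookup, keeping the package download-free; a record whose
stored context disagrees with its reference allele is left unclassified with
a warning rather than failing the run, since single inconsistent rows are
common in real exports. Strand invariance is asserted exhaustively over all
192 (ref, alt, flank) configurations.

### NMF

The per-sample spectrum matrix V (samples × 96) is factorized as V ≈ WH by
multiplicative updates under the Frobenius objective: 10 random starts,
2000 max iterations, relative-error tolerance 1e-6, seed 17 by default, best
start kept by final error. The error trace is recorded and is non-increasing
(a property of the updates, asserted in tests). H's rows are renormalized to
probability profiles with the scale folded into W, so exposures are in
mutation counts. Results are bit-identical for a fixed seed. The
implementation is deliberately in-package — the per-iteration monotonicity
contract and best-of-starts determinism are part of the module's tested
surface — and is cross-checked against scikit-learn's NMF in the test suite.

The rank is unknown in practice; `scan_ranks` reports reconstruction error
and explained variance over k = 2…6 and `pick_rank_elbow` selects the
interior rank with maximal discrete curvature of the error curve. On planted
rank-3 spectra the elbow lands on 3 in ≥ 80% of seeds; all per-k outputs are
written so the choice remains inspectable.

### Catalog matching

Each extracted signature is assigned its argmax-cosine catalog column;
assignments below cosine 0.75 are labelled `unassigned`. The packaged
catalog generator (`synthetic_catalog`) produces **synthetic** stand-in
profiles — sparse Dirichlet draws with COSMIC-style names and shape (96 × 30,
columns summing to 1) — because the measured COSMIC v2 profiles cannot be
redistributed here. Its columns are mutually near-orthogonal (max pairwise
cosine ≈ 0.56), which makes planted-mixture recovery tests meaningful; any
real catalog TSV in the same layout can be passed instead.

## Synthetic cohort generator

The generator emulates the study conditions: the default cross-table
reproduces the sequenced-cohort margins (289 samples; 67 diffuse /
192 intestinal / 19 mixed / 11 unknown; 55 GS, of which 39 diffuse). Cell
counts beyond those margins are not published and were fixed once at
plausible values.

Per sample, the mutation burden is negative-binomial (mean 20, dispersion 2
— ≈ 12 mutations/Mb on the simulated 1.7 Mb gene space, a realistic mixed
gastric-cohort figure given the MSI fraction) and mutations are allocated
multinomially with probability ∝ coding length × a planted driver
multiplier. Gene lengths are lognormal (median 1.5 kb, σ = 0.6); planted
drivers get a fixed 2.7 kb coding length (CDH1-like) so that detection power
is governed by the planted multiplier rather than the length lottery. A
driver planted in several cohorts is elevated at its multiplier in samples
of *any* of them (max, not product). About 10% of events are frameshift
indels without context; SNV contexts are drawn from the cohort's signature
mixture over the catalog, and half the SNV records are emitted on the purine
strand to exercise the reverse-complement path. Default mixtures share four
signatures across all subtypes and give GS one distinguishing signature,
mirroring a shared-backbone / subtype-specific structure. Positions are
uniform within concatenated gene blocks on a synthetic chromosome; exact
duplicate collisions are allowed and exercise the dedupe rule. The optional
hypermutator toggle inflates one sample's burden. Everything is
deterministic given the seed, to the byte in the written files.

What the generator does **not** emulate: real trinucleotide abundance of the
exome, gene-level covariates of mutability (expression, replication timing),
subclonal structure, MSI-specific indel signatures, or the heavy-tailed
hypermutator distribution of real cohorts. Passing recovery tests therefore
shows the statistics are implemented correctly and identifiable under their
own model — not that the single-rate background is adequate for real tumor
exomes (it demonstrably is not for genes like TTN; that limitation is shared
with the modelled analysis).

### Recovery test design

Two configurations are used deliberately:

- **Study-overlap configuration** (the default): measures sensitivity and
  observed FDR of the planted 8× drivers, and shared-driver membership in
  both differential sets. A driver planted only in GS is genuinely elevated
  in the diffuse cohort here (39 shared samples), so such genes are scored
  as true positives, and exclusivity *cannot* be asserted — the leak is the
  shared-gene phenomenon itself. Conversely this design is the robust home
  for the shared-membership check, because the non-GS counterpart dilutes
  the shared driver's contamination (28 elevated among 234).
- **Crossed configuration** (diffuse samples all CIN, GS samples all
  Lauren-mixed, intestinal/CIN background; 300 samples): diffuse ∩ GS = ∅
  and each counterpart is clean where it matters, so each exclusive driver
  appears in exactly one differential set.

Planted-truth assertions run at fixed seeds, as is standard for stochastic
recovery tests; the acceptance script reports the same metrics averaged over
five replicate cohorts.

## Numerical choices

- P-value floor 1e-300 before ratios; p clipped into (0, 1]; x = 0 returns
  exactly 1.
- Storey sort is stable; cumulative-minimum enforcement makes the result
  order-independent.
- NMF denominators carry an additive 1e-12 guard; the spectral scale
  initialization is √(mean(V)/k).
- Degenerate inputs: empty cohorts produce all-zero spectra and p = 1
  everywhere; a cohort with zero classifiable SNVs is skipped with a warning
  in the CLI; empty differential sets produce empty network outputs and exit
  code 0.

## Known limitations

- The single global background rate ignores gene-level mutability
  covariates; long, late-replicating genes will inflate the false-positive
  tail on real data.
- The Storey π̂₀ estimator is intentionally the canonical λ-grid smoother;
  at small m it falls back to a cruder plug-in.
- The shared-gene network policy is one defensible convention; counts are
  also reported strictly so alternative conventions can be recomputed from
  the output.
- The packaged signature catalog is synthetic; matching results on real data
  require supplying a real catalog in the same TSV layout.
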