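# gcprofiler

Subtype-stratified somatic mutation profiling for cancer cohorts, built
around the comparison of gastric cancer's histopathological **diffuse type**
(Lauren classification) with its molecular **genomically stable (GS)**
subtype — two cohorts that overlap heavily yet carry distinct mutation
profiles. The package is for computational cancer-genomics practitioners who
want the full chain from a somatic mutation table to subtype-preferential
driver genes, network statistics, and mutational signatures, with every
stage testable on synthetic cohorts carrying planted ground truth.

## What it computes

**Significantly mutated genes (SMGs).** Pooled over a cohort, *M*
protein-altering mutations fall on genes with total coding length
*L*<sub>tot</sub>, giving a background rate *r = M / L*<sub>tot</sub> per bp.
A gene of length *L<sub>g</sub>* with *x<sub>g</sub>* observed mutations and
expectation *e<sub>g</sub> = r L<sub>g</sub>* is tested one-sided for an
elevated rate only when *x<sub>g</sub> > e<sub>g</sub>*:

- `conditional_exact` (default): the exact conditional rate-ratio test,
  *p = P(Bin(M, L<sub>g</sub>/L<sub>tot</sub>) ≥ x<sub>g</sub>)*;
- `poisson_tail`: *p = P(Poisson(e<sub>g</sub>) ≥ x<sub>g</sub>)*.

Multiple testing uses Storey q-values (π̂₀ from the λ-grid smoother); calls
require *p* < 0.01 and *q* < 0.25.

**Differential significance.** A gene significant in a target cohort whose
counterpart-cohort p-value is at least *k*-fold larger (default *k* = 10;
*k* = 100 for the strictest set) is subtype-preferential; the statistic is
log₁₀ *p*<sub>out</sub> − log₁₀ *p*<sub>in</sub>.

**Network partition.** Given both differential gene sets and a scored
interaction edge table (STRING-style), edges of the induced subgraph are
classified as within-set, cross-set, or shared-gene-incident; per-gene
fractions *f*<sub>in</sub> and *f*<sub>inter</sub> feed a paired t-test on
*d<sub>g</sub> = f*<sub>in</sub> − *f*<sub>inter</sub> per set.

**Mutational signatures.** SNVs with flanking context are placed in the 96
trinucleotide categories (pyrimidine-strand convention); per-sample spectra
are factorized by multiplicative-update NMF (Frobenius objective, best of
*n* random starts) and the extracted 96-dimensional profiles are matched to
a reference catalog by cosine similarity.

**Synthetic cohorts.** `simulate_cohort` generates all five input tables
with planted drivers, signature mixtures, and network modules, defaulting to
the sequenced-cohort structure of the motivating study (289 samples:
67 diffuse / 192 intestinal, 55 GS / 234 non-GS, 39 in both).

## Worked example

```python
from gcprofiler import SmgModel, differential_extract

lengths = {"CDH1": 2700, "TP53": 1200, "FILLER1": 1500, "FILLER2": 1800}
diffuse_counts = {"CDH1": 12, "TP53": 4, "FILLER1": 1}
intestinal_counts = {"CDH1": 1, "TP53": 6, "FILLER2": 2}

res_d = SmgModel(diffuse_counts, lengths).fit()
res_i = SmgModel(intestinal_counts, lengths).fit()
print(res_d.summary())
print(differential_extract(res_d, res_i, fold=10))
```

prints

```
Significantly mutated genes
================================================================
method:            conditional_exact
genes scored:      4
total mutations:   17
total length (bp): 7200
background rate:   0.002361 per bp
thresholds:        p < 0.01, q < 0.25
significant genes: 1
----------------------------------------------------------------
         observed  expected  p_value  q_value  significant
gene
CDH1           12      6.38  0.00582   0.0233         True
TP53            4      2.83    0.311    0.623        False
FILLER1         1      3.54    0.981        1        False
FILLER2         0      4.25        1        1        False
          p_in     p_out  log10_ratio
gene
CDH1  0.005821  0.985448     2.228646
```

CDH1 is the one significant gene (12 observed vs. 6.38 expected,
p = 0.0058 < 0.01, q = 0.023 < 0.25) and its counterpart p-value is about
170-fold larger (log₁₀ ratio 2.23), so it survives both the 10-fold and the
100-fold differential filter. The same flow on a simulated 289-sample cohort
recovers planted 8× drivers with sensitivity 1.0 and observed FDR ≈ 0.05
(see `gcprofiler.simulate.end_to_end_recovery`).

The command-line pipeline mirrors the library:

```bash
gcprofiler simulate --outdir sim/
gcprofiler smg --mutations sim/mutations.tsv --clinical sim/clinical.tsv \
    --gene-lengths sim/gene_lengths.tsv --outdir smg/
gcprofiler network --diff-a smg/differential_diffuse_vs_non_diffuse.tsv \
    --diff-b smg/differential_gs_vs_non_gs.tsv --edges sim/edges.tsv --outdir net/
gcprofiler signatures --mutations sim/mutations.tsv --clinical sim/clinical.tsv \
    --outdir sigs/
```

Each stage writes a JSON run manifest (version, config snapshot, input
digests, row counts, seed) next to its outputs.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and what it does and does not emulate, numerical choices, and
known limitations.
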