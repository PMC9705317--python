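# Methods

This note documents the models and numerical choices behind each pipeline
stage, what the synthetic-cohort generator does and does not emulate, and
the design decisions taken where several defensible options existed.

## The synthetic cohort generator

### Divergence model

Per variant site, an ancestral allele frequency `p` is drawn from the
ancestral spectrum (below). Population frequencies arise by Beta drift
along a rooted hierarchy: a child node's frequency is Beta-distributed
with mean `q` (the parent's frequency) and variance `q(1−q)·F_edge`
(the Balding–Nichols model). Diploid genotypes are independent Bernoulli
draws of two alleles at the population frequency.

The hierarchy is fitted to the configured pairwise-F matrix by UPGMA
(average linkage), treating the matrix entries as ultrametric node heights;
each edge's drift is the height difference between its endpoints. For two
leaves j, k whose most recent common ancestor sits at height h, the
expected Hudson F_ST is

    E[F_ST(j,k)] = (c_j + c_k) / 2,   c = 1 − Π(1 − F_edge) over the path,

independently of drift shared above the MRCA, so pairwise targets are
recovered exactly to second order in F (for the study-scale values ≤ 0.03
the approximation error is ~0.3% relative). The study-configuration matrix
(0.003 between the TD/PV analogues, 0.03 for every pair involving an RK
analogue) yields exactly the intended two-level topology. Matrices that are
not ultrametric are approximated by their UPGMA projection.

Because the ultrametric fit equalises total root-to-leaf drift, it cannot
by itself express *between-population diversity differences*. The
`pop_extra_f` knob adds terminal Beta drift to named populations, lowering
their heterozygosity by the factor (1 − F_extra) while raising their
pairwise divergence — the joint signature of a diverging, low-diversity
clade such as the RK2-analogue. The study configuration leaves it empty.

### Ancestral spectrum

Two options:

- `uniform` (default): p ~ U(0.05, 0.95). Dense intermediate-frequency
  polymorphism; avoids degenerate monomorphic draws and gives every site
  high information content for structure analyses. Sites that end up
  monomorphic in the sampled cohort are retained (they exercise the
  invariant-site census).
- `neutral`: density ∝ 1/p on [0.001, 0.999] (log-uniform draw), the
  infinite-sites equilibrium shape. Under this spectrum with no drift,
  E[π] ≈ E[θ_W] (truncation makes the ratio ≈ 1.01 at n = 56), which is
  the regime used to validate the diversity estimators against each other.

### Planted features

- **Sweeps**: inside a configured interval, the target population's
  terminal-edge F is replaced by `f_sweep` (validated to exceed every
  background pairwise F). This reshapes allele-frequency divergence only —
  deliberately not a haplotype/hitchhiking model; it is sufficient to
  exercise window and threshold logic. Linkage disequilibrium,
  recombination and demography are out of scope.
- **Outliers**: each outlier individual is drawn from its *own* private
  Balding–Nichols population with large drift (default F = 0.5, a free
  parameter — no quantitative description of real outliers was available).
  Giving each outlier an independent draw makes them isolated points in
  PCA space rather than a spurious extra cluster.
- **Mislabels**: genuine draws from one population (default the
  RK2-analogue) whose recorded collection site/label is another
  population's (default the PV-analogue). They are *extra* samples on top
  of the configured population sizes, so the study configuration is
  41 + 156 + 58 + 28 assigned-population samples + 9 mislabeled + 10
  outliers = 302.
- **Multiallelic sites**: a configured fraction (default 0.134) of
  segregating sites have their alternate-allele copies relabelled into two
  (or, for a 0.056 share, three) alternate alleles, conserving the total
  allele count; the first copies are forced distinct so the intended class
  is guaranteed.
- **Coverage metadata**: median coverage ~ N(35, 6) clipped at 12×,
  breadth-at-1× ~ U(0.90, 0.995) — a cohort that passed sequencing QC.
  Missingness defaults to 0 (QC-passing, site-filtered data); the
  statistics' handling of partial calls is unit-tested directly.

### Reference and gene models

Contigs are i.i.d. random nucleotide sequences with implanted single-exon
CDS genes: ATG, a run of sense codons, a stop codon; minus-strand genes
are implanted as reverse complements so the annotated strand reads as a
valid ORF. Genes are non-overlapping, cover `gene_fraction` of each contig
(default 0.3) with lengths ~ U(0.5, 1.5)×`mean_gene_bp`, and one
mid-contig gene per contig (up to four) is labelled as a canonical
insecticide-resistance locus so the IR stage has configured targets.
Variant REF alleles match the reference base at the site.

Determinism: one global seed; every stochastic operation draws from a
named substream keyed by (seed, operation, contig index), so stages and
re-runs are independently reproducible bit-for-bit.

### What passing tests do and do not show

The generator reproduces the *statistical* structure the pipeline assumes
(drift-based differentiation, site-class mixture, isolated outliers,
label errors) but not linkage disequilibrium, sequencing error, batch
effects, or realistic gene architecture. Tests passing here demonstrate
that the estimators and decision rules are correct under their model
assumptions — not that real cohorts satisfy those assumptions.

## Quality control

A sample fails if median genome-wide coverage < 10× or breadth-at-1× <
80%; boundary values pass (the exclusion rule is phrased as "less than").
The site census counts distinct alleles among non-missing calls: 1 →
invariant, 2/3/4 → bi/tri/quadriallelic; a site is unclassified only when
every call is missing. Accessibility masks are an *input* (or trivially
all-true): the underlying short-read site filters are not re-derivable
from summary descriptions, so the pipeline treats accessibility as given
and uses the masked-in count as the denominator of per-base statistics.

## Population structure

- **Site selection**: biallelic segregating sites whose minor allele is on
  ≥ 2 chromosomes (non-singleton), autosomal contigs only; uniformly
  down-sampled (seeded) to 100,000 when the supply exceeds it.
- **PCA**: dosage 0/1/2, missing imputed to the site mean (avoids biased
  centering), per-site mean-centering, eigendecomposition of the sample
  Gram matrix. Component signs are arbitrary; they are fixed by convention
  (largest-magnitude coordinate positive) and all tests compare up to sign.
- **Outlier rule**: a sample is flagged on a component when
  |score − median| > 6 × MAD, with two guards. (a) *Structure guard*: if
  more than 5% of samples exceed the threshold along one component, that
  component is treated as population structure and skipped — a genuine
  cluster (e.g. 28 of 302 samples) sits hundreds of MADs out along its own
  axis, and a raw MAD rule would delete entire populations. (b)
  *Isolation gap*: a flagged sample must be ≥ 3 MADs from the nearest
  unflagged score on that component, which suppresses marginal tail
  fluctuations (a 6-MAD rule is ≈ 4σ under Gaussian noise, so over ~300
  samples × 10 components a false flag per run would otherwise be likely).
  Flagged samples are removed and the PCA loop repeats to a fixed point
  (≤ 20 iterations). The rule is scale-free and idempotent.
- **Assignment and mislabel flagging**: single linkage on the top PCs
  (default 2), cut at `cluster_cutoff` (default 0.15) × the largest
  pairwise distance. Each recorded label's *home* cluster is the cluster
  holding the majority of samples carrying that label; a sample in any
  other cluster is excluded as anomalous. The home-cluster rule is robust
  to two weakly diverged populations merging at 2 PCs: their samples still
  sit in their label's home cluster, while a mislabeled group clustering
  with a different population is flagged. Resolving k clusters generally
  needs k−1 components, so recovering all four study populations requires
  `n_pcs = 3`; the assigned/excluded counts are identical either way.
  Small noisy cohorts (tens of samples, few thousand sites) need a wider
  cut (≈ 0.3) because single-linkage chain noise grows relative to
  cluster separation.
- **Thinning for external structure tools**: biallelic sites with minor
  allele frequency strictly > 1%, evenly rank-spaced to exactly 50,000 per
  contig when the supply exceeds it.

## Diversity statistics

Computed genome-wide over the pooled four-fold degenerate accessible
positions of autosomal contigs > 2,000,000 bp. A third codon position is
four-fold degenerate iff all four substitutions there are synonymous;
positions covered by multiple CDS are flagged only if every covering frame
agrees; incomplete terminal codons and CDS running off the contig are
skipped (with a warning). Minus-strand codons are read on the reverse
complement and flags are placed on forward-strand coordinates.

Populations are first downsampled (seeded, without replacement) to a
common size, by default the smallest population. π uses each site's
realized called-chromosome count; θ_W counts any segregating site once
(multiallelic sites contribute all alleles to π); Tajima's D requires a
uniform chromosome count and therefore restricts to fully-called sites in
the downsampled set. D is NaN — never 0 — when no site segregates.

**Bootstrap CIs** resample individuals with replacement (100 replicates,
percentile 2.5/97.5). Duplicating individuals systematically depresses
diversity statistics (fewer distinct lineages per replicate), so the
replicate distribution is recentred on the full-sample point estimate
before taking percentiles; this removes the resampling bias while keeping
the bootstrap spread. A CI is flagged unreliable when > 20% of replicates
are undefined.

## Divergence and selection scan

Hudson's estimator (Bhatia et al. parameterisation) is used because it is
the convention of large *Anopheles* cohort projects and is unbiased under
the generator: the genome-wide ratio-of-sums equals the planted F in
expectation. Only biallelic sites enter; a usable site has ≥ 2 called
chromosomes in both populations and is polymorphic in their union.
Windows combine sites as Σnum/Σden (ratio of sums — avoids small-window
bias); contig and genome averages are means over window values.
Positional windows tile [0, contig length) half-open; SNP windows are
consecutive non-overlapping blocks of exactly 1000 usable SNPs with the
final partial block dropped (non-overlapping chosen; a stepped variant
was considered and rejected as it inflates run lengths).

Signal detection: threshold = 2 × the genome-wide mean window value for
that population pair (computed over all emitted windows on contigs > 2 Mb
before detection); candidate runs are maximal sets of consecutive
above-threshold windows (a gap tolerance is exposed, defaulting to 0 —
runs split by even one below-threshold window are distinct); runs of ≥ 5
windows become signals, ranked by peak window F_ST with ties broken by
contig id then position. Genes whose interval lies within 100 kb of the
peak midpoint (inclusive) are attached with signed distance to the nearest
feature edge (0 when overlapping the peak).

## Insecticide-resistance report

Gene coordinates are configuration (BED or YAML), not hard-coded — real
coordinates depend on the annotation in use, and the simulator supplies its
own. Every variant inside a region is decomposed into one record per
alternate allele; frequencies are per assigned population over non-missing
chromosomes, and a record is reported when its frequency strictly exceeds
2% in at least one population (the threshold applies to SNP alleles, not
annotated codon changes). Copy-number variation is out of scope.

## Orchestration

One YAML configuration drives all stages; statistical defaults equal the
study-scale values quoted above (10×/80% QC, 100,000 PCA sites,
50,000/contig thinning, MAF 0.01, downsampling to the smallest population,
100 bootstraps, 20-kb and 1000-SNP windows, run ≥ 5, multiplier 2, 100-kb
radius, 2% IR threshold). Unknown keys are rejected. Every run writes a
`manifest.json` with the parameter snapshot, seed and SHA-256 of each
output, so identical config + seed reproduces identical checksums. A
contig may be declared X-linked in the config; X-restricted PCA reuses the
same code path on the named contig.

## Problem sizes

The test suite and the acceptance script run the study-configuration
cohort at 4 contigs × 2.5 Mb × 32,000 sites (128,000 sites, 302 samples),
which leaves ~110,000 PCA-candidate sites — comfortably above the 100,000
selected — while completing the full structure stage in well under two
minutes on one CPU. Estimator-recovery experiments use 100,000 sites;
smaller unit-test cohorts use proportionally larger drift so the planted
structure stays resolvable at a few thousand sites.

## Known limitations

- No linkage disequilibrium: window statistics are over independent sites,
  so their sampling variance is lower than on real data at equal window
  size.
- The mislabel rule assumes each recorded label has a single home cluster;
  labels genuinely spanning several populations would need manual review.
- Accessibility masks and variant quality are taken as given; the pipeline
  starts from called genotypes.
- Tajima's D at study scale is computed over pooled degenerate sites, not
  as a sliding-window average, which matches a single-number-per-population
  presentation; windowed scans reuse the same kernels when needed.
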