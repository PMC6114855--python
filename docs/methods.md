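# Methods

## Count model and per-window test

Window read counts are negative binomial with the edgeR-style
dispersion parameterisation, Var(Y) = mu + phi·mu², used everywhere in
the package; phi = 0 is the Poisson limit. One common dispersion is
shared across windows: the comparisons of interest are plain two-group
contrasts with 6–13 samples per group, too few for stable per-window
dispersions, and no covariates are modelled (no GLM/quasi-likelihood
machinery).

Normalisation is TMM: the reference sample is the one whose
75th-percentile count fraction is closest to the mean of those
fractions; per sample, log2 ratios (M) and log2 abundances (A) over
windows positive in both samples are trimmed (30% M tails, 5% A tails),
and the surviving M values are averaged with inverse delta-method
variance weights. Factors are re-centred to geometric mean 1, and the
effective library size is raw size × factor.

Before testing, counts are linearly scaled and rounded to the geometric
mean of the effective library sizes. This "equalised pseudocount"
approximation keeps counts integral — required by the conditional exact
law — at the cost of a small rounding perturbation; full quantile
adjustment was not implemented because the linear form already passes
type-I calibration at the study's depths (null fraction of p < 0.05 is
0.047–0.052 across seeds at 2000 windows, 6 vs 6, phi = 0.1).

The common dispersion maximises the summed conditional log-likelihood
of the equalised counts given each group's window total (the
conditional law is mean-free), optimised on log10(phi) in [1e-6, 10] by
bounded scalar minimisation. Simulation recovery is essentially
unbiased at phi in {0.05, 0.1, 0.2} with 2000 windows.

The exact test conditions on the pooled window count S: the sum of n
iid NB(mu, phi) is NB(n·mu, phi/n), so the probability of a split
(a, S−a) is the product of the two group-sum masses, and the two-sided
p-value sums all splits with probability ≤ that observed. All mass
arithmetic is in log space with log-sum-exp; the ≤ comparison uses a
relative tolerance of 1e-12 so float evaluation order cannot flip a
tie, and when every split qualifies (the observed split is the mode)
p is exactly 1. Windows with zero total count across all samples are
dropped before testing; nothing else is filtered. Fold changes are
disease/non-disease group means with a 0.5 pseudocount added to both
means only when either is zero, keeping log ratios finite.
Benjamini–Hochberg FDR is computed over all tested windows of a
comparison (not per chromosome).

## DMR construction

Windows with p below the seed threshold (default 1e-5) nucleate DMRs.
Extension absorbs any window with p < 0.1 whose inter-interval gap to
the current span is ≤ 1000 bp (edge-to-edge distance, inclusive),
iterated to a fixed point; DMRs sharing windows or overlapping merge.
That fixed point equals single-linkage clustering of the sub-threshold
windows at the gap distance, which is how it is computed; the tests
verify the equivalence against a literal iterative-closure oracle on
1000 random instances. `n_significant_windows` counts members below
the seed threshold at the threshold in force — in the sweep report each
threshold therefore counts its own seeds. CpG number is the
forward-strand CG-dimer count of the span (the dimer is
strand-symmetric); density is per 100 bp of span; the reported fold
change is taken at the member window with the largest |log2 ratio|.
DMR clusters are single-linkage runs of DMR starts within 2 Mb
containing at least 3 DMRs — chromosome-map cluster boxes are
conventionally drawn by eye, so the definition here is
package-defined and configurable.

## Signatures, genes, PCA

Signature overlap is by genomic-interval intersection (≥1 bp),
transitively merged into overlap groups; each group lands in the Venn
cell of the diseases it contains, so cells sum to the number of groups.
Interval identity is deliberately not used: DMR boundaries differ
between comparisons run on the same grid. Gene association uses
inter-interval gap ≤ 10 kb (0 when overlapping). Functional categories
are tallied from a user-supplied gene→category map with an "unknown"
bucket — no live database queries.

PCA operates on samples × DMR-window RPKM (RPKM = count /
(window kb × library size/1e6)), mean-centred, unscaled and untransformed
by default since the read depth itself is the signal; log2(RPKM+1) is
available by flag. External cohorts are projected with the stored
centre and loadings, never refit, and their RPKM uses their own library
sizes — systematic cohort offsets therefore remain visible, which is
the point of the projection check. Separation is the mean silhouette on
the first two PCs.

## Pathology rules

Observer cutoffs are control mean + 2 SD per (tissue, observer), with
the n−1 SD (small control groups); a tissue is diseased on a 2-of-3
observer consensus, where an observer's mark requires the count to
*strictly* exceed the cutoff. With only two observers scored, both must
agree (conservative reading of the consensus rule); fewer than two is
an error. Ovarian calls compare section-averaged follicle and cyst
counts against control mean ∓/± 2 SD, strict inequalities, so boundary
values are healthy. Obesity/lean use ±1.5 SD cutoffs on the adipocyte
metric (mean of the 20 largest cells per image across 5 images) and BMI
(weight g / length cm²); by default both criteria must exceed their
cutoff, with an either-criterion mode available — protocols in this field list the
criteria without stating a combination rule, so both
readings are exposed and the conjunctive one is the default. Cohort
summaries exclude unevaluated (blank) records from each disease's
denominator, which is why evaluated populations differ per disease; the
multiple-disease tally counts animals with ≥2 true flags among all
animals. Frequency contrasts use two-sided Fisher's exact tests;
continuous traits use the classical equal-variance two-sample t-test
(with p = 1 when both variances are zero and means agree, p = 0 when
they differ).

## Synthetic data: what it emulates, what it does not

The generator is the package's study-conditions module; its defaults
are the conditions the tests run under.

**Genome.** Chromosomes (default 2 × 1 Mb) are random A/C/G/T sequence
scrubbed of accidental CG dimers, with CpG dinucleotides placed as a
Bernoulli field at 1.5 per 100 bp in deserts and 10 per 100 bp in
periodic 1-kb islands covering 10% of the genome. The realized CG count
is therefore exactly the placed count, and desert density lands within
a few percent of target.

**Coverage.** MeDIP is an immunoprecipitation: read depth concentrates
where methylated CpGs are, and at realistic depths (~30M reads against
tens of millions of 100-bp windows) a typical window holds well under
one read. The default coverage model therefore scatters ~150 methylated
loci of DMR-like size (0.5–1 kb, ≥5 kb apart, outside islands) through
the deserts; within a locus the window mean is proportional to its CpG
count, scaled so a window of average desert density has mean
`background_mean_count` (default 50 at the default library size);
outside loci a nonspecific floor of 0.5% of that mean applies, and
islands — high-CpG but unmethylated — are scaled by 0.05. True DMRs are
a subset of the loci, snapped to window boundaries, with the disease
group's mean multiplied or divided by the fold change (default 4).
A `flat` model (every window at the background mean) exists for
statistical-calibration runs. Library sizes are log-normal with CV 0.2.
The default dispersion 0.1 is a placeholder in the realistic range for
designed count experiments; no empirical estimate is available for these
data, and the estimator recovers it within a few percent in simulation.

Not emulated: read-level sequencing (no FASTQ, error model or mapping),
fragment-size smearing across adjacent windows, mappability and copy
number artefacts, chromosome-scale covariates. Passing tests therefore
demonstrate the statistics and the region-calling logic, not robustness
to alignment artefacts in real data.

**Cohort.** Disease labels follow the configured marginals (defaults
are the transgenerational F3 vinclozolin male frequencies) through a
Gaussian copula with equicorrelation rho = 1 − 1/comorbidity_odds, so
marginals are preserved exactly while odds > 1 concentrates disease in
fewer animals. Note that with marginals fixed, positive dependence
*raises* the fully-healthy fraction and the variance of the per-animal
disease count — that over-dispersion, not an increased P(≥2) (which is
pinned near 0.5 for ~50% marginals by symmetry), is the testable
comorbidity signature. Observer abnormality counts are
Poisson(0.5) for healthy tissue and Poisson(3.5) for diseased tissue,
making the mean + 2 SD rule sensitive (~0.95) but imperfect.

## Numerical and design choices

- 0-based half-open intervals internally; 1-based starts only in report
  tables. Reads are assigned to the window containing their midpoint —
  one integer count per read, preserving exact-test integrality;
  fractional-overlap assignment was rejected for that reason.
- Terminal short windows are kept; their true length is used in RPKM.
- DMR names are `{chrom}:{ordinal}` in start order, assigned after
  merging.
- Degenerate inputs error loudly rather than defaulting: empty control
  groups, all-zero samples, single-label silhouettes, constant PCA
  matrices, unknown chromosomes (named in the message).
- Determinism: every generator draws from `default_rng([seed, stream])`
  with fixed stream ids, so any artifact is byte-reproducible from its
  configuration; the pipeline writes a manifest with config hash and
  input checksums.

## Problem sizes

The bundled simulations use 2 × 1 Mb genomes (20,000 windows), 6 vs 6
samples, 30 true DMRs, and 2000-window calibration matrices — sizes
chosen so the full suite and the acceptance script each run in well
under a minute while leaving every statistical check adequately
powered (e.g. ~19,000 tested windows per recovery run, ≥170 BH
discoveries in the FDR check).

## Known limitations

- The exact test's equalised-count rounding is an approximation to
  quantile adjustment; at very low depths (< ~1 read/window in both
  groups) its p-values are conservative, which the calibration tests
  document but do not remove.
- TMM weights assume roughly binomial count sampling; with very few
  covered windows the factors are noisy (they are re-centred, so bias
  is bounded).
- The comorbidity copula cannot represent negative disease
  associations, and the observer-score model ignores inter-observer
  correlation beyond the shared disease state.
- Cluster calling (2 Mb / ≥3 DMRs) has no published ground truth; treat
  cluster lists as descriptive.
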