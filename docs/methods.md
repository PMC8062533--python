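# Methods

`atacmotif` re-implements, as one tested pipeline, the statistical chain
that links chromatin-accessibility counts to transcription-factor motif
activities and target genes in a two-condition ATAC-seq study (the
motivating setting is postnatal pancreatic-islet maturation: immature P10
islets against mature adult islets, three replicates each).  This note
records the models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## Differential accessibility

Counts of Tn5 insertions per accessible chromatin site (ACS) are modeled
as negative binomial with a common dispersion:
`var = mu + phi * mu^2`.

- **Normalization.** Library sizes times TMM factors (trimmed mean of
  M-values): against a reference sample (the one whose upper-quartile
  expression is closest to the mean upper-quartile), M-values are trimmed
  30% on each side and A-values 5% on each side, and the factor is the
  inverse-variance weighted mean of the surviving M-values, exponentiated
  and rescaled to geometric mean 1.  This matches the edgeR convention to
  ~0.3% on random count tables.
- **Dispersion.** One common `phi`, estimated by maximizing the
  *conditional* NB likelihood given each site's within-group sum.
  Conditioning eliminates the per-site group means exactly; a profile
  (plug-in mean) likelihood is biased low by roughly (n-1)/n at n = 3
  replicates, which is why the conditional form is used.  The search is
  golden-section on log(phi) in [1e-6, 10], tolerance 1e-4.  Degenerate
  inputs (all sites constant) return the lower bound with a warning.
- **Exact test.** Counts are first scaled to the geometric-mean effective
  library and rounded (a documented approximation to full quantile
  adjustment).  Conditional on the total t of the two group sums, the
  split is free of the common mean; the two-sided p-value sums the
  probabilities of all splits no more probable than the observed one
  (not a doubled tail).  At `phi = 0` this reduces to the conditional
  Binomial(t, n_A/(n_A+n_B)) test, which is asserted in the tests.  On
  simulated 3-vs-3 NB data the p-values agree with edgeR's exactTest with
  log10-p correlation > 0.999.
- **Effect size.** log2 fold-change of prior-augmented normalized group
  means (prior 0.5, scaled by relative effective library size), treatment
  (adult) minus reference (P10): positive means opening on maturation.
- **Classification.** Benjamini-Hochberg FDR; Up/Down require
  `p < 0.05` and `FDR < 0.2` (configurable; these defaults mirror the
  motivating study) plus the matching fold-change sign; everything else
  is Stable.

## Motif scanning

JASPAR-style position frequency matrices are converted to log2-odds
PSSMs against a 0-order background with a background-proportional
pseudocount (default 0.1).  The default background is the empirical
mononucleotide composition of the scanned ACS set, symmetrized over
complementary bases so the null distribution is identical on both
strands; a uniform background is available by flag.

P-values are exact: the null distribution of the score of a random
background word is built by convolving the per-column score
distributions as a *sparse distribution over the distinct attainable
float scores* (exact ties merged).  This agrees with exhaustive
enumeration of all 4^w words at machine precision — a fixed-granularity
grid cannot do this, because real PFMs produce score levels separated by
~1e-6 that any practical grid merges or splits near a query point.  Only
when the distinct-score state space exceeds 2e6 (wide, information-poor
motifs) does the computation fall back to a 1e6-bin integer grid, with
cell scores grid-rounded consistently for the null and for window
scoring.  Windows containing N are excluded; matches on both strands at
`p <= 1e-4` (the common FIMO default; the threshold is configurable) are
collected into a binary ACS x motif match matrix (a count mode exists).
Overlapping matches are all reported; no per-match q-values are
computed, since the match matrix only needs thresholded calls.

## Motif-set enrichment (preranked GSEA)

ACS are ranked by accessibility log2 fold-change — by default only the
significantly changing ACS, matching how the motivating analysis ranked
its input; an all-ACS mode exists for sensitivity.  For each motif, the
member set is the ACS carrying a match.  The enrichment score is the
signed extremum of the weighted Kolmogorov-Smirnov walk (weight
exponent 1); the walk is computed as cumulative hit mass over total hit
mass minus the miss count over (n - k), and the streaming form used for
permutations reproduces the item-by-item walk bit for bit.  The null is
the ES of random member sets of equal size drawn from the same ranking
(10,000 permutations by default; nulls are shared between sets of equal
size).  P-values are one-sided per ES sign and normalized by the
same-sign null count — the convention that makes a null set's p-value
uniform on (0, 1] — so they are never zero, with a floor of about
2/(n_perm + 2).  NES divides ES by the mean |null ES| of the same sign;
BH adjustment runs across sets.  Ties in the ranking are broken by
stable input order.  The multilevel exact-p refinement used by fgsea is
out of scope; the permutation floor is sufficient for the adj-p < 0.05
regime the pipeline targets.

## Motif activity (elastic net)

The activity model regresses the per-ACS log2 fold-change (all ACS, not
only significant ones) on the binary match matrix:

    (1/2n)||y - b0 - N beta||^2 + lambda(alpha||beta||_1 + (1-alpha)/2 ||beta||_2^2)

solved by cyclic coordinate descent with soft-thresholding on the Gram
matrix, warm-started down a 100-point geometric lambda path from
lambda_max (the smallest penalty nulling every coefficient) to
lambda_max * 1e-4.  Predictors are standardized internally (binary
columns like any other); coefficients are reported on the original
scale.  Convergence is max coefficient change < 1e-7; KKT stationarity
residuals at the solution are below 1e-6 on random problems.  The
penalty is chosen by 10-fold cross-validation with a seeded shuffle;
the default rule is lambda_min, with the 1-SE rule available.  The
mixing parameter defaults to alpha = 0.5: motif predictors are strongly
correlated (motifs co-occur and share similarity), and the ridge
component spreads weight across correlated columns instead of picking
one arbitrarily, while the L1 part still zeroes inactive motifs.
Motifs matching fewer than 10 ACS are dropped.  A positive activity
means the motif's presence associates with sites opening in the adult;
a negative activity marks the repressor-like, closing-site pattern
(the SCRT1 signature in the motivating study).

## Gene integration

Each ACS is linked to the gene with the nearest TSS (distance from the
ACS midpoint, `floor((start+end)/2)`; ties go to the lexicographically
smallest gene id; the sign is flipped for minus-strand genes so positive
means downstream).  Location classes: TSS when |d| <= 1 kb, proximal
when 1 kb < |d| <= 10 kb, distal beyond — boundaries inclusive on the
smaller class.  A differential ACS is called an *enhancer* when the
linked gene changes significantly (gene FDR < 0.05 by default) in the
same direction, a *repressor* when it changes in the opposite
direction, and unlinked otherwise.  Motif-target enrichment asks, by an
exact hypergeometric upper tail, whether differentially expressed genes
are over-represented among genes whose linked ACS carry the motif; the
"vicinity" notion is the nearest-gene link itself, with an optional
maximum-distance restriction.  Fold-change vectors (for example a
knockdown signature against the maturation signature) are compared by
Pearson correlation with the t-transform p-value (df = n - 2).
Midpoint-to-TSS distance is a deliberate simplification of full
feature-model annotation (exon/intron/UTR classes are out of scope).

## Synthetic data

The generator emulates the statistical structure of the study, not its
genome:

- ACS sequences are i.i.d. letters at configurable GC (default 0.45)
  with lengths uniform in 250-450 bp, laid out on synthetic chromosomes
  with wide spacing so each gene's nearest ACS is its own.
  No dinucleotide structure is modeled.
- Motifs are random PWMs (width 8-14, per-column information content
  1.1-1.6 bits) with a single preferred base per column.  Instances are
  planted with per-motif probability at non-overlapping uniform
  positions and random strand, drawn from the PWM sharpened by an
  inverse temperature (`instance_bias = 2`): genuinely bound sites are
  affinity-biased relative to the PWM, which averages over all
  occurrences, and at bias 1 a realistic fraction (~20%) of weak planted
  words would legitimately fall below the scan threshold.
- The true accessibility change is the linear activity model
  `log2fc = match_truth @ beta + Normal(0, noise_sd)`; by default 10 of
  50 motifs are active with |beta| in [0.3, 1] and alternating signs, so
  a study always contains opening- and closing-site motifs.  The default
  residual noise is 0.25, which keeps the fraction of ACS with
  |log2fc| > 0.5 in the "about 20% differential" regime.
- Counts are NB with edgeR-style dispersion (`var = mu + phi mu^2`,
  default phi 0.2), per-ACS lognormal baselines around 100 insertions,
  mild library-size variation, effect coded on the adult group.
  Fragments consistent with the counts are laid with 5' ends uniform in
  the ACS and a two-mode size mixture (80 bp nucleosome-free / 260 bp
  mono-nucleosome), which is what the fragment-size QC histogram shows.
- Gene tables assign each linked gene enhancer/repressor/none roles with
  configurable fractions; responding genes move by ±0.8 times their
  ACS's log2fc plus Gaussian noise and receive FDR < 0.05.

What this does **not** emulate: read-level artifacts (no FASTQ, no
alignment or mapping bias), mitochondrial contamination, peak-calling
uncertainty (region boundaries are exact), dinucleotide or repeat
structure, correlated motif co-occurrence beyond chance, and multi-gene
regulation (one gene per ACS).  Passing tests therefore demonstrate the
statistical machinery recovers planted structure under the stated noise
model — not that any particular biological claim holds in real data.

## Numerical and fixture choices

- All randomness flows through `numpy.random.default_rng`; the pipeline
  fans one global seed into per-stage seeds via `SeedSequence.spawn`, so
  reruns are byte-identical and stages are independently reproducible.
- Score comparisons in scanning use a 1e-9 tie tolerance; exact-test
  two-sided sums use a 1e-10 relative tie tolerance; BH is the standard
  step-up capped at 1.
- The packaged end-to-end fixture is 1,500 ACS x 40 motifs (8 active),
  3 vs 3, 2,000 GSEA permutations — a scale at which the whole pipeline
  runs in well under a minute while every recovery property (repressor
  motif with negative activity and negative NES, ~20-25% differential
  sites) is stable.  The validation suite uses 5,000 ACS x 100 motifs
  for activity recovery, 2,000-2,500 ACS for test calibration and
  classification, widths <= 8 for exhaustive scan oracles, and N <= 60
  for hypergeometric enumeration.
- The differential-classification fixture uses phi = 0.05 and ~200
  insertions per site — tight, deeply covered replicates — because
  direction recovery of |log2fc| >= 1 effects at 3-vs-3 is
  power-limited: at phi = 0.2 no method reaches 90% there, and the
  property under test is the classifier, not the assay's power ceiling.

## Known limitations

- Common dispersion only; no tagwise/trended shrinkage, no GLM
  covariates or batch terms.
- The exact test's library equalization rounds scaled counts instead of
  quantile-adjusting them; at extreme factor imbalance this is coarser
  than edgeR's adjustment.
- The elastic net fits a Gaussian response only, and no resampling-based
  significance for activities is provided.
- GSEA p-values are floored by the permutation count; very small
  adjusted p-values saturate rather than refine.
- Nearest-TSS linking assigns exactly one gene per ACS; enhancers acting
  over loops or on several genes are invisible by construction.
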