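# Methods

`alfadiv` implements, end to end, the statistical pipeline used to relate
phenotypic diversity to genetic structure in a panel of pooled-GBS crop
accessions (the motivating case is cultivated alfalfa, a tetraploid
outcrosser genotyped as bulks of ~100 plants, so "genotypes" are continuous
allele frequencies in [0, 1]). This note records the models, the defaults
and why they were chosen, the numerical details, and what the synthetic
benchmarks do and do not demonstrate.

## Marker data and the genomic relationship matrix

A panel is an accession × marker matrix M of pooled allele frequencies with
a missing mask and a marker map (chromosome, 1-based position). Filtering
keeps markers with missing fraction ≤ 0.05, panel minor-allele frequency
min(p̄, 1−p̄) ≥ 0.01, and (optionally) a known position. Missing cells are
imputed with the marker's mean observed frequency (a minor-allele-frequency
fill is available as `method="maf"`; the mean is the default because it
preserves marker means and hence the centering used by the GRM).

The genomic relationship matrix follows the VanRaden construction adapted
to frequencies:

    Z = M − P,          G = Z Z′ / ((1/n) Σ_j p̄_j (1 − p̄_j))

with P broadcasting the per-marker panel mean p̄_j (this makes Z's column
sums exactly zero) and n a scaling constant. The denominator is the
expected total SNP variance; n = 16 is the default appropriate for
tetraploid pool data, where it brings the mean diagonal close to 1. Because
"close to 1" depends on the panel, `auto_scale=True` instead solves n so
that mean(diag G) = 1 exactly and reports the value.

Under the synthetic model below, with each accession an independent
Balding–Nichols draw at drift F, E[diag G] = n·F·(1 − 1/n_acc) plus a
binomial pool-noise term ≈ n/C (C = pool chromosomes); hence F = 1/16 with
n = 16 gives a mean diagonal of ≈ 0.98 for 60 accessions with pool noise
off, which the scaling benchmark measures.

## Synthetic data generator

The generator reproduces the statistical structure the pipeline assumes,
together with the generating truth (group frequencies, outlier loci, true
surface, true breeding values) needed for recovery tests.

* **Group frequencies** — Balding–Nichols: ancestral p ~ U[0.05, 0.95] per
  marker; each group draws Beta(p(1−F)/F, (1−p)(1−F)/F), i.e. mean p and
  variance F·p(1−p). A designated fraction of loci uses a larger F
  ("outlier" loci standing in for divergent selection). Note that the
  realized *pairwise* Nei FST between two groups is substantially smaller
  than F — the two-deme total heterozygosity is computed at the mean of
  only the two groups, which absorbs half of the between-group variance,
  and the per-marker ratio is further reduced by the variability of the
  numerator (measured: mean pairwise FST ≈ 0.024 at F = 0.05). Tests
  therefore check realized FST against a simulation oracle, not against F.
* **Pooled sampling** — accession frequency = Binomial(C, group freq)/C
  with C = 400 chromosomes (4 × 100 tetraploid plants), ignoring
  within-pool relatedness; `pool_chromosomes=None` switches noise off.
  Within-group drift between accessions is not modeled by default; panels
  needing per-accession structure use one accession per group.
* **Trial layout** — randomized augmented design on a rows × columns grid
  (default scale 10 × 44 = 440 plots) with contiguous column-band blocks
  and configurable check replication.
* **Spatial surface** — a seedable sum of eight random low-frequency plane
  waves (wavelength ≥ 2 × length scale, default 4 plots), centered and
  rescaled to the requested variance; a squared-exponential GP draw is
  available (`method="gp"`) but is O(n²)–O(n³) in plots.
* **Phenotypes** — y = μ + u(accession) + s(plot) + ε with
  u ~ MVN(0, G σa²), ε ~ N(0, σe²), plus optional per-group trait shifts
  for group-differentiated traits.

What the generator does *not* emulate: linkage disequilibrium along
chromosomes, tetraploid dosage segregation, GBS read-depth noise,
genotype-by-environment interaction, and non-Gaussian trait scales
(scores, percentages). Passing benchmarks therefore demonstrate
correctness of the estimators under their own assumptions, not field
performance on real data.

## Spatial adjustment (GBLUP with a tensor-product B-spline surface)

Per trait and trial the model is y = μ1 + Zu + Ws + ε with u ~ N(0, G σa²),
s ~ N(0, S σs²), ε ~ N(0, I σe²). W is the row-wise tensor product of two
clamped cubic B-spline bases (open-uniform knots over the coordinate range;
n_knots breakpoints give n_knots + degree − 1 basis functions; rows of W
sum to 1). S is the identity by default — independent random knot effects;
a separable AR(1) ⊗ AR(1) option (fixed ρ, default 0.5) is provided for
correlated knot effects.

REML maximizes the restricted likelihood over log-variances with L-BFGS-B
from equal-split moment starting values, followed by a Nelder–Mead polish
(the finite-difference gradient can stall short of the optimum; the polish
recovers ~8 significant digits, which the balanced one-way ANOVA
cross-check requires). μ is profiled out via the REML projection. BLUPs are
u_hat = σa² G Z′Py and s_hat = σs² S W′Py at the optimum. A non-PSD or
singular G receives a logged ridge jitter. The knot grid search minimizes
AIC = −2·loglik + 2·(number of variance parameters) — only the three
variance components are counted, the smallest defensible count for a REML
fit; ties break toward fewer knots. Degenerate inputs: a constant response
returns all components at the zero boundary; non-finite observations are
dropped row-wise per trait.

Adjustment subtracts only the fitted spatial trend (adjusted = y − W s_hat),
keeping genetic and residual parts so accession means estimate μ + u.
Repeated accessions are averaged after adjustment, then traits are
standardized to mean 0 and sample SD 1 (ddof = 1); constant traits are
dropped with a warning. Averaging precedes standardization.

## Phenotypic structure (PCA, k-means/BIC, DAPC)

PCA uses a full SVD with axis signs canonicalized (largest-|loading|
positive) so outputs are order- and run-reproducible. The cluster scan runs
restarted k-means (20 restarts) for each k and scores

    BIC(k) = n·d·ln(WSS_k /(n·d)) + k·d·ln(n)

on d retained PCs (default: smallest number explaining ≥ 90% variance),
choosing the minimum with ties toward smaller k. This spherical-Gaussian
BIC recovers the true k reliably when the dimensionality is not small
relative to the sample (the k-means overfitting gain per extra centroid,
≈ a constant fraction of the split cluster's points, must stay below the
d·ln n penalty increment). The benchmark uses 3 clusters of 40 points in
20 dimensions at 8 SD separation — comparable to retained-PC counts in
real multi-trait panels; with few dimensions and many points the criterion
over-splits, a known property of this BIC family rather than a defect of
the scan.

DAPC is a linear discriminant analysis on the retained PC scores: the
generalized eigenproblem S_B a = λ S_W a is solved by Cholesky whitening,
with a small ridge (10⁻⁶ × mean eigenvalue) on S_W for stability with many
traits. Discriminant axes are mapped back through the PC loadings to
per-trait contributions; traits are ranked by squared contribution.

## Concordance (distances and the Mantel test)

Genetic distance is Euclidean on allele-frequency profiles; phenotypic
distance is Mahalanobis on the standardized trait matrix. Because a
217-trait covariance estimated from ~400 accessions is ill-conditioned,
the covariance can be shrunk toward a scaled identity: `shrinkage=a`
mixes (1−a)S + a·(tr S/p)I, and `shrinkage="auto"` (the default) uses the
Ledoit–Wolf analytic rule. At shrinkage 0 a singular covariance raises an
error that suggests regularization.

The Mantel statistic is the Spearman correlation (average ranks for ties)
of the strictly-upper-triangle entries; the null jointly permutes rows and
columns of the second matrix; the one-sided p-value is
(1 + #{r_perm ≥ r_obs})/(1 + n_perm), so p ≥ 1/(n_perm + 1) — e.g. 0.001
at the default 999 permutations. Identity of the two matrices attains
r = 1 and the floor p exactly; calibration is checked by a 500-replicate
type-I simulation.

## Trait selection (prefilter + Boruta)

The prefilter removes one member of every trait pair with |Pearson r| >
0.9: pairs are visited in a deterministic order (descending |r|, ties by
name) and the member with the larger mean absolute correlation to all
remaining traits is dropped, repeating until no pair exceeds the
threshold.

Boruta appends a shuffled shadow copy of every still-undecided trait each
iteration, fits a 500-tree random forest, and scores a hit when a trait's
importance exceeds the maximum shadow importance. Accumulated hits are
tested two-sided against Binomial(iterations, 0.5) with a Bonferroni
divisor equal to the number of currently undecided traits (re-evaluated
each iteration); significant excess confirms, significant deficit rejects,
and whatever remains at `max_runs` (default 1000) stays tentative — no
"rough fix" pass. Decisions are sticky; confirmed traits stay in the
forest, rejected ones are removed. Importance is the forest's
impurity-based (Gini) measure — one of the two canonical random-forest
importances — chosen over out-of-bag permutation importance because it
comes free with the fit and the per-tree permutation loop costs an order
of magnitude more per iteration at no measurable benefit on the benchmark;
the bootstrap is the forest's ordinary (unstratified) resampling. The
benchmark (10 features with guaranteed 1.5-SD group-mean steps + 40 pure
noise, n = 300, 3 groups) confirms every informative feature and rejects
≥ 95% of noise within 50 iterations.

## FST outlier scan

Group frequencies are unweighted means of member accessions' pooled
frequencies (accessions are equal-design pools; a weighted option exists);
groups below 3 members are excluded, mirroring the treatment of very small
taxonomic groups. For each unordered group pair and marker,

    p̄ = (p1+p2)/2,  H_T = 2p̄(1−p̄),  H_S = p1(1−p1) + p2(1−p2),
    F_ST = (H_T − H_S)/H_T,

with H_T − H_S ≡ (p1−p2)²/2, so FST ≥ 0 always; monomorphic comparisons
(H_T = 0) are flagged undefined and excluded from p/q computation rather
than set to 0.

"Putatively neutral" loci are a single uniform random sample (seeded,
configurable size, default 5000) shared across *all* pairwise comparisons;
an explicit user list overrides — real analyses should prefer an
externally justified neutral set, since a random sample contains whatever
selected loci the genome contains. The empirical p-value of a marker is
(1 + #{null ≥ fst})/(1 + |null|) (ties counted against the marker,
conservative; the +1/+1 keeps p > 0 and BH well-defined), followed by
Benjamini–Hochberg correction (via `statsmodels`, cross-checked against a
brute-force step-up oracle) and a strict q < 0.05 outlier call.

A structural consequence worth knowing: with m markers tested and a null
of size N, BH at level q can only reject markers whose p is near the floor
1/(N+1), which requires roughly m/(q·(N+1)) markers to exceed *the entire
null*. Detection therefore needs truly extreme loci (near-fixed
differences), and moderate-divergence loci are invisible at desk scale.
The operating-characteristics benchmark (2000 neutral F = 0.05 + 50
divergent F = 0.5 loci, two groups of 30) measures exactly this: the
false-discovery proportion is controlled (≈ 0), while sensitivity is low
because most Balding–Nichols F = 0.5 draws land on the same side of the
ancestral frequency and produce small pairwise FST. The acceptance suite
reports both numbers as measured.

Outlier SNPs are intersected with GFF3 gene models (1-based inclusive
coordinates; gene id attribute configurable, default "ID"): a hit is
inside the gene (distance 0) or within a 500 bp window of either end,
orientation genomic rather than strand-relative; one SNP can hit several
genes. BED output converts to 0-based half-open coordinates.

## Pipeline and reproducibility

All stages run behind one YAML-configured CLI (`alfadiv run config.yaml`;
individual subcommands exist for each stage). Configs are validated
strictly — unknown keys are errors. Per-stage seeds derive from the single
global seed via `SeedSequence([seed, stage_index])`, so stages re-run in
isolation reproduce their outputs; the run report records every output
file with a SHA-256 hash, plus per-stage timing and seeds. Outputs are TSV
(matrices, tables), JSON (fits, Mantel, report) and BED (outliers).

## Problem sizes used by the test suite and acceptance script

Benchmarks run at desk scale, chosen so each check completes in seconds to
a few minutes on one CPU while leaving Monte-Carlo error well inside the
asserted margins: FST closed form on a 101 × 101 grid; BH vs oracle on
1000 random vectors; scan operating characteristics on 2050 loci × 60
accessions × 20 replicates; Mantel calibration on 500 replicates of n = 30
with 999 permutations; spatial recovery on 20 replicates of a 440-plot,
400-accession trial; cluster recovery on 20 seeds; Boruta on 5 seeds of a
50-feature, 300-sample problem. The full pipeline smoke test uses a
3-group, 150-marker panel.

## Known limitations

* REML fits one trait × trial at a time; no multi-trait or location × year
  joint models, and residual variance is homogeneous within a trial.
* The GRM assumes one allele-frequency convention per marker across the
  panel; per-marker allele flips change G through the centering term, so
  input files must be consistent.
* Boruta p-values are nominal binomial tests on sequentially accumulated
  hits; the sequential stopping makes them approximate, as in the original
  procedure.
* The empirical-null scan has the power ceiling described above; with
  genome-scale marker counts a proportionally larger neutral set is needed
  for any detections at all.
* The GP surface option is exact but quadratic in memory; the default
  sinusoid generator is the intended tool at trial scale.
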