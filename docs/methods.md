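# Methods

`ecmsom` implements the quantitative pipeline of a liquid-culture
decomposition experiment: two ectomycorrhizal fungi are grown on a
glucose-supplemented soil-organic-matter (SOM) extract, and the
chemistry, spectroscopy and transcriptome of the culture are followed
through four nutritional phases — active growth (AG), ammonium
depletion (ND), glucose depletion (CD) and prolonged glucose depletion
(pCD). All stages run on synthetic data whose generators are part of
the package; this note documents the models, the defaults, and the
design decisions that were genuinely open.

## Synthetic study design

The default design is 2 species x 4 time points x 3 biological
replicates, sampled on a 50 h chemistry grid.

**Chemistry.** Glucose-C and ammonium-N follow logistic decays
parameterized by the time at which the mean curve reaches its detection
threshold (glucose 1 mg C L^-1; ammonium 2% of its initial level); the
curves aim 2% below the threshold at that time so the threshold
crossing is numerically unambiguous. Defaults put ammonium depletion at
200 h and glucose depletion at 400 h for the fast-growing archetype
(the ordering ammonium-before-glucose is enforced). Organic N declines
slowly toward a floor; total N is ammonium plus organic N. Biomass
grows logistically while glucose lasts and then either declines
exponentially toward half its peak (brown-rot-derived archetype,
emulating autolysis) or stays flat (litter-decomposer archetype).
Replicate noise is multiplicative Gaussian with a 5% coefficient of
variation; the detection limits and replicate scatter are configuration
values, not literature facts.

**Counts.** Each gene follows a template: a triple over {U, D, S}
giving its state at the ND, CD and pCD transitions. The mean at time
point j is `base_mean * 2**(cumulative signed lfc)`; counts are
negative binomial with variance `mu + alpha*mu^2` (Poisson at
`alpha = 0`). Per-sample library factors are drawn log-uniformly in
[0.5, 2] so normalization is load-bearing. The default cohort seeds 15
distinct patterns (20 genes each) plus 500 flat null genes, with
`lfc = 2`, `alpha = 0.02`, and trough-anchored expression: the lowest
per-time-point mean is drawn log-normally (median 200), so patterns
with deep declines start correspondingly high. This mirrors real time
courses — the "gradually decreasing" class is the most highly expressed
at the start — and keeps every seeded transition above the counting
noise floor. The 15 patterns are closed under single-transition
dropout: a missed call produces another seeded pattern (or all-S),
never a spurious new type.

**Spectra.** FTIR-like data are bilinear: `D = C S^T + noise`, k = 4
components whose band sets (polysaccharide-, ammonium/amide-,
carbonyl- and aromatic-like) are well separated, and whose logistic
concentration profiles (two decaying, two accumulating, staggered
midpoints) each vanish over part of the time course. These two features
give the factorization pure channels and zero regions — the standard
conditions under which non-negative bilinear factorizations are
essentially unique and recovery claims are meaningful. Default noise is
0.1% of the maximum clean intensity.

**Fe pre-edge.** One spectrum is an area-weighted mixture of two
unit-area Gaussians at the ferrous (7112.1 eV) and ferric (7113.5 eV)
reference centroids (sigma 0.7 eV) over a linear baseline, on a 0.05 eV
grid spanning 7105-7120 eV.

## Phase detection

Replicate trajectories are averaged, then thresholded: t1 is the last
sampled time with both glucose and ammonium above threshold, t2 the
first with ammonium depleted but glucose present, t3 the first with
glucose depleted, t4 the first time at least `pcd_lag` (default 150 h)
after t3. The pCD lag is a convention — the experiment defines pCD only
as "prolonged" starvation — and the t2/t4 rules are this package's
formalization of choices the original study made graphically. Raising
the glucose threshold can only move t3 earlier; outputs are always a
subset of the sampled times.

## MCR-ALS

`fit_mcr` alternates non-negative least squares (per-column NNLS) on
C given S and S given C; the residual sum of squares is non-increasing
by construction and iteration stops at a relative RSS change below
1e-8 (max 500 iterations). Non-negativity is the only constraint; no
closure or unimodality is imposed. Initialization is purest-variable
selection (a SIMPLISMA-style purity criterion with determinant-based
orthogonality correction over channels); four further seeded-random
restarts guard against poor local minima. The restart with the lowest
residual is returned **unless** it improves explained variance over the
purest-variable solution by less than 0.01 percentage points: residual
differences at the noise floor are rotations of the same bilinear fit,
and strict lowest-RSS selection would return an arbitrary rotation
where the informed initialization returns the interpretable one.
Spectra are reported with unit-maximum columns, the scale absorbed into
C; component identity is established by matching against ground truth
(Hungarian assignment on cosine similarity), never by column index.
`select_components` returns the smallest k whose best fit reaches the
explained-variance threshold (default 99.9%), or k_max with a warning
flag.

## Fe pre-edge and N speciation

`fit_preedge` isolates the 7108-7118 eV window, fits a baseline to the
two flanking 1 eV sub-windows (linear by default, cubic optional),
subtracts it, and fits up to two symmetric Gaussians initialized at the
ferrous/ferric reference energies. The centroid is the area-weighted
mean of the fitted peaks; the ferrous fraction interpolates linearly
between the endmember centroids (clipped to [0, 1]). The linear
interpolation is a first-order approximation — the literature reports a
mildly non-linear centroid-fraction relation for some mixtures — and is
adequate for the two-endmember synthetic design, where round-trip
recovery is within 0.05 absolute for any fraction. Centroid groups are
compared by classical one-way ANOVA.

N 1s->pi* transition areas (pyridine, nitrile, amide, pyrrole) are
closed to unit sum per sample and ordinated by PCA on the
column-centered table. The default transition energies are
literature-typical configuration values.

## Ox/C3-G lignin-oxidation marker

`value = (Ox/C3)_sample / (TOC_sample/TOC_control) / (Ox/C3)_control`.
The TOC correction direction (divide by the relative TOC) is a
documented convention with a `multiply` switch; control replicates are
averaged before normalizing, so the control maps to 1 by construction.
The output is invariant to rescaling a sample's marker areas, strictly
increasing in Ox-G and decreasing in C3-G.

## Differential expression

This stage is a deliberately simple, simulation-validated NB analysis —
not a reimplementation of any published framework. Size factors are
median-of-ratios over genes nonzero in every sample (pseudo-reference
fallback available). Dispersions are method-of-moments from the pooled,
df-corrected within-group variance, floored at 0.01.

Two references were tuned for honesty at n = 3, where naive plug-in
asymptotics are badly anti-conservative (measured type-I error ~0.13 at
nominal 0.05):

* **Time course.** The NB likelihood ratio of the per-time-point-means
  model against the intercept-only model, computed at the cohort trend
  dispersion (median of gene-wise estimates), scaled by the gene's
  deviance-based quasi-likelihood dispersion, and referred to
  F(T-1, n-T). Measured type-I error is 0.047-0.050 across homogeneous
  and heterogeneous dispersion scenarios, with >0.99 power for an
  8-fold step at base mean 100. The naive chi-square reference remains
  available (`reference="chisq"`).
* **Pairwise.** The Wald statistic is the pseudocounted (0.5) log2
  fold-change of normalized group means over its delta-method standard
  error, with gene-wise dispersions squeezed toward the cohort median
  by `prior_df = 5` pseudo-replicates and a t reference with
  n1 + n2 - 2 + prior_df df. Measured type-I error 0.045-0.051;
  moderation restores the sensitivity that a raw t(4) reference loses
  on marginal calls.

BH adjustment uses the standard step-up procedure; time-DEGs are calls
at adjusted p < 0.01. The onset filter keeps genes in the top 20% of
mean normalized t2 expression (computed over genes with nonzero
expression) with log2FC > 1 and adjusted p < 0.01 in the t2-vs-t1
contrast.

## Response types

Each gene's state at the three transitions (U/D/S at the 2-fold,
adjusted-p < 0.01 conventions) maps to one of 27 canonical types,
enumerated by earliest transition of change, upregulation before
downregulation, complementary (U<->D mirrored) patterns adjacent, and
all-sustained last (excluded from "changing" types). The enumeration is
internally consistent but its numbering is not claimed to match any
published figure's labels. Classification is per gene and deterministic;
cluster membership is metadata.

Annotation-guided clustering attaches genes to the deepest node of
their category path (top-level element "SOM" marks SOM-interaction
genes, anything else metabolism) and, within each node, groups genes by
single-linkage on Pearson correlation of their per-time-point mean
log2 profiles at r > 0.8. Constant profiles are treated as
uncorrelated with everything and become singletons.

The permutation test shuffles sample time-point labels (group sizes,
hence the balanced replicate structure, are preserved — the label
vector is permuted rather than whole blocks, since 4 blocks admit only
24 distinct permutations), reruns the pairwise-DE -> classify -> count
chain, and records the per-type SOM-interaction gene count (a
hypergeometric enrichment score is available). The empirical p is
`(1 + #{null >= observed}) / (B + 1)`. For calibration studies the
classification can threshold raw p-values (`adjust=False`): under a
complete null, BH adjustment makes state calls (correctly) so rare that
the per-type statistic is degenerate and the test's operating
characteristics cannot be observed.

## Problem sizes and tolerances

The shipped tests and the acceptance script run at desk scale, chosen
to make every stochastic assertion stable under its stated seed: 800
genes in the default cohort (15 x 20 signal + 500 null), 5000 genes in
calibration matrices, 12 x 251 spectra, 1000-replicate Monte-Carlo
checks of generator moments (3 standard errors), 200 repetitions x 199
permutations for permutation-test calibration, and B = 999 for
single-dataset permutation claims. Fixed seeds make the whole pipeline
byte-reproducible; `run-all` writes a manifest recording the seed and a
configuration hash.

## Known limitations

* The NB stage has no dispersion trend over mean expression and no
  fold-change shrinkage; very-low-count transitions lose power, which
  the trough-anchored cohort design acknowledges rather than hides.
* MCR-ALS recovery claims hold under the identifiability conditions the
  generator enforces; on real spectra with heavy band overlap and no
  zero-concentration regions, rotational ambiguity returns and
  recovered factors must be interpreted accordingly.
* The centroid-to-ferrous-fraction map is linear; mixtures of phases
  with different pre-edge multiplicities can deviate from linearity.
* Synthetic data carry none of the batch structure, GC/length biases,
  or annotation incompleteness of real RNA-seq; passing tests validate
  the algorithms' contracts, not their field performance.
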