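# Methods

This note records the statistical models poolkin implements, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data generators do and do not emulate.

## Data model

The central object is a landrace × SNP matrix of reference-allele
frequencies p ∈ [0, 1] for biallelic markers, one row per population
genotyped as a DNA bulk (the convention emulated throughout is a bulk of
15 plants, i.e. 30 gene copies). The complementary allele is implicit;
this matches array genotyping output and halves storage. Missing calls
are NaN in memory and empty/`NA` on disk — never a sentinel numeric,
because a silent zero would bias every downstream statistic toward
fixation. Bulk frequency estimates carry measurement error (the
fluorescence-calibration approach they derive from has a mean absolute
error of roughly 7%), which motivates the configurable fixation tolerance
`eps` below.

### Filters

`filter_missing_loci` drops every locus with at least one missing call —
the conservative complete-case rule appropriate when downstream
statistics (distances, f3, EM) assume complete vectors. The report always
satisfies n_input = n_dropped + n_retained, and filtering is idempotent.

`detect_monomorphic(eps)` flags loci where every landrace is ≤ eps or
every landrace is ≥ 1 − eps. Default eps = 0 (exact fixation); raising it
absorbs bulk-estimation noise. Monomorphic loci are flagged but **not**
dropped by default — they carry no signal but do enter locus counts, and
whether to exclude them is left to an explicit switch
(`drop_monomorphic`) rather than a hidden default.

## Diversity

Per landrace: He = mean_l 2p_l(1 − p_l) (Nei's gene diversity, ≤ 0.5 for
biallelic loci), proportion of polymorphic loci P = #{eps < p < 1 − eps}/L,
and allelic richness Ar = 1 + P (each polymorphic locus shows two
alleles, each fixed locus one). Group-level He uses the unweighted mean
frequency over member landraces; by concavity of 2p(1 − p) it is at least
the mean of the members' He.

Rarefied group Ar resamples g landraces without replacement (defaults
g = 9, 1000 resamples — the smallest group size of interest and a
resampling effort that keeps Monte-Carlo error well below reporting
precision) and counts, per locus, the alleles present in the subsample
(reference present iff any p > eps; alternate iff any p < 1 − eps).
When C(n, g) ≤ the resample budget, all subsets are enumerated exactly —
e.g. a 12-member group admits only 220 draws of 9 — making the statistic
deterministic. Rarefaction is over landraces, not gene copies: a bulk
frequency vector is the observational unit, so the hypergeometric
gene-copy formula does not apply.

Pairwise group comparisons of per-locus statistics use the two-sided
Wilcoxon signed-rank test (scipy implementation; zero differences
dropped, normal approximation for large locus counts). When every paired
difference is zero the test is vacuous and returns p = 1 with a warning.

## Differentiation and distances

**Modified Rogers distance.** For biallelic loci,
d = sqrt(Σ_l 2(p₁_l − p₂_l)² / 2L) = ‖p₁ − p₂‖ / √L ∈ [0, 1]. It is a
Euclidean metric on frequency vectors scaled by 1/√L, which is why PCoA
of this matrix reproduces (up to sign) the PCA of the frequency matrix —
a cross-module identity asserted in the tests.

**Nei G_ST.** Two groups enter as their mean frequency vectors (bulk
semantics; each landrace already is a frequency vector). Per locus,
H_S = mean of the two group heterozygosities and H_T = heterozygosity of
their unweighted pooled mean; the multilocus value aggregates as
(Σ H_T − Σ H_S)/Σ H_T — ratio of sums, not mean of per-locus ratios,
because per-locus ratios are unstable where H_T is small. Loci with
H_T = 0 contribute to neither sum. For the two-population unweighted
case H_T − H_S = (p₁ − p₂)²/2 per locus, which the pairwise-matrix code
exploits for a fully vectorised computation. H_T ≥ H_S always (concavity),
so G_ST ∈ [0, 1] and no clamping is needed. Significance uses permutation
of landrace group labels: p = (#{G_perm ≥ G_obs} + 1)/(n_perm + 1). No
correction is applied for the 15-plant sampling error of each bulk; with
thousands of loci this inflates all pairwise values by a similar small
amount and is absorbed by the permutation null.

**Rousset linearization.** F_ST/(1 − F_ST), applied elementwise, is the
quantity regressed on geographic distance in isolation-by-distance
analyses.

**Geographic distance.** Spherical law of cosines,
d = R·arccos(sin φ₁ sin φ₂ + cos φ₁ cos φ₂ cos Δλ), with R = 6371.0 km
(conventional mean Earth radius) and the arccos argument clamped to
[−1, 1] against floating-point rounding. Landraces without coordinates
are excluded listwise from geographic analyses.

## Ordination and trees

**PCoA.** Gower's procedure: B = −½ J D∘D J, eigendecomposition,
coordinates = eigenvectors × √eigenvalue. Percent inertia is taken over
positive eigenvalues only; negative eigenvalues (non-Euclidean input) are
excluded from the denominator and reported. None arise for modified
Rogers input.

**PCA with supplementary rows.** Columns are centred by the ACTIVE-set
means only (no variance scaling by default — all variables are
frequencies on one scale; a flag enables scaling); axes come from the
active rows' SVD and supplementary rows are centred by the same means and
projected onto the same axes. This is the device for placing a large
derived collection relative to reference populations without letting it
distort the axes. Percent variance comes from active eigenvalues.

**Axis orientation.** Every ordination axis is flipped so its
largest-magnitude entry is positive — eigenvector signs are otherwise
arbitrary and platform-dependent, and a fixed convention makes outputs
reproducible.

**Neighbor joining.** Saitou–Nei agglomeration with the Studier–Keppler
criterion Q_ij = (n−2)d_ij − r_i − r_j; ties broken by the
lexicographically smallest index pair (deterministic topology); standard
branch-length formulas. A negative branch length is set to zero with the
deficit transferred to its sibling edge, preserving all leaf-to-leaf path
lengths — so additive matrices are still reproduced exactly. The tree is
unrooted (trifurcating top node). Newick serialization quotes labels
containing spaces or metacharacters; parsing and patristic distances use
scikit-bio.

## Structure inference

Bulk data defeat genotype-based clustering software, so the pipeline
mirrors the pseudo-haploid workaround:

1. **Map-window thinning.** The genetic map is cut into n_windows = 2500
   equal-cM windows, allocated to chromosomes proportionally to map
   length (largest-remainder rounding, ≥ 1 per chromosome), one uniformly
   random SNP kept per non-empty window. An equal-count window scheme is
   the obvious alternative; equal-cM is the simplest reproducible reading
   of "non-overlapping windows of the genetic map" and is what the
   generator's uniform maps assume.
2. **Pseudo-haploids.** n_rep = 5 haploid genotypes per landrace, allele
   1 drawn independently per locus with probability p_l (Hardy–Weinberg,
   no linkage).
3. **Admixture EM.** The haploid-form admixture likelihood
   log L = Σᵢ Σ_l log(Σ_k q_ik [g_il p_kl + (1 − g_il)(1 − p_kl)]) is
   maximised by EM block updates of Q (ancestry fractions) and P (cluster
   frequencies) from a seeded random start. EM is monotone in the
   likelihood (asserted on every trace); iteration stops at relative gain
   ≤ 1e−6 or 2000 iterations. The original software's quasi-Newton block
   relaxation optimises the same likelihood faster; the model, not the
   optimiser, is what matters here, and acceptance is judged on recovery
   quality. K = 1 is closed-form. Per-landrace ancestry is the mean over
   the landrace's replicate haploids.
4. **Model choice.** Replicate runs (default 3–5 per K, each an
   independent restart) feed Evanno's
   ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd_reps(L(K)), defined at interior K
   only; zero replicate sd flags that K as undefined rather than dividing
   by zero. The best-likelihood run per K supplies Q and P.
5. **Assignment.** Each landrace goes to its argmax-Q cluster;
   `is_pure` marks top ancestry ≥ 0.7 (the conventional cutoff for
   "unadmixed"); ties go to the lowest cluster index with a warning.

Identical seeds reproduce Q, P and the likelihood bit-for-bit.

## Three-population admixture tests

f3(X; Y, W) = mean_l (x_l − y_l)(x_l − w_l) on group mean frequencies.
For X = αY + (1−α)W with no drift, f3 = −α(1−α)·mean((y − w)²) ≤ 0,
minimised at α = ½; drift specific to X adds a positive offset, so the
test is conservative for old admixture. The standard error is a
delete-one block jackknife over contiguous blocks of 500 map-ordered loci
(robust to local LD; block size configurable), sd = sqrt((B−1)/B ·
Σ_b (f3₍₋b₎ − mean)²); with equal blocks this equals sd(block means)/√B.
Z = f3/sd, and Z < −2 flags a significant mixture. If every per-locus
term is zero (the focal group is one of the references) the jackknife is
degenerate and the result is reported as f3 = 0, Z = 0, not significant.

The plain (uncorrected) product form is the default: the within-focal
bias correction used by sequence-based implementations requires
within-population sample sizes that pooled bulks obscure. An optional
correction subtracting x(1−x)/(2n), n = landraces in the focal group, is
exposed but off by default. The scan evaluates each focal group against
every unordered reference pair, sorts by Z ascending and flags
negative-f3 rows; membership derived from a structure run should be
restricted to landraces at the purity cutoff first.

## Spatial analysis

**Mantel test.** Pearson correlation over the n(n−1)/2 unordered pairs;
the permutation null relabels rows and columns of the second matrix
jointly; two-sided p = (#{|r_perm| ≥ |r_obs|} + 1)/(n_perm + 1), default
9999 permutations, seeded. Super-uniformity under exchangeability and
nominal type-I error are verified by simulation in the tests.

**MRM.** OLS on vectorized upper triangles; per-coefficient and R²
p-values by jointly permuting the rows/columns of the response matrix and
refitting. Near-perfect predictor collinearity (|r| > 0.999 between
predictor triangles) is rejected with the offending pair named. With one
predictor the slope is cov/var of the triangles and the permutation
decision matches the Mantel test's.

**Gradients.** Pearson r between an ordination axis and
longitude/latitude with the two-sided t-test p — the diagnostic for
clinal structure.

**Climatic distance.** The 12 growing-season variables (May–October
monthly mean temperature and precipitation) are centred and unit-scaled —
temperatures and precipitations are incommensurable, so correlation-PCA
is the defensible default (flag to disable) — and the distance is
|PC1_i − PC1_j|, with PC1's percent variance reported. Rows with missing
climate values are excluded beforehand.

## Synthetic data

Drift is Balding–Nichols: given ancestral p₀ and drift F, a daughter
frequency is Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) — mean p₀, variance
F p₀(1−p₀); fixed loci stay fixed. The model is standard and
moment-tractable; it is a test harness, not a claim about maize history.
Useful consequences exploited by the tests:

- Two sister groups drifted at F from a common pool have expected
  pairwise G_ST = (F/2)/(1 − F/2) between their mean frequency vectors
  (the pooled H_T itself shrinks with F). `drift_from_pairwise_gst`
  inverts this (F = 2G/(1+G)); recovery of a known F from measured G_ST
  goes through that inversion, and conditions described as "F_ST ≈ 0.2"
  use group drift F = 1/3 accordingly.
- Bulk genotyping of b plants is binomial over 2b gene copies, adding
  variance p(1−p)/(2b); with the default b = 15 this matches the checked
  simulation variance. An optional uniform jitter emulating the ~7% array
  calibration error exists and is off by default.

Generators (all pure functions of config + seed):

- **Reference panel** — ancestral frequencies U(0.05, 0.95) (U(0.1, 0.9)
  in the acceptance setup), group drift, landrace drift (default 0.05,
  giving within-group differentiation of the order seen between real
  landraces of one group), bulk noise; uniform marker maps over 10
  chromosomes totalling 1600 cM (maize-like).
- **Longitudinal gradient** — two pools drifted at 0.10 from the shared
  ancestor; landrace ancestry linear in longitude between configurable
  endpoints across a 5° range; neighbor smoothing (rate 0.3) adds spatial
  autocorrelation; local drift 0.02; climate covariates linear in
  longitude (temperature rising eastward, precipitation falling) plus
  noise, mimicking an Atlantic-west / Mediterranean-east climatic
  contrast; optionally some landraces are emitted without coordinates.
- **Admixed focal group** — base αY + (1−α)W, per-landrace drift, bulk
  noise.
- The `swf-panel` preset emulates a full-size panel: seven reference
  groups of realistic sizes, a 194-landrace gradient, 23412 loci of which 378
  carry missing calls, 15-plant bulks, 36 landraces without coordinates;
  a `scale` parameter shrinks it proportionally for fast runs.

What the generators do **not** emulate: linkage disequilibrium within
chromosomes (loci are drawn independently, so map-window thinning is
exercised mechanically, not against real LD), selection, the array's
ascertainment bias, correlated drift between groups (group histories are
star-shaped from one ancestor), and realistic migration topology beyond
the one-dimensional cline. Passing recovery tests therefore demonstrates
correctness of the estimators under the assumed model, not robustness to
those real-data features.

## Problem sizes and runtimes

The test suite runs the recovery simulations at deliberately modest
sizes chosen to keep Monte-Carlo error small relative to the asserted
margins: EM/ΔK recovery on 30 landraces × 600 loci (5 haploids each,
K = 1..4, 3 replicates); f3 recovery at 5000 loci; Mantel power at 50–60
landraces × 800 loci over 60 replicates; type-I calibration at 16
landraces × 200 loci over 500 replicates with 99 permutations. The whole
suite completes in well under a minute of CPU; the full-scale
`swf-panel` preset (194 + 148 landraces, 23K loci, K to 13) is built for
overnight-style runs and is not exercised at full scale by the tests.

## Known limitations

- The EM optimiser, while provably monotone, can need many iterations
  near convergence on large K; restarts mitigate local optima but the
  likelihood surface's label-switching symmetry means Q/P are identified
  only up to cluster permutation (tests match by best permutation).
- G_ST and f3 on bulk frequencies ignore the finite (15-plant) sampling
  of each bulk; both are therefore slightly biased in opposite
  directions relative to individual-genotype estimators.
- The Mantel and MRM permutation tests assume exchangeable rows under the
  null; strong autocorrelation structure beyond what the permutation
  preserves (e.g. phylogenetic structure among landraces) inflates
  type-I error, as for all such tests.
- `climate_pc1_distance` reduces climate to one axis by design; where PC1
  explains little variance the distance is a poor climate summary (the
  percent variance is reported so callers can check).
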