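# Methods

This note documents the models, estimators and numerical choices behind
`pleioscope`, and what the synthetic-data generator does and does not
emulate.

## Correlation partitioning

For cells nested in clonal strains, every observation of a trait splits into
a between-group deviation `b_ij = x̄_j − x̄` and a within-group deviation
`w_ij = x_ij − x̄_j`. `r_B` is the Pearson correlation of the b-scores of two
traits over all N observations — algebraically the size-weighted correlation
of strain means — and `r_W` is the correlation of the w-scores. Because
b-scores are constant within groups and w-scores sum to zero within groups,
the cross-terms vanish and the identity
`r_total = η_Bx η_By r_B + η_Wx η_Wy r_W` holds to machine precision; the
test suite asserts it at 1e−10 on random data. For clonal groups `r_W` and
`r_B` play the roles of the environmental and genetic correlations of
quantitative genetics. Known caveat: `r_B` is a correlation of strain means
and therefore mildly biased toward the within-strain component at small
cell counts; the large per-strain samples this package targets (hundreds of
cells) make the bias negligible, and it is conservative for detecting
`r_B > r_W`.

**Comparing r_B with r_W.** Magnitudes are compared: `|r_W|`, and `|r_B|`
negated when the two disagree in sign (a genetic correlation opposing the
inherent one is not evidence of horizontal strengthening). The statistic is

```
z = (atanh r_B*) − atanh |r_W|) / sqrt(1/(J−3) + 1/(N−J−3))
```

with J strains as the effective sample size of the between component and
N − J cells for the within component — the degrees of freedom of the two
deviation-score sets. The test is one-tailed: at α = 0.01 Bonferroni-
corrected over 5,645 pairs the critical value is Φ⁻¹(1 − 0.01/5,645) =
4.6365, printed as 4.63 at two decimals. `|r| = 1` is capped at
1 − 1e−12 before `atanh`. A consequence of the sign-adjustment convention:
for a pair whose true `r_W` is *exactly* zero the estimated sign is a coin
flip and the adjusted comparison is ill-posed; the generator therefore
gives "weakly correlated" horizontal target pairs a small nonzero base
correlation (0.05 in the validation panels), matching the scenario the
method is meant for.

**Pseudo-strain null.** Cells are permuted across strain labels within each
cell type, preserving the group-size multiset exactly. Under this null the
z statistics are approximately standard normal and essentially no pair
clears the Bonferroni cutoff, which is the calibration check that
single-cell noise does not systematically depress `r_W` relative to `r_B`.

**ACE maximal correlation.** Alternating conditional expectations: iterate
θ(y) ∝ E[φ(x)|y], φ(x) ∝ E[θ(y)|x], each standardized, until the
correlation changes by < 1e−5 (max 50 iterations; non-convergence returns
the last iterate flagged). Conditional expectations use an equal-count
binned local-mean smoother (50 bins) with linear interpolation between bin
centers and clamped ends — deterministic and O(n log n), adequate at the
10⁴–10⁵ observations used here. For bivariate Gaussians the fixed point is
|ρ| (Gebelein), recovered to ±0.005 at n = 50,000; for y = x² it recovers
the transformable correlation (> 0.999) that Pearson's r misses entirely.

## Preprocessing

Fixed order: missingness filter → Box–Cox → plate correction → outlier
filter. Traits missing in > 10% of their cell type's cells are dropped;
remaining cells must be complete for their type's retained traits. Box–Cox
λ is chosen per trait on a grid [−2, 2] step 0.1 to maximize the normality
of residuals from the strain-mean model; the normality score is the
probability-plot correlation coefficient (Shapiro–Wilk W available via
`criterion="shapiro"`), with ties broken toward λ = 1 and nonpositive
traits shifted by −min + 1e−6·range first (shift recorded). Plate
correction subtracts, per (plate, trait), the difference between the
plate's mid-parent control mean and the grand mid-parent mean. Outliers are
cells with any |z| > 5 on the corrected scale. Broad-sense heritability
uses one-way random-effects method of moments with the unbalanced-design
coefficient `n₀ = (N − Σn_j²/N)/(J−1)` and negative between-strain variance
clipped to zero.

## QTL mapping

Strains are fully homozygous recombinants coded −1/+1, so Haley–Knott
regression at a marker is an ordinary single-regressor fit with
`LOD = −(n/2) log10(1 − R²)` (asserted against the closed form to 1e−10).
Between markers the regressor is the expected genotype given the flanking
markers under the Haldane map function; conditional scans for a second
additive locus re-run the same machinery with the first peak's expected
genotype as covariate (both phenotype and genotype are residualized on the
covariate, giving the LOD gain). The mapped phenotype is the strain mean of
the preprocessed trait (per-replicate means available by flag).

Significance is per trait: the empirical distribution of genome-wide
maximum LOD over phenotype permutations, threshold at the 95th percentile,
p-values with the plus-one rule `(1 + #{null ≥ obs})/(n_perm + 1)`. Across
traits, per-chromosome peak p-values are pooled and converted to
Benjamini–Hochberg q-values (BH is slightly conservative relative to
Storey-type estimators; a π₀ estimate can be added upstream without
changing interfaces). Type-I calibration is verified by simulation: 200
null traits at n_perm = 1,000 detect within the 95% binomial band around
0.05.

Peaks on a chromosome are chained into one locus while consecutive gaps are
≤ 5 cM; dense runs (all gaps ≤ 2 cM) can therefore never be broken, which
is this package's resolution of the interplay between the 5-cM separation
rule and the dense-region rule. A cluster spanning more than 17 cM — the
largest span the method is expected to produce on data of this type — is
kept but flagged with a warning. Effect sizes are reported as
|difference of allele-group means| / |parental difference|.

## Pleiotropy classification and the r_W network

A pair is `vertical-consistent` if |r_W| > 0.2, it shares ≥ 1 QTL cluster,
and r_B is not significantly greater; `horizontal-candidate` if r_B
significantly exceeds r_W; `both` or `neither` otherwise. The r_W threshold
0.2 and test α = 0.01 live in `PipelineConfig`.

The trait network of one cell type uses |r_W| as edge weights (the sign
has no meaning across arbitrary pairs). The weighted clustering coefficient
of node *i*, with weights normalized by the global maximum, is

```
wcc_i = Σ_{j≠k} ŵ_ij ŵ_jk ŵ_ki / ((Σ_j ŵ_ij)² − Σ_j ŵ_ij²)
```

— the complete-weighted-graph form, bounded in [0, 1] for nonnegative
weights, suitable for fully connected correlation networks (a binary-
adjacency variant would require an arbitrary edge threshold). It is
verified against brute-force triangle enumeration on all graph sizes up to
6 nodes. Permutation nulls resample the off-diagonal weight multiset onto
random pairs, preserving the weight distribution while destroying
clustering structure.

## Cell-cycle ordering and binning

An asynchronous exponential culture samples the division cycle uniformly,
so a cell's morphology encodes its cycle position. The ordering is a
single-branch diffusion pseudotime: standardize traits, build a symmetric
k-nearest-neighbor graph (k = 30, doubled with a warning if disconnected),
take the leading nontrivial eigenvector of the degree-normalized adjacency
(deterministic start vector, so the computation is reproducible without a
seed), orient so the anchor "start" cell sits near 0, and rescale ranks to
[0, 1]. Branch detection is deliberately out of scope — only the position
along the trajectory is used downstream. On synthetic cells whose traits
follow low-noise monotone/bump trajectories the ordering recovers true
pseudotime at |Spearman| ≈ 0.98.

Cells are split into 16 equal-count pseudotime bins *within each strain*
(strains with fewer cells than bins are excluded and logged), then like
bins are merged across strains so genotype representation is constant per
bin; 8 bins are available as an option. Correlation partitioning is
repeated per bin, and for a pair with an r_B-over-r_W discrepancy the
resolution score is

```
percent_resolved = 100 · max(0, (max_bin r_W,bin − r_W) / (r_B − r_W))
```

on sign-adjusted magnitudes, capped at 100. Pairs whose discrepancy is pure
cell-cycle mixing (coupled within any stage, decoupled by opposite
trajectories) resolve at ≈ 100%; pairs with genuinely genetic discrepancies
stay near 0 and are instead resolved by allele splits.

## Allele splits and the two horizontal modes

For each QTL cluster, strains are divided by allele at the marker nearest
the largest number of member hits (ties to the smaller position) and
partitioning is repeated per subset. The drop
`Δr_B = r_B*(all) − r_B*(subset)` uses sign-adjusted magnitudes with the
all-strain r_W as the sign reference. A locus that jointly shifts two trait
means loses its between-strain correlation in **both** subsets
(`both-drop`); an allele that strengthens the within-organism coupling of
the traits — modeled in the generator as an allele-dependent correlation at
both the cell-noise and strain-effect level — produces a drop in **one**
subset only (`one-drop`). Drops are called against a noise band, by default
the 95th percentile of |Δr_B| over 200 random strain bisections of matching
sizes (raw-sign calls available by flag, band size configurable); the band
guards against the substantial sampling noise of subset r_B at J/2 strains.
Mean-shifting loci leave r_W essentially unchanged under splitting, which
is asserted as a property test.

## Context dependence

**MA lines.** Within-line Pearson correlations per pair; the deviation
score of line ℓ on pair p is `(r_ℓp − mean_{others}) / SD_{others}` with
leave-one-out mean and SD (the inclusive variant is available by flag;
leave-one-out prevents a strong outlier from inflating its own reference
SD). Scores are computed on raw r rather than Fisher z by default to match
the scale on which results are reported; the z variant is a flag. Flags at
|score| > 4. With 94 lines at 1,000 cells each, an injected 0.1 → 0.9
correlation shift is flagged in effectively 100% of simulations.

**Dose series.** Each drug condition is paired with a control generated
from identical underlying random draws, so `Δr_W = r_W(drug) −
r_W(control)` is exactly zero under a zero shift; a replicate-vs-replicate
null (two control conditions) provides the reference spread. Recovered
median |Δr_W| is monotone in the injected per-dose shifts.

## The synthetic-data generator

Defaults mirror the motivating study design: 374 strains, 225 markers on 16
chromosomes (≈ 4,076 cM total, even marker spacing), 167 traits split
28/47/92 among unbudded/small/large cell types, ~800 cells per strain over
3 replicate plates, and a low-heritability regime (strain-level variance a
few percent of the cell-level variance, keeping H² well under 15%). Since
the real within-strain covariance magnitudes are not published, the base
within-strain correlation defaults to identity plus user-specified
structure; validation suites use the scaled-down sizes stated in their
docstrings (e.g. 100 strains × 500 cells × 36 traits) to keep runtimes in
seconds to minutes on one CPU.

Cell values are additive: direct QTL shifts + strain random effect + plate
effect (per replicate × trait, SD 0.1) + deterministic trajectory of a
Uniform(0,1) pseudotime (monotone cubic or single-peak bump, mean-centered)
+ correlated Gaussian cell noise. Genotypes are coded −1/+1 so β is half
the allele-mean difference. The three mechanisms:

- **vertical** — a latent factor with per-trait loadings fluctuates cell to
  cell (creating r_W) and is shifted β per allele (creating matching r_B);
- **direct_horizontal** — per-trait mean shifts β per allele with no
  cell-level coupling beyond the base correlation;
- **corr_modifying** — the target pair's correlation is ρ₀ for one allele
  and ρ₀+δ for the other, applied to the cell noise *and* to the strain
  random effects. The strain-level application is a deliberate modeling
  choice: an allele that strengthens the intracellular coupling of two
  traits also channels background genetic effects on one trait into the
  other, which is what makes the one-subset r_B drop observable. A purely
  cell-level correlation change would leave r_B untouched in both subsets.

Per-context correlation matrices are checked for positive semi-definiteness
(hard error otherwise, tiny ridge only for exactly singular PSD cases). All
randomness flows from a single config seed through fixed child streams
(cross/cells/MA/dose), so identical seeds give bit-identical outputs.

What the generator does **not** emulate: raw images and feature-extraction
artifacts beyond the 5-SD miscall rule; diploid heterozygotes, epistasis,
segregation distortion, linked-gene confounding within a QTL; branching or
non-uniform cell-cycle sampling; non-Gaussian trait marginals. Passing
tests therefore demonstrate the estimators' correctness and calibration
under the stated generative assumptions, not robustness to every artifact
of real imaging data.

## Degenerate inputs and numerical conventions

Constant traits are skipped and flagged (Box–Cox, partitioning errors name
the trait); monomorphic marker regions scan as LOD 0 with a warning; a
single strain makes r_B and H² undefined (errors, not NaN); subsets smaller
than 4 strains abort an allele split with a log entry; strains with fewer
cells than bins are excluded from binning. Equal-count splits put the
remainder cells one-per-bin from the front, so bin sizes differ by at most
one. The pipeline runner records every stage, parameter and output checksum
in a manifest; identical configs and seeds reproduce identical manifests.
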