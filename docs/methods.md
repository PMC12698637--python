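# Methods

This note documents the statistical models behind `rhizopheno`, the
defaults and why they were chosen, what the synthetic scenes do and do not
emulate, and the numerical decisions that were genuinely open.

## Synthetic scenes

The generator produces joint taxonomic/phenotypic scenes with known ground
truth, so every downstream stage can be validated by recovery rather than
by eyeballing.

**Abundance model.** Latent per-sample log basis abundances are drawn from
a multivariate normal whose correlation matrix embeds the planted
structure; they are closed to proportions by softmax and sampled
multinomially at lognormal sequencing depths. This is exactly the
compositional model SparCC assumes, which makes network-recovery tests
well-posed. Defaults: 2 production systems × 4 plant species × 5 replicate
plants (40 samples), 120 taxa, depths lognormal around 1.5 × 10⁴ reads
(σ_log = 0.3) with a floor of 1,000 so coverage stays high and rarefaction
is exercised; per-taxon mean log abundance ~ N(0, 1.5²) and within-sample
log s.d. 1.0. Five replicates per plant and ≥ 100 spectra per sample mirror
the field design this pipeline targets; the remaining scene sizes are the
package's own desk-scale choice and are stated with every computed result.

**Planted structure.**

- *Correlation blocks*: equicorrelated taxon sets; requests that are not
  positive definite are rejected with the offending block named.
- *Hubs*: each hub bridges three otherwise-uncorrelated partner groups
  (within-group correlation 0.6, hub–partner correlation 0.4). The factor
  construction is positive definite and gives hubs simultaneously high
  degree and high betweenness — the two criteria by which hubs are later
  detected. A simple star construction was rejected: making all partners
  load on one factor creates a partner clique, which destroys the hub's
  betweenness.
- *Differential taxa*: log2 effects applied as group offsets on the latent
  log scale for production, plant, or interaction terms.
- *Couplings*: each coupled OPU template owns a per-sample latent factor
  u ~ N(0, 1) that shifts the template's mixture logit and (with the
  recorded sign) the coupled taxa's log abundances. Taxa carrying planted
  structure (couplings, blocks, hubs) are pinned to at least moderate mean
  abundance, otherwise multinomial counting noise at desk-scale depths
  attenuates the planted signal regardless of method; the pinning is
  applied identically in null scenes so calibration comparisons stay fair.

**Spectra.** Each phenotype template is a sum of Gaussian bands: the two
signature bands (phenylalanine 1003 cm⁻¹, amide I 1657 cm⁻¹) plus 2–7
diagnostic bands from a pool covering lipid (1250/1450), protein
(1358/1574), carbon-related (687) and nucleic-acid/carbohydrate regions.
Cells add band-amplitude jitter, a random low-order polynomial baseline,
i.i.d. noise (σ = 0.01 on unit-scale bands), and lognormal multiplicative
intensity jitter. Junk spectra (default 10%) carry random bands away from
both signature windows; outlier spectra (5%) carry signature bands plus a
unique random band set, so they pass QC and end as singletons. The grid is
600–1800 cm⁻¹ at 1 cm⁻¹ (configurable).

**What the scenes do not emulate:** PCR/chimera artifacts, taxon-specific
amplification bias, instrument physics (cosmic rays, detector etalon),
non-Gaussian band shapes, within-cell heterogeneity, and spatial
autocorrelation between samples. Passing recovery tests therefore shows the
algorithms are correctly implemented and calibrated under their own model
assumptions — not that real field data satisfy those assumptions.

## Raman phenotyping

**QC gate.** A spectrum passes iff, after asymmetric-least-squares (ALS)
baseline subtraction and light Savitzky–Golay smoothing, a local maximum
with height and prominence ≥ `snr_min` (default 3) × a robust noise
estimate exists in both 1003 ± 5 and 1657 ± 5 cm⁻¹ windows. Noise is
1.4826 × MAD of the 1750–1800 cm⁻¹ region, assumed signal-free. Peak
prominence is evaluated within a local window (±50 grid steps) rather than
spectrum-wide; global prominence lets broad valleys inflate the prominence
of pure-noise maxima and destroys the junk/valid separation.

**Preprocessing.** Interpolation to the common grid → ALS baseline
(λ = 10⁵, p = 0.01, pentadiagonal banded solve) → Savitzky–Golay (window
11, order 3) → L2 normalization. ALS is exactly equivariant to constant
offsets, so additive offsets cancel. Spectra that are zero after baseline
removal are flagged degenerate and excluded.

**OPU clustering.** Pairwise dissimilarity d = 1 − Pearson correlation,
average linkage, flat clusters at the cutoff (default 0.44). Correlation
distance with average linkage is the standard choice for Raman phenotype
clustering and is bounded, which makes a fixed cutoff meaningful.
Singletons are pooled as "unclassified"; surviving clusters are labeled
OPU-0, OPU-1, … by decreasing size (ties broken by smallest member cell
id), so OPU-0 is always the most abundant phenotype.

**AIC cutoff selection.** For each candidate cutoff h:
AIC(h) = n·q·ln(RSS(h)/(n·q)) + 2·k(h)·q, with n spectra, q the
dimensionality of the PCA subspace explaining 95% of variance, RSS the
within-cluster sum of squares in that subspace, and k the number of flat
clusters (each singleton counts). This is the Gaussian
spherical-within-cluster interpretation of AIC for a clustering; ties go to
the smallest cutoff, and an all-singleton scan returns the largest
candidate with a degeneracy flag.

**OPU tables and diversity.** Per-sample shares include the unclassified
pool (rows sum to 1); a reporting view lumps OPUs under 0.5% overall share
into "Other minor OPUs (<0.5%)", and both the renormalized-without-
unclassified and including-unclassified views are available. Diversity
(richness, Shannon H = −Σ p ln p, Pielou evenness H/ln richness, defined 0
at richness ≤ 1) is computed over identified OPUs only, with the
unclassified pool excluded and shares renormalized.

## Community structure

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric) to the minimum depth by default. Coverage uses the
singleton/doubleton estimator; f₁ = 0 gives coverage 1. The core filter
applies the abundance rule before the prevalence rule; prevalence is
inclusive at the boundary (4/5 = 0.8 passes). CLR uses pseudocount 0.5 (a
common default that avoids log 0; configurable). Bray–Curtis is computed on
row proportions. PERMANOVA Gower-centers −½D², accumulates sequential
(Type I) sums of squares through nested projection matrices in the stated
term order (interaction after main effects, covariates last), and tests
each term's pseudo-F against free row permutations,
p = (#{F* ≥ F} + 1)/(n_perm + 1); permuted F values within a 10⁻⁹ relative
tolerance of the observed count as ties, since label-equivalent
permutations must not fall below the observed statistic through roundoff.
Aliased terms get df = 0 with a warning. NMDS minimizes Kruskal stress-1 by
alternating isotonic regression (primary tie approach: ties ordered by
current configuration distance; exact-zero dissimilarities are forced to
target distance 0) with Guttman majorization updates over 20 random starts;
the best configuration is centered and principal-axis rotated. An
Aitchison (CLR-Euclidean) distance option exists alongside Bray–Curtis for
the ordination/PERMANOVA response; Bray–Curtis is the default.

## Differential abundance

Counts (non-rarefied, by design) are expanded into `n_mc` = 128 Dirichlet
Monte-Carlo instances with prior 0.5 per count; each instance is
CLR-transformed and tested per taxon with sequential F-tests for
production, plant, and production:plant. BH adjustment is applied across
taxa within each instance and term, then expectations are taken over
instances — the order that preserves the conservative operating
characteristics this family of methods is used for. A Welch two-group
shortcut and phylum-level aggregation (summing counts before testing) are
provided. Unestimable interactions (empty design cells) are dropped with a
warning.

## Co-occurrence networks

SparCC runs at the algorithm's reference defaults: 20 inner Dirichlet
(counts + 1) draws, basis variances from ((D−2)I + 11ᵀ)ω² = rowsums(T)
where t_ij = Var[ln(f_i/f_j)], iterative exclusion of the strongest pair
above |ρ| = 0.1 for up to 10 rounds, correlations clipped to [−1, 1], and
the median over draws. Negative basis variances are clamped to a small
positive value with a warning. Pseudo p-values permute each taxon's counts
across samples independently (breaking all between-taxon association while
preserving marginals) and count two-sided exceedances with the +1
correction; the resampling scheme behind published "bootstrap" pseudo
p-values is rarely specified, and this permutation null is the committed
choice because its calibration is testable. Edges require pseudo p < 0.1;
positive and negative correlations are both kept. MCL alternates expansion
and inflation (2.0) with pruning at 10⁻⁵ on the column-stochastic
adjacency with unit self-loops; clusters are connected components of the
attractor support. Betweenness is exact and normalized by (n−1)(n−2)/2;
hubs are nodes in the top decile of both betweenness and degree, with
thresholds taken as quantiles over *distinct* values ('higher'
interpolation) so tied nodes enter or leave together and hub sets cannot
depend on tie-breaking order. Networks are inferred separately per
production system by subsetting samples first.

## Genotype–phenotype integration

Diversity-coupling regressions fit OPU diversity on ASV diversity per
treatment and metric, in raw and log1p (x → ln(1+x), both variables)
forms; cells with n < 3 are omitted, not fabricated. dbRDA eigen-
decomposes the Gower-centered distance matrix, drops negative-eigenvalue
axes, regresses the principal coordinates on centered (full-rank-reduced)
constraints, and eigen-decomposes the fitted values; the constrained
fraction is fitted inertia over total retained inertia, and overall
significance is a permutation pseudo-F over constraint-row permutations.
envfit regresses each centered variable on the first two axis scores;
r² = 1 − RSS/TSS, direction is the unit coefficient vector, p permutes the
variable's rows (default 999 permutations, configurable upward), BH across
variables, significance at BH p < 0.1. envfit is applied to dbRDA site
scores by default (NMDS scores optional). Spearman maps use average-rank
ties and the t-approximation, BH over the full taxon × OPU family (one
heat map, one legend threshold), stars at BH p < 0.1 (*) and < 0.05 (**);
the taxon representation is relative abundance of the filtered core taxa
(a CLR option exists). Constant columns yield missing entries excluded
from the BH family.

## Pipeline

Stage order: simulate → phenotype → community → diffabund → network (per
production system) → integrate. Stage seeds derive from the master seed
through fixed per-stage counters, so toggling one stage never shifts
another's random stream. The manifest records parameters, derived seeds,
outputs, and SHA-256 checksums; identical config + seed reproduces
byte-identical artifacts. Sample ids are the join key everywhere. The
dbRDA constraint set in the pipeline drops zero-variance OPUs and, when
OPUs outnumber n − 2, keeps the most abundant; with ~34 recovered OPUs on
40 samples the constrained model is near-saturated, so the pipeline's
default-scene dbRDA fraction is high while its permutation p is
conservative — a small-n property, not a defect.

## Calibration scenes and problem sizes

The validation suite uses: a 50-taxon × 200-sample scene for SparCC
recovery and null calibration; a 500-spectrum, 5-template scene for the
OPU pipeline; 20-taxon, n = 10-per-group scenes with within-group log s.d.
0.5 for differential-abundance type-I and power (moderate biological
variability — at 4-fold effects the power question is only meaningful when
the effect is not drowned by within-group spread); 1,000 12-sample null
scenes at 199 permutations for PERMANOVA type-I; and 20 zero-coupling
scenes for the integration FDR check. These sizes are the package's own
validation design and are reported alongside every computed value.

## Known limitations

- The AIC form for cutoff selection is one committed interpretation;
  alternatives (e.g. BIC, gap statistic) can pick different cutoffs on
  weakly separated data.
- SparCC's sparsity assumption breaks on densely correlated communities;
  the exclusion heuristic mitigates but does not remove this.
- The permutation null for pseudo p-values treats samples as exchangeable;
  strata-aware permutation is available in PERMANOVA but not in the
  network bootstrap.
- Attenuation of planted correlations for rare taxa is expected behavior
  of count-based compositional inference, not an implementation error.
- envfit on two axes can miss variables aligned with higher ordination
  axes.
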