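# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each module, and what the synthetic-data generator does
and does not emulate.

## Synthetic data

**Genotypes** follow the Balding–Nichols model: per locus an ancestral
frequency p ~ Uniform(0.05, 0.95), per population a frequency drawn from
Beta(p(1−F)/F, (1−p)(1−F)/F) — a point mass at p when F = 0 — and genotypes
Binomial(2, freq). F is on the F_ST scale, so the Weir–Cockerham estimator
should recover it; over 100 replicates at the default study conditions
(12 populations × 15 individuals × 2000 loci, F = 0.118) the estimate
distributes as 0.1182 ± 0.0013 (mean ± SD). The ancestral-frequency bounds
keep loci away from quasi-monomorphism so MAF-filter tests are not
confounded. An optional within-population inbreeding coefficient deflates
heterozygote probability by (1−f) for F_IS recovery tests. Defaults mirror
a 12-site, ~15-individuals-per-site SNP study with a few thousand markers.
The generator does **not** model linkage, coalescent genealogy, or
selection; high-divergence loci for outlier-scan tests are planted by a
separate helper that draws extra loci at a larger F.

**Landmarks.** A deterministic 22-point template (12 fixed points on an
outer outline, 10 sliding points along an inner arc) is deformed along one
fixed unit direction in tangent shape space (orthogonal to translation,
rotation and scale of the template). A specimen's scalar offset is the sum
of a population effect N(0, σ²_B) and an individual effect N(0, σ²_W),
applied at 0.05 shape units per unit offset — large enough that the planted
variance ratio dominates digitization jitter, small enough to stay in the
linear tangent regime. Isotropic landmark jitter (default 1% of template
centroid size) emulates digitization error. With `nuisance=True` each
configuration is additionally rotated U(0, 2π), translated, and scaled
log-normally around a 100-pixel centroid size, emulating images captured at
arbitrary positions and magnifications; the underlying shapes are identical
for the same seed with nuisance on or off, which is what the
Procrustes-invariance tests exploit.

One subtlety matters for recovery tests: **without** nuisance transforms,
centroid size is a deterministic even function of the planted offset
(CS ≈ √(1 + c²d²)), so the centroid-size adjustment regression can strip
between-population signal through the realized skewness of the offsets and
bias P_ST downward by ~0.08. Real images vary in scale, so recovery is
always assessed with nuisance transforms on, where CS variation is real and
independent and the adjustment is harmless.

**Haplotypes.** A random reference sequence is mutated at exactly
`n_segsites` distinct positions, each private to one non-reference
haplotype (round-robin), guaranteeing the planted segregating-site count
and haplotype uniqueness; a duplication profile assigns copy numbers. The
default emulates a 60-sequence, 612-bp COI sample collapsing to 15
haplotypes with 42 segregating sites. No substitution-model heterogeneity,
no indels, no recombination.

## Morphometrics

Generalized Procrustes analysis translates each configuration to a common
centroid, scales to unit centroid size, and iteratively rotates to the
running consensus (proper rotations only, via SVD with a determinant
guard); convergence tolerance 1e-10, at most 100 iterations. Because the
consensus orientation after GPA is arbitrary, the whole aligned set is
rotated so the consensus principal axes lie along x/y (sign fixed by the
first landmark), making output orientation canonical — this is what makes
aligned coordinates bit-comparable across nuisance conditions.

Semilandmarks slide along chord tangents (the unit vector between their
neighbours) minimizing thin-plate-spline bending energy against the
consensus: for tangent matrix T and bending-energy matrix E = I₂ ⊗ BE the
slide amounts are d = −(TᵀET)⁻¹TᵀE·v. Five slide/re-superimposition rounds,
the convention of the standard relative-warps tools. Sliding treats
tangential position along the curve as arbitrary, so any planted signal
with tangential components at semilandmarks is partly absorbed — a property
of the method, not a defect.

Relative warps are computed at α = 0: an ordinary PCA of the aligned
coordinates including the uniform component (the α the original software
used is not generally reported; α = 0 is the assumption-free default). Axis
signs follow a largest-|loading|-positive convention. Thin-plate-spline
grids use the U(r) = r²log r² kernel with exact landmark interpolation;
affine deformations carry zero bending energy.

Repeatability is ICC(3,1) — two-way mixed, consistency, single measurement
— from the ANOVA mean squares. The shape MANCOVA regresses the retained
relative-warp scores on centroid size plus group and reports Pillai's trace
with its F approximation using partial (type III-style) sums of squares;
with a single response this reduces exactly to the ANCOVA F. Post hocs are
Tukey–Kramer with studentized-range p-values and an insert-and-absorb
compact letter display.

## SNP population genetics

The QC cascade applies, in a fixed order: locus call rate ≥ 0.95 →
individual call rate ≥ 0.85 → (locus statistics recomputed) → MAF ≥ 0.05 →
monomorphic removal → one SNP per sequence tag. Order changes results, so
the removal report attributes every removed item to exactly the first rule
that removed it. The one-per-tag rule keeps the SNP with the highest call
rate, ties broken by lowest position.

Diversity: Ho is the heterozygote proportion among called genotypes; He is
Nei's unbiased gene diversity 2p̂q̂·2n/(2n−1); population values are means
over loci with SE = sd/√L, and F_IS = 1 − H̄o/H̄e from the locus-averaged
components (reported missing when H̄e = 0).

F_ST is Weir & Cockerham's (1984) θ with the unequal-sample-size
corrections; loci with zero total variance among the selected populations
are skipped, and the global value is the ratio of sums. Confidence
intervals resample loci with replacement (percentile, default 1000
replicates). Pairwise θ restricts the components to each population pair.

The Mantel test correlates off-diagonal distances with a joint
row/column permutation null, p = (1 + #{r* ≥ r}) / (n_perm + 1); one-sided
by default (the isolation-by-distance convention), two-sided for the
P_ST–F_ST comparison where either sign is meaningful. Geographic distances
are great-circle (haversine, km), natural-log-transformed for
isolation-by-distance.

Diversity contrasts use Kruskal–Wallis on per-locus He with Dunn's z post
hocs (midranks, tie correction) and Benjamini–Hochberg adjustment.

Cluster discovery mirrors DAPC's find.clusters: center/scale genotypes
(mean-imputing missing calls only here), PCA (default 40 components),
k-means for k = 1..k_max with 25 seeded restarts, and
BIC = n·log(WSS/n) + k·log(n); the best k minimizes BIC; linear
discriminant axes are then computed on the retained PCs. Note that for a
12-deme island model at moderate F the BIC optimum often sits at k_max
rather than the true deme count — BIC-based cluster counting is a
heuristic, which is why the recovery tests use well-separated demes
(k_true ∈ {1, 3}).

## Outlier scans

The trimmed-χ² scan computes per-locus Weir–Cockerham F_ST, excludes loci
with pooled expected heterozygosity < 0.1 from fitting, trims the lowest
and highest 5% of the remainder, and fits F̄ and an effective df by maximum
likelihood under F·df/F̄ ~ χ²_df with the likelihood properly truncated at
the observed trim bounds (fitting an untruncated χ² to trimmed data would
inflate df). Right-tail p-values for all loci, BH q-values, flag at
q ≤ 0.05. If all trimmed F_ST are identical the tail test is degenerate and
nothing is flagged.

The PCA–Mahalanobis scan scales genotypes by √(2p̂(1−p̂)), takes z-scores of
per-locus regressions on the first K principal components, and scores loci
by Mahalanobis distance with mean/covariance estimated from the central
5th–95th percentile bulk, iterated twice; distances are divided by the
genomic inflation factor (median distance over the χ²_K median) and
converted to χ²_K p-values. K defaults to the number of populations minus
one in the pipeline: with K much smaller, planted outliers whose
among-deme pattern is orthogonal to the leading PCs are invisible (measured
power ~0 at K = 2 versus 0.9 at K = 11 for a 12-deme design).

The consensus rule flags loci identified by at least `min_methods` scans
(default 2 — with two scans, the intersection); the complement is the
neutral set. The original study used three scans with an "any two" rule;
the Bayesian MCMC scan is out of scope here, and the substitution is
recorded in output metadata (`min_methods` is configurable).

## P_ST

Size adjustment is a single OLS regression of the trait on centroid size
across all specimens; the adjusted trait is residual + grand mean, with
zero sample correlation with size. Variance components come from the
one-way random-effects ANOVA: σ²_W = MS_within,
σ²_B = max(0, (MS_between − MS_within)/n₀) with the unequal-n effective
group size n₀. The formula P_ST(φ) = φσ²_B/(φσ²_B + 2σ²_W) is
parameterized by φ = c/h² — the convention under which the sweep and the
"robust at φ < 1" criterion are defined. (The printed form of the formula
in parts of the literature has c·h² in the numerator; the sweep semantics
used in practice are in terms of the ratio, and only the ratio enters.)

The trace evaluates P_ST on φ ∈ [0, 2] in steps of 0.01. Confidence bands
default to inverting the exact balanced one-way random-effects pivot
MSB/MSW ∕ (1 + n₀σ²_B/σ²_W) ~ F(k−1, N−k) (the Burdick–Graybill interval
for the variance ratio), mapped through the monotone P_ST formula per grid
point; unbalanced designs use n₀ as an approximation. This choice is
deliberate: with only ~12 populations, resampling-based bands centered on
the plug-in estimate cannot carry the full between-population sampling
uncertainty. Measured at the recovery conditions (σ²_B = 2, σ²_W = 1,
12 × 15, three independent 50-seed batches), two-stage cluster-bootstrap
percentile bands cover the generative P_ST in ~87% of runs, parametric
bootstrap ~91%, bootstrap-t ~92% but with badly long lower tails, and the
pivot bands 94–98% at nominal 95%. A two-stage cluster bootstrap
(populations, then individuals within) remains available as
`ci_method="bootstrap"` for users who want the resampling convention.

`robust_flag` is true when the lower band exceeds the supplied neutral
F_ST at the grid point nearest below φ = 1; since the lower band is
monotone in φ this is equivalent to exceeding F_ST on the whole interval
between the reported critical φ and 1. The F_ST used is the global
neutral-SNP θ passed in, never recomputed from trait data.

Pairwise P_ST fixes φ = 1 and runs the two-population ANOVA per pair; the
comparison with pairwise F_ST is a two-sided Mantel test.

## mtDNA

Distances are uncorrected p-distances in percent with pairwise deletion of
positions where either sequence is N or gapped — no substitution-model
correction, matching the pairwise-identity scale on which intraspecific
(~1%) and interspecific (>10%) insect COI divergences separate. Haplotype
collapse is strict string equality (sequences differing only at ambiguous
positions stay distinct), IDs by first occurrence. Segregating sites are
columns with ≥2 resolved states. Trees are Saitou–Nei neighbor joining
(negative branch lengths clamped to zero; optional outgroup rooting) — a
distance method standing in for maximum-likelihood inference, defensible
here because the species-status conclusion rests on distance-scale
separation that NJ preserves. The haplotype network is a Kruskal minimum
spanning tree on raw mismatch counts with all co-minimal alternative edges
reported, rather than a median-joining network: no inferred median
vectors.

## Pipeline

The `run-all` pipeline executes morphometrics → SNP QC → outlier scans →
neutral set → diversity/F_ST/Mantel/clustering → P_ST traces and
comparisons → mtDNA summaries, writing CSV tables, a JSON summary, a
status file, and a manifest with SHA-256 hashes of every output.
Configuration is flat key=value with strict unknown-key rejection. Every
stochastic stage derives its seed as SHA-256(master_seed:stage_name) mod
2³¹, so stages are independently reproducible. Simulated inputs are used
for any input path left empty.

## Problem sizes in the test suite

The suite exercises the estimators at the study scale where that is cheap
(12 × 15 × 2000 genotypes; 180-specimen landmark sets) and at reduced
replicate counts where full Monte Carlo would be slow: recovery properties
quoted over 50 seeds run at 50 seeds in the acceptance tests; screening
versions in module tests use 10–20 seeds. Frozen oracle constants (the θ̂
band) come from 100-replicate runs of the generator recorded in the test
source.

## Known limitations

- The generator's shape signal is one-dimensional; real shape divergence is
  multivariate and relative warps beyond RW1 carry real signal.
- P_ST inference assumes Gaussian random effects; the pivot bands are exact
  only under that model and for balanced designs.
- BIC-based cluster counting saturates for many-deme equilibrium island
  models (see above).
- The VCF reader is deliberately minimal (GT only, biallelic SNPs).
- Sexes are analyzed as separate datasets by convention (shape dimorphism
  would otherwise dominate the first warps); the pipeline operates on one
  dataset at a time and the generator does not simulate dimorphism.
- p-distances and the MST network ignore multiple hits; at >10% divergence
  both underestimate true substitution counts.
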