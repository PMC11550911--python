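# morphopop

Tools for asking whether phenotypic divergence among wild populations
exceeds what neutral evolution can explain — the P_ST–F_ST comparison —
together with everything such a study needs around it: landmark-based
geometric morphometrics, SNP quality control and population genetics,
F_ST-outlier screening, and mtDNA barcoding checks. The package was built
around the study design of an introduced dung beetle spreading across a
continent (shape of the foretibia, the digging tool, versus thousands of
genome-wide SNPs), but every component is generic.

Because field collections cannot be rerun, the package ships a first-class
synthetic-data generator: island-model genotypes with a known divergence F,
landmark sets with known between/within-population shape variances, and
haplotype alignments with a planted number of segregating sites. Every
analysis stage has a parameter-recovery test against these truths.

## The statistics at the core

**Weir–Cockerham F_ST.** Per biallelic locus, variance components
*a* (among populations), *b* (among individuals within populations) and
*c* (within individuals) from allele frequencies, sample sizes and observed
heterozygosity; the global estimator is the ratio of sums
θ = Σa ⁄ Σ(a+b+c) over loci, with a locus-bootstrap confidence interval.

**P_ST.** For a quantitative trait measured in the wild,

P_ST(φ) = φ·σ²_B ⁄ (φ·σ²_B + 2·σ²_W),  φ = c/h²,

where σ²_B and σ²_W are the between- and within-population trait variances
(one-way random-effects ANOVA), c is the fraction of between-population
variance due to additive effects and h² the narrow-sense heritability.
Since c and h² are unknowable without breeding designs, P_ST is swept over
a grid of φ with confidence bands; the P_ST > F_ST conclusion is called
*robust* when the lower band still exceeds F_ST at φ < 1 (i.e. under
conservative genetic assumptions). Traits are relative-warp scores
(principal components of Procrustes-aligned landmarks), linearly adjusted
for centroid size.

**Outlier screening.** Two scans produce the neutral locus set: a
trimmed-χ² scan (per-locus F_ST against a maximum-likelihood χ² null fitted
to the trimmed bulk) and a PCA–Mahalanobis scan (z-scores of locus
regressions on leading principal components). Loci flagged by both are
treated as under directional selection and removed.

## Worked example

```
$ python examples/pst_trace.py
true P_ST at c/h2=1        : 0.500
RW1 explains               : 54.3% of shape variance
estimated P_ST(1)          : 0.536 (95% CI 0.351-0.775)
critical c/h2              : 0.25
P_ST > F_ST robust?        : True
```

Twelve populations of 15 specimens were simulated with between/within shape
variances 2 and 1, so the generative P_ST at φ = 1 is 0.5. The chain
(Procrustes superimposition with semilandmark sliding → first relative warp
→ size adjustment → variance components) estimates 0.536 with a 95% band of
0.351–0.775, and the band exceeds the neutral F_ST of 0.118 for every
φ ≥ 0.25 — so the phenotypic divergence is called robustly greater than
neutral expectation, exactly as planted.

The other examples each run one capability end to end and print what they
compute: `fst_recovery.py` (θ̂ = 0.1177, CI 0.1150–0.1204 against a
simulated F of 0.118), `outlier_scan.py` (17/20 planted selected loci
recovered by consensus), `coi_barcoding.py` (15 haplotypes, 42 segregating
sites, p-distances ≤ 0.98%), `full_pipeline.py` (every stage, with a
manifest). The `morphopop` CLI exposes the same stages from a shell
(`morphopop run-all --out run --seed 1`).

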