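# Methods

This note documents the models, the simulator, the numerical choices and the
known limitations of flavorqtl.

## Study design

Four homozygous founder inbreds — two cherry-fruited (C074, C085) and two
round-fruited (R075, R104) — are crossed in all six unordered pairs (a half
diallel). F2 populations (default 50 genotypes per cross, 300 total)
segregate for founder alleles; three crosses are advanced to F6 recombinant
inbred lines by single-seed descent (SSD). One founder (R075) carries a
ripening-mutant allele homozygously; because the mutation distorts fruit
metabolism, mutant-homozygous plants are removed during line development and
the mutant genotype enters the F2 analysis as a fixed nuisance term.

## The association models

**Diversity panel.** `y = type + marker + e` fitted by OLS, with `type`
coding cherry vs round/beef fruit (a two-level factor by default; a
three-level option keeps beef separate) and `marker` the 0/1/2 alt-allele
dosage. The marker coefficient is tested with a two-sided *t*-test.
Monomorphic markers are skipped.

**F2 half diallel.** All six crosses are analyzed simultaneously with

    y = Xc + rin + M beta + u + e,   u_i ~ N(0, sigma^2_{g,c(i)}),

on genotype means. The components are:

- `Xc`: fixed per-cross intercepts. These are a deliberate addition to the
  underlying formula: the marker term decomposes, on its informative subset,
  into per-cross intercept shifts plus within-cross slopes, so without fixed
  cross intercepts any between-cross mean difference created by genome-wide
  genetic architecture is partially absorbed by the marker columns and
  produces spurious Log P ≈ 5–6 peaks on unlinked chromosomes (measured: 11%
  of planted-QTL replicates mislocalized). Per-cross intercepts are the
  standard guard in multi-cross scans; `ScanConfig(cross_fixed_effects=False)`
  restores the literal single-intercept model.
- `rin`: per carrier cross, an (intercept, additive, dominance) column
  triple, zeroed outside carrier crosses. The additive code is mutant
  dosage − 1 (−1/0/+1), the dominance code the heterozygote indicator —
  the standard F2 parameterization. The mutant dosage comes from tracked
  origins when available, else from the genotype at the designated rin
  marker counted relative to the carrier's allele.
- `M`: the n × 4 parental allele-count matrix. Informative rows sum to 2
  and are therefore collinear with the intercept; the four parental effects
  enter under a sum-to-zero constraint (orthonormal Helmert basis). The
  Wald statistic is computed as the quadratic form on the marker subspace
  orthogonal to all nuisance columns in the V⁻¹ metric, which is invariant
  to the constraint basis; its df is the rank of that subspace (≤ 3).
  Directions whose singular value falls below 1e−7 of the leading one are
  treated as inestimable (they arise at markers nearly collinear with the
  rin term or with partially informative cross subsets) and excluded from
  both the statistic and the df.
- `u`: a genetic variance component per cross, estimated by REML. With one
  observation per genotype, sigma²_g,c and sigma²_e are identified only
  through their sum, so the model collapses to per-cross total variances
  v_c (flagged `collapsed` on the result) — the likelihood's actual
  identifiable parameterization of "cross.genotype + error" on means. With
  replicates the full two-level structure is fitted using closed-form
  block inversion (Woodbury within genotype groups).

**Reference distribution.** A plug-in GLS Wald chi-square ignores the
sampling error of the estimated per-cross variances and is measurably
liberal at this design (empirical type-I ≈ 0.069 at nominal 0.05 over 4500
null replicates, 6 crosses × 50). The scan therefore defaults to the
Kenward–Roger small-sample correction: the fixed-effect covariance is
inflated by the REML information of the variance components, and a scaled
statistic is referred to an F distribution with an estimated denominator df.
This restores the empirical level to ≈ 0.05 (measured 0.044–0.056 across
seeds). `ScanConfig(wald_reference="chi2")` selects the uncorrected
chi-square reference. The reported `statistic` is always the unscaled Wald
quadratic form.

**F6 RILs.** `y = marker + e` per cross by OLS with a two-sided *t*-test;
crosses are never pooled (the three RIL populations are genetically
heterogeneous). R² is reported and equals the squared Pearson correlation.

**Kruskal–Wallis.** Tie-corrected H referred to chi-square with k−1 df;
all-tied input returns H = 0, P = 1. Used for fine-mapping marker/trait
contrasts where normality is doubtful.

**Thresholding and binning.** Log P = −log10 P, capped at 300. Associations
with Log P > 3.5 are retained (no further multiple-testing correction) and
binned by floor(pos / 5 Mbp); per trait × bin the maximum Log P and
contributing cross tags (CC/RR/CR) are kept.

## The simulator

The generator's defaults are the study conditions: 4 founders, 6 crosses,
50 F2 genotypes per cross, 12 chromosomes when localization is at stake,
per-cross background SDs of order 0.5–1.5 trait SD, residual SD 1, a +1 SD
planted allelic effect for recovery experiments, 500-accession germplasm
panels with a 60% planted founder mixture, and n = 273 profiles with 20
compounds for the sensory models.

- **Founders** carry one binary allele per marker (fully homozygous
  inbreds; the crossed parents are the inbred parents of commercial
  hybrids). Marker positions are drawn uniformly per chromosome and sorted.
  `pair_diff_fraction` sets the expected fraction of markers at which any
  founder pair differs: polymorphic markers receive a uniformly drawn
  non-constant pattern over the four founders (which separates a given pair
  with probability 8/14). With two alleles and four founders some pair
  always shares an allele, so the per-pair fraction saturates at 4/7; the
  default 0.4 is exactly representable.
- **Meiosis** follows Haldane: crossover counts Poisson with mean equal to
  the chromosome map length (uniform 2.0 cM/Mbp by default — no genetic
  map is assumed — configurable), positions uniform, no interference, no
  crossover-count coupling between homologs. Founder origin of every
  transmitted allele is tracked.
- **F2** individuals are independent selfings of the cross F1. **F6 RILs**
  descend from distinct F2 plants through four rounds of SSD (one random
  selfed seed per generation). With rin selection on, mutant-homozygous F2
  plants never enter SSD and only wild-type-homozygous F5 plants produce F6
  seed; a line that fails F5 selection is redrawn from the same F2 plant.
  Closed forms used as oracles: F2 segregation 1:2:1; F6 per-locus
  heterozygosity (1/2)^5.
- **Traits**: value = baseline + founder-allelic QTL effects (per inherited
  allele, from tracked origins) + rin additive/dominance + a per-genotype
  cross-background draw + residual. Metabolites are exponentiated (2^value,
  log-normal abundances) and multiplied by per-trial batch factors —
  multiplicative on the abundance scale precisely so that trial-mean
  centering on the log scale removes them exactly. Replication per genotype
  (one trial per replicate) is supported; the scan aggregates to unweighted
  genotype means.
- **Sensory attributes** are weighted combinations of log2 compound
  abundances plus noise, with an optional monotone link.
- **Germplasm panels** are homozygous accessions that carry, per designated
  region, a founder haplotype with the planted probability and otherwise a
  mutated haplotype guaranteed to mismatch every founder in that region.
  The planted assignment is retained as truth.

What the simulator does **not** emulate: linkage disequilibrium structure of
real breeding germplasm, residual founder heterozygosity, genotyping error
beyond missingness, segregation distortion other than the rin selection,
epistasis, genotype-by-trial interaction beyond multiplicative batch
factors, and heterozygous germplasm accessions (an option exists at the
genotype level but panels default to homozygous). Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to those real-data features.

## Numerical choices

- REML is maximized with L-BFGS-B on variance scale with non-negativity
  bounds (analytic gradient in the collapsed case, via tr(P V_c) and
  (Py)² identities) to ftol 1e−15, followed by an optional Nelder–Mead
  polish (`fit(polish=True)`, the default) that sharpens bound-constrained
  optima to oracle precision; scans use the quasi-Newton path only
  (agreement 5e−8 measured) with warm starts from the previous marker.
  Components at the bound are reported as exactly 0.
- A constant response short-circuits to all components 0, Wald 0, P = 1.
- Rank-deficient fixed designs are handled by pseudo-inverse; estimable
  rank is reported as the Wald df.
- Genotype means are unweighted means over non-missing replicates.
- Markers uninformative for a cross are skipped for that cross (per-entry
  masking); the effective sample size is reported per test. Skipping (rather than imputing across flanking markers) is the
  conservative choice for a single-marker model.
- Interval arithmetic: BED is 0-based half-open, internal coordinates are
  1-based inclusive. Fine-mapping interval widths follow the Mbp-endpoint
  convention, width_kbp = (end − start)/1000 with Mbp endpoints
  treated as exact (54.52 Mbp = 54,520,000 bp), so the two-round refinement
  yields 330 and 110 kbp exactly. Differential-segment boundaries are
  marker-resolved; the flanking-marker uncertainty gap is kept inside the
  refined interval so localization is never overstated.
- Refinement semantics: intersection of significant families' segments
  minus the union of non-significant segments; an empty or split remainder
  raises with the conflicting family ids rather than guessing.
- Haplotype matching is exact on genotype strings with missing positions as
  wildcards; `min_call` (default 0.8) excludes poorly called accessions
  from denominators. Heterozygous "1" matches only "1" — no phase
  inference, the reproducible reading of unphased panel genotypes. The
  marker missing-rate filter default is 0.23 and fully configurable.
- Random forest: 500 trees, feature subset ⌊p/3⌋, bootstrap with OOB
  tracking (scikit-learn trees). The requested number of permutation draws
  (default 500) is distributed over trees — one OOB permutation per tree
  per compound at the defaults, the R randomForest convention — and the
  importance is mean(ΔMSE) / (sd(ΔMSE)/√n_trees), i.e. standardization
  after per-tree averaging. Signs come from Pearson correlation on the
  preprocessed data. Zero abundances are replaced by half the compound's
  minimum positive value before log2 (a documented choice). "Scaled by a trial mean" is read as
  log-scale centering; raw-scale division is available via
  `PreprocessConfig(center_by="trial-mean-raw")`.
- PCA is an SVD of the column-centered matrix with per-column mean
  imputation of missing cells.

## Validation experiments and their scales

`flavorqtl.experiments` fixes the problem sizes used by the test suite and
the acceptance script: 1000 null replicates for type-I calibration (one
fixed informative marker on a fixed simulated design — the standard
conditional-on-genotypes calibration), 100 replicates with fresh populations
for QTL localization on 12 chromosomes × 15 markers, 100 replicates for the
rin false-positive contrast on the rin-linked marker window, 2000
independent line × unlinked-locus draws for SSD heterozygosity, 4000
gametes for the Haldane check, 500 accessions for the representation
estimate, and 20 seeded runs at n = 273 for random-forest weight recovery.
These sizes give binomial/Monte-Carlo error bands comfortably inside the
assertion tolerances while keeping the whole suite fast.

## Known limitations

- The Kenward–Roger correction is implemented for the collapsed
  (heteroscedastic diagonal) case; replicated fits fall back to the
  chi-square reference.
- Single-marker association only — no interval mapping, no kinship/GRM
  correction, no epistasis: the three single-marker models above are the full scope.
- The diversity-panel model treats fruit type as the only structure
  correction; population structure beyond type is not modelled.
- Candidate genes are reported as an any-overlap list from GFF3, without
  annotation-based prioritization.
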