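# Methods

This note documents the statistical models behind `snppanel`, the
parameters that matter, the design choices made where several defensible
options existed, and what the validation suite does and does not
establish.

## Data model

A panel is a matrix of diploid biallelic calls in four states (HOM_REF,
HET, HOM_ALT, MISSING) over accessions × markers, with a marker map
(chromosome 1–12 or "unknown"; genetic position in cM; physical position
in bp, 1-based as in VCF) and an accession table (subpopulation label,
hybrid flag, duplicate link). The Illumina A/B convention maps AA →
HOM_REF; calls are taken as reported, with no strand flipping, since
array data are strand-consistent by design. Within a chromosome markers
are kept sorted by genetic then physical position. Markers without a
chromosome assignment are retained for QC and diversity but excluded from
per-chromosome and LD analyses. Hybrids and duplicate re-samples are
excluded from all frequency-based computations by default, so that
denominators refer to the unique inbred accessions.

## Synthetic panels

The generator emulates an inbred crop germplasm panel:

- **Subpopulation divergence.** Ancestral frequencies are Uniform(0.05,
  0.95); each subpopulation's frequency at a locus is Beta(p(1−F)/F,
  (1−p)(1−F)/F) — the Balding–Nichols model — with its own divergence F.
  F = 0 reproduces the ancestral frequency exactly; F = 1 is rejected.
  Default subpopulation sizes and F values (7 groups, 410 accessions,
  F between 0.15 and 0.65) mirror a tomato-type germplasm collection in
  which contemporary market classes, heirlooms, cherry types, landraces
  and a wild relative diverge to very different degrees.
- **LD.** Haplotypes arise from a latent Gaussian process along each
  chromosome with correlation exp(−d/λ) at genetic distance d,
  thresholded per marker at the quantile matching its target frequency
  (Gaussian copula). Because the exponential kernel is Markov, the
  process is generated by an AR(1)-in-distance recursion in O(markers).
  The copula was chosen over forward simulation because its decay scale
  is controllable and analytically checkable: for p = 0.5 the binary
  correlation at latent correlation ρ is (2/π)·asin(ρ), which the tests
  use as an oracle. Default λ = 5 cM.
- **Inbreeding.** With probability F_IS (default 0.96) a locus of an
  individual is autozygous: the second haplotype's allele is copied from
  the first. The autozygosity draw is made per (individual, locus), not
  per individual: residual heterozygosity in a selfing lineage is
  scattered along the genome, and the per-locus form makes the realized
  panel heterozygosity concentrate tightly around the closed form
  2p(1−p)(1−F_IS) ≈ 0.02, matching the 0.01–0.05 range typical of
  inbred tomato-type panels. A per-individual draw would leave the
  realized value dominated by the binomial noise of the handful of
  outbred individuals.
- **Missingness and duplicates.** Calls are deleted uniformly at the
  missing rate (default 1%). Optional duplicate re-samples receive
  symmetric random flips among the three called states at the duplicate
  error rate (default 1.3%), emulating the plate-to-plate discordance
  that duplicate-concordance QC measures.

What the generator does **not** emulate: ascertainment bias of array SNP
discovery, batch/plate effects, genotype-calling cluster artifacts,
pedigree structure within subpopulations, and admixed individuals.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to those real-data features.

## Estimators

- **Weir–Cockerham θ.** Per locus, the among-population (a),
  among-individuals-within (b) and within-individual (c) variance
  components are computed from the two groups' sample sizes, allele
  frequencies and observed heterozygote proportions — the full diploid
  form, because the panels carry residual heterozygotes. The multilocus
  estimate is ratio-of-sums, Σa/Σ(a+b+c); loci with undefined
  denominators are skipped. Significance comes from permuting accessions
  between the two groups holding sizes fixed, with
  p = (1+#{θ* ≥ θ})/(n_perm+1); the matrix report applies a Bonferroni
  factor equal to the number of unordered pairs, with codes ** (<0.005),
  * (<0.05), NS. ("Permuting genotypes" is read as permuting
  individuals; a genotype-wise shuffle would break within-individual
  structure the estimator uses.)
- **Diversity.** He uses Nei's unbiased correction on gene copies,
  n/(n−1)·(1−Σp²), switchable to the uncorrected form. Rarefied allelic
  richness uses the hypergeometric expectation at g = the smallest
  non-missing copy count over all (group, marker) cells, computed via
  log-gamma. Heterozygotes contribute one copy of each allele.
  Multilocus A/He/PIC are unweighted means over the analysis marker set.
  Accumulation curves subsample accessions without replacement (default
  100 permutations) and report mean ± sd of the polymorphic count at
  each subset size.
- **PCA.** Proportional coding fixes the common allele per marker from a
  reference accession set (ties at 0.5 resolve to the ALT allele, the
  same tie-break as the minor-allele tables). Missing cells are
  completed by iterative rank-k SVD reconstruction (default k = 10,
  tol 1e-6, max 100 iterations; observed cells never altered; refuses
  inputs with ≥50% missing). PCA is column-centred SVD without variance
  scaling; loadings are unit-norm right singular vectors — the 0.02
  loading-screen threshold is only meaningful under a fixed
  normalisation, and unit norm is the one used here. Scores are U·S.
- **Outlier scan.** Neutral loci are simulated as two demes diverging
  from an ancestral allele pool at a controlled divergence (Dirichlet /
  Balding–Nichols draws; the infinite-alleles option draws a 4-allele
  ancestral locus and collapses to biallelic by pooling all but the
  ancestrally most common allele), then *sampled*: genotypes are drawn
  per deme with the panel's inbreeding level, and He (pooled gene
  diversity 2p̄(1−p̄)) and θ are computed exactly as for real loci. The
  divergence parameter is calibrated by bisection so the pooled
  multilocus θ of the cloud matches the target ("forced mean") within
  0.005 — widened to 2.5× the Monte-Carlo standard error of the pooled
  mean when few loci are simulated, so that calibration does not fail
  on noise. The target itself comes from one trimming round
  ("neutral mean"): a provisional envelope at the raw multilocus mean,
  observed loci outside it dropped, ratio-of-sums mean of the rest. The
  final cloud (default 5 runs × 10,000 loci) is cut into 25 equal-count
  He bins; per-bin empirical quantiles at (1±ci)/2, smoothed by a
  running median over adjacent bins, form the envelope; bounds at a
  locus's He are linearly interpolated (clamped at the simulated He
  range, with a flag). Calls are strict: θ above the upper bound →
  positive selection; below the lower → balancing (reported separately).
  For validation, *selected* loci are planted as deterministic
  divergence: deme frequencies pushed symmetrically apart so each
  planted locus's two-deme θ parameter equals the target
  (δ² = θ·p̄q̄/(2−θ)). Planting them as Balding–Nichols noise instead
  would leave a large fraction of "selected" loci with realized
  divergence indistinguishable from the background — the per-locus Fst
  distribution under that model is strongly right-skewed (median ≈0.32
  at mean 0.6) — which tests the generative model, not the detector.
- **LD.** Calls are haploidised (heterozygotes treated as missing
  pairwise), defensible at ≥95% homozygosity; r² = D²/(p_A q_A p_B q_B)
  over jointly non-missing accessions; pairs with fewer than 10 joint
  observations are dropped with a count. LOESS uses tricube-weighted
  local linear regression at span 0.3 (the span a practitioner would
  tune in 0.1–0.5). The parametric fit minimises least squares of the
  Hill–Weir drift expectation with a single free parameter ρ in
  C = ρ·d and n fixed at the number of accessions used; the optimiser
  works in log ρ from four starts. Note the expectation's large-C
  asymptote at finite n is the sampling floor 1/n, not 0; the zero limit
  holds jointly with n → ∞. Baselines: fixed 0.2, or the parametric 95th
  percentile of unlinked (inter-chromosomal) pairs computed on
  square-root-transformed r² (mean + 1.645·sd, squared back; empirical
  percentile available), pooled genome-wide to give one baseline per
  group. Decay distance is the first grid point (0.01 cM grid, below
  the 0.1 cM precision of reported decay values) where the fitted curve
  falls to the baseline; a curve starting at or below the baseline
  reports 0 with a flag, and one never reaching it reports
  not-determined.

## Numerical choices and degenerate inputs

Exact-threshold comparisons follow the conventions "≥10% missing" and
"MAF ≥ 0.1" (missing fractions are computed as integer-count ratios so
the 10% boundary is exact; the MAF cut carries a 1e-9 tolerance against
representation error). Loci that are monomorphic in both groups have
undefined θ and are skipped by the ratio-of-sums. All-missing markers are
flagged rather than dropped silently. Envelope bounds outside the
simulated He range clamp to the nearest bin. The copula rejects
non-monotone maps; λ must be positive (the unlinked limit is reached by
small λ, e.g. 0.01 cM).

## Validation problem sizes

The test suite validates at desk scale: divergence recovery on 2,000-locus
panels with 50 accessions per group (planted F 0.05–0.5, tolerance
±0.03); outlier-scan coverage on 50,000-draw envelopes (5% ± 1% outside
at ci = 0.95, pooled over seeds) and ≥80% sensitivity for planted
divergence 0.6 over a 0.1 background; LD-scale recovery on 150-marker /
50 cM chromosomes with 150 accessions (decay distance strictly increasing
in λ ∈ {1, 5, 20} cM for both fits); 200 null permutation tests against
uniformity (KS, α = 0.01); and 3-group PCA recovery at F = 0.3 (≥95%
k-means agreement on PC1/PC2). `scripts/acceptance.py` reruns these
measurements from a single seed and additionally analyses a scaled-down
(~200-accession, ~1,300-marker) seven-group germplasm panel end to end.

## Known limitations

- The island-model cloud is generated from frequency draws, not a
  coalescent, so its He–θ joint shape approximates (well, at these
  sample sizes) but does not exactly reproduce a mutation-drift
  equilibrium; the envelope is calibrated on the controlled quantity
  (mean θ) rather than the full process.
- Haploidised r² ignores the information in heterozygotes; a composite
  (Burrows) estimator would be preferable for panels with substantial
  heterozygosity.
- The SVD imputation assumes the missing pattern is ignorable; markers
  failing systematically (e.g. by subpopulation) would bias scores.
- Balancing-selection calls at low He are unreliable because the lower
  envelope bound is near zero there; they are reported but should be
  interpreted cautiously.
- Optional plot outputs (PC scatter, per-chromosome decay panels) are
  not implemented; the TSV tables are the interface.
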