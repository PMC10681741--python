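# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical conventions, and the design choices where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Conventions

All positions are VCF-style 1-based inclusive; no 0-based conversion
exists anywhere in the package. Site identity is the exact uppercased
`(chrom, pos, ref, alt)` tuple: there is no strand flipping, allele
swapping or indel normalization, so a ref/alt-swapped record is simply
unmatched. Genotypes are coded 0/1/2 as the count of alternate alleles,
with −1 for missing; missing genotypes are excluded from every
concordance tally, and `0|1` and `0/1` are equivalent. Reported
percentages round half-up to two decimals, matching how such tables are
usually printed.

## Sample and site QC

The four per-sample gates follow their printed operators exactly:
contamination (FREEMIX) and duplication are strict `<` (0.03, 0.05),
depth is inclusive `≥ 10×`, and the GC window [40, 44] is read as a
closed interval. All violated gates are reported, not just the first.

Genotypes with GQ < 20 (strict) are set missing before site filtering.
Site removal applies four predicates in a fixed order with the first
match logged: post-masking alternate allele count AC < 1, missing ALT,
ExcessHet > 54.69 (strict), and non-PASS FILTER. VQSR is an external
trained model; the FILTER column is trusted as given. The AC < 1 /
missing-ALT pair is implemented as written — as degeneracy of the record
itself, not a sequence-context low-complexity mask.

**ExcessHet** is the phred-scaled one-sided exact probability of
observing at least the seen number of heterozygotes under HWE,
conditional on the allele totals. The conditional pmf is

P(h | n, n_alt) = n! / (n_rr! h! n_aa!) · 2^h / C(2n, n_alt),

evaluated in log space with `gammaln` and summed with `logsumexp`; tests
verify it against exact rational enumeration for all configurations with
≤ 20 alleles. The popular variant-calling implementation of this
statistic adds small-sample smoothing details that are not published; any
difference is far below the 54.69 decision boundary for the panel sizes
this package targets, and the boundary itself is configurable.

**Relative pruning** builds a graph over pairs whose kinship exceeds the
KING degree boundary (2nd degree ⇒ kinship > 2^−3.5 ≈ 0.0884) and
greedily removes the highest-degree sample (ties by sample id) until no
edge remains. Greedy max-degree vertex cover is not guaranteed minimum,
but it is deterministic, fast, and tests confirm the removed set is
always a valid cover close to the brute-force minimum on small graphs.

**Multiallelic splitting** emits one biallelic row per ALT with the
allele dose counted against that ALT only. Alleles belonging to a
*different* ALT count as reference by default (mainstream normalization
behaviour; `other_alt_to="missing"` is available). Total non-reference
dose per sample is conserved across the split rows, which tests assert on
randomized fixtures.

## Imputation evaluation

The 3×3 (truth × imputed) genotype table is collapsed to TP/FP/FN/TN
under the default **allele-dose policy**: FP means the imputed call
asserts more alternate alleles than the truth (including het→hom-alt),
FN means it asserts fewer (including hom-alt→het), exact agreement on a
variant genotype is TP and concordant hom-ref is TN. Because published
evaluations of this kind report TN = 0, concordant hom-ref pairs are
*excluded* by default (`drop_concordant_homref=True`), making the ratio
metrics describe variant genotypes only; with the flag off TN counts
normally — parameter-recovery checks use the flag off, since only then is
(FP+FN)/total an estimate of the raw per-genotype error rate. Two
alternative collapse policies (`mismatch-to-FP`, `mismatch-to-FN`) are
selectable because the off-diagonal assignment is a convention, not a
theorem.

Under the synthetic error model with uniform class error *e* and the
adjacent-dose kernel (see below), the expected counts over truth class
totals (n₀, n₁, n₂) are TP = (1−e)(n₁+n₂), FP = e(n₀ + n₁/2),
FN = e(n₁/2 + n₂), which yields closed-form expectations for precision
and sensitivity that the acceptance suite checks at 5×10⁶ genotype pairs.

NRC (non-reference concordance) is genotype-aware recall: the fraction of
truth-variant genotypes (codes 1 or 2) called with the exact same code.
Dosage R² is computed per sample as the squared Pearson correlation of
truth hard calls against imputed dosages across matched sites (the
per-sample axis matches how panel evaluations quote "R² of N samples");
samples with fewer than two usable sites or zero variance on either side
are flagged NaN and excluded from the mean with a warning, never silently
zeroed.

Info-score tiers follow the printed operators: high is strictly > 0.8,
medium is the closed interval [0.4, 0.8], low is < 0.4. AF bins are
(0, 1%], (1%, 5%], (5%, 1] with right-closed edges. The ALL column is an
exact integer sum of the bins.

## Synthetic cohort model

The generator emulates a biobank WGS panel at desk scale; every function
is a pure function of its seed (bit-identical reruns).

- **AF spectrum** — default beta(0.3, 2) truncated to [0.001, 0.5] by
  rejection: a rare-skewed spectrum appropriate for a deeply sequenced
  panel in which most variants are rare, with enough mass above 1% and 5%
  to populate all tier-table bins. `uniform` and `fixed` models exist for
  controlled experiments.
- **Genotypes** — i.i.d. binomial(2, p) per site (HWE). With `ld_block`
  set, haplotypes are assembled by copying blocks of consecutive sites
  from a 20-founder haplotype pool, inducing within-block LD. This is a
  deliberately crude LD model: it produces correlation, not
  coalescent-realistic decay, and nothing downstream depends on LD shape.
- **Imputation error** — each genotype is independently miscalled with
  its class probability (e_rr, e_ra, e_aa); the destination follows an
  adjacent-dose kernel (an erroneous hom becomes het with probability
  0.9, an erroneous het splits evenly between homs), reflecting that
  real imputation errors overwhelmingly move one allele dose. Dosage =
  imputed hard call + N(0, dosage_sd²) truncated to [0, 2].
- **Info score of simulated sites** — the squared Pearson correlation
  between the emitted dosages and the imputed hard calls. This
  construction is exactly 1 for a polymorphic site at zero noise and
  degrades monotonically with `dosage_sd`, which is the behaviour an
  engine-reported certainty score should have. The variance-ratio
  estimator `compute_info_score` (var(dosage)/2p̂q̂, clipped to [0, 1],
  0 for monomorphic input) is provided separately for scoring dosage
  vectors from the outside; note that additive dosage noise *inflates*
  that ratio, so it is not used to annotate the simulator's own output.
- **Phenotypes** — null: i.i.d. standard normal. Alternative:
  y = Σ βⱼ·gⱼ + ε with ε ~ N(0, noise_sd²); with all β = 0 and
  noise_sd = 1 this reduces bit-for-bit to the null draw at the same
  seed. The default causal configuration attaches the five effect sizes
  (0.02, 0.01, 0.02, 0.03, 0.01) to five common (MAF ≥ 0.2) sites spread
  evenly across the genome. For power studies,
  `power_calibrated_scale` multiplies all five effects so the weakest
  SNP reaches a target non-centrality (default 73 ≈ power 0.999 at
  5×10⁻⁸), accounting for the phenotypic variance the causal SNPs
  themselves contribute to the residual of a single-SNP test.
- **Sample metrics** — passing samples drawn uniformly inside the
  acceptance region; planted failures violate exactly one named gate.
- **Kinship** — planted pairs receive the midpoint of their KING degree
  interval (duplicate 0.40, 1st 0.25, 2nd 0.1326, 3rd 0.0663); all other
  pairs get |N(0, background_sd)| capped strictly below the unrelated
  boundary 0.0442.

What passing tests on this generator do **not** show: realistic LD decay
and haplotype structure, population stratification or admixture,
genotype-likelihood-level uncertainty, indels and strand ambiguities,
batch effects. Results on real cohorts can differ wherever those
features matter (e.g. imputation error is not independent across sites in
LD; λ_gc inflation from stratification is absent here by construction).

## GWAS stage

SNP filters are strict, as printed: MAF > 0.01, exact HWE p > 10⁻⁶,
missing rate < 0.01. The HWE test is the standard exact conditional
two-sided test (sum of all heterozygote-count probabilities not exceeding
that of the observed count), which is robust at the rare-variant tail
where the 10⁻⁶ cut operates; tests verify it against exact rational
enumeration and its hom-ref/hom-alt swap symmetry.

Association is OLS of phenotype on genotype dose plus intercept and
covariates, with the p-value from the two-sided t distribution. The
genome-scan path residualizes phenotype and genotypes on the covariate
block (Frisch–Waugh) and fits each residual simple regression in closed
form — algebraically identical to the per-SNP fit, and tested to agree
with statsmodels to float precision; columns with missing codes fall
back to the per-SNP fit with row dropping.

λ_gc is the median of the 1-df chi-square quantiles of the p-values
divided by the null median 0.45494. The genome-wide threshold is
p < 5×10⁻⁸ (strict); published text occasionally prints the inequality
inverted, but the accompanying usage ("at the significance threshold of
5e-8") fixes the direction.

**Locus grouping** formalizes "sliding a fixed-width 1-Mb window" as a
left-anchored greedy scan: open a window at the first unassigned
significant SNP, take every SNP strictly within 1 Mb of the anchor,
repeat. Windows never extend as members arrive ("fixed-width" excludes
chain-extension clumping), so every locus spans strictly less than the
window and every significant SNP lands in exactly one locus. The locus
center is the midpoint of the first and last member; the lead SNP is the
member with the smallest p (ties by position). Anchoring at the leftmost
member rather than the lead SNP is the default because it makes the
partition independent of the p-values.

**Locus matching** pairs same-chromosome loci whose centers differ by at
most 500 kb, greedily by ascending distance, one-to-one, with a
symmetric tie-break — so swapping the inputs preserves the shared count.
Greedy matching is not guaranteed maximum-cardinality when one locus's
only candidate partner is taken by a closer rival; for real
well-separated GWAS loci (at most one candidate each) greedy attains the
maximum, which the tests assert, along with the ≤-maximum bound in
general.

## Problem sizes and tolerances

Monte-Carlo checks use a 4-standard-error band on binomial quantities.
The parameter-recovery suite runs 50 samples × 100,000 sites (5×10⁶
genotype pairs) at e = 0.02; GWAS calibration uses 2,000 samples ×
10,000 independent SNPs, where λ_gc is required to land in [0.95, 1.05]
and the expected genome-wide false-positive count is 10⁴·5×10⁻⁸ =
5×10⁻⁴ (zero hits in ≈ 99.95% of seeds). These sizes keep the whole
suite within a half-minute on one CPU while leaving all asymptotic checks
comfortably inside their bands.

## Known limitations

- BCF, tabix random access, ploidy ≠ 2 and structural variants are out
  of scope; VCF writing emits plain text.
- The exact-test implementations enumerate the conditional support per
  site (O(n) per site), fine up to tens of thousands of samples but not
  tuned for millions.
- The imputation info score of external files is whatever the configured
  INFO tag carries (DR2, INFO or R2 tried in that order); different
  engines define their certainty measures differently, and tier
  boundaries (0.4, 0.8) are conventions, not estimates.
- Greedy relative pruning and greedy locus matching are deterministic
  approximations; both expose the exact quantities needed to audit them
  (the kinship graph, the candidate pair distances).
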