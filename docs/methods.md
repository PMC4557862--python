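# Methods

This note documents the models and procedures msgen implements, the
parameters that matter, the synthetic-data model and what it does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Study design the package serves

The target design is a three-cohort MS genetics study in a founder
population: two case–control SNP-chip cohorts and one trio cohort, with
a small, well-characterised Ashkenazi (AJ) reference panel used to
anchor ancestry assignment. The analysis chain is: variant QC → ancestry
extraction → HLA and SNP association (logistic in the case–control
cohorts, TDT in the trios) → polygenic burden comparison →
cross-study meta-analysis → LD-decay profiling.

## Ancestry extraction

**Distance.** Genome-wide relatedness is summarised by the
allele-sharing distance d(i,j) = meanₖ |dᵢₖ − dⱼₖ| / 2 over sites
non-missing in both individuals (0 for identical genotypes, 1 for
opposite homozygotes everywhere). This is a deterministic substitute for
haplotype-sharing (IBD) distances produced by an HMM phaser: the
downstream stages consume the distance only through its ordering
(MDS and Ward), which the allele-sharing metric preserves, and the
substitute removes a heavyweight stochastic dependency. A consequence is
that nothing corresponds to averaging over multiple phasing rounds.

**Embedding and clustering.** Classical (Torgerson) MDS —
double-centre the squared distances, eigendecompose, scale eigenvectors
by √λ — with `k = 50` dimensions by default; dimensions are truncated
to the positive-eigenvalue count with a warning. Ward agglomeration in
the D2 convention (scipy linkage) runs directly on the distances.
Case–control cohorts are labelled by cutting the tree at `K` clusters
(default 3: in each real dataset the geometry is one large EUNW
cluster, one small AJ cluster, and one small third cluster — southern
European or Finnish); the cluster holding the largest share of the
reference-panel AJ becomes AJ, the largest remaining cluster EUNW, the
rest OTHER. An even split of the reference panel across clusters is an
error, not a guess.

**Trios.** Tree cuts are distorted by within-family relatedness, so trio
cohorts are labelled on the first MDS coordinate: PC1's sign is anchored
so the reference-AJ mean is positive, the default threshold is the
midpoint of the reference AJ and EUNW PC1 means, a member is AJ iff
PC1 exceeds the threshold, and a trio is an AJ trio iff at least one
parent is AJ (mixed trios contribute transmissions from both parents).
Probands land near the mean of their parents' PC1 by construction of
inheritance; the test suite checks this within two within-group SDs.

## QC

Variants are kept when minor allele frequency ≥ `maf_min` (default 1 %)
and missing-call rate ≤ `miss_max` (default 0.1 %), applied in that
order so the report attributes each removal to exactly one rule. LD
pruning is greedy and windowed (defaults: window 50 variants, step 5,
r² threshold 0.1); r² is the squared Pearson correlation of dosages
(composite LD — needs no phase), missing values pairwise-deleted. The
window/step defaults follow the dominant chip-era convention; only the
r² threshold is dictated by the design itself. Pruning is deterministic
in position order, and a post-hoc exhaustive re-check of within-window
pairs is part of the test suite.

## Burden score

MSGB(s) = Σᵢ wᵢ · dᵢ(s) with wᵢ = ln(published ORᵢ) over a risk-weight
table (the emulated catalogue carries 110 non-HLA SNPs with OR 1.2–1.4).
Missing dosages are imputed as 2·(cohort risk-allele frequency), which
keeps scores comparable across individuals with different missingness.
Group comparisons use a one-sided Wilcoxon rank-sum test (cases
expected higher, because the score is built exclusively from risk
alleles): exact enumeration when the smaller group has ≤ 10 members and
the data are tie-free, otherwise the normal approximation with tie
correction. The group difference `d` is reported as the difference of
group means — a location-shift estimate would be equally defensible;
the mean difference was chosen as the simpler, moment-based summary.
Note the normal approximation is only guaranteed near the centre of the
null distribution; at n = 10 the extreme tail is discreteness-limited.

## Association

**Logistic fit.** IRLS/Newton with tolerance 1e-8 on the deviance and
at most 50 iterations; Wald SEs from the inverse observed information.
Complete separation (any |β| escaping 15, or a singular information
matrix) is flagged on the record with p set missing rather than raised —
in a small founder cohort a fully-penetrant allele among cases is an
expected outcome, not a crash. Markers with fewer than 5 carriers or
constant dosage are skipped with a log entry.

**Nagelkerke r².** r² = [1 − exp((2/n)(ll₀ − ll₁))]/[1 − exp((2/n)ll₀)],
the rescaled Cox–Snell pseudo-R², computed from the fitted and
intercept+covariate log-likelihoods.

**Step-wise conditional scan.** Each step scans every remaining marker
(SNPs and HLA alleles) conditioned on the base covariates plus all
previously selected alleles. Selection is always the most significant
HLA allele — even when a SNP is more significant, and even when the
allele itself misses Bonferroni — because the purpose of the scan is to
resolve the HLA signal into named alleles; SNPs serve as evidence that
unexplained MHC signal remains. Termination: no marker of any kind
passes α / (markers tested that step). The Bonferroni denominator is
the per-step test count, a choice the design leaves open. Separated
alleles are flagged and the next-best allele selected. The per-PC
covariate count defaults to 5 where PCs are used.

## Trio TDT

Per marker, each heterozygous parent contributes one transmission
event; the proband's counted-allele copies minus the homozygous
parents' fixed contribution gives the transmitted count from het
parents, handling the double-het case (child dosage 1 → one T and one
U) without phase. Mendelian-inconsistent trios are excluded per marker
(the real alternative, per-family exclusion, discards information the
per-marker rule keeps). χ² = (T−U)²/(T+U) on 1 df with no continuity
correction — the classical TDT; the 12:4 worked example (OR 3.00,
p 0.0455) pins this convention. The χ² tail tracks the mid-p exact
McNemar binomial within 10 % for T+U ≥ 30 in the tested range; the
plain (non-mid) exact tail differs by up to ~40 % at these counts, a
property of discreteness rather than of the implementation.

## Meta-analysis

Fisher's method (X² = −2Σln pᵢ on 2k df) reproduces the three-study
per-allele meta p-values; a printed p of exactly 0 cannot be combined
and is rejected. Inverse-variance fixed-effect and DerSimonian–Laird
random-effects pooling serve the genome-wide SNP meta-analysis; with
Q ≤ df the DL estimator truncates τ² to 0 and collapses onto the fixed
model (this is the regime of the reconstructed three-study HLA row:
Q ≈ 1.34 on 2 df). SEs are reconstructed from printed OR/p pairs as
|ln OR|/z (degenerate at OR = 1). BH-FDR uses the statsmodels step-up.
Chi-square and normal tails come from scipy; the even-df finite-series
closed form appears only as an independent oracle in the tests.

## LD

Haplotype frequencies for an unphased pair of biallelic loci are
estimated by EM over the double-heterozygote phase ambiguity (all other
genotypes decompose uniquely): uniform start, tolerance 1e-10 on the
frequency update, at most 1000 iterations. D = f_AB − p_A p_B;
D′ = |D|/D_max with the sign-appropriate D_max, reported in [0, 1];
r² = D²/(p_A(1−p_A)p_B(1−p_B)). Monomorphic loci are an error (LD is
undefined). Decay profiles subsample every group to a common size
(seeded) so medians are comparable across groups of different sizes,
bin site pairs by base-pair distance into log-spaced bins (default 10
bins to 500 kb; the source figures give no bin edges), and cap the
per-bin pair count (default 500, seeded subsample) to bound cost.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
with defaults set to the study-like conditions:

* **Divergence**: Balding–Nichols — ancestral p ~ U(0.1, 0.9) per site,
  each population draws Beta(p(1−f)/f, (1−p)(1−f)/f), so f is an
  Fst-style knob. The default f = 0.01 is a placeholder for the
  AJ–EUNW divergence, which no published figure quantifies; it is
  deliberately config-exposed.
* **LD**: Li–Stephens-style copying of 2n haplotypes from a founder
  pool with per-base switch probability `recomb_per_bp`. This rate is
  an *effective, population-scaled* rate, not the meiotic ~1e-8/bp: at
  1e-8 a 1-Mb region sees < 0.01 expected switches and no measurable
  decay; around 1e-6–1e-5 the r² medians decay over hundreds of kb,
  matching the qualitative decay-profile contract, and a smaller
  founder pool (stronger bottleneck) raises LD at all distances.
* **HLA**: alleles are drawn per chromosome within haplotype blocks, so
  alleles sharing a block tag (DRB1\*15:01–DQB1\*06:02;
  B\*38:01–C\*12:03) co-occur on one simulated chromosome and alleles at
  one locus are mutually exclusive. Default haplotype frequencies solve
  1−(1−q)² = carrier target: ~5 % DRB1\*15:01 carriers in AJ vs 17.5 %
  in EUNW (middle of the quoted 15–20 % range), with the protective
  class I haplotype AJ-enriched (0.06 vs 0.02) at OR 0.5.
* **Disease**: P(case|d) = logistic(α + Σwᵢdᵢ) with α solved by root
  finding so the marginal prevalence matches `baseline_prevalence`
  (default 0.2, a case-enriched study mix rather than a population
  prevalence); labels are independent draws. Case quotas are met by
  rejection sampling, mirroring case–control ascertainment without an
  incidence model.
* **Trios**: parents are phased haplotype pairs from their population's
  frequencies; probands inherit one allele per parent per site
  (independently per site — markers are unlinked in trios, which is all
  the per-marker TDT consumes); a configurable fraction (default 1/3)
  of trios has exactly one non-AJ parent; proband ascertainment
  optionally rejection-samples until affected.
* **Determinism**: one global integer seed; every stage derives its
  generator from (seed, stage-key) via hashed SeedSequence entropy, so
  fixed seed ⇒ bit-identical cohorts regardless of stage order.

What the generator does **not** emulate: demographic history
(bottleneck dating, admixture), mutation, sex chromosomes, genotyping
batch effects, array ascertainment of SNPs, and real haplotype
structure beyond the founder-copying mosaic. Passing tests therefore
demonstrate that the statistical machinery is correct and calibrated
under the assumed generative model — not that the pipeline is robust to
artefacts real cohorts carry.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run the simulation checks at:
log-OR recovery at 2000 per arm × 20 replicates; ancestry recovery at
Fst 0.01, 200 per population, 5000 SNPs × 10 replicates (mean label
accuracy ≥ 98 %; per-replicate accuracy fluctuates ±2 % at these sizes);
MSGB power at 110 planted SNPs, 500 per arm × 20 replicates; TDT
type-I error over 250 independent null markers × 10,000 trios × 20
replicates; BH-FDR over 1000 screens of 1000 nulls; step-wise selection
at n = 2000 × 10 replicates. These sizes put Monte-Carlo error well
inside each acceptance band while keeping the whole suite desk-scale.

## Known limitations

* The allele-sharing distance is not an IBD estimate; it compresses
  relatedness less sharply than haplotype sharing and will separate
  populations more slowly at very low divergence.
* The EM LD estimator assumes Hardy–Weinberg within the sample when
  splitting double heterozygotes.
* `se_from_summary` inherits the rounding of printed OR/p pairs;
  downstream pooled values are internal-consistency checks, not
  re-derivations of unpublished statistics.
* The stepwise scan's Bonferroni denominator (tests per step) makes the
  threshold slightly more permissive at later steps as markers are
  consumed; with a fixed denominator the stop decisions would be
  marginally stricter.
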