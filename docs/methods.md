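# Methods

This note documents the models implemented in `ehrgenpop`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not emulate.

## Synthetic cohorts

The generator produces every input the downstream stages consume, with
ground truth retained for recovery measurements.

**Allele frequencies.** K ancestral populations diverge from a shared
ancestral frequency p (drawn uniformly on an interval inside (0, 1),
default (0.05, 0.95)) by the Balding–Nichols construction: population
frequencies are Beta-distributed with shape parameters
`p(1−F)/F` and `(1−p)(1−F)/F`, so each population's frequency has mean p
and variance `F·p(1−p)`. F is the per-population divergence (Fst-like)
parameter; defaults in the standard designs are 0.1–0.15, the range typical
of continental-scale human differentiation. This is the divergence model
that PCA- and admixture-style methods assume, which is exactly why it is
the right generator for testing them.

**Genotypes.** Reference-panel individuals are unadmixed draws
`Binomial(2, p_k)`. Study individuals receive Dirichlet ancestry
proportions q (one concentration vector per cohort group) and genotypes
`Binomial(2, Σ_k q_k f_k)`. Variants are independent given ancestry: there
is no linkage disequilibrium, no phasing and no recombination map. LD
pruning of real data moves it toward exactly this regime, but the absence
of LD means the pruning operations are exercised on planted correlated
copies rather than realistic decay patterns, and nothing here validates
haplotype-based methods.

**Demographics and labels.** Each cohort group carries a self-identified
race/ethnicity (SIRE) label and a preferred language; with probability
`label_noise_rate` (default 0 unless a design says otherwise) a person's
SIRE is replaced by another group's label, emulating the imperfect
correlation between self-identification and genetic ancestry. Age is
uniform on [18, 90] — a covariate with nonzero variance, nothing more is
claimed — and sex is binary M/F because every model downstream codes sex as
a single 0/1 covariate.

**Phenotypes.** Case status per phecode follows a logistic model
`logit P(case) = β0 + β1·group + β2·sex + β3·age + β4·SIRE + Σ β_v·dosage_v`
with any subset of terms active. Cases receive ≥1 phecode occurrence,
each occurrence a distinct encounter carrying one mapped ICD code, spread
over visit-like (appointment/office/hospital/procedure) and message-like
(telehealth, phone, lab, note) channels (70% visit-like by default).
Controls receive no encounter for that phecode, so the generated tables
realize the case definitions exactly; real billing data is far noisier,
and nothing here models coding practice heterogeneity.

**IBD.** Pairwise segment counts are Poisson with rate `within_rate`
(default 2.0) inside a planted community and `between_rate` (default 0.05)
across communities; segment lengths are shifted-exponential with minimum
3 cM and mean 8 cM, roughly the detectable range of segment callers.
Segments are painted onto random chromosome intervals; their positions
carry no population-genetic meaning.

All draws flow from `numpy.random.default_rng(seed)`; the same (spec, seed)
pair reproduces outputs bit for bit.

## Genotype QC and relatedness

* Missingness filters are strict (rate > threshold removes; the rate is
  computed as missing/n so an exact 5% survives a 0.05 threshold).
* Strand-ambiguous = A/T or C/G pairs.
* Duplicate resolution keeps the pair member with the **lower** missing
  rate; `drop_policy="drop_cleaner"` reproduces the opposite reading.
  Duplicate groups are closed transitively before choosing a survivor.
* Kinship defaults to the KING-robust between-family estimator
  (heterozygote-concordance based): with i the member of the pair with
  fewer heterozygous calls over co-observed sites,
  `φ = (N_het,het − 2·N_opp-hom)/(2·N_het(i)) + 1/2 − (N_het(i)+N_het(j))/(4·N_het(i))`.
  It is exactly 0.5 for identical genotypes and needs no allele
  frequencies, which makes it robust to cohort structure. An
  allele-frequency GRM estimator (`method="grm"`) is provided as an
  alternative backend; note it is biased at very small n because the
  frequencies are estimated in-sample.
* Degree cutoffs: φ ≥ 0.354 duplicate/MZ, φ < 0.0884 second-degree
  inclusion, φ ≥ 0.0442 third-degree-or-closer (used when filtering
  relatives out of IBD networks).
* The unrelated-set selector greedily removes the node with the most
  remaining related partners (ties by sample id). The output is guaranteed
  to contain no related pair; it matches the exhaustive maximum independent
  set on stars and small random graphs, but is not globally optimal in
  general.
* Hardy–Weinberg: 1-df chi-square goodness of fit on (hom, het, hom)
  counts, no continuity correction; monomorphic variants return p = 1.
  The threshold is context-dependent: 0.001 when preparing PCA input,
  1e-10 for IBD input, 1e-12 in per-group GWAS QC.
* LD pruning mirrors the two window rules: pairwise r² (window 100,
  step 5, r² > 0.1 removes the later variant of the pair) and VIF
  (window 200, step 5, iteratively remove the variant with the largest
  1/(1−R²) until all ≤ 1.15; exact ties drop the later variant; a ridge
  epsilon of 1e-8 keeps collinear windows invertible). r² is computed on
  mean-imputed dosages. A third thinning rule keeps variants ≥ 2 kb apart.
* Reference alignment intersects on (chrom, bp): identical allele pairs
  merge as-is, swapped pairs recode the study dosage g → 2−g, non-ACGT or
  irreconcilable allele sets are dropped. Strand flips are not attempted
  because strand-ambiguous variants are removed upstream.
* Mendel-error filtering is a documented no-op without a pedigree (the
  synthetic cohorts are founders-only).

## Ancestry inference

**PCA.** Joint PCA of the merged study+panel matrix: mean-impute missing
calls, center each variant at 2p̂ and scale by √(2p̂(1−p̂)) with p̂ the
joint allele frequency, then an economy SVD. Scores are deterministic up
to column sign, which is fixed by making each loading vector's
largest-magnitude entry positive. Ten components are computed by default.

**GIA assignment.** One KNN classifier per reference ancestry, on that
ancestry's two-PC plane. "Cluster membership" is operationalized as the
fraction of the k nearest panel neighbors carrying the ancestry's label;
the paper-style procedure never defines it more precisely, and a neighbor
vote is the natural reading. k is selected per ancestry from {5, 10, 15, 20}
by 10-fold cross-validated multi-class accuracy on the panel, ties toward
smaller k. A sample is assigned iff exactly one ancestry's membership
exceeds the threshold — 0.50 continental, 0.90 subcontinental — otherwise
it is Ambiguous. Which two PCs form each ancestry's plane is, by default,
chosen per panel as the two PCs with the largest one-vs-rest centroid
separation (squared centroid gap over pooled within-group variance) for
that ancestry; fixed pairs (e.g. the 1000G-style 1–2/2–3/4–5 convention)
can be supplied instead. The automatic rule exists because PCA axes of an
arbitrary panel are rotation-dependent, and a hard-coded pair valid for
one reference panel can place another panel's ancestry in an uninformative
plane. Subcontinental assignment runs within one continental group on PCs
1–4, using either panel subpopulation labels or study SIRE labels; SIRE
classes with N ≤ 20 are dropped from the label set.

**Admixture.** Unsupervised binomial-mixture maximum likelihood:

    L(Q, F) = Σ_ij [ g_ij log(Σ_k q_ik f_kj) + (2−g_ij) log(Σ_k q_ik (1−f_kj)) ]

maximized by EM block updates of Q (N×K, rows on the simplex) and F (K×M,
clipped to [1e-6, 1−1e-6]) from random Dirichlet/Uniform starts. EM was
chosen over quasi-Newton acceleration deliberately: it is provably
monotone in the likelihood (which the tests assert every iteration) and
adequate at the problem sizes used here. Missing dosages contribute
nothing to the likelihood or the updates. `tol` is the **relative**
log-likelihood gain (|ΔLL|/|LL|, default 1e-6) — an absolute gain
criterion is meaningless against likelihood magnitudes of order N·M.
Three random restarts by default keep the best likelihood; the standard
recovery designs (K = 2 and 4, F = 0.15, N = 200–500, M = 2000) recover Q
with mean absolute error < 0.05 after Hungarian alignment of components
on truth correlation. K = 1 is solved in closed form. Q is identifiable
only up to component permutation; every recovery statement aligns first.
Component naming follows SIRE majorities (NH-White → European,
NH-AfAm → African, NH-Asian → East Asian, highest HL-Other+HL-White →
Native American for K = 4); an exact tie withholds the label with a
warning.

## IBD networks

Segments are summed per unordered pair into total genome-wide cM; pairs
related at third degree or closer (φ ≥ 0.0442) are removed; communities
are detected with InfoMap (map equation) on the weighted undirected graph
via igraph, seeded for determinism. The reporting view keeps communities
with **more than** `min_size` members (strict, per the >100 convention)
and nodes with degree **at least** `min_degree` on the filtered graph
(the ≥30 reading; a strict comparator is available because the two
conventions circulate). The assignment itself is never altered by
reporting filters.

## Phecodes

An occurrence is one distinct encounter (by encounter id, not date)
carrying ≥1 ICD code mapped to the phecode; multiple qualifying codes on
one encounter count once. Scope `all` admits every encounter type; scope
`visit` restricts to appointment/office/hospital/procedure. Cases need
count ≥ `min_occurrences` (default 1), controls have count 0, and people
strictly in between are excluded from both sides — the conservative
convention, with a flag to treat them as controls instead. The retention
curve reports cases(min)/cases(1) per phecode and scope; testability
filters require case counts strictly above the per-analysis minimum
(50 for GIA scans and GWAS/PheWAS, 20 subcontinental, 10 admixture scans).
The real phecode v1.2 ontology is not bundled; the ontology is a pluggable
TSV and the generator ships a miniature synthetic one.

## Association scans

All scans are maximum-likelihood logistic regressions (statsmodels IRLS,
max 100 iterations, tol 1e-8) reporting the coefficient of interest on the
log-odds scale with Wald SE/z/p and OR with 95% CI = exp(β ± 1.96·SE).
Separation is declared when statsmodels raises or when any |β̂| > 20;
affected fits carry a flag and a missing p, and scans continue past
per-cell failures rather than aborting — the NA-propagation behavior of
standard GWAS tooling. Constant outcomes and rank-deficient designs raise
errors that scans record per cell. Sex enters as 0/1 (female = 1) and is
dropped within sex-specific strata, where it is constant. SIRE adjustment
uses a categorical factor with the largest SIRE as the reference level;
the reference choice does not affect the group coefficient's p-value.

* **GIA–phecode scan**: one-vs-rest group indicator + sex + age (+ SIRE),
  Ambiguous samples excluded from both sides of the contrast; Bonferroni
  across all (phecode, group) cells.
* **Admixture–phecode scan**: one ancestry proportion at a time + sex +
  age, within one SIRE; phenotypes with > 10 cases in that SIRE;
  Bonferroni across phenotype × component cells.
* **GWAS**: per-variant additive dosage + age + sex + the group's own
  PCs 1–10, after per-group QC (±3 SD heterozygosity outliers, HWE
  p < 1e-12, in-group MAF > 1%); genome-wide significance 5e-8; λ-GC
  (median association χ² over 0.4549) reported per scan.
* **Meta-analysis**: fixed effects, inverse-variance weights w = 1/SE²,
  combined β = Σwβ/Σw, SE = (Σw)^(−1/2); variants contributed by fewer
  than two groups are dropped; zero SEs rejected.
* **PheWAS**: one variant against all testable phecodes in a group, with
  the group's own PCs; two thresholds, 0.05/#phecodes and 5e-8/#phecodes.
* **Effective sample size**: N_eff = 2/(1/N_cases + 1/N_controls), the
  harmonic mean of the case and control counts (so balanced counts return
  the common count).

## Problem sizes and numerical choices

The standard verification designs are: 5 populations at F = 0.1 with
200/panel population and a 1000-sample admixed study cohort for ancestry
assignment (held-out panel accuracy and ambiguity); K = 2 (N = 200) and
K = 4 (N = 500) at M = 2000 for admixture recovery; 3 planted communities
of 100 for IBD; 1000 null phenotypes at N = 800 for scan calibration and
~4000 null variants at N = 1200 for λ-GC; N = 4000–5000 for planted-effect
recovery (group OR 3, variant OR 1.8). These sizes were chosen so each
statistic's Monte-Carlo error is small against the property it checks
while the whole suite remains a desk-scale computation.

Degenerate inputs: SD = 0 heterozygosity flags nothing; zero-variance
variants get r = 0 in LD pruning; monomorphic variants p = 1 in HWE;
empty p-value sets and zero test counts are rejected rather than guessed.

## Known limitations

No LD, phasing, imputation or X chromosome; KNN membership is a vote
fraction, not a posterior; the greedy unrelated set is not a maximum
independent set in general; EM admixture can need many iterations for
heavily admixed cohorts at low divergence (the restart mechanism and the
monotone likelihood make this visible rather than wrong); passing
recovery tests on these generators demonstrates correctness of the
machinery, not performance on real biobank data.
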