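# ehrgenpop

Ancestry-aware analysis of EHR-linked biobank genotypes: genotype QC and
relatedness, reference-anchored genetically-inferred-ancestry (GIA)
assignment, unsupervised admixture estimation, identity-by-descent (IBD)
sharing networks, phecode construction from encounter-level ICD codes, and
the association machinery that ties them together (GIA–phecode scans,
admixture–phecode scans, per-group GWAS, fixed-effects meta-analysis and
PheWAS).

The package is aimed at methodologists and biobank analysts who need a
tested, fully synthetic-data-driven implementation of this pipeline: every
stage can be exercised end to end with no external downloads, because a
first-class generator module produces reference panels, admixed cohorts,
demographics, encounters and IBD segments with known ground truth.

## The models at the core

**Ancestry assignment.** Study and panel genotypes are merged, standardized
per variant by mean 2p̂ and scale √(2p̂(1−p̂)), and decomposed by PCA. For
each reference ancestry a K-nearest-neighbor classifier runs on the two PCs
that best separate that ancestry (k ∈ {5, 10, 15, 20} by 10-fold CV);
*membership* is the fraction of the k nearest panel neighbors carrying the
ancestry label. A sample receives a GIA label iff exactly one ancestry's
membership exceeds 0.50 (continental) or 0.90 (subcontinental), else it is
Ambiguous.

**Admixture.** Unsupervised maximum likelihood on the binomial mixture

```
L(Q, F) = Σ_ij [ g_ij log Σ_k q_ik f_kj + (2 − g_ij) log Σ_k q_ik (1 − f_kj) ]
```

via EM block updates of the N×K proportions Q and the K×M component
frequencies F, with restarts and a provably monotone likelihood.

**Relatedness.** KING-robust pairwise kinship φ (0.5 duplicates, 0.25
first degree, ~0 unrelated; degree cutoffs 0.0884 and 0.0442), greedy
unrelated-set selection, and duplicate resolution.

**IBD communities.** Pairwise segments (cM) summed per pair, relatives
filtered, InfoMap community detection on the weighted sharing graph.

**Associations.** Logistic regression throughout
(`logit(phecode) = β0 + β1·group + β2·sex + β3·age [+ β4·SIRE]`),
inverse-variance fixed-effects meta-analysis (β = Σwβ/Σw, w = 1/SE²),
Bonferroni thresholds α/#tests, genomic-control λ (median χ²/0.4549), and
effective sample size N_eff = 2/(1/N_cases + 1/N_controls).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a three-population reference panel and an admixed study cohort,
assign continental GIA, and recover admixture proportions:

```python
import numpy as np
from ehrgenpop import synthdata as sd, genoqc as gq, ancestry as anc

model = sd.PopulationModel.simulate(K=3, M=2000, fst=0.1, seed=7)
panel = sd.simulate_reference_panel(model, 150, seed=8, pop_names=["EUR", "AFR", "EAS"])
spec = sd.CohortSpec(
    groups=[
        sd.GroupSpec("euro", 200, [40, 0.3, 0.3], sire="NH-White"),
        sd.GroupSpec("afro", 120, [0.3, 40, 0.3], sire="NH-AfAm"),
        sd.GroupSpec("easia", 120, [0.3, 0.3, 40], sire="NH-Asian"),
        sd.GroupSpec("admix", 60, [5, 5, 0.3], sire="NH-AfAm"),
    ],
)
study, truth, demo = sd.simulate_admixed_cohort(model, spec, seed=9)

merged = gq.maf_filter(gq.align_to_reference(study, panel), 0.01)
_, scores = anc.fit_pca(merged, n_pc=10)
labels = panel.samples.set_index("id")["population"]
gia = anc.assign_continental_gia(scores, labels, seed=0)
print(gia.table["label"].value_counts().to_string())
print("chosen k per ancestry:", gia.k_per_ancestry)

fit = anc.fit_admixture(study, K=3, seed=0, max_iter=600, n_init=2)
perm = anc.align_components(fit.Q, truth.q)
print(f"mean |Q_hat - Q_true| = {np.abs(fit.Q[:, perm] - truth.q).mean():.4f}")
```

Output:

```
EA           228
AA           148
EAA          120
Ambiguous      4
chosen k per ancestry: {'EUR': 20, 'AFR': 5, 'EAS': 5}
mean |Q_hat - Q_true| = 0.0681
```

The three anchored groups are assigned their expected GIA labels; the 60
half-European/half-African individuals split between the EA and AA calls
or come out Ambiguous, exactly the behavior a hard-threshold neighbor vote
should produce for genuinely admixed genomes; and the EM recovers the
planted ancestry proportions to ~0.07 mean absolute error (admixed
individuals carry the most per-genome sampling noise at M = 2000).

The full pipeline — synthetic cohort → QC → ancestry → IBD → phecodes →
association scan, with TSV outputs and a JSON manifest — runs from one
configuration:

```bash
ehrgenpop run-all --seed 1 --out run/
```

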